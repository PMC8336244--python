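"""Subject summaries, two-group comparisons, cohort descriptives.

One row per subject carries the three headline sleep biomarkers -- beta
(12-30 Hz) power by electrode group, spindle density, and percent SWS by
both definitions -- and groups are compared with two-sample pooled-variance
(Student's) t tests, with the conventional significance stars
(* p<0.05, ** p<0.01, *** p<0.001, **** p<0.0001).  A packaged clinical
characteristics table for the Dup15q cohort supports offline descriptive
statistics (mean/range of age, epilepsy and duplication-type counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .edf_io import Recording
from .params import PipelineParams
from .preprocess import preprocess_recording
from .spectral import ChannelGroups, band_power, group_channel_power, \
    spectrogram_epochs
from .spindle import build_valid_epochs, detect_spindles, spindle_density
from .sws import delta_epoch_series, detect_sws_auto, score_n3_aasm
from .synthetic import Hypnogram

__all__ = ["SubjectSummary", "GroupComparison", "summarize_subject",
           "analyze_subject", "compare_groups", "cohort_table_summary",
           "load_table1", "run_cohort", "comparisons_frame",
           "summaries_frame"]


# --------------------------------------------------------------------------
# Types
# --------------------------------------------------------------------------

@dataclass
class SubjectSummary:
    """Per-subject biomarker row; missing metrics are None, never zero."""

    subject_id: str
    group: str
    beta_power: dict[str, float]             # electrode group -> uV^2/Hz
    spindle_density: float | None            # events/min
    percent_sws_auto: dict[str, float]       # electrode group -> %
    percent_sws_aasm: float | None           # %
    effective_duration_h: float

    def __post_init__(self) -> None:
        for v in self.beta_power.values():
            if v < 0:
                raise ValueError("beta power must be >= 0")
        if self.spindle_density is not None and self.spindle_density < 0:
            raise ValueError("spindle density must be >= 0")
        for v in list(self.percent_sws_auto.values()) + \
                ([self.percent_sws_aasm]
                 if self.percent_sws_aasm is not None else []):
            if not 0 <= v <= 100:
                raise ValueError("percentages must be within [0, 100]")


@dataclass
class GroupComparison:
    metric: str
    t_statistic: float
    degrees_of_freedom: int
    p_value: float
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    n_a: int
    n_b: int
    stars: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p value must be in [0, 1]")


def significance_stars(p: float) -> str:
    for thresh, mark in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"),
                         (0.05, "*")):
        if p < thresh:
            return mark
    return ""


# --------------------------------------------------------------------------
# Per-subject pipeline
# --------------------------------------------------------------------------

def summarize_subject(subject_id: str, group: str,
                      beta: dict[str, float],
                      density: float | None,
                      sws_auto: dict[str, float],
                      sws_aasm: float | None,
                      duration_h: float) -> SubjectSummary:
    if not group:
        raise ValueError("group label is required")
    return SubjectSummary(subject_id, group, dict(beta), density,
                          dict(sws_auto), sws_aasm, duration_h)


def analyze_subject(rec: Recording, hypnogram: Hypnogram | None = None,
                    params: PipelineParams | None = None,
                    groups: ChannelGroups | None = None,
                    subject_id: str = "", group: str = "NA",
                    preprocess: bool = True) -> SubjectSummary:
    """Full biomarker pipeline for one recording.

    Cleans the recording (unless ``preprocess=False``), then computes beta
    power per electrode group, spindle density over artifact-free sleep,
    and percent SWS by the delta-threshold (per group) and AASM methods.
    """
    params = params or PipelineParams()
    groups = (groups or ChannelGroups()).restrict_to(rec.channel_labels)
    if preprocess:
        clean, mask, _report = preprocess_recording(rec, params)
    else:
        from .preprocess import ArtifactMask
        clean, mask = rec, ArtifactMask.empty(rec.n_samples, rec.fs)

    spec = spectrogram_epochs(clean, params)
    beta = group_channel_power(band_power(spec, params.beta_band), groups,
                               mask, epoch_len_s=params.tf_win_s)

    valid = build_valid_epochs(mask, hypnogram, params)
    events = detect_spindles(clean, mask, valid, params)
    density, _ = spindle_density(events, valid)

    delta = delta_epoch_series(clean, params, groups)
    sws_auto = {name: detect_sws_auto(delta, params, group=name).percent_sws
                for name in groups.as_dict()}

    n_ep = clean.n_samples // int(round(params.sws_epoch_s * clean.fs))
    if hypnogram is not None:
        sleep = hypnogram.sleep_mask()[:n_ep]
        sleep = np.pad(sleep, (0, n_ep - sleep.size))
    else:
        sleep = np.ones(n_ep, dtype=bool)
    aasm = score_n3_aasm(clean, sleep, params, groups).percent_sws

    return summarize_subject(subject_id, group, beta, density, sws_auto,
                             aasm, clean.duration_s / 3600.0)


# --------------------------------------------------------------------------
# Group comparison
# --------------------------------------------------------------------------

def compare_groups(a, b, metric: str = "",
                   welch: bool = False) -> GroupComparison:
    """Two-sample t test (pooled-variance Student's by default).

    Two-sided p from the t distribution with ``n_a + n_b - 2`` degrees of
    freedom (pooled).  Zero pooled variance with equal means yields
    t = 0, p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("group values must be finite")
    df = a.size + b.size - 2
    sp2 = (((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
           / df)
    if sp2 == 0 and not welch:
        if a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t = np.inf if a.mean() > b.mean() else -np.inf
            p = 0.0
    else:
        res = sstats.ttest_ind(a, b, equal_var=not welch)
        t, p = float(res.statistic), float(res.pvalue)
        if welch:
            df = int(np.floor(res.df))
    return GroupComparison(metric, t, df, p,
                           float(a.mean()), float(a.std(ddof=1)),
                           float(b.mean()), float(b.std(ddof=1)),
                           int(a.size), int(b.size),
                           stars=significance_stars(p))


# --------------------------------------------------------------------------
# Cohort descriptives (clinical characteristics table)
# --------------------------------------------------------------------------

def load_table1() -> pd.DataFrame:
    """Packaged Dup15q participant-characteristics table."""
    with resources.files("nddsleep").joinpath(
            "data/dup15q_table1.csv").open() as fh:
        return pd.read_csv(fh, keep_default_na=False)


def cohort_table_summary(table: pd.DataFrame) -> dict:
    """Descriptive statistics of a participant-characteristics table."""
    if len(table) == 0:
        raise ValueError("empty cohort table")
    ages = table["age_months"].astype(float)
    if (ages <= 0).any():
        raise ValueError("age_months must be positive")
    epilepsy = table["epilepsy"].str.lower().value_counts().to_dict()
    dup = table["duplication_type"].str.lower().value_counts().to_dict()
    return {
        "n": int(len(table)),
        "mean_age_years": round(float(ages.mean()) / 12.0, 2),
        "age_range_months": (int(ages.min()), int(ages.max())),
        "age_range_years": (int(ages.min() // 12), int(ages.max() // 12)),
        "epilepsy_counts": epilepsy,
        "duplication_counts": dup,
    }


# --------------------------------------------------------------------------
# Cohort-level assembly
# --------------------------------------------------------------------------

def run_cohort(subjects: list[tuple[str, str, Recording, object]],
               params: PipelineParams | None = None,
               groups: ChannelGroups | None = None,
               preprocess: bool = True) -> list[SubjectSummary]:
    """Analyze every ``(subject_id, group, recording, truth)`` tuple.

    The fourth element, when it carries a ``hypnogram`` attribute (as the
    synthetic ground truth does), restricts spindle/AASM analysis to sleep.
    """
    out = []
    for sid, grp, rec, truth in subjects:
        hyp = getattr(truth, "hypnogram", None)
        out.append(analyze_subject(rec, hyp, params, groups,
                                   subject_id=sid, group=grp,
                                   preprocess=preprocess))
    return out


def summaries_frame(summaries: list[SubjectSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {"subject_id": s.subject_id, "group": s.group,
               "spindle_density": s.spindle_density,
               "percent_sws_aasm": s.percent_sws_aasm,
               "effective_duration_h": s.effective_duration_h}
        for g, v in s.beta_power.items():
            row[f"beta_{g}"] = v
        for g, v in s.percent_sws_auto.items():
            row[f"sws_auto_{g}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def comparisons_frame(summaries: list[SubjectSummary],
                      group_a: str, group_b: str) -> pd.DataFrame:
    """Pooled-variance t tests of every biomarker column, A vs B."""
    df = summaries_frame(summaries)
    metrics = [c for c in df.columns
               if c.startswith(("beta_", "sws_auto_"))
               or c in ("spindle_density", "percent_sws_aasm")]
    rows = []
    for m in metrics:
        sub = df[df[m].notna()]
        a = sub.loc[sub.group == group_a, m].to_numpy()
        b = sub.loc[sub.group == group_b, m].to_numpy()
        if a.size < 2 or b.size < 2:
            continue
        c = compare_groups(a, b, metric=m)
        rows.append({"metric": m, "t": c.t_statistic,
                     "df": c.degrees_of_freedom, "p": c.p_value,
                     f"mean_{group_a}": c.mean_a, f"sd_{group_a}": c.sd_a,
                     f"mean_{group_b}": c.mean_b, f"sd_{group_b}": c.sd_b,
                     "stars": c.stars})
    return pd.DataFrame(rows)
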