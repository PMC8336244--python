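"""Pipeline parameters.

Every numeric constant used anywhere in the pipeline lives here, as a field
of :class:`PipelineParams`, so that no analysis stage re-declares a literal
threshold.  Defaults encode the published analysis settings this package
re-implements: 1-50 Hz band-pass, four bad-channel criteria, burst
suppression at 20x the calibration RMS, 60-s/30-s Hann spectrogram epochs,
the 11-16 Hz sigma relative-power spindle detector with its morphological
rules, and the delta-threshold / AASM slow-wave-sleep quantifiers.

Clock times (``night_start``, ``night_end``) are stored as seconds since
midnight; recordings are assumed to span a single local night, so the
window 22:00 -> 05:00 crosses midnight.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

__all__ = ["PipelineParams", "load_params", "parse_clock"]


def parse_clock(value: str | float | int) -> float:
    """Parse a clock time into seconds since midnight.

    Accepts ``"HH:MM"`` or ``"HH:MM:SS"`` strings, or a bare number of
    seconds.  Values must land in [0, 86400).
    """
    if isinstance(value, (int, float)):
        secs = float(value)
    else:
        m = re.fullmatch(r"(\d{1,2}):(\d{2})(?::(\d{2}))?", value.strip())
        if m is None:
            raise ValueError(f"cannot parse clock time {value!r}")
        h, mi, s = int(m.group(1)), int(m.group(2)), int(m.group(3) or 0)
        if h > 23 or mi > 59 or s > 59:
            raise ValueError(f"clock time out of range: {value!r}")
        secs = h * 3600.0 + mi * 60.0 + s
    if not 0.0 <= secs < 86400.0:
        raise ValueError(f"clock time must be in [0, 86400) s, got {secs}")
    return secs


def _fmt_clock(seconds: float) -> str:
    s = int(round(seconds))
    return f"{s // 3600:02d}:{s % 3600 // 60:02d}:{s % 60:02d}"


@dataclass(frozen=True)
class PipelineParams:
    """All tunable constants of the sleep-EEG biomarker pipeline.

    Units are given per field; frequencies in Hz, durations in seconds,
    amplitudes in microvolts.
    """

    # --- band-pass filtering -------------------------------------------------
    hp_hz: float = 1.0          #: high-pass edge (Hz)
    lp_hz: float = 50.0         #: low-pass edge (Hz)
    line_hz: float = 60.0       #: power-line frequency (Hz)

    # --- bad-channel criteria ------------------------------------------------
    bad_power_sd: float = 3.0       #: |z| of log 1-50 Hz power across channels
    bad_flat_s: float = 5.0         #: flat (zero) run longer than this flags FLAT
    bad_corr_r: float = 0.7         #: min Pearson r vs neighbour reconstruction
    bad_linenoise_sd: float = 4.0   #: z of line/broadband power ratio across channels
    neighbor_radius: float = 1.0    #: neighbour chord distance on the unit-radius scalp

    # --- burst suppression ---------------------------------------------------
    burst_cutoff: float = 20.0      #: window-RMS multiple of calibration RMS

    # --- spectrogram epochs --------------------------------------------------
    tf_win_s: float = 60.0          #: Hann window length (s)
    tf_overlap_s: float = 30.0      #: window overlap (s); hop = win - overlap

    # --- frequency bands (lo, hi) in Hz -------------------------------------
    beta_band: tuple[float, float] = (12.0, 30.0)
    delta_band: tuple[float, float] = (1.0, 4.0)
    sigma_band: tuple[float, float] = (11.0, 16.0)
    broadband: tuple[float, float] = (1.0, 30.0)

    # --- spindle detection ---------------------------------------------------
    spindle_win_s: float = 2.0          #: sliding window (s)
    spindle_win_shift_s: float = 0.2    #: window hop (s)
    spindle_relpow_thresh: float = 0.20  #: sigma/broadband power fraction kept
    spindle_merge_gap_s: float = 0.5    #: candidates closer than this merge
    spindle_min_dur_s: float = 0.5
    spindle_max_dur_s: float = 2.0
    spindle_consolidate_s: float = 0.3  #: cross-channel start-time consolidation
    min_valid_epoch_s: float = 120.0    #: artifact-free sleep run floor (s)

    # --- slow-wave sleep -----------------------------------------------------
    sws_epoch_s: float = 30.0        #: delta-series epoch length (s)
    sws_baseline_frac: float = 0.5   #: lowest-delta fraction forming the baseline
    sws_sd_mult: float = 1.0         #: threshold = baseline mean + mult * SD
    sws_min_run_epochs: int = 32     #: min consecutive high-delta epochs (16 min)
    aasm_sw_band: tuple[float, float] = (0.5, 2.0)
    aasm_sw_amp_uv: float = 75.0     #: slow-wave peak-to-peak criterion (uV)
    aasm_occupancy_frac: float = 0.20  #: of a 30-s epoch that must be slow waves

    # --- overnight analysis window (seconds since midnight) ------------------
    night_start: float = 22 * 3600.0
    night_end: float = 5 * 3600.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Raise ``ValueError`` naming the offending key on any bad value."""
        for key in ("hp_hz", "lp_hz", "line_hz"):
            if getattr(self, key) <= 0:
                raise ValueError(f"{key}: frequency must be positive")
        if self.hp_hz >= self.lp_hz:
            raise ValueError("hp_hz: must be below lp_hz")
        for key in ("beta_band", "delta_band", "sigma_band", "broadband",
                    "aasm_sw_band"):
            lo, hi = getattr(self, key)
            if lo <= 0 and key != "aasm_sw_band":
                if lo < 0:
                    raise ValueError(f"{key}: band edges must be positive")
            if not lo < hi:
                raise ValueError(f"{key}: band lower edge must be < upper edge")
        sl, sh = self.sigma_band
        bl, bh = self.broadband
        if not (bl <= sl and sh <= bh):
            raise ValueError("sigma_band: must be nested inside broadband")
        for key in ("spindle_relpow_thresh", "sws_baseline_frac",
                    "aasm_occupancy_frac"):
            v = getattr(self, key)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{key}: fraction must be in (0, 1)")
        for key in ("bad_power_sd", "bad_flat_s", "bad_corr_r",
                    "bad_linenoise_sd", "burst_cutoff", "tf_win_s",
                    "spindle_win_s", "spindle_win_shift_s",
                    "spindle_merge_gap_s", "spindle_min_dur_s",
                    "spindle_max_dur_s", "spindle_consolidate_s",
                    "min_valid_epoch_s", "sws_epoch_s", "aasm_sw_amp_uv",
                    "neighbor_radius", "sws_sd_mult"):
            if getattr(self, key) <= 0:
                raise ValueError(f"{key}: must be positive")
        if self.tf_overlap_s < 0 or self.tf_overlap_s >= self.tf_win_s:
            raise ValueError("tf_overlap_s: must be in [0, tf_win_s)")
        if not self.spindle_min_dur_s < self.spindle_max_dur_s:
            raise ValueError(
                "spindle_min_dur_s: must be below spindle_max_dur_s")
        if int(self.sws_min_run_epochs) < 1:
            raise ValueError("sws_min_run_epochs: must be >= 1")
        for key in ("night_start", "night_end"):
            v = getattr(self, key)
            if not 0.0 <= v < 86400.0:
                raise ValueError(f"{key}: must be in [0, 86400) seconds")

    # --- (de)serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["night_start"] = _fmt_clock(self.night_start)
        d["night_end"] = _fmt_clock(self.night_end)
        return d

    def replace(self, **kwargs) -> "PipelineParams":
        return dataclasses.replace(self, **kwargs)

    def provenance_lines(self) -> list[str]:
        """``key = value`` lines echoing the effective parameters."""
        return [f"{k} = {v}" for k, v in sorted(self.to_dict().items())]


_TUPLE_FIELDS = {"beta_band", "delta_band", "sigma_band", "broadband",
                 "aasm_sw_band"}
_CLOCK_FIELDS = {"night_start", "night_end"}
_INT_FIELDS = {"sws_min_run_epochs"}
_FIELD_NAMES = {f.name for f in dataclasses.fields(PipelineParams)}


def _coerce(key: str, raw) -> object:
    try:
        if key in _CLOCK_FIELDS:
            return parse_clock(raw)
        if key in _TUPLE_FIELDS:
            if isinstance(raw, str):
                parts = [p for p in re.split(r"[,\s]+", raw.strip("()[] ")) if p]
            else:
                parts = list(raw)
            if len(parts) != 2:
                raise ValueError("expected two band edges")
            return (float(parts[0]), float(parts[1]))
        if key in _INT_FIELDS:
            return int(raw)
        return float(raw)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{key}: cannot parse {raw!r} ({exc})") from None


def load_params(config_source: Mapping | str | Path | None = None) -> PipelineParams:
    """Build a :class:`PipelineParams` from a config mapping or file.

    ``config_source`` may be ``None`` (all defaults), a mapping, or a path to
    a text file of ``key = value`` lines (``#`` comments allowed; band values
    written as ``lo, hi``; clock times as ``HH:MM``).  Unknown keys and
    invalid values raise ``ValueError`` naming the key.
    """
    if config_source is None:
        return PipelineParams()
    if isinstance(config_source, (str, Path)):
        items: dict[str, object] = {}
        for lineno, line in enumerate(
                Path(config_source).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line or line.startswith("["):
                continue
            if "=" not in line:
                raise ValueError(
                    f"{config_source}:{lineno}: expected 'key = value'")
            key, _, raw = line.partition("=")
            items[key.strip()] = raw.strip()
        config_source = items
    overrides = {}
    for key, raw in dict(config_source).items():
        if key not in _FIELD_NAMES:
            raise ValueError(f"{key}: unknown parameter")
        overrides[key] = _coerce(key, raw)
    return PipelineParams(**overrides)
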