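"""Epoch-wise time-frequency analysis and band power.

Power spectral density is computed per channel in 60-s Hann-tapered
segments with a 30-s hop (one-sided, density normalization, uV^2/Hz).
Band power is the mean PSD over the band's frequency bins -- "absolute"
power, not relative -- and per-subject scalars aggregate channels within
the frontal/central/occipital electrode groups and then epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .edf_io import Recording
from .params import PipelineParams
from .preprocess import ArtifactMask

__all__ = ["EpochSpectra", "EpochBandPower", "ChannelGroups",
           "spectrogram_epochs", "band_power", "group_channel_power"]


@dataclass
class EpochSpectra:
    """PSD per spectrogram epoch: power is (epochs, channels, freqs)."""

    epoch_start_s: np.ndarray
    freqs_hz: np.ndarray
    power: np.ndarray
    channel_labels: list[str]

    @property
    def n_epochs(self) -> int:
        return self.power.shape[0]


@dataclass
class EpochBandPower:
    """Mean PSD over a band's bins: values is (epochs, channels), uV^2/Hz."""

    band: tuple[float, float]
    values: np.ndarray
    epoch_start_s: np.ndarray
    channel_labels: list[str]


@dataclass(frozen=True)
class ChannelGroups:
    """Frontal / central / occipital electrode groups (disjoint)."""

    frontal: tuple[str, ...] = ("Fp1", "Fp2", "F3", "F4", "F7", "F8", "Fz")
    central: tuple[str, ...] = ("C3", "C4", "Cz")
    occipital: tuple[str, ...] = ("O1", "O2")

    def __post_init__(self) -> None:
        all_labels = [*self.frontal, *self.central, *self.occipital]
        if len(set(all_labels)) != len(all_labels):
            raise ValueError("channel groups must be disjoint")

    def as_dict(self) -> dict[str, tuple[str, ...]]:
        return {"frontal": self.frontal, "central": self.central,
                "occipital": self.occipital}

    def restrict_to(self, montage: list[str]) -> "ChannelGroups":
        """Drop labels absent from ``montage``; error on an empty group."""
        out = {}
        for name, labs in self.as_dict().items():
            kept = tuple(l for l in labs if l in montage)
            if not kept:
                raise ValueError(f"channel group {name!r} has no channel "
                                 f"in the montage")
            out[name] = kept
        return ChannelGroups(**out)


def spectrogram_epochs(rec: Recording,
                       params: PipelineParams) -> EpochSpectra:
    """Hann-tapered one-sided PSD per 60-s segment, 30-s hop.

    Density normalization: integrating PSD x bin width over frequency
    recovers the signal variance (Parseval).  Epoch count is
    floor((T - win) / hop) + 1.
    """
    nper = int(round(params.tf_win_s * rec.fs))
    nover = int(round(params.tf_overlap_s * rec.fs))
    if rec.n_samples < nper:
        raise ValueError(
            f"recording ({rec.duration_s:.0f} s) shorter than one "
            f"{params.tf_win_s:.0f}-s window")
    freqs, t, sxx = sps.spectrogram(
        rec.signal, rec.fs, window=sps.get_window("hann", nper),
        noverlap=nover, nperseg=nper, scaling="density", mode="psd",
        detrend=False, axis=1)
    power = np.moveaxis(sxx, 2, 0)                  # (epochs, channels, freqs)
    starts = t - params.tf_win_s / 2.0              # scipy returns centres
    return EpochSpectra(starts, freqs, power, list(rec.channel_labels))


def band_power(spec: EpochSpectra,
               band: tuple[float, float]) -> EpochBandPower:
    """Mean PSD over bins with lo <= f <= hi, per epoch per channel."""
    lo, hi = band
    if lo >= hi:
        raise ValueError(f"band lower edge must be < upper edge: {band}")
    sel = (spec.freqs_hz >= lo) & (spec.freqs_hz <= hi)
    if not sel.any():
        raise ValueError(
            f"band {band} Hz contains no frequency bins "
            f"(spectrum spans 0-{spec.freqs_hz[-1]:.1f} Hz)")
    values = spec.power[:, :, sel].mean(axis=2)
    return EpochBandPower((lo, hi), values, spec.epoch_start_s,
                          spec.channel_labels)


def group_channel_power(bp: EpochBandPower, groups: ChannelGroups,
                        mask: ArtifactMask | None = None,
                        epoch_len_s: float = 60.0) -> dict[str, float]:
    """One scalar per electrode group: channel mean, then epoch mean.

    Epochs with more than half their samples artifact-masked are excluded.
    Raises ``ValueError`` naming the group when nothing survives.
    """
    if mask is not None:
        frac = mask.epoch_masked_fraction(bp.epoch_start_s, epoch_len_s)
        keep = frac <= 0.5
    else:
        keep = np.ones(len(bp.epoch_start_s), dtype=bool)
    out: dict[str, float] = {}
    for name, labels in groups.as_dict().items():
        idx = [bp.channel_labels.index(l) for l in labels
               if l in bp.channel_labels]
        if not idx:
            raise ValueError(f"group {name!r}: no channels in montage")
        vals = bp.values[keep][:, idx]
        if vals.size == 0:
            raise ValueError(f"group {name!r}: no unmasked epochs to average")
        out[name] = float(vals.mean(axis=1).mean())
    return out
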