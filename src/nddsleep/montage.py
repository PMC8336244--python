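"""Standard 10-20 scalp geometry.

A frozen table of 10-20 electrode positions (head frame, metres; matches the
standard montage shipped with MNE), normalized here to the unit sphere so
neighbour distances are expressed in head-radius units.  Adjacent 10-20
electrodes sit 0.6-0.8 head-radius units apart (chord), next-nearest at
>= 1.2, so the default neighbour radius of 1.0 cleanly separates the two.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MONTAGE_1020", "DEFAULT_MONTAGE_19", "unit_positions",
           "neighbor_weights", "is_1020_label"]

# x: left(-) -> right(+), y: back(-) -> front(+), z: up.
MONTAGE_1020: dict[str, tuple[float, float, float]] = {
    "Fp1": (-0.0294367, 0.0839171, -0.00699),
    "Fp2": (0.0298723, 0.0848959, -0.00708),
    "F7": (-0.0702629, 0.0424743, -0.01142),
    "F3": (-0.0502438, 0.0531112, 0.042192),
    "Fz": (0.0003122, 0.058512, 0.066462),
    "F4": (0.0518362, 0.0543048, 0.040814),
    "F8": (0.0730431, 0.0444217, -0.012),
    "T3": (-0.0841611, -0.0160187, -0.009346),
    "C3": (-0.0653581, -0.0116317, 0.064358),
    "Cz": (0.0004009, -0.009167, 0.100244),
    "C4": (0.0671179, -0.0109003, 0.06358),
    "T4": (0.0850799, -0.0150203, -0.00949),
    "T5": (-0.0724343, -0.0734527, -0.002487),
    "P3": (-0.0530073, -0.0787878, 0.05594),
    "Pz": (0.0003247, -0.081115, 0.082615),
    "P4": (0.0556667, -0.0785602, 0.056561),
    "T6": (0.0730557, -0.0730683, -0.00254),
    "O1": (-0.0294134, -0.112449, 0.008839),
    "O2": (0.0298426, -0.112156, 0.0088),
}

# Modern equivalents accepted as aliases.
_ALIASES = {"T7": "T3", "T8": "T4", "P7": "T5", "P8": "T6"}

#: The 19-electrode referential montage used throughout the synthetic cohort.
DEFAULT_MONTAGE_19: list[str] = list(MONTAGE_1020)


def _canonical(label: str) -> str:
    lab = label.strip()
    return _ALIASES.get(lab, lab)


def is_1020_label(label: str) -> bool:
    return _canonical(label) in MONTAGE_1020


def unit_positions(labels: list[str]) -> np.ndarray:
    """(n, 3) electrode positions projected onto the unit sphere."""
    pos = []
    for lab in labels:
        key = _canonical(lab)
        if key not in MONTAGE_1020:
            raise ValueError(f"unknown 10-20 channel label: {lab!r}")
        p = np.asarray(MONTAGE_1020[key], dtype=float)
        pos.append(p / np.linalg.norm(p))
    return np.asarray(pos)


def neighbor_weights(labels: list[str], index: int,
                     radius: float = 1.0,
                     exclude: set[int] | None = None) -> dict[int, float]:
    """Inverse-distance weights of ``labels[index]``'s spatial neighbours.

    Neighbours are channels within ``radius`` head-radius units (chord
    distance on the unit sphere), excluding the channel itself and any index
    in ``exclude``.  Weights are normalized to sum to 1.  Empty dict when no
    neighbour qualifies.
    """
    pos = unit_positions(labels)
    exclude = exclude or set()
    d = np.linalg.norm(pos - pos[index], axis=1)
    w: dict[int, float] = {}
    for j in range(len(labels)):
        if j == index or j in exclude:
            continue
        if 0 < d[j] <= radius:
            w[j] = 1.0 / d[j]
    total = sum(w.values())
    return {j: v / total for j, v in w.items()} if total else {}
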