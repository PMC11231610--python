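"""Kyte–Doolittle hydropathy and Zimmermann polarity of protein sequences.

Two whole-sequence summaries are provided: the plain residue-index sum
(:func:`total_index`) and the sum over the centred sliding-window profile
(:func:`profile_sum`).  The windowed profile follows the ProtScale
convention — value at position i is the unweighted mean of the scale values
over a centred window — so the profile has ``len − window + 1`` positions
and ``window = 1`` reproduces the raw per-residue values.  Whole-protein
hydropathy figures quoted in the lipid-transport literature are typically
the window-9 profile sums, which differ from the raw sums by the
edge-residue under-coverage of the sliding window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import SequenceError

__all__ = ["SequenceRecord", "HydropathyScale", "KYTE_DOOLITTLE",
           "ZIMMERMANN_POLARITY", "total_index", "window_profile", "profile_sum"]

_CANONICAL = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class SequenceRecord:
    """A protein sequence with its identifier; canonical residues only."""

    id: str
    residues: str

    def __post_init__(self):
        object.__setattr__(self, "residues", self.residues.upper())
        for i, ch in enumerate(self.residues):
            if ch not in _CANONICAL:
                raise SequenceError(
                    f"record {self.id!r}: non-canonical residue {ch!r} at "
                    f"position {i + 1}")

    def __len__(self):
        return len(self.residues)


@dataclass(frozen=True)
class HydropathyScale:
    name: str
    values: dict[str, float]

    def __post_init__(self):
        missing = _CANONICAL - set(self.values)
        if missing:
            raise ValueError(f"scale {self.name} missing residues {sorted(missing)}")


#: Kyte & Doolittle hydropathy indices (positive = hydrophobic)
KYTE_DOOLITTLE = HydropathyScale("kyte_doolittle", {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
})

#: Zimmermann polarity grades (large = polar/charged)
ZIMMERMANN_POLARITY = HydropathyScale("zimmermann_polarity", {
    "A": 0.00, "R": 52.00, "N": 3.38, "D": 49.70, "C": 1.48,
    "Q": 3.53, "E": 49.90, "G": 0.00, "H": 51.60, "I": 0.13,
    "L": 0.13, "K": 49.50, "M": 1.43, "F": 0.35, "P": 1.58,
    "S": 1.67, "T": 1.66, "W": 2.10, "Y": 1.61, "V": 0.13,
})


def _values(seq: SequenceRecord, scale: HydropathyScale) -> np.ndarray:
    return np.array([scale.values[ch] for ch in seq.residues], float)


def total_index(seq: SequenceRecord, scale: HydropathyScale) -> float:
    """Sum of per-residue scale values over the whole sequence (0 if empty)."""
    if len(seq) == 0:
        return 0.0
    return float(_values(seq, scale).sum())


def window_profile(seq: SequenceRecord, scale: HydropathyScale,
                   window: int = 9) -> np.ndarray:
    """Centred sliding-window mean profile (ProtScale-style, linear weights).

    Output length is ``len(seq) − window + 1``; ``window`` must be odd,
    positive and no longer than the sequence.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd positive integer")
    if window > len(seq):
        raise ValueError(f"window {window} exceeds sequence length {len(seq)}")
    v = _values(seq, scale)
    kernel = np.full(window, 1.0 / window)
    return np.convolve(v, kernel, mode="valid")


def profile_sum(seq: SequenceRecord, scale: HydropathyScale,
                window: int = 9) -> float:
    """Sum of the sliding-window profile — the conventional whole-protein
    hydropathy figure (window 9 by default)."""
    return float(window_profile(seq, scale, window).sum())
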