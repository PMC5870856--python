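"""Sliding-window profiles and transmembrane-segment detection.

Three per-position quantities are profiled over a window centred at each
residue: mean Kyte-Doolittle hydropathy, signed Henderson-Hasselbalch net
charge at pH 7 summed over the window (termini excluded), and fold
propensity (the Uversky-boundary distance applied to the window residues).
Only full windows are reported — no residues are invented at the edges —
so a window of w covers centres ceil(w/2) .. L - floor(w/2) (1-based).

The transmembrane rule operates on the hydropathy profile: a protein is
flagged when any 21-residue window has mean hydropathy strictly above 1.6.
Sequences shorter than the window cannot be tested and are never flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .scales import EMBOSS_PKA, KYTE_DOOLITTLE, PKaSet, ScaleTable
from .seqio import ProteinSequence
from .features import UVERSKY_INTERCEPT, UVERSKY_SLOPE

PROFILE_KINDS = ("hydropathy", "fold_propensity", "net_charge")

#: The only window length stated by the transmembrane rule; used as the
#: default for all three profile kinds so the plots are comparable.
DEFAULT_WINDOW = 21

TM_THRESHOLD = 1.6


@dataclass(frozen=True)
class Profile:
    """Windowed per-position values for one sequence."""

    kind: str
    window: int
    centers: np.ndarray  # 1-based residue indices of window centres
    values: np.ndarray
    too_short: bool = False  # sequence shorter than the window

    def __len__(self) -> int:
        return len(self.centers)


@dataclass(frozen=True)
class TMResult:
    """Outcome of the transmembrane screen."""

    flag: bool
    centers: tuple[int, ...] = ()  # 1-based centres of offending windows
    too_short: bool = False  # sequence shorter than the window: untestable


def _check_window(window: int) -> None:
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be an odd integer >= 3, got {window}")


def _per_residue_charge(residues: str, pka: PKaSet) -> np.ndarray:
    """Signed Henderson-Hasselbalch charge of each residue at pH 7."""
    charge_of = {aa: 0.0 for aa in set(residues)}
    for aa in PKaSet.ACIDIC:
        charge_of[aa] = -1.0 / (1.0 + 10.0 ** (pka.side_chain[aa] - 7.0))
    for aa in PKaSet.BASIC:
        charge_of[aa] = 1.0 / (1.0 + 10.0 ** (7.0 - pka.side_chain[aa]))
    return np.array([charge_of.get(aa, 0.0) for aa in residues])


def _window_sums(x: np.ndarray, window: int) -> np.ndarray:
    return np.lib.stride_tricks.sliding_window_view(x, window).sum(axis=-1)


def windowed_profile(
    seq: ProteinSequence | str,
    kind: str,
    window: int = DEFAULT_WINDOW,
    pka: PKaSet = EMBOSS_PKA,
) -> Profile:
    """Compute a windowed profile of the requested kind.

    Each value equals the corresponding whole-sequence feature evaluated on
    the window's substring (hydropathy: window mean; net_charge: signed sum
    over the window, termini excluded; fold_propensity: the boundary
    distance of the window residues).
    """
    if kind not in PROFILE_KINDS:
        raise ValueError(f"kind must be one of {PROFILE_KINDS}, got {kind!r}")
    _check_window(window)
    residues = seq.residues if isinstance(seq, ProteinSequence) else seq
    n = len(residues)
    if n < window:
        return Profile(kind, window, np.array([], dtype=int), np.array([]), too_short=True)
    centers = np.arange((window + 1) // 2, n - window // 2 + 1)
    if kind == "hydropathy":
        kd = np.array([KYTE_DOOLITTLE[aa] for aa in residues])
        values = _window_sums(kd, window) / window
    elif kind == "net_charge":
        values = _window_sums(_per_residue_charge(residues, pka), window)
    else:  # fold_propensity
        kd = np.array([KYTE_DOOLITTLE[aa] for aa in residues])
        h_norm = (_window_sums(kd, window) / window + 4.5) / 9.0
        mean_abs_charge = np.abs(_window_sums(_per_residue_charge(residues, pka), window)) / window
        values = h_norm - (mean_abs_charge + UVERSKY_INTERCEPT) / UVERSKY_SLOPE
    return Profile(kind, window, centers, values)


def detect_tm(
    seq: ProteinSequence | str,
    window: int = DEFAULT_WINDOW,
    threshold: float = TM_THRESHOLD,
    scale: ScaleTable | None = None,
) -> TMResult:
    """Screen for a predicted transmembrane segment.

    Flags the sequence iff some full window of ``window`` residues has mean
    hydropathy strictly greater than ``threshold``.  A sequence shorter
    than the window is reported as too short to test and never flagged.
    The prediction pipeline still scores flagged sequences; the flag is a
    warning that the solubility model is not valid for membrane proteins.
    """
    _check_window(window)
    scale = scale or KYTE_DOOLITTLE
    residues = seq.residues if isinstance(seq, ProteinSequence) else seq
    n = len(residues)
    if n < window:
        return TMResult(flag=False, too_short=True)
    values = _window_sums(np.array([scale[aa] for aa in residues]), window) / window
    hits = np.nonzero(values > threshold)[0]
    centers = tuple(int(i) + (window + 1) // 2 for i in hits)
    return TMResult(flag=len(centers) > 0, centers=centers)
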