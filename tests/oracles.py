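"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately written from first principles (character
counting, closed forms, grid scans, pair counting) and shares no code with
the implementation under test.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np

# Kyte-Doolittle values re-entered independently from the published table.
KD = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

# EMBOSS pKa values; acids carry -1 when deprotonated, bases +1 when protonated.
PKA_ACID = {"D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}
PKA_BASE = {"H": 6.5, "K": 10.8, "R": 12.5}
PKA_NTERM, PKA_CTERM = 8.6, 3.6


def composition(seq: str) -> dict[str, float]:
    counts = Counter(seq)
    return {aa: counts.get(aa, 0) / len(seq) for aa in "ACDEFGHIKLMNPQRSTVWY"}


def entropy(seq: str) -> float:
    counts = Counter(seq)
    n = len(seq)
    return -sum((c / n) * math.log(c / n) for c in counts.values()) / math.log(20)


def net_charge(seq: str, pH, termini: bool = True):
    """Charge at pH (scalar or numpy array) by per-residue summation."""
    charge = np.zeros_like(np.asarray(pH, dtype=float))
    for aa in seq:
        if aa in PKA_ACID:
            charge = charge - 1.0 / (1.0 + 10.0 ** (PKA_ACID[aa] - pH))
        elif aa in PKA_BASE:
            charge = charge + 1.0 / (1.0 + 10.0 ** (pH - PKA_BASE[aa]))
    if termini:
        charge = charge - 1.0 / (1.0 + 10.0 ** (PKA_CTERM - pH))
        charge = charge + 1.0 / (1.0 + 10.0 ** (pH - PKA_NTERM))
    return charge


def pI_grid(seq: str, coarse: float = 1e-3, fine: float = 1e-5) -> float:
    """Two-stage grid scan for the pH of zero charge (resolution ``fine``)."""
    grid = np.arange(0.0 + coarse, 14.0, coarse)
    charge = net_charge(seq, grid)
    i = int(np.argmin(np.abs(charge)))
    lo, hi = grid[i] - coarse, grid[i] + coarse
    grid2 = np.arange(lo, hi + fine, fine)
    charge2 = net_charge(seq, grid2)
    return float(grid2[int(np.argmin(np.abs(charge2)))])


def mean_scale(seq: str, scale: dict[str, float]) -> float:
    return sum(scale[aa] for aa in seq) / len(seq)


def fold_propensity(seq: str) -> float:
    h = (mean_scale(seq, KD) + 4.5) / 9.0
    r = abs(float(net_charge(seq, 7.0, termini=False))) / len(seq)
    return h - (r + 1.151) / 2.785


def auc_paircount(pred, labels) -> float:
    """AUC as the Mann-Whitney pair statistic, ties counted one half."""
    pred = list(map(float, pred))
    pos = [p for p, l in zip(pred, labels) if l == 1]
    neg = [p for p, l in zip(pred, labels) if l == 0]
    wins = sum(1.0 if p > q else (0.5 if p == q else 0.0) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))
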