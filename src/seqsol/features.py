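"""The 35 sequence features used by the solubility model.

The feature set comprises the 20 amino-acid composition fractions, 7 charge
and aromaticity composites formed from them (K-R, D-E, K+R, D+E, K+R-D-E,
K+R+D+E, F+W+Y), and 8 further sequence-derived quantities: length, pI,
mean Kyte-Doolittle hydropathy, per-residue absolute net charge at pH 7,
fold propensity (signed distance from the Uversky charge-hydropathy
boundary), mean disorder propensity, normalised Shannon entropy of the
composition, and mean beta-strand propensity.

Every feature is order-free (a function of residue counts only), which is
what makes the windowed profile values in :mod:`seqsol.profiles` exactly
consistent with whole-sequence features computed on window substrings.

Conventions
-----------
* Charge is modelled by Henderson-Hasselbalch titration of D, E, C, Y
  (acids) and H, K, R (bases); histidine contributes its small fractional
  positive charge at pH 7 rather than being treated as neutral.
* The pI includes the termini; the ``abs_charge`` feature and windowed net
  charge exclude them (windows are sequence-internal, and a per-residue
  charge with termini would be dominated by 1/L).
* ``abs_charge`` is normalised by length so it is on the same per-residue
  footing as the composition fractions.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .scales import (
    AMINO_ACIDS,
    CHOU_FASMAN_BETA,
    EMBOSS_PKA,
    KYTE_DOOLITTLE,
    PKaSet,
    ScaleTable,
    TOP_IDP,
)
from .seqio import ProteinSequence

#: Canonical ordering of the 35 feature names.  Composite names follow the
#: ``KmR`` (= K - R) / ``KpR`` (= K + R) display convention.
FEATURE_NAMES: tuple[str, ...] = tuple(AMINO_ACIDS) + (
    "KmR", "DmE", "KpR", "DpE", "KpRmDmE", "KpRpDpE", "FpWpY",
    "length", "pI", "hydropathy", "abs_charge", "fold_propensity",
    "disorder", "entropy", "beta_strand",
)

#: The Uversky boundary <R> = UVERSKY_SLOPE * <H> - UVERSKY_INTERCEPT
#: separating natively folded from intrinsically unstructured sequences in
#: the mean-net-charge / mean-hydrophobicity plane.
UVERSKY_SLOPE = 2.785
UVERSKY_INTERCEPT = 1.151

_LOG20 = math.log(20.0)


def _residues(seq: ProteinSequence | str) -> str:
    return seq.residues if isinstance(seq, ProteinSequence) else seq


def composition(seq: ProteinSequence | str) -> dict[str, float]:
    """Fraction of the sequence made up by each of the 20 residues."""
    residues = _residues(seq)
    n = len(residues)
    return {aa: residues.count(aa) / n for aa in AMINO_ACIDS}


def composites(comp: Mapping[str, float]) -> dict[str, float]:
    """The 7 composite features, as arithmetic on composition fractions."""
    k, r, d, e = comp["K"], comp["R"], comp["D"], comp["E"]
    return {
        "KmR": k - r,
        "DmE": d - e,
        "KpR": k + r,
        "DpE": d + e,
        "KpRmDmE": (k + r) - (d + e),
        "KpRpDpE": k + r + d + e,
        "FpWpY": comp["F"] + comp["W"] + comp["Y"],
    }


def sequence_entropy(comp: Mapping[str, float]) -> float:
    """Shannon entropy of the composition, normalised to [0, 1] by log 20.

    0 for a homopolymer, 1 when all 20 residues are used uniformly.  A
    whole-sequence, order-free measure of sequence complexity.
    """
    h = -sum(p * math.log(p) for p in comp.values() if p > 0.0)
    return h / _LOG20


def net_charge_at_pH(
    seq: ProteinSequence | str,
    pH: float,
    pka: PKaSet = EMBOSS_PKA,
    include_termini: bool = True,
) -> float:
    """Henderson-Hasselbalch net charge (elementary units) at the given pH.

    Acids (D, E, C, Y and the C-terminus) contribute -1/(1+10^(pKa-pH));
    bases (H, K, R and the N-terminus) contribute +1/(1+10^(pH-pKa)).
    """
    if not 0.0 < pH < 14.0:
        raise ValueError(f"pH must lie in (0, 14), got {pH}")
    residues = _residues(seq)
    charge = 0.0
    for aa in PKaSet.ACIDIC:
        count = residues.count(aa)
        if count:
            charge -= count / (1.0 + 10.0 ** (pka.side_chain[aa] - pH))
    for aa in PKaSet.BASIC:
        count = residues.count(aa)
        if count:
            charge += count / (1.0 + 10.0 ** (pH - pka.side_chain[aa]))
    if include_termini:
        charge -= 1.0 / (1.0 + 10.0 ** (pka.c_terminus - pH))
        charge += 1.0 / (1.0 + 10.0 ** (pH - pka.n_terminus))
    return charge


def isoelectric_point(seq: ProteinSequence | str, pka: PKaSet = EMBOSS_PKA) -> float:
    """pH at which the modelled net charge (termini included) is zero.

    Found by bisection on (0, 14); the net charge is strictly decreasing in
    pH, so the root is unique.  The interval is narrowed well below the
    1e-4 pH reporting tolerance so the residual charge is negligible.
    """
    residues = _residues(seq)
    lo, hi = 1e-9, 14.0 - 1e-9
    for _ in range(64):
        mid = 0.5 * (lo + hi)
        if net_charge_at_pH(residues, mid, pka) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def mean_scale(seq: ProteinSequence | str, scale: ScaleTable) -> float:
    """Arithmetic mean of a per-residue scale over the sequence."""
    residues = _residues(seq)
    return sum(residues.count(aa) * scale[aa] for aa in AMINO_ACIDS) / len(residues)


def fold_propensity(
    seq: ProteinSequence | str,
    pka: PKaSet = EMBOSS_PKA,
) -> float:
    """Signed distance from the Uversky charge-hydropathy boundary.

    ``FP = <H> - (<R> + 1.151)/2.785`` where ``<H>`` is the mean
    Kyte-Doolittle hydropathy rescaled to [0, 1] and ``<R>`` the mean
    absolute net charge per residue at pH 7 (termini excluded).  Positive
    values favour a compact fold; negative values place the sequence on the
    intrinsically-unstructured side of the boundary.
    """
    residues = _residues(seq)
    h_norm = (mean_scale(residues, KYTE_DOOLITTLE) + 4.5) / 9.0
    mean_abs_charge = abs(
        net_charge_at_pH(residues, 7.0, pka, include_termini=False)
    ) / len(residues)
    return h_norm - (mean_abs_charge + UVERSKY_INTERCEPT) / UVERSKY_SLOPE


def feature_vector(
    seq: ProteinSequence | str,
    pka: PKaSet = EMBOSS_PKA,
    disorder_scale: ScaleTable = TOP_IDP,
    beta_scale: ScaleTable = CHOU_FASMAN_BETA,
) -> dict[str, float]:
    """All 35 features for one sequence, keyed by :data:`FEATURE_NAMES`."""
    residues = _residues(seq)
    n = len(residues)
    comp = composition(residues)
    values: dict[str, float] = dict(comp)
    values.update(composites(comp))
    hyd = sum(comp[aa] * KYTE_DOOLITTLE[aa] for aa in AMINO_ACIDS)
    abs_charge = abs(net_charge_at_pH(residues, 7.0, pka, include_termini=False)) / n
    values["length"] = float(n)
    values["pI"] = isoelectric_point(residues, pka)
    values["hydropathy"] = hyd
    values["abs_charge"] = abs_charge
    values["fold_propensity"] = (hyd + 4.5) / 9.0 - (
        (abs_charge + UVERSKY_INTERCEPT) / UVERSKY_SLOPE
    )
    values["disorder"] = sum(comp[aa] * disorder_scale[aa] for aa in AMINO_ACIDS)
    values["entropy"] = sequence_entropy(comp)
    values["beta_strand"] = sum(comp[aa] * beta_scale[aa] for aa in AMINO_ACIDS)
    return {name: values[name] for name in FEATURE_NAMES}


def feature_table(
    seqs: Iterable[ProteinSequence | str],
    pka: PKaSet = EMBOSS_PKA,
    disorder_scale: ScaleTable = TOP_IDP,
    beta_scale: ScaleTable = CHOU_FASMAN_BETA,
) -> pd.DataFrame:
    """Feature vectors for many sequences as a (n, 35) DataFrame.

    The index carries sequence ids where available, otherwise row numbers.
    """
    rows, index = [], []
    for i, seq in enumerate(seqs):
        rows.append(feature_vector(seq, pka, disorder_scale, beta_scale))
        index.append(seq.id if isinstance(seq, ProteinSequence) else i)
    return pd.DataFrame(rows, index=index, columns=list(FEATURE_NAMES), dtype=float)


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Write a feature table as TSV with an ``id`` column first."""
    out = table.copy()
    out.insert(0, "id", out.index)
    out.to_csv(path, sep="\t", index=False)
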