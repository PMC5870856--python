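"""Synthetic sequence sets with known solubility structure.

The generator emulates the statistical shape of a cell-free expression
solubility dataset — a bimodal distribution of per-protein percentage
solubilities (values above 100 occur in the high mode) over ~2400 proteins
— with the crucial difference that here the feature-solubility structure is
known by construction, so training, feature elimination, prediction and
evaluation can all be validated without any external download.

Mechanism
---------
Each informative feature f carries its own independent latent
``t_f ~ N(0, 1)`` per protein.  Residues are drawn i.i.d. from a
composition whose log-odds are shifted by ``t_f`` along that feature's
direction vector (e.g. an informative ``KmR`` with direction +1 raises the
sampling odds of K and lowers R when ``t_f`` is high).  Independent latents
keep the non-informative features free of solubility signal beyond the
mechanical correlation that composition closure imposes.  Measured
solubility is then an affine function of the standardized realized
informative feature values plus Gaussian noise, with half the bimodal gap
added on each side of zero — producing two modes separated by
``bimodal_gap`` percent.  With the default base of 50% and gap of 70, the
modes sit near 15% and 85%, the low mode is truncated at 0, and the upper
mode's tail exceeds 100%, as real cell-free data does.

No attempt is made at sequence realism beyond composition statistics: the
model only sees order-free features, so composition-biased i.i.d. sampling
exercises every code path that real sequences would.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .features import FEATURE_NAMES, UVERSKY_SLOPE, feature_table
from .scales import (
    AMINO_ACIDS,
    CHOU_FASMAN_BETA,
    EMBOSS_PKA,
    KYTE_DOOLITTLE,
    TOP_IDP,
)
from .seqio import ProteinSequence, TrainingRecord

#: Default informative features and their solubility directions: lysine
#: favoured over arginine, more D+E (negative charge), fewer aromatics,
#: more valine, lower hydropathy — the composition signatures associated
#: with soluble proteins.
DEFAULT_INFORMATIVE: dict[str, tuple[int, float]] = {
    "KmR": (+1, 1.0),
    "DpE": (+1, 1.0),
    "FpWpY": (-1, 1.0),
    "V": (+1, 1.0),
    "hydropathy": (-1, 1.0),
}

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic dataset.

    ``informative_features`` maps a feature name to ``(direction, effect)``
    with direction +1 (solubility-raising) or -1 (lowering) and a
    dimensionless effect size on the standardized feature; features must
    be expressible as a linear function of residue composition (all
    compositions and composites, the mean-scale features, ``abs_charge``,
    ``fold_propensity``) or ``length``; ``entropy`` and ``pI`` have no
    residue-odds direction and are rejected.
    """

    n: int = 2395
    length_range: tuple[int, int] = (50, 500)
    informative_features: Mapping[str, tuple[int, float]] = field(
        default_factory=lambda: dict(DEFAULT_INFORMATIVE)
    )
    noise_sd: float = 0.25
    bimodal_gap: float = 70.0
    base_percent: float = 50.0
    slope_percent: float = 10.0
    coupling: float = 0.4  # strength of the residue-odds shift per unit t*effect

    def __post_init__(self) -> None:
        if self.n < 40:
            raise ValueError(f"need n >= 40, got {self.n}")
        if self.noise_sd < 0 or self.bimodal_gap < 0:
            raise ValueError("noise_sd and bimodal_gap must be non-negative")
        unknown = set(self.informative_features) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown informative features: {sorted(unknown)}")
        for name in self.informative_features:
            _direction_vector(name)  # raises for infeasible bias targets


def _per_residue_charge() -> np.ndarray:
    charge = np.zeros(20)
    for aa, pka in EMBOSS_PKA.side_chain.items():
        if aa in ("H", "K", "R"):
            charge[_AA_INDEX[aa]] = 1.0 / (1.0 + 10.0 ** (7.0 - pka))
        else:
            charge[_AA_INDEX[aa]] = -1.0 / (1.0 + 10.0 ** (pka - 7.0))
    return charge


def _direction_vector(feature: str) -> np.ndarray | None:
    """Residue log-odds direction realising an increase of the feature.

    Returns None for ``length`` (biased through the drawn length instead);
    raises for features with no composition-linear direction.
    """
    v = np.zeros(20)
    if feature in _AA_INDEX:
        v[_AA_INDEX[feature]] = 1.0
        return v
    signs = {
        "KmR": {"K": 1, "R": -1}, "DmE": {"D": 1, "E": -1},
        "KpR": {"K": 1, "R": 1}, "DpE": {"D": 1, "E": 1},
        "KpRmDmE": {"K": 1, "R": 1, "D": -1, "E": -1},
        "KpRpDpE": {"K": 1, "R": 1, "D": 1, "E": 1},
        "FpWpY": {"F": 1, "W": 1, "Y": 1},
    }
    if feature in signs:
        for aa, s in signs[feature].items():
            v[_AA_INDEX[aa]] = float(s)
        return v
    if feature == "length":
        return None
    scale_vectors = {
        "hydropathy": np.array([KYTE_DOOLITTLE[aa] for aa in AMINO_ACIDS]) / 4.5,
        "disorder": np.array([TOP_IDP[aa] for aa in AMINO_ACIDS]),
        "beta_strand": np.array([CHOU_FASMAN_BETA[aa] for aa in AMINO_ACIDS]) - 1.0,
        "abs_charge": np.abs(_per_residue_charge()),
        "fold_propensity": (np.array([KYTE_DOOLITTLE[aa] for aa in AMINO_ACIDS]) + 4.5) / 9.0
        - np.abs(_per_residue_charge()) / UVERSKY_SLOPE,
    }
    if feature in scale_vectors:
        v = scale_vectors[feature]
        return v / np.max(np.abs(v))
    raise ValueError(
        f"feature {feature!r} cannot be realised by biasing residue sampling odds"
    )


def generate(spec: SyntheticSpec, seed: int) -> list[TrainingRecord]:
    """Generate a fully reproducible synthetic training set.

    The same ``(spec, seed)`` pair always yields byte-identical records.
    """
    rng = np.random.default_rng(seed)
    names = list(spec.informative_features)
    t = rng.standard_normal((spec.n, len(names)))  # one latent per feature
    lmin, lmax = spec.length_range
    lengths = rng.integers(lmin, lmax + 1, size=spec.n)

    vectors = np.zeros((len(names), 20))
    for j, name in enumerate(names):
        direction, effect = spec.informative_features[name]
        v = _direction_vector(name)
        if v is None:  # length: bias the drawn length with its latent
            span = (lmax - lmin) / 2.0
            mid = (lmax + lmin) / 2.0
            shift = np.clip(0.5 * direction * effect * t[:, j], -1.0, 1.0) * span
            lengths = np.clip(
                np.round(mid + shift + (lengths - mid) * 0.5), lmin, lmax
            ).astype(int)
        else:
            vectors[j] = direction * effect * v

    base_logp = np.log(np.full(20, 0.05))
    seqs: list[ProteinSequence] = []
    aa = np.array(list(AMINO_ACIDS))
    logits_all = base_logp + spec.coupling * t @ vectors
    for i in range(spec.n):
        logits = logits_all[i]
        p = np.exp(logits - logits.max())
        p /= p.sum()
        residues = "".join(rng.choice(aa, size=lengths[i], p=p))
        seqs.append(ProteinSequence(id=f"syn{i:05d}", residues=residues))

    X = feature_table(seqs)
    raw = np.zeros(spec.n)
    total_effect = 0.0
    for name, (direction, effect) in spec.informative_features.items():
        col = X[name].to_numpy()
        sd = col.std(ddof=0)
        if sd == 0.0:
            continue
        raw += direction * effect * (col - col.mean()) / sd
        total_effect += effect
    if total_effect > 0:
        raw /= total_effect
    raw += rng.normal(0.0, spec.noise_sd, size=spec.n)

    solubility = spec.base_percent + spec.slope_percent * raw
    if spec.bimodal_gap > 0:
        solubility += 0.5 * spec.bimodal_gap * np.sign(raw)
    solubility = np.maximum(solubility, 0.0)

    return [
        TrainingRecord(seqs[i].id, seqs[i], float(solubility[i]))
        for i in range(spec.n)
    ]


def make_tm_decoy(seq: ProteinSequence, seed: int) -> ProteinSequence:
    """Insert a guaranteed transmembrane-like stretch into a sequence.

    Replaces a random 21-residue stretch with residues drawn from
    {I, L, V, F} (minimum Kyte-Doolittle 2.8, so the window mean always
    exceeds the 1.6 flagging threshold).  All other positions are
    unchanged.
    """
    if len(seq) < 21:
        raise ValueError(f"sequence {seq.id!r} is too short for a 21-residue TM stretch")
    rng = np.random.default_rng(seed)
    start = int(rng.integers(0, len(seq) - 21 + 1))
    stretch = "".join(rng.choice(np.array(list("ILVF")), size=21))
    residues = seq.residues[:start] + stretch + seq.residues[start + 21:]
    return ProteinSequence(id=seq.id, residues=residues)
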