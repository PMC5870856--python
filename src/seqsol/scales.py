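"""Per-residue numeric scales and pKa sets.

All scales are stored as data (20-entry residue -> value mappings), never as
code, so that users can swap any of them for an alternative table via a
two-column ``residue<TAB>value`` file (see :func:`load_scale_file`).

Built-in defaults
-----------------
``hydropathy``
    Kyte-Doolittle hydropathy.  This is the scale on which the transmembrane
    rule (window mean > 1.6 over 21 residues) and the fold-propensity
    normalisation are defined, so it is not meant to be replaced.
``disorder``
    TOP-IDP disorder propensity (Campen et al. 2008).  Disorder does not
    enter the final prediction model, only the 35-feature deviation display,
    so the exact choice of table affects diagnostics, not predictions.
``beta_strand``
    Chou-Fasman beta-sheet conformational propensity P(beta).  Same remark
    as for disorder.

The default pKa set is the EMBOSS one (side chains D, E, C, Y, H, K, R plus
the two termini).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from types import MappingProxyType
from typing import Mapping

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class ScaleTable:
    """An immutable per-residue scale: one real value per standard residue."""

    name: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = set(AMINO_ACIDS) - set(self.values)
        extra = set(self.values) - set(AMINO_ACIDS)
        if missing or extra:
            raise ValueError(
                f"scale {self.name!r} must cover exactly the 20 standard residues; "
                f"missing={sorted(missing)} extra={sorted(extra)}"
            )
        object.__setattr__(self, "values", MappingProxyType(dict(self.values)))

    def __getitem__(self, residue: str) -> float:
        return self.values[residue]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ScaleTable):
            return NotImplemented
        return self.name == other.name and dict(self.values) == dict(other.values)


@dataclass(frozen=True)
class PKaSet:
    """Side-chain and terminal pKa values used by the titration model.

    Acidic groups: D, E, C, Y side chains and the C-terminus.
    Basic groups: H, K, R side chains and the N-terminus.
    """

    side_chain: Mapping[str, float]
    n_terminus: float
    c_terminus: float

    ACIDIC = ("D", "E", "C", "Y")
    BASIC = ("H", "K", "R")

    def __post_init__(self) -> None:
        expected = set(self.ACIDIC) | set(self.BASIC)
        if set(self.side_chain) != expected:
            raise ValueError(f"side-chain pKa set must cover exactly {sorted(expected)}")
        for label, v in [*self.side_chain.items(),
                         ("n_terminus", self.n_terminus),
                         ("c_terminus", self.c_terminus)]:
            if not 0.0 < float(v) < 14.0:
                raise ValueError(f"pKa for {label} must lie in (0, 14), got {v}")
        object.__setattr__(self, "side_chain", MappingProxyType(dict(self.side_chain)))


KYTE_DOOLITTLE = ScaleTable("hydropathy", {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
})

# TOP-IDP: positive values favour intrinsic disorder.
TOP_IDP = ScaleTable("disorder", {
    "W": -0.884, "F": -0.697, "Y": -0.510, "I": -0.486, "M": -0.397,
    "L": -0.326, "V": -0.121, "N": 0.007, "C": 0.020, "T": 0.059,
    "A": 0.060, "G": 0.166, "R": 0.180, "D": 0.192, "H": 0.303,
    "Q": 0.318, "S": 0.341, "K": 0.586, "E": 0.736, "P": 0.987,
})

CHOU_FASMAN_BETA = ScaleTable("beta_strand", {
    "A": 0.83, "R": 0.93, "N": 0.89, "D": 0.54, "C": 1.19,
    "Q": 1.10, "E": 0.37, "G": 0.75, "H": 0.87, "I": 1.60,
    "L": 1.30, "K": 0.74, "M": 1.05, "F": 1.38, "P": 0.55,
    "S": 0.75, "T": 1.19, "W": 1.37, "Y": 1.47, "V": 1.70,
})

EMBOSS_PKA = PKaSet(
    side_chain={"C": 8.5, "D": 3.9, "E": 4.1, "Y": 10.1,
                "H": 6.5, "K": 10.8, "R": 12.5},
    n_terminus=8.6,
    c_terminus=3.6,
)

_REGISTRY: dict[str, ScaleTable] = {
    "hydropathy": KYTE_DOOLITTLE,
    "disorder": TOP_IDP,
    "beta_strand": CHOU_FASMAN_BETA,
}


def get_scale(name: str) -> ScaleTable:
    """Return a registered scale by name.

    Raises
    ------
    KeyError
        If no scale of that name is registered.
    """
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown scale {name!r}; registered scales: {sorted(_REGISTRY)}"
        ) from None


def load_scale_file(path: str | Path, name: str | None = None) -> ScaleTable:
    """Load a user scale from a two-column ``residue<TAB>value`` text file.

    The file must contain exactly one row per standard residue (20 rows;
    blank lines and ``#`` comments are ignored).
    """
    path = Path(path)
    values: dict[str, float] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'residue<TAB>value', got {line!r}")
        residue, value = parts[0].upper(), parts[1]
        if residue in values:
            raise ValueError(f"{path}:{lineno}: duplicate residue {residue!r}")
        try:
            values[residue] = float(value)
        except ValueError:
            raise ValueError(f"{path}:{lineno}: unparseable value {value!r}") from None
    return ScaleTable(name or path.stem, values)
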