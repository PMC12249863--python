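"""Intrinsic amino-acid hydrophobicity scales.

The observed hydrophobicity distribution is built from per-residue intrinsic
hydrophobicities ``h_r``.  Any scale can be used as long as every value is
nonnegative (a negative intrinsic hydrophobicity would break the probabilistic
interpretation of the observed profile).  The package ships a single default:
the Kyte–Doolittle hydropathy index rescaled linearly onto [0, 1]
(``(kd + 4.5) / 9``), so that arginine maps to 0 and isoleucine to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

STANDARD_AA = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

_KYTE_DOOLITTLE = {
    "ILE": 4.5, "VAL": 4.2, "LEU": 3.8, "PHE": 2.8, "CYS": 2.5,
    "MET": 1.9, "ALA": 1.8, "GLY": -0.4, "THR": -0.7, "SER": -0.8,
    "TRP": -0.9, "TYR": -1.3, "PRO": -1.6, "HIS": -3.2, "GLU": -3.5,
    "GLN": -3.5, "ASP": -3.5, "ASN": -3.5, "LYS": -3.9, "ARG": -4.5,
}

# Common non-standard residues folded onto their standard parent;
# UNK maps to alanine so that unassigned density behaves like poly-alanine.
ALIASES = {
    "MSE": "MET", "SEC": "CYS", "PYL": "LYS", "ASX": "ASN", "GLX": "GLN",
    "UNK": "ALA",
}


class UnknownResidueError(KeyError):
    """Residue name absent from the active hydrophobicity scale."""


@dataclass(frozen=True)
class HydrophobicityScale:
    """A named map from three-letter residue codes to nonnegative h_r values."""

    name: str
    values: dict[str, float] = field(repr=False)

    def __post_init__(self) -> None:
        missing = [aa for aa in STANDARD_AA if aa not in self.values]
        if missing:
            raise ValueError(f"scale {self.name!r} missing residues: {missing}")
        neg = {k: v for k, v in self.values.items() if v < 0}
        if neg:
            raise ValueError(f"scale {self.name!r} has negative values: {neg}")

    def get(self, residue_name: str) -> float:
        """Look up h_r, resolving common aliases (MSE, UNK, ...)."""
        name = residue_name.upper()
        name = ALIASES.get(name, name)
        try:
            return self.values[name]
        except KeyError:
            raise UnknownResidueError(
                f"residue {residue_name!r} not in scale {self.name!r}"
            ) from None

    def __contains__(self, residue_name: str) -> bool:
        name = residue_name.upper()
        return ALIASES.get(name, name) in self.values

    def standard_values(self) -> list[float]:
        """The 20 standard-residue values (the scale's empirical distribution)."""
        return [self.values[aa] for aa in STANDARD_AA]


def kd_normalized() -> HydrophobicityScale:
    """Kyte–Doolittle hydropathy rescaled to [0, 1]; the package default."""
    vals = {aa: (v + 4.5) / 9.0 for aa, v in _KYTE_DOOLITTLE.items()}
    return HydrophobicityScale(name="kd_normalized", values=vals)


_REGISTRY = {"kd_normalized": kd_normalized}


def get_scale(name: str) -> HydrophobicityScale:
    try:
        return _REGISTRY[name]()
    except KeyError:
        raise KeyError(
            f"unknown scale {name!r}; available: {sorted(_REGISTRY)}"
        ) from None
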