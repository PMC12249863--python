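"""Structure reading, effective atoms, and structural-unit selection.

A protein structure is reduced to one *effective atom* per residue — the mean
position of the residue's heavy atoms — each carrying a single intrinsic
hydrophobicity h_r looked up in the active scale.  All downstream scoring
operates on these (position, h_r) chains, so PDB and mmCIF inputs, synthetic
point clouds and poly-alanine guest chains all flow through the same types.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import gemmi
import numpy as np

from .scales import ALIASES, STANDARD_AA, HydrophobicityScale, UnknownResidueError

log = logging.getLogger(__name__)

ResidueKey = tuple[str, int, str]  # (chain_id, author seq number, insertion code)


class StructureParseError(ValueError):
    """File could not be parsed as PDB or mmCIF."""


class EmptyStructureError(ValueError):
    """No protein polymer chains in the file."""


class UnitTooSmallError(ValueError):
    """A unit selection resolved to fewer than two residues."""


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    pos: tuple[float, float, float]


@dataclass(frozen=True)
class RawResidue:
    seq_id: int
    icode: str
    name: str
    atoms: tuple[Atom, ...]

    @property
    def label(self) -> str:
        return f"{self.name}{self.seq_id}{self.icode.strip()}"


@dataclass(frozen=True)
class RawChain:
    chain_id: str
    residues: tuple[RawResidue, ...]

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Structure:
    id: str
    chains: tuple[RawChain, ...]
    source_format: str = "pdb"

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate chain identifiers in {self.id}: {ids}")

    @property
    def chain_ids(self) -> tuple[str, ...]:
        return tuple(c.chain_id for c in self.chains)

    def chain(self, chain_id: str) -> RawChain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"chain {chain_id!r} not in structure {self.id}")

    def with_chain(self, new: RawChain) -> "Structure":
        chains = tuple(new if c.chain_id == new.chain_id else c for c in self.chains)
        return replace(self, chains=chains)


@dataclass(frozen=True)
class Selection:
    """One chain plus an optional inclusive author-numbered residue range."""

    chain_id: str
    start: Optional[int] = None
    end: Optional[int] = None

    def covers(self, seq_id: int) -> bool:
        if self.start is not None and seq_id < self.start:
            return False
        if self.end is not None and seq_id > self.end:
            return False
        return True


@dataclass(frozen=True)
class UnitDefinition:
    """A named structural unit: chain/range selections plus scoring context.

    ``contexts`` may contain ``individual`` (Gaussian field fitted to the unit
    alone) and/or ``in_complex`` (field and interaction neighbourhood of the
    parent unit, profiles restricted to this unit's residues).  ``in_complex``
    requires ``parent`` to name a unit whose selection is a superset.
    """

    name: str
    selections: tuple[Selection, ...]
    contexts: tuple[str, ...] = ("individual",)
    parent: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.selections:
            raise ValueError(f"unit {self.name!r} has no selections")
        bad = set(self.contexts) - {"individual", "in_complex"}
        if bad:
            raise ValueError(f"unit {self.name!r}: unknown contexts {sorted(bad)}")
        if "in_complex" in self.contexts and not self.parent:
            raise ValueError(f"unit {self.name!r}: in_complex context needs a parent")

    @classmethod
    def whole_chains(
        cls,
        name: str,
        chain_ids: Iterable[str],
        contexts: Sequence[str] = ("individual",),
        parent: Optional[str] = None,
    ) -> "UnitDefinition":
        sels = tuple(Selection(c) for c in chain_ids)
        return cls(name=name, selections=sels, contexts=tuple(contexts), parent=parent)


@dataclass(frozen=True)
class EffectiveAtomChain:
    """Ordered residues, one representative point + one h_r each."""

    unit_name: str
    keys: tuple[ResidueKey, ...]
    labels: tuple[str, ...]
    positions: np.ndarray = field(repr=False)  # (n, 3) Å
    h: np.ndarray = field(repr=False)  # (n,) unitless, nonnegative

    def __post_init__(self) -> None:
        if not (len(self.keys) == len(self.labels) == len(self.positions) == len(self.h)):
            raise ValueError("effective-atom arrays have inconsistent lengths")

    def __len__(self) -> int:
        return len(self.keys)

    def subset(self, indices: Sequence[int], name: Optional[str] = None) -> "EffectiveAtomChain":
        idx = np.asarray(indices, dtype=int)
        return EffectiveAtomChain(
            unit_name=name or self.unit_name,
            keys=tuple(self.keys[i] for i in idx),
            labels=tuple(self.labels[i] for i in idx),
            positions=self.positions[idx],
            h=self.h[idx],
        )


# ---------------------------------------------------------------------------
# reading

_FORMAT_MAP = {
    "pdb": gemmi.CoorFormat.Pdb,
    "mmcif": gemmi.CoorFormat.Mmcif,
    "cif": gemmi.CoorFormat.Mmcif,
}


def _is_amino_acid(name: str) -> bool:
    if name in STANDARD_AA or name in ALIASES:
        return True
    info = gemmi.find_tabulated_residue(name)
    return bool(info is not None and info.is_amino_acid())


def _resolve_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """One atom per atom name: highest occupancy wins, ties go to first listed."""
    best: dict[str, gemmi.Atom] = {}
    for atom in res:
        if atom.element.is_hydrogen:
            continue
        prev = best.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            best[atom.name] = atom
    # preserve file order of the winning atoms
    order = {a.name: i for i, a in enumerate(res) if a.name in best}
    return [best[n] for n in sorted(best, key=order.__getitem__)]


def read_structure(path: str | Path, format: Optional[str] = None) -> Structure:
    """Read a PDB/mmCIF file, keeping protein polymer residues only.

    Waters and hetero ligands are dropped; hydrogens are ignored; alternate
    locations are resolved to the highest-occupancy conformer.  Residues are
    ordered by author numbering then insertion code.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if format is not None:
            st = gemmi.read_structure(str(path), format=_FORMAT_MAP[format.lower()])
        else:
            st = gemmi.read_structure(str(path))
    except KeyError:
        raise ValueError(f"unknown format hint {format!r}") from None
    except Exception as exc:  # gemmi raises RuntimeError with line context
        raise StructureParseError(f"cannot parse {path.name}: {exc}") from exc

    if len(st) == 0:
        raise EmptyStructureError(f"{path.name}: no models")
    source_format = "mmcif" if st.input_format == gemmi.CoorFormat.Mmcif else "pdb"
    model = st[0]

    chains: list[RawChain] = []
    for chain in model:
        residues: list[RawResidue] = []
        for res in chain:
            if res.is_water() or not _is_amino_acid(res.name):
                continue
            atoms = tuple(
                Atom(a.name, a.element.name, (a.pos.x, a.pos.y, a.pos.z))
                for a in _resolve_altlocs(res)
            )
            if not atoms:
                continue
            icode = res.seqid.icode if res.seqid.icode.strip() else ""
            residues.append(RawResidue(res.seqid.num, icode, res.name, atoms))
        if residues:
            residues.sort(key=lambda r: (r.seq_id, r.icode))
            chains.append(RawChain(chain.name, tuple(residues)))

    if not chains:
        raise EmptyStructureError(f"{path.name}: no protein polymer chains")
    return Structure(id=path.stem.upper(), chains=tuple(chains), source_format=source_format)


# ---------------------------------------------------------------------------
# effective atoms

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

AtomMode = Literal["all_heavy", "side_chain"]


def apply_polyalanine(chain: RawChain) -> RawChain:
    """Rename every residue to ALA, leaving coordinates untouched.

    Used for guest chains deposited without sequence (backbone + CB only),
    which are treated as poly-alanine.
    """
    residues = tuple(replace(r, name="ALA") for r in chain.residues)
    return replace(chain, residues=residues)


def _effective_position(res: RawResidue, atom_mode: AtomMode) -> np.ndarray:
    atoms = res.atoms
    if atom_mode == "side_chain":
        side = [a for a in atoms if a.name not in BACKBONE_ATOMS]
        if side:
            atoms = tuple(side)
        # glycine (or CA-only residues): fall back to all available atoms
    coords = np.array([a.pos for a in atoms], dtype=float)
    return coords.mean(axis=0)


def effective_atoms(
    structure: Structure,
    unit: UnitDefinition,
    scale: HydrophobicityScale,
    atom_mode: AtomMode = "all_heavy",
) -> EffectiveAtomChain:
    """Reduce a structural unit to one mean-position point + h_r per residue.

    Residues declared in a selection range but absent from the structure are
    skipped with a warning (chain gaps are routine in cryo-EM entries).
    """
    keys: list[ResidueKey] = []
    labels: list[str] = []
    positions: list[np.ndarray] = []
    h: list[float] = []
    for sel in unit.selections:
        chain = structure.chain(sel.chain_id)
        picked = [r for r in chain.residues if sel.covers(r.seq_id)]
        if sel.start is not None and sel.end is not None:
            span = sel.end - sel.start + 1
            if len(picked) < span:
                log.warning(
                    "unit %s: chain %s range %d-%d has %d/%d residues present",
                    unit.name, sel.chain_id, sel.start, sel.end, len(picked), span,
                )
        for res in picked:
            try:
                h_r = scale.get(res.name)
            except UnknownResidueError:
                raise UnknownResidueError(
                    f"unit {unit.name!r}: residue {res.label} (chain {sel.chain_id}) "
                    f"not in scale {scale.name!r}; consider the poly-alanine policy"
                ) from None
            keys.append((sel.chain_id, res.seq_id, res.icode))
            labels.append(f"{sel.chain_id}:{res.label}")
            positions.append(_effective_position(res, atom_mode))
            h.append(h_r)
    if len(keys) < 2:
        raise UnitTooSmallError(
            f"unit {unit.name!r} resolved to {len(keys)} residue(s); need >= 2"
        )
    return EffectiveAtomChain(
        unit_name=unit.name,
        keys=tuple(keys),
        labels=tuple(labels),
        positions=np.asarray(positions, dtype=float),
        h=np.asarray(h, dtype=float),
    )
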