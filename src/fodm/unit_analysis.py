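"""Study orchestration: run the FOD-M scoring over a configured unit set.

A study configuration names a set of structure files, the structural units to
score (whole complexes, single chains in and out of complex context, and
manually delimited pseudo-domains), the poly-alanine guest chains, the
hydrophobicity scale and the model parameters.  ``run_study`` produces one
result row per (unit, context) pair — the machine form of the per-structure
summary tables this kind of analysis reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .fod_core import DEFAULT_CUTOFF, DEFAULT_K_MAX, FODResult, UnitProfiles, score_chain
from .scales import get_scale
from .structure_io import (
    AtomMode,
    EffectiveAtomChain,
    Selection,
    Structure,
    UnitDefinition,
    apply_polyalanine,
    effective_atoms,
    read_structure,
)

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Study configuration is internally inconsistent."""


class ComparisonError(ValueError):
    """Result matrices share no comparable units."""


@dataclass(frozen=True)
class StudyUnit:
    """A UnitDefinition bound to a declared structure id."""

    structure_id: str
    unit: UnitDefinition


@dataclass(frozen=True)
class StudyConfig:
    structures: tuple[tuple[str, Path], ...]  # (id, file path)
    units: tuple[StudyUnit, ...]
    polyalanine_chains: dict[str, tuple[str, ...]] = field(default_factory=dict)
    scale_name: str = "kd_normalized"
    cutoff_c: float = DEFAULT_CUTOFF
    k_max: float = DEFAULT_K_MAX
    atom_mode: AtomMode = "all_heavy"
    include_self: bool = True

    def __post_init__(self) -> None:
        ids = [sid for sid, _ in self.structures]
        if len(set(ids)) != len(ids):
            raise ConfigError(f"duplicate structure ids: {ids}")
        known = set(ids)
        names = set()
        for su in self.units:
            if su.structure_id not in known:
                raise ConfigError(
                    f"unit {su.unit.name!r} references undeclared structure {su.structure_id!r}"
                )
            key = (su.structure_id, su.unit.name)
            if key in names:
                raise ConfigError(f"duplicate unit {key}")
            names.add(key)
        unit_names = {(su.structure_id, su.unit.name) for su in self.units}
        for su in self.units:
            if su.unit.parent and (su.structure_id, su.unit.parent) not in unit_names:
                raise ConfigError(
                    f"unit {su.unit.name!r}: parent {su.unit.parent!r} not declared"
                )
        for sid in self.polyalanine_chains:
            if sid not in known:
                raise ConfigError(f"polyalanine_chains references undeclared structure {sid!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        path = Path(path)
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls.from_dict(doc, base_dir=path.parent)

    @classmethod
    def from_dict(cls, doc: dict, base_dir: Optional[Path] = None) -> "StudyConfig":
        base = Path(base_dir) if base_dir is not None else Path(".")
        structures = []
        for entry in doc.get("structures", []):
            p = Path(entry["path"])
            structures.append((str(entry["id"]), p if p.is_absolute() else base / p))
        units = []
        for u in doc.get("units", []):
            sels = []
            if "chains" in u:
                sels += [Selection(str(c)) for c in u["chains"]]
            for s in u.get("selections", []):
                sels.append(Selection(str(s["chain"]), s.get("start"), s.get("end")))
            unit = UnitDefinition(
                name=str(u["name"]),
                selections=tuple(sels),
                contexts=tuple(u.get("contexts", ["individual"])),
                parent=u.get("parent"),
            )
            units.append(StudyUnit(structure_id=str(u["structure"]), unit=unit))
        polyala = {
            str(sid): tuple(str(c) for c in chains)
            for sid, chains in (doc.get("polyalanine_chains") or {}).items()
        }
        return cls(
            structures=tuple(structures),
            units=tuple(units),
            polyalanine_chains=polyala,
            scale_name=doc.get("scale", "kd_normalized"),
            cutoff_c=float(doc.get("cutoff", DEFAULT_CUTOFF)),
            k_max=float(doc.get("k_max", DEFAULT_K_MAX)),
            atom_mode=doc.get("atom_mode", "all_heavy"),
            include_self=bool(doc.get("include_self", True)),
        )


@dataclass
class ResultMatrix:
    """Rows of FODResult keyed by (structure, unit, context), plus error rows."""

    rows: list[FODResult] = field(default_factory=list)
    errors: list[tuple[str, str, str, str]] = field(default_factory=list)
    profiles: dict[tuple[str, str, str], UnitProfiles] = field(default_factory=dict)
    scale_name: str = "kd_normalized"

    def add(self, result: FODResult, profiles: Optional[UnitProfiles] = None) -> None:
        key = (result.structure_id, result.unit_name, result.context)
        if any(
            (r.structure_id, r.unit_name, r.context) == key for r in self.rows
        ):
            raise ValueError(f"duplicate result row {key}")
        self.rows.append(result)
        if profiles is not None:
            self.profiles[key] = profiles

    def get(self, structure_id: str, unit_name: str, context: str) -> FODResult:
        for r in self.rows:
            if (r.structure_id, r.unit_name, r.context) == (structure_id, unit_name, context):
                return r
        raise KeyError((structure_id, unit_name, context))

    def to_dataframe(self) -> pd.DataFrame:
        cols = ["structure", "unit", "context", "n_residues", "rd", "k",
                "dkl_ot", "dkl_or", "dkl_om_at_k"]
        return pd.DataFrame([r.to_dict() for r in self.rows], columns=cols)

    def to_json(self) -> str:
        doc = {
            "scale": self.scale_name,
            "rows": [r.to_dict() for r in self.rows],
            "errors": [
                {"structure": s, "unit": u, "context": c, "message": m}
                for s, u, c, m in self.errors
            ],
        }
        return json.dumps(doc, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ResultMatrix":
        doc = json.loads(text)
        m = cls(scale_name=doc.get("scale", "kd_normalized"))
        for row in doc["rows"]:
            m.rows.append(
                FODResult(
                    unit_name=row["unit"],
                    context=row["context"],
                    rd=row["rd"],
                    k=row["k"],
                    dkl_ot=row["dkl_ot"],
                    dkl_or=row["dkl_or"],
                    dkl_om_at_k=row["dkl_om_at_k"],
                    n_residues=row["n_residues"],
                    structure_id=row["structure"],
                )
            )
        for err in doc.get("errors", []):
            m.errors.append((err["structure"], err["unit"], err["context"], err["message"]))
        return m


def _resolve_structure(
    structure: Structure, polyala_chains: Sequence[str]
) -> Structure:
    for cid in polyala_chains:
        structure = structure.with_chain(apply_polyalanine(structure.chain(cid)))
    return structure


def _unit_keyset(structure: Structure, unit: UnitDefinition) -> set:
    keys = set()
    for sel in unit.selections:
        chain = structure.chain(sel.chain_id)
        for res in chain.residues:
            if sel.covers(res.seq_id):
                keys.add((sel.chain_id, res.seq_id, res.icode))
    return keys


def run_study(
    config: StudyConfig,
    structures: Optional[dict[str, Structure]] = None,
) -> ResultMatrix:
    """Score every configured (unit, context) pair.

    Pre-loaded structures may be passed in ``structures`` (keyed by id) to
    bypass file reading; otherwise each declared path is read once.  Unit
    failures are recorded as error rows and the run continues; configuration
    errors abort before any computation.
    """
    scale = get_scale(config.scale_name)
    loaded: dict[str, Structure] = {}
    for sid, path in config.structures:
        if structures is not None and sid in structures:
            st = structures[sid]
        else:
            st = read_structure(path)
        loaded[sid] = _resolve_structure(st, config.polyalanine_chains.get(sid, ()))

    # validate chain references before computing anything
    for su in config.units:
        st = loaded[su.structure_id]
        for sel in su.unit.selections:
            if sel.chain_id not in st.chain_ids:
                raise ConfigError(
                    f"unit {su.unit.name!r}: chain {sel.chain_id!r} not in "
                    f"structure {su.structure_id} (has {st.chain_ids})"
                )
    for sid, chains in config.polyalanine_chains.items():
        for cid in chains:
            if cid not in loaded[sid].chain_ids:
                raise ConfigError(f"polyalanine chain {cid!r} not in structure {sid}")

    units_by_name = {(su.structure_id, su.unit.name): su.unit for su in config.units}
    parent_cache: dict[tuple[str, str], EffectiveAtomChain] = {}

    def parent_chain(sid: str, name: str) -> EffectiveAtomChain:
        key = (sid, name)
        if key not in parent_cache:
            parent_cache[key] = effective_atoms(
                loaded[sid], units_by_name[key], scale, config.atom_mode
            )
        return parent_cache[key]

    matrix = ResultMatrix(scale_name=config.scale_name)
    for su in config.units:
        st = loaded[su.structure_id]
        for context in su.unit.contexts:
            try:
                chain = effective_atoms(st, su.unit, scale, config.atom_mode)
                if context == "in_complex":
                    parent = parent_chain(su.structure_id, su.unit.parent)
                    unit_keys = _unit_keyset(st, su.unit)
                    indices = [i for i, k in enumerate(parent.keys) if k in unit_keys]
                    if len(indices) != len(chain):
                        raise ConfigError(
                            f"unit {su.unit.name!r}: parent {su.unit.parent!r} "
                            f"is not a superset ({len(indices)} of {len(chain)} residues)"
                        )
                    result, profs = score_chain(
                        chain, config.cutoff_c, config.k_max, context,
                        su.structure_id, config.include_self,
                        parent=parent, indices=indices,
                    )
                else:
                    result, profs = score_chain(
                        chain, config.cutoff_c, config.k_max, context,
                        su.structure_id, config.include_self,
                    )
                matrix.add(result, profs)
            except ConfigError:
                raise
            except Exception as exc:
                log.warning("unit %s [%s] failed: %s", su.unit.name, context, exc)
                matrix.errors.append((su.structure_id, su.unit.name, context, str(exc)))
    return matrix


def compare_forms(
    matrices: Sequence[ResultMatrix],
    labels: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Side-by-side RD/K per (unit, context) across structural forms.

    Units are matched by (unit name, context); the structure id is the form
    label unless ``labels`` is given.  Delta columns are taken against the
    first matrix; the row with the maximum |ΔRD| is flagged.
    """
    if len(matrices) < 2:
        raise ComparisonError("need at least two result matrices to compare")
    if labels is None:
        labels = []
        for m in matrices:
            sids = sorted({r.structure_id for r in m.rows})
            labels.append(sids[0] if len(sids) == 1 else "+".join(sids))
    if len(labels) != len(matrices):
        raise ComparisonError("one label per matrix required")

    keyed = [
        {(r.unit_name, r.context): r for r in m.rows}
        for m in matrices
    ]
    shared = set(keyed[0])
    for k in keyed[1:]:
        shared &= set(k)
    if not shared:
        raise ComparisonError("no shared (unit, context) pairs across matrices")

    order = [
        (r.unit_name, r.context) for r in matrices[0].rows
        if (r.unit_name, r.context) in shared
    ]
    records = []
    for unit, context in order:
        rec: dict = {"unit": unit, "context": context}
        base = keyed[0][(unit, context)]
        for label, k in zip(labels, keyed):
            row = k[(unit, context)]
            rec[f"rd_{label}"] = row.rd
            rec[f"k_{label}"] = row.k
        for label, k in zip(labels[1:], keyed[1:]):
            row = k[(unit, context)]
            rec[f"delta_rd_{label}"] = row.rd - base.rd
            rec[f"delta_k_{label}"] = row.k - base.k
        rec["max_abs_delta_rd"] = max(
            (abs(k[(unit, context)].rd - base.rd) for k in keyed[1:]), default=0.0
        )
        records.append(rec)
    df = pd.DataFrame(records)
    df["is_max_delta"] = df["max_abs_delta_rd"] == df["max_abs_delta_rd"].max()
    return df


def max_delta_unit(comparison: pd.DataFrame) -> str:
    """Name of the unit with the largest RD change across forms."""
    idx = int(np.argmax(comparison["max_abs_delta_rd"].to_numpy()))
    return str(comparison.iloc[idx]["unit"])
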