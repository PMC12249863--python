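"""Interchain-contact residues and their local hydrophobicity status.

A residue of chain A is an interface residue toward chain B when its
effective atom lies within a contact cutoff of any effective atom of B.
Each is classified by the sign of O_i - T_i evaluated on chain A scored as an
individual unit: a positive difference is a local *excess* of hydrophobicity
(a hydrophobic residue exposed on the surface, available for interchain
packing), a negative one a *deficit* (a polar patch, often a cavity that the
partner chain fills).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .fod_core import DEFAULT_CUTOFF, fit_gaussian_field, observed_profile, theoretical_profile
from .scales import HydrophobicityScale
from .structure_io import Structure, UnitDefinition, effective_atoms


@dataclass(frozen=True)
class InterfaceResidue:
    chain_id: str
    residue_label: str
    partner_chain: str
    min_distance: float  # Å
    status: str  # excess | deficit | neutral
    o_minus_t: float

    def to_dict(self) -> dict:
        return {
            "chain": self.chain_id,
            "residue": self.residue_label,
            "partner": self.partner_chain,
            "min_distance": self.min_distance,
            "o_minus_t": self.o_minus_t,
            "status": self.status,
        }


def _classify(diff: float, eps: float) -> str:
    if diff > eps:
        return "excess"
    if diff < -eps:
        return "deficit"
    return "neutral"


def interface_residues(
    structure: Structure,
    chain_a: str,
    chain_b: str,
    scale: HydrophobicityScale,
    contact_cutoff: float = DEFAULT_CUTOFF,
    interaction_cutoff: float = DEFAULT_CUTOFF,
    eps: float = 0.0,
) -> list[InterfaceResidue]:
    """Residues of ``chain_a`` in contact with ``chain_b``, with O-T status.

    The contact criterion is effective-atom distance <= ``contact_cutoff``
    (default: the Levitt interaction cutoff, the model's only distance
    scale).  O and T are computed for chain_a as an individual unit; the
    symmetric call gives chain_b's side of the interface.
    """
    eff_a = effective_atoms(structure, UnitDefinition.whole_chains(chain_a, [chain_a]), scale)
    eff_b = effective_atoms(structure, UnitDefinition.whole_chains(chain_b, [chain_b]), scale)

    field = fit_gaussian_field(eff_a)
    t = theoretical_profile(eff_a, field)
    o = observed_profile(eff_a, interaction_cutoff)
    diff = o.values - t.values

    dists, _ = cKDTree(eff_b.positions).query(eff_a.positions, k=1)
    out: list[InterfaceResidue] = []
    for i in np.flatnonzero(dists <= contact_cutoff):
        out.append(
            InterfaceResidue(
                chain_id=chain_a,
                residue_label=eff_a.labels[i],
                partner_chain=chain_b,
                min_distance=float(dists[i]),
                status=_classify(float(diff[i]), eps),
                o_minus_t=float(diff[i]),
            )
        )
    return out


def interface_summary(residues: list[InterfaceResidue]) -> dict:
    """Counts of excess/deficit/neutral interface residues, and excess fraction."""
    counts = {"excess": 0, "deficit": 0, "neutral": 0}
    for r in residues:
        counts[r.status] += 1
    total = len(residues)
    return {
        **counts,
        "total": total,
        "fraction_excess": counts["excess"] / total if total else 0.0,
    }
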