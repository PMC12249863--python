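"""Synthetic structures and profiles with known ground truth.

The generator emulates the statistical structure the scoring model assumes:
residues as a 3D point cloud drawn from an anisotropic Gaussian envelope,
with intrinsic hydrophobicities assigned by centrality rank.  Three regimes
span the model's discrimination range:

* ``micelle``  — most hydrophobic residues innermost (aqueous ideal, low RD);
* ``uniform``  — hydrophobicity uncorrelated with position (R-like, high RD);
* ``inverted`` — most hydrophobic residues outermost (membrane-like: high RD
  and a large fitted K).

``coupling`` in [0, 1] controls the fraction of residues whose hydrophobicity
follows the centrality ranking; the remainder are shuffled at random.  A
fixed seed makes every fixture byte-reproducible.  Fixtures can be written
as minimal CA-only PDB files so the full I/O pipeline is exercised without
any external structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import gemmi
import numpy as np

from .scales import STANDARD_AA, HydrophobicityScale, kd_normalized
from .structure_io import (
    Atom,
    EffectiveAtomChain,
    RawChain,
    RawResidue,
    Structure,
)

MODES = ("micelle", "uniform", "inverted", "dimer")


class GenerationError(ValueError):
    """Requested synthetic geometry cannot be constructed."""


@dataclass(frozen=True)
class SyntheticSpec:
    n_residues: int = 200
    sigmas: tuple[float, float, float] = (18.0, 14.0, 10.0)
    mode: str = "micelle"
    coupling: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; choose from {MODES}")
        if self.n_residues < 10:
            raise ValueError("n_residues must be >= 10")
        if min(self.sigmas) <= 0:
            raise ValueError("sigmas must be positive")
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must lie in [0, 1]")


def _assign_names(
    positions: np.ndarray,
    sigmas: tuple[float, float, float],
    mode: str,
    coupling: float,
    rng: np.random.Generator,
    scale: HydrophobicityScale,
) -> list[str]:
    """Sample residue types and distribute them over positions by centrality.

    Centrality is the Mahalanobis distance under the generating Gaussian —
    the same ordering the fitted T field will see.  micelle: hydrophobic
    innermost; inverted: hydrophobic outermost; uniform: random.  After rank
    assignment a (1 - coupling) fraction of positions is shuffled.
    """
    n = len(positions)
    names = list(rng.choice(STANDARD_AA, size=n))
    if mode == "uniform":
        return names
    h = np.array([scale.get(nm) for nm in names])
    centrality = np.linalg.norm(positions / np.asarray(sigmas), axis=1)
    inner_first = np.argsort(centrality)  # most central position first
    by_h = np.argsort(h)[::-1]  # most hydrophobic residue first
    if mode == "inverted":
        inner_first = inner_first[::-1]
    assigned = [""] * n
    for pos_idx, name_idx in zip(inner_first, by_h):
        assigned[pos_idx] = names[name_idx]
    n_shuffle = round((1.0 - coupling) * n)
    if n_shuffle >= 2:
        which = rng.choice(n, size=n_shuffle, replace=False)
        perm = rng.permutation(n_shuffle)
        shuffled = [assigned[i] for i in which]
        for slot, src in zip(which, perm):
            assigned[slot] = shuffled[src]
    return assigned


def make_structure(
    spec: SyntheticSpec,
    scale: Optional[HydrophobicityScale] = None,
    pdb_path: Optional[str | Path] = None,
) -> EffectiveAtomChain:
    """Generate a synthetic single-chain structure (one effective atom/residue).

    Positions are drawn from the anisotropic Gaussian of ``spec.sigmas``;
    residue identities are assigned per the regime.  If ``pdb_path`` is
    given, a minimal CA-only PDB fixture is also written.
    """
    if spec.mode == "dimer":
        raise ValueError("use make_dimer for dimer mode")
    scale = scale or kd_normalized()
    rng = np.random.default_rng(spec.seed)
    positions = rng.normal(0.0, 1.0, size=(spec.n_residues, 3)) * np.asarray(spec.sigmas)
    names = _assign_names(positions, spec.sigmas, spec.mode, spec.coupling, rng, scale)

    keys = tuple(("A", i + 1, "") for i in range(spec.n_residues))
    labels = tuple(f"A:{nm}{i + 1}" for i, nm in enumerate(names))
    h = np.array([scale.get(nm) for nm in names])
    chain = EffectiveAtomChain(
        unit_name=f"synthetic-{spec.mode}", keys=keys, labels=labels,
        positions=positions, h=h,
    )
    if pdb_path is not None:
        write_ca_pdb(pdb_path, {"A": list(zip(names, positions))})
    return chain


def make_profile_pair(
    n: int, k_true: float, seed: int
) -> tuple["Profile", "Profile"]:
    """A random smooth T profile and O constructed exactly as M(T, k_true).

    The pair is the ground-truth fixture for K recovery: fitting K on (T, O)
    must return k_true.
    """
    from .fod_core import Profile, m_profile

    if n < 2:
        raise ValueError("need n >= 2")
    if k_true < 0:
        raise ValueError("k_true must be nonnegative")
    rng = np.random.default_rng(seed)
    walk = np.cumsum(rng.normal(0.0, 0.35, size=n))
    kernel = np.ones(7) / 7.0
    smooth = np.convolve(walk, kernel, mode="same")
    t = Profile.from_raw("T", np.exp(smooth - smooth.max()))
    o = m_profile(t, k_true)
    o = Profile(role="O", values=o.values, normalizer=o.normalizer)
    return t, o


def make_dimer(
    spec: SyntheticSpec,
    contact_pairs: int,
    contact_cutoff: float = 9.0,
    pdb_path: Optional[str | Path] = None,
) -> Structure:
    """Two chains with exactly ``contact_pairs`` cross-chain contacts.

    Residues of each chain sit on parallel lines spaced so that only the
    first ``contact_pairs`` opposite pairs fall within the contact cutoff;
    every other cross-chain distance exceeds it by construction.
    """
    if contact_pairs < 1:
        raise GenerationError("contact_pairs must be >= 1")
    n = spec.n_residues
    if contact_pairs > n:
        raise GenerationError(f"cannot fit {contact_pairs} contacts in {n} residues")
    rng = np.random.default_rng(spec.seed)
    step = 2.0 * contact_cutoff  # along-chain spacing: cross terms stay far
    near = 0.85 * contact_cutoff
    far = 4.0 * contact_cutoff
    names_a = list(rng.choice(STANDARD_AA, size=n))
    names_b = list(rng.choice(STANDARD_AA, size=n))
    # small z jitter keeps each chain non-collinear without touching the
    # contact bookkeeping (|dz| <= 2 << cutoff margins)
    z_a = rng.uniform(-1.0, 1.0, size=n)
    z_b = rng.uniform(-1.0, 1.0, size=n)
    coords_a = [(0.0, step * i, z_a[i]) for i in range(n)]
    coords_b = [
        ((near if i < contact_pairs else far), step * i, z_b[i]) for i in range(n)
    ]
    # verify the construction rather than trust it
    pa = np.asarray(coords_a)
    pb = np.asarray(coords_b)
    dists = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
    if int((dists <= contact_cutoff).sum()) != contact_pairs:
        raise GenerationError("dimer geometry infeasible for this cutoff")

    def build(cid: str, names: list[str], coords: list[tuple]) -> RawChain:
        residues = tuple(
            RawResidue(i + 1, "", nm, (Atom("CA", "C", xyz),))
            for i, (nm, xyz) in enumerate(zip(names, coords))
        )
        return RawChain(cid, residues)

    structure = Structure(
        id=f"SYNDIMER{spec.seed}",
        chains=(build("A", names_a, coords_a), build("B", names_b, coords_b)),
        source_format="pdb",
    )
    if pdb_path is not None:
        write_ca_pdb(
            pdb_path,
            {"A": list(zip(names_a, coords_a)), "B": list(zip(names_b, coords_b))},
        )
    return structure


def write_ca_pdb(path: str | Path, chains: dict[str, list]) -> None:
    """Write chains of (residue name, xyz) as a CA-only PDB fixture."""
    st = gemmi.Structure()
    st.name = "SYNTH"
    model = gemmi.Model("1")
    for cid, residues in chains.items():
        chain = gemmi.Chain(cid)
        for i, (name, xyz) in enumerate(residues, start=1):
            res = gemmi.Residue()
            res.name = name
            res.seqid = gemmi.SeqId(i, " ")
            res.het_flag = "A"
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*(float(v) for v in xyz))
            atom.occ = 1.0
            res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.write_pdb(str(path))
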