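"""Core fuzzy-oil-drop statistics: the T/O/R/M profiles, D_KL, RD and K.

The model compares three per-residue hydrophobicity distributions over a
structural unit of N residues:

* ``T`` — theoretical: a centred, axis-aligned 3D Gaussian fitted to the
  unit's effective atoms, evaluated at each residue and normalised.  This is
  the idealised micelle: maximal hydrophobicity at the geometric centre.
* ``O`` — observed: pairwise hydrophobic interactions between residues,
  summed with Levitt's polynomial distance weighting within a 9 Å cutoff.
* ``R`` — uniform reference, 1/N everywhere: no hydrophobic core at all.

The relative distance ``RD = D_KL(O|T) / (D_KL(O|T) + D_KL(O|R))`` locates O
between the two references; RD < 0.5 indicates a hydrophobic core.  The
modified model adds the blended profile ``M(K)``, proportional to
``T + K*(T_max - T)`` and renormalised, which interpolates from the aqueous
ideal (K=0, M=T) through the uniform field (K=1, M=R) toward the inverted,
membrane-like distribution as K grows.  The fitted K — the minimiser of
``D_KL(O|M(K))`` — measures the contribution of non-aqueous factors to the
external field the unit folded in.

All divergences are in bits (log base 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.spatial import cKDTree

from .structure_io import EffectiveAtomChain

DEFAULT_CUTOFF = 9.0  # Å, Levitt interaction cutoff
DEFAULT_K_MAX = 10.0

PROFILE_SUM_TOL = 1e-9


class DegenerateGeometryError(ValueError):
    """Effective atoms are collinear (or fewer than 3): no 3D envelope."""


class ZeroHydrophobicityError(ValueError):
    """All raw observed sums are zero; O is not a distribution."""


class SupportError(ValueError):
    """q_i = 0 at an index where p_i > 0: D_KL(p|q) diverges."""


class UndefinedRDError(ZeroDivisionError):
    """Both divergences are zero (O = T = R); RD is 0/0."""


# ---------------------------------------------------------------------------
# profiles


@dataclass(frozen=True)
class Profile:
    """A normalised per-residue hydrophobicity distribution."""

    role: str  # one of T, O, R, M
    values: np.ndarray = field(repr=False)
    normalizer: float = 1.0  # pre-normalisation sum H_sum

    def __post_init__(self) -> None:
        if self.role not in ("T", "O", "R", "M"):
            raise ValueError(f"unknown profile role {self.role!r}")
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or len(v) == 0:
            raise ValueError("profile must be a non-empty 1D array")
        if np.any(v < 0):
            raise ValueError(f"{self.role} profile has negative entries")
        if abs(v.sum() - 1.0) > PROFILE_SUM_TOL:
            raise ValueError(f"{self.role} profile sums to {v.sum()!r}, not 1")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.values)

    @classmethod
    def from_raw(cls, role: str, raw: np.ndarray) -> "Profile":
        raw = np.asarray(raw, dtype=float)
        total = float(raw.sum())
        if total <= 0:
            raise ZeroHydrophobicityError(f"{role} profile: raw sum is {total}")
        return cls(role=role, values=raw / total, normalizer=total)

    def restrict(self, indices: Sequence[int]) -> "Profile":
        """Restrict to a sub-unit and renormalise (in-complex scoping)."""
        sub = self.values[np.asarray(indices, dtype=int)]
        return Profile.from_raw(self.role, sub)


@dataclass(frozen=True)
class GaussianField:
    """Centred, axis-aligned 3D Gaussian envelope of a structural unit.

    ``rotation`` maps input-frame offsets to the field (principal-axes) frame:
    aligned = (x - center) @ rotation.
    """

    center: np.ndarray = field(repr=False)
    sigmas: tuple[float, float, float]
    rotation: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if min(self.sigmas) <= 0:
            raise ValueError(f"non-positive sigma: {self.sigmas}")
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be a 3x3 orthonormal matrix")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation must be proper (det +1)")

    def align(self, positions: np.ndarray) -> np.ndarray:
        return (np.asarray(positions, dtype=float) - self.center) @ self.rotation


def fit_gaussian_field(chain: EffectiveAtomChain, sigma_floor: float = 1.0) -> GaussianField:
    """Fit the molecular envelope: principal axes + the 3-sigma extent rule.

    The centre is the mean effective-atom position; axes are the principal
    axes of the position covariance; each sigma is the maximum absolute
    aligned coordinate divided by 3 (so the whole unit lies within 3 sigma),
    floored at ``sigma_floor`` Å to keep flat or small units well-posed.
    """
    pts = np.asarray(chain.positions, dtype=float)
    if len(pts) < 3:
        raise DegenerateGeometryError(
            f"unit {chain.unit_name!r}: need >= 3 effective atoms, have {len(pts)}"
        )
    center = pts.mean(axis=0)
    centered = pts - center
    cov = centered.T @ centered / len(pts)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[0] <= 0 or evals[1] / evals[0] < 1e-12:
        raise DegenerateGeometryError(
            f"unit {chain.unit_name!r}: effective atoms are collinear"
        )
    # deterministic axis signs: largest-magnitude component positive
    for d in range(3):
        col = evecs[:, d]
        if col[np.argmax(np.abs(col))] < 0:
            evecs[:, d] = -col
    if np.linalg.det(evecs) < 0:
        evecs[:, 2] = -evecs[:, 2]
    aligned = centered @ evecs
    sigmas = np.maximum(np.abs(aligned).max(axis=0) / 3.0, sigma_floor)
    return GaussianField(center=center, sigmas=tuple(float(s) for s in sigmas), rotation=evecs)


def theoretical_profile(chain: EffectiveAtomChain, field_: GaussianField) -> Profile:
    """T: the 3D Gaussian evaluated at each effective atom, normalised."""
    a = field_.align(chain.positions)
    s = np.asarray(field_.sigmas, dtype=float)
    raw = np.exp(-0.5 * np.sum((a / s) ** 2, axis=1))
    return Profile.from_raw("T", raw)


def levitt_weight(x: np.ndarray | float) -> np.ndarray | float:
    """Levitt's distance weighting on x = r/c: 1 - (7x^2 - 9x^4 + 5x^6 - x^8)/2.

    Equals 1 at contact (x=0) and 0 at the cutoff (x=1); zero beyond.
    """
    x = np.asarray(x, dtype=float)
    w = np.where(
        x <= 1.0,
        1.0 - 0.5 * (7 * x**2 - 9 * x**4 + 5 * x**6 - x**8),
        0.0,
    )
    return w if w.ndim else float(w)


def observed_profile(
    chain: EffectiveAtomChain,
    cutoff: float = DEFAULT_CUTOFF,
    include_self: bool = True,
) -> Profile:
    """O: summed pairwise hydrophobic interactions, Levitt-weighted.

    raw_i = sum_j (h_i + h_j) * w(r_ij / c) over pairs within the cutoff.
    The self term j = i (w(0) = 1, contributing 2 h_i) is included by default
    so isolated residues still carry their intrinsic hydrophobicity.
    """
    if len(chain) < 2:
        raise ValueError(f"unit {chain.unit_name!r}: observed profile needs >= 2 residues")
    h = chain.h
    raw = np.zeros(len(chain))
    if include_self:
        raw += 2.0 * h
    tree = cKDTree(chain.positions)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        r = np.linalg.norm(chain.positions[i] - chain.positions[j], axis=1)
        w = levitt_weight(r / cutoff)
        contrib = (h[i] + h[j]) * w
        np.add.at(raw, i, contrib)
        np.add.at(raw, j, contrib)
    return Profile.from_raw("O", raw)


def uniform_profile(n: int) -> Profile:
    """R: 1/N per residue — the no-core reference."""
    if n < 1:
        raise ValueError("empty unit: uniform profile needs n >= 1")
    return Profile(role="R", values=np.full(n, 1.0 / n), normalizer=float(n))


def m_profile(t: Profile, k: float) -> Profile:
    """M(K): raw m_i = T_i + K*(T_max - T_i), renormalised.

    K=0 returns T exactly; K=1 gives the uniform profile (raw is the constant
    T_max); large K approaches the normalised inverted (membrane) profile
    T_max - T_i.
    """
    if k < 0:
        raise ValueError(f"K must be nonnegative, got {k}")
    tv = t.values
    raw = tv + k * (tv.max() - tv)
    if k == 0.0:
        return Profile(role="M", values=tv.copy(), normalizer=t.normalizer)
    return Profile.from_raw("M", raw)


# ---------------------------------------------------------------------------
# divergences and statistics


def kl_divergence(p: Profile, q: Profile) -> float:
    """D_KL(p|q) in bits; 0 log 0 := 0; requires q > 0 wherever p > 0."""
    if len(p) != len(q):
        raise ValueError(f"profile length mismatch: {len(p)} vs {len(q)}")
    pv, qv = p.values, q.values
    mask = pv > 0
    if np.any(qv[mask] == 0):
        raise SupportError(f"D_KL({p.role}|{q.role}): zero in q where p > 0")
    return float(np.sum(pv[mask] * np.log2(pv[mask] / qv[mask])))


def rd(o: Profile, t: Profile, r: Profile) -> float:
    """Relative distance of O between T and R; < 0.5 means a hydrophobic core."""
    d_ot = kl_divergence(o, t)
    d_or = kl_divergence(o, r)
    denom = d_ot + d_or
    if denom == 0:
        raise UndefinedRDError("O = T = R: relative distance undefined")
    return d_ot / denom


def fit_k(
    t: Profile,
    o: Profile,
    k_max: float = DEFAULT_K_MAX,
    grid_step: float = 0.1,
    tol: float = 1e-3,
) -> tuple[float, float]:
    """Fit the environmental mixing parameter K.

    Minimises D_KL(O | M(T, K)) over [0, k_max] by coarse grid search
    (``grid_step``) followed by bounded local refinement to ``tol``.
    Deterministic for fixed inputs.  Returns (k, divergence at k).
    """
    if len(t) != len(o):
        raise ValueError(f"profile length mismatch: {len(t)} vs {len(o)}")

    def objective(k: float) -> float:
        return kl_divergence(o, m_profile(t, k))

    ks = np.arange(0.0, k_max + grid_step / 2, grid_step)
    vals = np.array([objective(k) for k in ks])
    if not np.all(np.isfinite(vals)):
        raise ArithmeticError("non-finite divergence across the K grid")
    best = int(np.argmin(vals))
    lo = max(0.0, ks[best] - grid_step)
    hi = min(k_max, ks[best] + grid_step)
    res = minimize_scalar(objective, bounds=(lo, hi), method="bounded", options={"xatol": tol})
    if res.fun <= vals[best]:
        k_opt, d_opt = float(res.x), float(res.fun)
    else:  # refinement failed to improve; keep the grid point
        k_opt, d_opt = float(ks[best]), float(vals[best])
    return k_opt, d_opt


# ---------------------------------------------------------------------------
# unit scoring


@dataclass(frozen=True)
class FODResult:
    """RD, fitted K and the underlying divergences for one unit in one context."""

    unit_name: str
    context: str  # individual | in_complex
    rd: float
    k: float
    dkl_ot: float
    dkl_or: float
    dkl_om_at_k: float
    n_residues: int
    structure_id: str = ""

    def to_dict(self) -> dict:
        return {
            "structure": self.structure_id,
            "unit": self.unit_name,
            "context": self.context,
            "n_residues": self.n_residues,
            "rd": self.rd,
            "k": self.k,
            "dkl_ot": self.dkl_ot,
            "dkl_or": self.dkl_or,
            "dkl_om_at_k": self.dkl_om_at_k,
        }


@dataclass(frozen=True)
class UnitProfiles:
    """The computed profiles backing one FODResult (for profile export)."""

    labels: tuple[str, ...]
    t: Profile
    o: Profile
    m_at_k: Profile
    k: float


def score_chain(
    chain: EffectiveAtomChain,
    cutoff: float = DEFAULT_CUTOFF,
    k_max: float = DEFAULT_K_MAX,
    context: str = "individual",
    structure_id: str = "",
    include_self: bool = True,
    parent: Optional[EffectiveAtomChain] = None,
    indices: Optional[Sequence[int]] = None,
) -> tuple[FODResult, UnitProfiles]:
    """Score one structural unit.

    ``individual``: the Gaussian field and interaction neighbourhood are the
    unit's own.  ``in_complex``: both are the parent's; the parent T and O
    are restricted to ``indices`` (the unit's residues within the parent) and
    renormalised before the divergences are computed.
    """
    if context == "in_complex":
        if parent is None or indices is None:
            raise ValueError("in_complex scoring needs parent chain and indices")
        field_ = fit_gaussian_field(parent)
        t = theoretical_profile(parent, field_).restrict(indices)
        o = observed_profile(parent, cutoff, include_self).restrict(indices)
        labels = tuple(parent.labels[i] for i in indices)
    elif context == "individual":
        field_ = fit_gaussian_field(chain)
        t = theoretical_profile(chain, field_)
        o = observed_profile(chain, cutoff, include_self)
        labels = chain.labels
    else:
        raise ValueError(f"unknown context {context!r}")

    r = uniform_profile(len(t))
    rd_val = rd(o, t, r)
    k, d_om = fit_k(t, o, k_max)
    result = FODResult(
        unit_name=chain.unit_name,
        context=context,
        rd=rd_val,
        k=k,
        dkl_ot=kl_divergence(o, t),
        dkl_or=kl_divergence(o, r),
        dkl_om_at_k=d_om,
        n_residues=len(t),
        structure_id=structure_id,
    )
    profiles = UnitProfiles(labels=labels, t=t, o=o, m_at_k=m_profile(t, k), k=k)
    return result, profiles
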