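"""Design objectives: pluggable contract plus two geometric surrogates.

The evolutionary engine optimizes candidates against an ordered list of
objectives, all oriented as *maximize*.  Two closed-form surrogates are
provided that preserve the structure of conditional metalloprotein design
objectives — a metal-site placement probability p(metal | sequence,
structure) and a sequence-compatibility score p(sequence | metal, structure)
— while remaining fully deterministic and hand-checkable:

``metal_site_objective``
    Lays a cubic grid over the scaffold's Cβ bounding box and scores every
    grid point g as S(g) = Σ_i w(aa_i) · k(‖Cβ_i − g‖), where w is a donor
    propensity (Cys 1.0, His 0.9, Asp/Glu 0.6, others 0) and k is a
    triangular kernel on the Cβ–metal distance window [2.5, 6.5] Å peaked at
    4.0 Å.  The best grid point becomes the metal placement and the score is
    the logistic probability σ(α·S + β).

``sequence_objective``
    Mean hydropathy/burial compatibility — Kyte–Doolittle hydropathy
    (normalized to [−1, 1]) times a burial sign (+1 buried, −1 exposed, by
    Cα neighbor count) — minus a penalty λ per *gratuitous* donor residue
    (Cys/His/Asp/Glu whose Cβ sits beyond the kernel window from the placed
    metal).  Donors that can reach the metal are exempt, so the two
    objectives trade off only on donors that buy no metal affinity.

Because neither kernel weights nor burial depend on the candidate sequence,
the per-scaffold geometry (grid, kernel matrix, burial flags) is precomputed
once in a :class:`ScaffoldContext` and every evaluation is a single
matrix–vector product.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from Bio.SeqUtils.ProtParamData import kd as _KYTE_DOOLITTLE

from .structure_io import MetalIon, Structure

__all__ = [
    "AMINO_ACIDS",
    "SequenceCandidate",
    "ObjectiveSpec",
    "ObjectiveVector",
    "MetalPlacement",
    "SurrogateParams",
    "ScaffoldContext",
    "ideal_cbeta",
    "metal_site_objective",
    "sequence_objective",
    "default_objectives",
    "evaluate",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Kyte–Doolittle hydropathy normalized by its extreme value and clipped.
HYDROPATHY_NORM = {aa: float(np.clip(v / 4.5, -1.0, 1.0)) for aa, v in _KYTE_DOOLITTLE.items()}

_DEFAULT_DONOR_PROPENSITY = {"C": 1.0, "H": 0.9, "D": 0.6, "E": 0.6}


@dataclass
class SequenceCandidate:
    """A candidate sequence over a fixed-backbone scaffold.

    ``designable_mask`` marks the positions the GA may change; masked-off
    positions stay at the seed sequence by construction of the operators.
    """

    sequence: str
    designable_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if any(aa not in AMINO_ACIDS for aa in self.sequence):
            raise ValueError("sequence contains non-standard amino-acid letters")
        if self.designable_mask is None:
            self.designable_mask = np.ones(len(self.sequence), dtype=bool)
        else:
            self.designable_mask = np.asarray(self.designable_mask, dtype=bool)
        if len(self.designable_mask) != len(self.sequence):
            raise ValueError("designable_mask length differs from sequence length")


@dataclass
class MetalPlacement:
    """A predicted metal position with its logistic placement probability."""

    coords: np.ndarray
    probability: float

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not 0.0 < self.probability < 1.0:
            raise ValueError("probability must be strictly inside (0, 1)")

    def as_metal_ion(self, element: str = "ZN") -> MetalIon:
        return MetalIon(element=element, coords=self.coords, source="predicted")


@dataclass
class SurrogateParams:
    """All tunable constants of the two surrogate objectives (distances in Å)."""

    donor_propensity: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_DONOR_PROPENSITY)
    )
    d_min: float = 2.5
    d_peak: float = 4.0
    d_max: float = 6.5
    alpha: float = 2.0
    beta: float = -5.0
    burial_radius: float = 10.0
    burial_threshold: int = 12
    donor_penalty: float = 0.5
    grid_spacing: float = 1.0
    grid_padding: float = 2.0

    def __post_init__(self) -> None:
        if not (self.d_min < self.d_peak < self.d_max):
            raise ValueError("kernel window must satisfy d_min < d_peak < d_max")
        if self.alpha <= 0:
            raise ValueError("logistic alpha must be positive")
        if self.grid_spacing <= 0:
            raise ValueError("grid spacing must be positive")

    def kernel(self, d: np.ndarray) -> np.ndarray:
        """Triangular distance kernel: 0 outside [d_min, d_max], 1 at d_peak."""
        d = np.asarray(d, dtype=float)
        rising = (d - self.d_min) / (self.d_peak - self.d_min)
        falling = (self.d_max - d) / (self.d_max - self.d_peak)
        return np.where(
            (d >= self.d_min) & (d <= self.d_peak),
            rising,
            np.where((d > self.d_peak) & (d <= self.d_max), falling, 0.0),
        )


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def _nerf_place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom D from internal coordinates relative to chain A–B–C.

    |CD| = bond, angle(B,C,D) = angle_deg, dihedral(A,B,C,D) = dihedral_deg.
    """
    theta = math.radians(angle_deg)
    phi = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array(
        [
            -bond * math.cos(theta),
            bond * math.sin(theta) * math.cos(phi),
            bond * math.sin(theta) * math.sin(phi),
        ]
    )
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def ideal_cbeta(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal Cβ position reconstructed from backbone N, Cα, C.

    Standard tetrahedral geometry: 1.521 Å Cα–Cβ bond, 110.4° N–Cα–Cβ angle,
    −122.6° C–N–Cα–Cβ improper dihedral.  Used for Gly and for backbone-only
    scaffolds.
    """
    return _nerf_place(np.asarray(c, float), np.asarray(n, float),
                       np.asarray(ca, float), 1.521, 110.4, -122.6)


# ---------------------------------------------------------------------------
# Scaffold context (precomputed geometry)
# ---------------------------------------------------------------------------

class ScaffoldContext:
    """Fixed-backbone geometry shared by every candidate evaluation.

    Extracts Cα and Cβ coordinates (reconstructing missing Cβ, e.g. Gly, from
    the backbone), builds the axis-aligned placement grid over the Cβ
    bounding box, and caches the grid-to-Cβ kernel matrix and per-position
    burial flags.  Also carries ``current_placement``, set by
    :func:`evaluate` so that the sequence objective sees the metal placement
    computed for the *same* candidate.
    """

    def __init__(self, scaffold: Structure, params: SurrogateParams | None = None):
        self.scaffold = scaffold
        self.params = params or SurrogateParams()
        residues = scaffold.protein_residues
        if len(residues) < 4:
            raise ValueError("scaffold must contain at least 4 protein residues")
        self.n_residues = len(residues)
        ca, cb = [], []
        for r in residues:
            ca_atom = r.atom("CA")
            if ca_atom is None:
                raise ValueError(f"residue {r.key} has no CA atom")
            ca.append(ca_atom.coords)
            cb_atom = r.atom("CB")
            if cb_atom is not None:
                cb.append(cb_atom.coords)
            else:
                n_atom, c_atom = r.atom("N"), r.atom("C")
                if n_atom is None or c_atom is None:
                    raise ValueError(
                        f"residue {r.key} lacks CB and the N/CA/C backbone "
                        "needed to reconstruct it"
                    )
                cb.append(ideal_cbeta(n_atom.coords, ca_atom.coords, c_atom.coords))
        self.ca = np.array(ca)
        self.cb = np.array(cb)
        self.grid = self._build_grid()
        # kernel matrix: grid points x residues; sequence only modulates weights
        # chunked so fine grids on large boxes stay within memory
        blocks = []
        for start in range(0, len(self.grid), 200_000):
            chunk = self.grid[start:start + 200_000]
            d = np.sqrt(
                ((chunk[:, None, :] - self.cb[None, :, :]) ** 2).sum(axis=2)
            )
            blocks.append(self.params.kernel(d))
        self.kernel_matrix = np.concatenate(blocks) if blocks else np.empty((0, len(self.cb)))
        self.buried = self._burial_flags()
        self.current_placement: MetalPlacement | None = None

    def _build_grid(self) -> np.ndarray:
        p = self.params
        lo = self.cb.min(axis=0) - p.grid_padding
        hi = self.cb.max(axis=0) + p.grid_padding
        axes = [np.arange(lo[k], hi[k] + 1e-9, p.grid_spacing) for k in range(3)]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        # 'ij' indexing + C-order ravel => points ordered lexicographically by
        # (x, y, z), so argmax tie-breaking picks the smallest grid coordinate
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    def _burial_flags(self) -> np.ndarray:
        d = np.linalg.norm(self.ca[:, None, :] - self.ca[None, :, :], axis=2)
        neighbors = (d <= self.params.burial_radius).sum(axis=1) - 1  # exclude self
        return neighbors >= self.params.burial_threshold

    def donor_weights(self, sequence: str) -> np.ndarray:
        prop = self.params.donor_propensity
        return np.array([prop.get(aa, 0.0) for aa in sequence])


@dataclass
class ObjectiveSpec:
    """A named maximize-objective; the evaluator must be deterministic."""

    name: str
    evaluator: Callable[[SequenceCandidate, ScaffoldContext], float]
    direction: str = "maximize"


@dataclass
class ObjectiveVector:
    """Ordered per-objective scores, one per registered objective."""

    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("objective scores must all be finite")

    def __len__(self) -> int:
        return len(self.scores)

    def __getitem__(self, i: int) -> float:
        return float(self.scores[i])

    def __iter__(self):
        return iter(self.scores.tolist())


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


# ---------------------------------------------------------------------------
# The two surrogate objectives
# ---------------------------------------------------------------------------

def metal_site_objective(
    c: SequenceCandidate,
    scaffold: Structure | ScaffoldContext,
    p: SurrogateParams | None = None,
) -> tuple[MetalPlacement, float]:
    """Best metal placement on the scaffold grid and its probability.

    Returns the grid point maximizing S(g) = Σ_i w(aa_i)·k(‖Cβ_i − g‖)
    (ties: lexicographically smallest grid coordinates) and the logistic
    probability σ(α·S + β), which is also the objective score.
    """
    ctx = scaffold if isinstance(scaffold, ScaffoldContext) else ScaffoldContext(scaffold, p)
    if len(c.sequence) != ctx.n_residues:
        raise ValueError(
            f"candidate length {len(c.sequence)} != scaffold length {ctx.n_residues}"
        )
    s = ctx.kernel_matrix @ ctx.donor_weights(c.sequence)
    best = int(np.argmax(s))  # first max = lexicographically smallest point
    prob = _sigmoid(ctx.params.alpha * float(s[best]) + ctx.params.beta)
    placement = MetalPlacement(coords=ctx.grid[best].copy(), probability=prob)
    return placement, prob


def sequence_objective(
    c: SequenceCandidate,
    scaffold: Structure | ScaffoldContext,
    metal: MetalPlacement,
    p: SurrogateParams | None = None,
) -> float:
    """Hydropathy/burial compatibility minus the gratuitous-donor penalty.

    C = (1/L) Σ_pos h̃(aa)·b(pos) − λ·|{donors with Cβ–metal > d_max}|/L,
    with h̃ the normalized clipped Kyte–Doolittle hydropathy and b(pos) ±1 by
    Cα-neighbor burial.  Bounded in [−1 − λ, 1].
    """
    ctx = scaffold if isinstance(scaffold, ScaffoldContext) else ScaffoldContext(scaffold, p)
    if len(c.sequence) != ctx.n_residues:
        raise ValueError(
            f"candidate length {len(c.sequence)} != scaffold length {ctx.n_residues}"
        )
    pr = ctx.params
    hyd = np.array([HYDROPATHY_NORM[aa] for aa in c.sequence])
    burial_sign = np.where(ctx.buried, 1.0, -1.0)
    compat = float(np.mean(hyd * burial_sign))
    cb_metal = np.linalg.norm(ctx.cb - np.asarray(metal.coords, float), axis=1)
    is_donor = np.array([aa in "CHDE" for aa in c.sequence])
    gratuitous = int(np.sum(is_donor & (cb_metal > pr.d_max)))
    return compat - pr.donor_penalty * gratuitous / ctx.n_residues


# ---------------------------------------------------------------------------
# Registry / evaluation
# ---------------------------------------------------------------------------

def _metal_evaluator(c: SequenceCandidate, ctx: ScaffoldContext) -> float:
    if ctx.current_placement is None:
        placement, prob = metal_site_objective(c, ctx)
        ctx.current_placement = placement
        return prob
    return ctx.current_placement.probability


def _sequence_evaluator(c: SequenceCandidate, ctx: ScaffoldContext) -> float:
    if ctx.current_placement is None:
        ctx.current_placement, _ = metal_site_objective(c, ctx)
    return sequence_objective(c, ctx, ctx.current_placement)


def default_objectives(params: SurrogateParams | None = None) -> list[ObjectiveSpec]:
    """The standard metal-then-sequence objective pair."""
    return [
        ObjectiveSpec("metal_site", _metal_evaluator),
        ObjectiveSpec("sequence", _sequence_evaluator),
    ]


def evaluate(
    c: SequenceCandidate,
    objectives: Sequence[ObjectiveSpec],
    context: ScaffoldContext,
) -> ObjectiveVector:
    """Score a candidate against every registered objective, in order.

    The metal placement is computed once per candidate (metal-first
    conditioning) and shared by all objectives via the context.
    """
    if len(objectives) == 0:
        raise ValueError("no objectives registered")
    if len(objectives) == 1:
        warnings.warn(
            "single-objective run: Pareto machinery degenerates to scalar "
            "optimization",
            stacklevel=2,
        )
    context.current_placement, _ = metal_site_objective(c, context)
    scores = []
    for spec in objectives:
        try:
            scores.append(float(spec.evaluator(c, context)))
        except Exception as exc:  # noqa: BLE001 - re-raise with objective name
            raise RuntimeError(f"objective {spec.name!r} failed: {exc}") from exc
    return ObjectiveVector(np.array(scores))
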