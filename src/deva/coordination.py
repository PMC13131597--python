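"""Zinc coordination-sphere analysis and dataset-curation filters.

For every metal ion in a structure this module finds the coordinating donor
atoms (N, O, S; side chain or backbone, plus water oxygens) within a distance
cutoff, classifies the donor pattern (e.g. ``N2S2``, the classic His2Cys2
zinc finger; ``O1`` with three open sites, the most common artefactual
surface-zinc pattern), applies a minimum-coordinating-residue curation filter
("Clean" policy: at least 3 protein residues within 3.0 Å), and summarizes
ligand-count and pattern statistics over a structure set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure_io import Atom, MetalIon, Residue, Structure

__all__ = [
    "DONOR_ELEMENTS",
    "CoordinationShell",
    "CoordinationPattern",
    "SiteFilterPolicy",
    "DatasetSummary",
    "find_metal_sites",
    "coordination_shell",
    "classify_pattern",
    "apply_filter",
    "summarize_dataset",
]

#: Chemically standard first-shell donor elements for Zn(II).
DONOR_ELEMENTS = frozenset({"N", "O", "S"})

#: Ideal Zn coordination number used for open-site accounting (tetrahedral).
IDEAL_ZN_COORDINATION = 4

#: Fixed element order for canonical pattern labels.
_PATTERN_ORDER = ("N", "O", "S")


@dataclass
class CoordinationShell:
    """A metal ion with its coordinating atoms inside ``cutoff``.

    ``coordinating_atoms`` holds (residue, atom, distance) triples sorted by
    distance; ``n_protein_residues`` counts distinct non-water residues with
    at least one atom in the shell; ``denticity`` maps each residue key to the
    number of atoms it contributes (e.g. a bidentate Asp carboxylate -> 2).
    """

    metal: MetalIon
    cutoff: float
    coordinating_atoms: list[tuple[Residue, Atom, float]]
    structure_id: str = ""

    def __post_init__(self) -> None:
        for _, _, d in self.coordinating_atoms:
            # same 1e-12 A rounding guard as the shell search itself
            if d > self.cutoff + 1e-12:
                raise ValueError("coordinating atom beyond the shell cutoff")

    @property
    def n_atoms(self) -> int:
        return len(self.coordinating_atoms)

    @property
    def n_protein_residues(self) -> int:
        return len({r.key for r, _, _ in self.coordinating_atoms if not r.is_water})

    @property
    def donor_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, a, _ in self.coordinating_atoms:
            counts[a.element] = counts.get(a.element, 0) + 1
        return counts

    @property
    def denticity(self) -> dict[tuple[str, str], int]:
        dent: dict[tuple[str, str], int] = {}
        for r, _, _ in self.coordinating_atoms:
            dent[r.key] = dent.get(r.key, 0) + 1
        return dent


@dataclass
class CoordinationPattern:
    """Canonical donor label (fixed N→O→S order) and open coordination sites."""

    label: str
    open_sites: int


@dataclass
class SiteFilterPolicy:
    """Curation rule for metal sites.

    The default "Clean" reading keeps sites with at least ``min_residues``
    coordinating *protein* residues within ``cutoff``; setting
    ``count_waters_as_residues`` adopts the alternative reading in which
    water ligands also count toward the residue threshold.
    """

    cutoff: float = 3.0
    min_residues: int = 3
    donor_elements: frozenset[str] = DONOR_ELEMENTS
    count_waters_as_residues: bool = False

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.min_residues < 0:
            raise ValueError("min_residues must be non-negative")

    def residue_count(self, shell: CoordinationShell) -> int:
        if self.count_waters_as_residues:
            return len({r.key for r, _, _ in shell.coordinating_atoms})
        return shell.n_protein_residues


@dataclass
class DatasetSummary:
    """Coordination statistics over a structure set (one shell per Zn site)."""

    ligand_count_histogram: dict[int, int]
    pattern_frequencies: dict[str, int]
    fraction_zero: float
    fraction_le2: float
    n_sites: int
    table: pd.DataFrame = field(repr=False, default_factory=pd.DataFrame)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def find_metal_sites(s: Structure, element: str = "ZN") -> list[MetalIon]:
    """All metal ions of the requested element, in file order."""
    el = element.strip().upper()
    return [m for m in s.metals if m.element == el]


def coordination_shell(
    s: Structure, m: MetalIon, cutoff: float = 3.0, structure_id: str = ""
) -> CoordinationShell:
    """First coordination shell of metal ``m``: every N/O/S atom (any residue
    atom, side chain or backbone, including water oxygen) with metal–atom
    distance ≤ ``cutoff`` (inclusive).  Carbon, phosphorus and hydrogens never
    coordinate here.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    donors: list[tuple[Residue, Atom]] = [
        (res, a)
        for res in s.residues
        for a in res.atoms
        if a.element in DONOR_ELEMENTS
    ]
    hits: list[tuple[Residue, Atom, float]] = []
    if donors:
        coords = np.array([a.coords for _, a in donors])
        tree = cKDTree(coords)
        # kd-tree narrows candidates; the inclusive boundary is decided on the
        # exact distance so a donor at exactly `cutoff` is kept.
        idx = tree.query_ball_point(m.coords, cutoff + 1e-9)
        for i in sorted(idx):
            res, a = donors[i]
            d = float(np.linalg.norm(a.coords - m.coords))
            # inclusive boundary with a 1e-12 A guard, so sites constructed
            # at exactly the cutoff survive floating-point rounding
            if d <= cutoff + 1e-12:
                hits.append((res, a, d))
    hits.sort(key=lambda t: (t[2], t[0].key, t[1].name))
    return CoordinationShell(
        metal=m, cutoff=cutoff, coordinating_atoms=hits, structure_id=structure_id
    )


def classify_pattern(shell: CoordinationShell) -> CoordinationPattern:
    """Canonical donor-composition label and open-site count.

    The label lists donor elements with multiplicities in fixed N, O, S order
    ("N2S2", "O1", ...); an empty shell yields the empty label.  Open sites
    assume ideal tetrahedral coordination for Zn: ``max(0, 4 − n_atoms)``, so
    5- and 6-coordinate sites report 0.
    """
    counts = shell.donor_counts
    label = "".join(
        f"{el}{counts[el]}" for el in _PATTERN_ORDER if counts.get(el, 0) > 0
    )
    open_sites = max(0, IDEAL_ZN_COORDINATION - shell.n_atoms)
    return CoordinationPattern(label=label, open_sites=open_sites)


def apply_filter(
    sites: Sequence[CoordinationShell], policy: SiteFilterPolicy
) -> tuple[list[CoordinationShell], list[CoordinationShell]]:
    """Partition shells into (kept, removed) under the curation policy.

    Shells must have been computed at ``policy.cutoff``; mixing cutoffs is an
    error because the residue counts would not mean what the policy assumes.
    Order is preserved in both partitions.
    """
    for shell in sites:
        if shell.cutoff != policy.cutoff:
            raise ValueError(
                f"shell computed at {shell.cutoff} Å but policy expects "
                f"{policy.cutoff} Å"
            )
    kept = [s for s in sites if policy.residue_count(s) >= policy.min_residues]
    removed = [s for s in sites if policy.residue_count(s) < policy.min_residues]
    return kept, removed


def summarize_dataset(
    structure_set: Iterable[Structure | tuple[str, Structure]],
    cutoff: float = 3.0,
    element: str = "ZN",
) -> DatasetSummary:
    """Coordination census over a structure set.

    Computes a shell for every metal of ``element`` in every structure and
    returns the ligand-count histogram, pattern frequencies, the fraction of
    sites with zero coordinating protein residues, the fraction with two or
    fewer, and a tidy one-row-per-site table for downstream plotting.
    Structures may be given bare or as (id, structure) pairs.
    """
    rows: list[dict] = []
    histogram: dict[int, int] = {}
    patterns: dict[str, int] = {}
    n_zero = n_le2 = n_sites = 0
    for item in structure_set:
        sid, s = item if isinstance(item, tuple) else ("", item)
        for m in find_metal_sites(s, element):
            shell = coordination_shell(s, m, cutoff, structure_id=sid)
            pat = classify_pattern(shell)
            nres = shell.n_protein_residues
            n_sites += 1
            histogram[nres] = histogram.get(nres, 0) + 1
            if pat.label:
                patterns[pat.label] = patterns.get(pat.label, 0) + 1
            n_zero += nres == 0
            n_le2 += nres <= 2
            counts = shell.donor_counts
            rows.append(
                {
                    "structure_id": sid,
                    "metal_id": m.id,
                    "n_atoms": shell.n_atoms,
                    "n_residues": nres,
                    "pattern": pat.label,
                    "open_sites": pat.open_sites,
                    "n_N": counts.get("N", 0),
                    "n_O": counts.get("O", 0),
                    "n_S": counts.get("S", 0),
                }
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "structure_id", "metal_id", "n_atoms", "n_residues",
            "pattern", "open_sites", "n_N", "n_O", "n_S",
        ],
    )
    return DatasetSummary(
        ligand_count_histogram=dict(sorted(histogram.items())),
        pattern_frequencies=dict(sorted(patterns.items())),
        fraction_zero=n_zero / n_sites if n_sites else float("nan"),
        fraction_le2=n_le2 / n_sites if n_sites else float("nan"),
        n_sites=n_sites,
        table=table,
    )
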