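"""Deterministic synthetic structures for testing and benchmarking.

Everything the other modules consume can be generated here without any
download: idealized zinc coordination sites (tetrahedral/octahedral donor
geometry with minimal parent residues), toy protein scaffolds (helix,
hairpin, compact cluster), scaffolds with a planted four-residue metal
pocket whose Cβ geometry sits in the high-weight region of the placement
kernel, soak-like structures carrying many weakly coordinated surface
zincs, and census sets with an exact, requested ligand-count distribution.

Residue geometry is idealized, not rotamer-accurate: parent residues are
built outward from the donor atom along the coordination direction with
standard bond lengths, which is sufficient for residue-level counting,
denticity and Cβ-based scoring.  Every generator self-validates its key
promise (shell counts, burial, pocket feasibility) before returning, and is
byte-stable for a given seed.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial.transform import Rotation

from .objectives import ScaffoldContext, SurrogateParams, ideal_cbeta, _nerf_place
from .structure_io import Atom, MetalIon, Residue, Structure

__all__ = [
    "make_tetrahedral_site",
    "make_toy_scaffold",
    "plant_pocket",
    "make_census_set",
    "make_soak_structure",
]

#: default metal–donor bond lengths, Å, by donor element (Zn values)
DEFAULT_BOND_LENGTHS = {"N": 2.05, "S": 2.30, "O": 2.10}

_TETRAHEDRAL = np.array([(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)]) / math.sqrt(3)
_OCTAHEDRAL = np.array([(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)])

# element of a donor atom, from its PDB name
_DONOR_ELEMENT = {
    "NE2": "N", "ND1": "N", "NZ": "N", "N": "N",
    "SG": "S", "SD": "S",
    "OD1": "O", "OD2": "O", "OE1": "O", "OE2": "O", "OG": "O", "OH": "O", "O": "O",
}


def _perpendicular(u: np.ndarray) -> np.ndarray:
    ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    v = np.cross(u, ref)
    return v / np.linalg.norm(v)


def _build_parent_residue(
    res_type: str,
    donor_names: list[str],
    donor_coords: list[np.ndarray],
    u: np.ndarray,
    seq_pos: int,
) -> Residue:
    """Minimal idealized residue extending outward (direction u) from its donor."""
    atoms = [
        Atom(name, _DONOR_ELEMENT.get(name, name[0]), c)
        for name, c in zip(donor_names, donor_coords)
    ]
    if res_type == "HOH":
        return Residue("W", seq_pos, "HOH", atoms)
    anchor = donor_coords[0]
    v = _perpendicular(u)
    # stub side chain out to CB, then a short backbone so CA/N/C/CB all exist
    if res_type == "CYS":
        cb = anchor + 1.81 * u
    elif res_type in ("ASP", "GLU", "ASN", "GLN"):
        carboxyl_c = anchor + 1.25 * (0.5 * u + 0.866 * v)
        cname = {"ASP": "CG", "GLU": "CD", "ASN": "CG", "GLN": "CD"}[res_type]
        atoms.append(Atom(cname, "C", carboxyl_c))
        cb = carboxyl_c + 1.52 * u
    else:  # HIS and anything ring-like: skip ring atoms, stub straight to CB
        cb = anchor + 2.2 * u
    ca = cb + 1.53 * (0.94 * u + 0.34 * v)
    n = ca + 1.46 * (0.33 * u + 0.94 * v)
    c = ca + 1.53 * (0.33 * u - 0.94 * v)
    atoms.extend(
        [Atom("CB", "C", cb), Atom("CA", "C", ca), Atom("N", "N", n), Atom("C", "C", c)]
    )
    return Residue("A", seq_pos, res_type, atoms)


def make_tetrahedral_site(
    donors: list[tuple],
    bond_lengths: dict[str, float] | None = None,
) -> Structure:
    """Idealized Zn site: metal at the origin, donors on ideal vertices.

    ``donors`` holds up to 6 entries, one residue each, as
    ``(res_type, donor_atom_name)`` or ``(res_type, donor_atom_name,
    distance)``.  A ``"+"``-joined atom name with a tuple of distances makes
    a bidentate residue (e.g. ``("ASP", "OD1+OD2", (2.1, 2.4))``).  Donors
    sit on tetrahedral directions (octahedral beyond four) at element-typical
    metal–donor distances unless overridden.  Self-validates that the number
    of donor atoms within 3.0 Å matches construction.
    """
    if len(donors) > 6:
        raise ValueError("at most 6 donors supported (octahedral maximum)")
    lengths = dict(DEFAULT_BOND_LENGTHS)
    if bond_lengths:
        lengths.update(bond_lengths)
    directions = _TETRAHEDRAL if len(donors) <= 4 else _OCTAHEDRAL

    residues: list[Residue] = []
    expected_in_shell = 0
    for i, entry in enumerate(donors):
        res_type, atom_spec = entry[0], entry[1]
        override = entry[2] if len(entry) > 2 else None
        u = directions[i]
        names = atom_spec.split("+")
        if len(names) == 1:
            el = _DONOR_ELEMENT.get(names[0], names[0][0])
            d = float(override) if override is not None else lengths[el]
            coords = [d * u]
        else:
            dists = override or tuple(lengths[_DONOR_ELEMENT[n]] for n in names)
            v = _perpendicular(u)
            coords = []
            for j, (name, d) in enumerate(zip(names, dists)):
                w = u if j == 0 else math.cos(math.radians(40)) * u + math.sin(
                    math.radians(40)
                ) * v
                coords.append(float(d) * w)
        expected_in_shell += sum(
            1 for c in coords if np.linalg.norm(c) <= 3.0 + 1e-12
        )
        residues.append(_build_parent_residue(res_type, names, coords, u, i + 1))

    # renumber waters onto their own chain positions to keep keys unique
    for i, r in enumerate(residues):
        r.seq_pos = i + 1
    zn = MetalIon(element="ZN", coords=np.zeros(3), source="observed", id="ZN1")
    s = Structure(residues=residues, metals=[zn], title="synthetic Zn site")
    _validate_shell_count(s, zn, expected_in_shell)
    return s


def _validate_shell_count(s: Structure, m: MetalIon, expected: int, cutoff: float = 3.0) -> None:
    # brute-force scan, independent of the coordination module's kd-tree path
    found = sum(
        1
        for res in s.residues
        for a in res.atoms
        if a.element in {"N", "O", "S"}
        and np.linalg.norm(a.coords - m.coords) <= cutoff + 1e-12
    )
    if found != expected:
        raise AssertionError(
            f"fixture self-validation failed: {found} donors in shell, "
            f"expected {expected}"
        )


# ---------------------------------------------------------------------------
# Toy scaffolds
# ---------------------------------------------------------------------------

_BB = {  # standard backbone internal coordinates
    "n_ca": 1.458, "ca_c": 1.525, "c_n": 1.329, "c_o": 1.231,
    "ang_n_ca_c": 111.2, "ang_ca_c_n": 116.2, "ang_c_n_ca": 121.7,
}

_FOLD_DIHEDRALS = {
    "helix": (-57.0, -47.0),
    "strand": (-139.0, 135.0),
}


def _dihedral_chain(n_residues: int, phi_psi: list[tuple[float, float]]) -> list[dict]:
    """Build backbone coordinates from a per-residue (φ, ψ) list (ω = 180°)."""
    bb = _BB
    res: list[dict] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([bb["n_ca"], 0.0, 0.0])
    ang = math.radians(bb["ang_n_ca_c"])
    c0 = ca0 + bb["ca_c"] * np.array([-math.cos(ang), math.sin(ang), 0.0])
    res.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_residues):
        prev = res[-1]
        psi_prev = phi_psi[i - 1][1]
        phi = phi_psi[i][0]
        n = _nerf_place(prev["N"], prev["CA"], prev["C"], bb["c_n"], bb["ang_ca_c_n"], psi_prev)
        ca = _nerf_place(prev["CA"], prev["C"], n, bb["n_ca"], bb["ang_c_n_ca"], 180.0)
        c = _nerf_place(prev["C"], n, ca, bb["ca_c"], bb["ang_n_ca_c"], phi)
        res.append({"N": n, "CA": ca, "C": c})
    for i, r in enumerate(res):
        psi = phi_psi[i][1]
        r["O"] = _nerf_place(r["N"], r["CA"], r["C"], _BB["c_o"], 120.5, psi + 180.0)
        r["CB"] = ideal_cbeta(r["N"], r["CA"], r["C"])
    return res


def _residues_from_backbone(coords: list[dict]) -> list[Residue]:
    out = []
    for i, r in enumerate(coords):
        atoms = [
            Atom("N", "N", r["N"]), Atom("CA", "C", r["CA"]),
            Atom("C", "C", r["C"]), Atom("O", "O", r["O"]), Atom("CB", "C", r["CB"]),
        ]
        out.append(Residue("A", i + 1, "ALA", atoms))
    return out


def make_toy_scaffold(n_residues: int, fold: str = "helix") -> Structure:
    """Deterministic toy backbone: ``helix``, ``hairpin`` or ``compact_cluster``.

    The compact cluster places Cα on a dense lattice so every position
    exceeds the default burial threshold (validated on emission); the helix
    and hairpin are dihedral-built chains with ideal geometry.
    """
    if n_residues < 8:
        raise ValueError("toy scaffolds need at least 8 residues")
    if fold == "helix":
        coords = _dihedral_chain(n_residues, [_FOLD_DIHEDRALS["helix"]] * n_residues)
        residues = _residues_from_backbone(coords)
    elif fold == "hairpin":
        residues = _hairpin(n_residues)
    elif fold == "compact_cluster":
        residues = _compact_cluster(n_residues)
    else:
        raise ValueError(f"unknown fold {fold!r}")
    return Structure(residues=residues, title=f"toy {fold} scaffold")


def _hairpin(n_residues: int, separation: float = 10.0, step: float = 3.5) -> list[Residue]:
    """Two pleated antiparallel strands joined by a 3-residue arc.

    The strands run along x at y = 0 and y = ``separation`` with Cβ pointing
    ±z (outward), so Cβ vectors of different residues never converge on a
    common point — donor clusters buy little metal score unless a pocket is
    planted.  The wide inter-strand gap is deliberate: this is an idealized
    design scaffold, not a hydrogen-bonded β-sheet.
    """
    n_turn = 3
    n1 = (n_residues - n_turn) // 2
    n2 = n_residues - n_turn - n1
    cas: list[np.ndarray] = []
    for i in range(n1):  # strand 1, +x
        cas.append(np.array([step * i, 0.0, 0.5 * (-1) ** i]))
    x_end = step * (n1 - 1)
    for j in range(1, n_turn + 1):  # arc around to the return strand
        ang = math.pi * j / (n_turn + 1)
        cas.append(
            np.array(
                [x_end + (separation / 2) * math.sin(ang),
                 (separation / 2) * (1 - math.cos(ang)), 0.0]
            )
        )
    for k in range(n2):  # strand 2, -x
        cas.append(np.array([x_end - step * (k + 1), separation, 0.5 * (-1) ** k]))
    residues = []
    for i, ca in enumerate(cas):
        direction = 1.0 if i < n1 + n_turn else -1.0
        n = ca + np.array([-1.20 * direction, 0.35, 0.35])
        c = ca + np.array([1.20 * direction, 0.35, -0.35])
        o = c + np.array([0.0, 1.15, -0.4])
        cb_dir = np.array([0.0, 0.0, 1.0 if i % 2 == 0 else -1.0])
        cb = ca + 1.521 * cb_dir
        atoms = [
            Atom("N", "N", n), Atom("CA", "C", ca), Atom("C", "C", c),
            Atom("O", "O", o), Atom("CB", "C", cb),
        ]
        residues.append(Residue("A", i + 1, "ALA", atoms))
    return residues


def _compact_cluster(n_residues: int, spacing: float = 4.0) -> list[Residue]:
    params = SurrogateParams()
    if n_residues <= params.burial_threshold:
        raise ValueError(
            f"compact_cluster needs more than {params.burial_threshold} residues "
            "to satisfy the burial guarantee"
        )
    # lattice points sorted by distance from the center -> a compact ball
    r = 4
    pts = np.array(
        [(i, j, k) for i in range(-r, r + 1) for j in range(-r, r + 1) for k in range(-r, r + 1)],
        dtype=float,
    )
    order = np.lexsort((pts[:, 2], pts[:, 1], pts[:, 0], np.linalg.norm(pts, axis=1)))
    cas = pts[order[:n_residues]] * spacing
    residues = []
    for i, ca in enumerate(cas):
        n = ca + np.array([-1.20, 0.50, 0.30])
        c = ca + np.array([1.20, 0.50, -0.30])
        o = c + np.array([0.40, 1.10, 0.00])
        cb = ideal_cbeta(n, ca, c)
        atoms = [
            Atom("N", "N", n), Atom("CA", "C", ca), Atom("C", "C", c),
            Atom("O", "O", o), Atom("CB", "C", cb),
        ]
        residues.append(Residue("A", i + 1, "ALA", atoms))
    # burial self-check under the default surrogate parameters
    d = np.linalg.norm(cas[:, None, :] - cas[None, :, :], axis=2)
    neighbors = (d <= params.burial_radius).sum(axis=1) - 1
    if neighbors.min() < params.burial_threshold:
        raise AssertionError(
            "compact_cluster self-validation failed: a position is not buried"
        )
    return residues


# ---------------------------------------------------------------------------
# Planted pocket
# ---------------------------------------------------------------------------

def plant_pocket(
    scaffold: Structure,
    positions: tuple[int, int, int, int],
    params: SurrogateParams | None = None,
) -> Structure:
    """Redirect four Cβ vectors so a placement-grid node sees all four at 4.0 Å.

    ``positions`` are 0-based residue indices, mutually non-adjacent in
    sequence.  Backbone (Cα) coordinates are untouched; only the four Cβ
    atoms move.  The target point is snapped to the axis-aligned placement
    grid the metal-site objective will use, so a sequence carrying donors at
    the pocket scores the kernel maximum exactly.  Raises if no nearby grid
    node admits a bounded Cβ adjustment.
    """
    params = params or SurrogateParams()
    if len(positions) != 4 or len(set(positions)) != 4:
        raise ValueError("exactly 4 distinct pocket positions required")
    pos = sorted(positions)
    if any(b - a < 2 for a, b in zip(pos, pos[1:])):
        raise ValueError("pocket positions must be mutually non-adjacent in sequence")
    residues = scaffold.protein_residues
    if max(pos) >= len(residues):
        raise ValueError("pocket position beyond scaffold length")

    target_r = params.d_peak  # 4.0 Å: the kernel maximum
    # bounded adjustment: the Cβ must stay a plausible bond away from its Cα
    feasible = lambda dist: 0.8 <= abs(dist - target_r) <= 2.6  # noqa: E731

    new = _copy_structure(scaffold)
    new_res = new.protein_residues
    cas = {i: new_res[i].atom("CA").coords for i in pos}
    centroid = np.mean(list(cas.values()), axis=0)

    # pass 1: provisional Cβ toward the centroid, to get a stable grid origin
    for i in pos:
        u = centroid - cas[i]
        u /= np.linalg.norm(u)
        new_res[i].atom("CB").coords = cas[i] + 1.521 * u
    for _ in range(2):  # origin can shift once if a pocket Cβ was extremal
        ctx = ScaffoldContext(new, params)
        origin = ctx.cb.min(axis=0) - params.grid_padding
        node = _feasible_grid_node(origin, params.grid_spacing, centroid, cas, feasible)
        if node is None:
            raise ValueError(
                "geometric infeasibility: no placement-grid node near the pocket "
                "centroid admits a bounded Cβ adjustment"
            )
        for i in pos:
            u = cas[i] - node
            d = np.linalg.norm(u)
            new_res[i].atom("CB").coords = node + target_r * (u / d)

    # self-validation: the node is on the final grid and all four Cβ hit 4.0 Å
    ctx = ScaffoldContext(new, params)
    on_grid = np.min(np.linalg.norm(ctx.grid - node, axis=1))
    dists = [np.linalg.norm(new_res[i].atom("CB").coords - node) for i in pos]
    if on_grid > 1e-6 or any(abs(d - target_r) > 1e-6 for d in dists):
        raise AssertionError("planted-pocket self-validation failed")
    new.title = f"{scaffold.title} + planted pocket {tuple(pos)}"
    return new


def _feasible_grid_node(origin, spacing, centroid, cas, feasible):
    base = np.round((centroid - origin) / spacing)
    candidates = []
    for di in (-2, -1, 0, 1, 2):
        for dj in (-2, -1, 0, 1, 2):
            for dk in (-2, -1, 0, 1, 2):
                node = origin + (base + np.array([di, dj, dk])) * spacing
                candidates.append(node)
    candidates.sort(key=lambda g: (np.linalg.norm(g - centroid), g[0], g[1], g[2]))
    for g in candidates:
        if all(feasible(np.linalg.norm(ca - g)) for ca in cas.values()):
            return g
    return None


def _copy_structure(s: Structure) -> Structure:
    residues = [
        Residue(
            r.chain_id, r.seq_pos, r.res_type,
            [Atom(a.name, a.element, a.coords.copy(), a.occupancy, a.altloc) for a in r.atoms],
            r.icode,
        )
        for r in s.residues
    ]
    metals = [MetalIon(m.element, m.coords.copy(), m.source, m.id) for m in s.metals]
    return Structure(residues=residues, metals=metals, title=s.title)


# ---------------------------------------------------------------------------
# Census sets
# ---------------------------------------------------------------------------

_DONOR_CYCLE = [("HIS", "NE2"), ("CYS", "SG"), ("ASP", "OD1"), ("GLU", "OE1")]


def _random_rigid(s: Structure, rng: np.random.Generator) -> Structure:
    q = rng.normal(size=4)
    rot = Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()
    t = rng.uniform(-20.0, 20.0, size=3)
    out = _copy_structure(s)
    for r in out.residues:
        for a in r.atoms:
            a.coords = rot @ a.coords + t
    for m in out.metals:
        m.coords = rot @ m.coords + t
    return out


def make_census_set(
    spec: dict[int, int], seed: int = 0
) -> list[tuple[str, Structure]]:
    """One synthetic Zn site per request: ``spec[k] = number of sites with
    exactly k coordinating protein residues`` (k ≤ 6).

    Each site is an idealized donor arrangement, rigidly moved by a seeded
    random rotation+translation, and verified against a brute-force distance
    scan before emission.  Returns (id, structure) pairs.
    """
    rng = np.random.default_rng(seed)
    out: list[tuple[str, Structure]] = []
    idx = 0
    for k in sorted(spec):
        if spec[k] < 0:
            raise ValueError("site counts must be non-negative")
        if k > 6:
            raise ValueError("at most 6 coordinating residues per synthetic site")
        for _ in range(spec[k]):
            donors = [_DONOR_CYCLE[j % len(_DONOR_CYCLE)] for j in range(k)]
            site = make_tetrahedral_site(donors)
            site = _random_rigid(site, rng)
            _validate_shell_count(site, site.metals[0], k)
            idx += 1
            sid = f"SYN{idx:04d}"
            site.title = f"synthetic census site {sid} ({k} residues)"
            out.append((sid, site))
    return out


def make_soak_structure(n_zincs: int = 20, seed: int = 0) -> Structure:
    """A soak-like artefact: many surface zincs, each with one carboxylate ligand.

    Emulates depositions where crystallization additives leave dozens of
    weakly coordinated zincs (single Asp/Glu oxygen within 3.0 Å).
    """
    rng = np.random.default_rng(seed)
    residues: list[Residue] = []
    metals: list[MetalIon] = []
    for i in range(n_zincs):
        site = make_tetrahedral_site([("ASP", "OD1")])
        site = _random_rigid(site, rng)
        center = site.metals[0].coords + np.array([40.0 * i, 0.0, 0.0])
        shift = np.array([40.0 * i, 0.0, 0.0])
        for r in site.residues:
            for a in r.atoms:
                a.coords = a.coords + shift
            r.seq_pos = len(residues) + 1
            residues.append(r)
        metals.append(MetalIon("ZN", center, "observed", id=f"ZN{i + 1}"))
    s = Structure(residues=residues, metals=metals, title="synthetic zinc soak")
    for m in metals:
        _validate_shell_count(s, m, 1)
    return s
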