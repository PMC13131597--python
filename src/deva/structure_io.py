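"""Structure I/O and rigid-body superposition.

Reads and writes fixed-column PDB files into a light-weight structure model
(chains -> residues -> atoms, plus metal ions kept separately), and provides
Kabsch least-squares superposition, Cα-RMSD between a design model and an
experimental structure, and point transformation for mapping a designed metal
into the experimental frame.

Parsing is backed by gemmi; on top of it this module applies the conventions
used throughout the package: alternate locations are resolved to the highest
occupancy conformer (ties: first in file), hydrogens are dropped, HETATM
records whose element is a metal become :class:`MetalIon`, waters are retained
as ordinary residues with res_type ``"HOH"``, and only the first model of a
multi-model file is read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Atom",
    "Residue",
    "MetalIon",
    "Structure",
    "Superposition",
    "PDBParseError",
    "read_structure",
    "write_structure",
    "kabsch_superpose",
    "ca_rmsd",
    "transform_point",
]

# Elements treated as metals when encountered in HETATM records.  Covers the
# biologically common di-/trivalent cations; ZN is the one the rest of the
# package cares about.
METAL_ELEMENTS = frozenset(
    "LI NA K RB CS MG CA SR BA MN FE CO NI CU ZN CD HG PB "
    "AL GA V CR MO W PT AU AG".split()
)

_PDB_COORD_MIN, _PDB_COORD_MAX = -999.999, 9999.999


class PDBParseError(ValueError):
    """Raised when a PDB record cannot be parsed; carries the line number."""


@dataclass
class Atom:
    """A single non-hydrogen atom with PDB-convention naming."""

    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name!r}: coords must be a finite 3-vector")
        self.element = self.element.strip().upper()


@dataclass
class Residue:
    """One residue: chain id, author sequence position (+ insertion code), atoms."""

    chain_id: str
    seq_pos: int
    res_type: str
    atoms: list[Atom] = field(default_factory=list)
    icode: str = ""

    @property
    def key(self) -> tuple[str, str]:
        """(chain_id, seq_pos with any insertion code appended) — unique in a Structure."""
        return (self.chain_id, f"{self.seq_pos}{self.icode}")

    @property
    def is_water(self) -> bool:
        return self.res_type == "HOH"

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class MetalIon:
    """A metal ion; ``source`` records whether it was observed, designed or predicted."""

    element: str = "ZN"
    coords: np.ndarray = field(default_factory=lambda: np.zeros(3))
    source: str = "observed"
    id: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.element = self.element.strip().upper()
        if self.element not in METAL_ELEMENTS:
            raise ValueError(f"{self.element!r} is not a recognized metal element")
        if self.source not in {"observed", "designed", "predicted"}:
            raise ValueError(f"invalid metal source {self.source!r}")


@dataclass
class Structure:
    """An ordered set of residues plus metal ions; the substrate of all modules."""

    residues: list[Residue] = field(default_factory=list)
    metals: list[MetalIon] = field(default_factory=list)
    title: str = ""

    def __post_init__(self) -> None:
        keys = [r.key for r in self.residues]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate residue (chain_id, seq_pos) keys")

    @property
    def protein_residues(self) -> list[Residue]:
        return [r for r in self.residues if not r.is_water]

    def residue_by_key(self, key: tuple[str, str]) -> Residue | None:
        for r in self.residues:
            if r.key == key:
                return r
        return None


@dataclass
class Superposition:
    """A proper rigid transformation (rotation then translation) and its RMSD."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if not math.isclose(float(np.linalg.det(self.rotation)), 1.0, abs_tol=1e-8):
            raise ValueError("rotation determinant is not +1 (improper rotation)")
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")

    def inverse(self) -> "Superposition":
        r_inv = self.rotation.T
        return Superposition(r_inv, -r_inv @ self.translation, self.rmsd)


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _validate_fixed_columns(pdb_text: str) -> None:
    # gemmi is forgiving; enforce the fixed-column contract up front so that a
    # malformed ATOM/HETATM record is reported with its line number.
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        if len(line) < 54:
            raise PDBParseError(
                f"line {lineno}: record too short for coordinate columns"
            )
        for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
            try:
                float(line[lo:hi])
            except ValueError:
                raise PDBParseError(
                    f"line {lineno}: cannot parse {what} coordinate "
                    f"{line[lo:hi]!r}"
                ) from None


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep, per atom name, the altloc with highest occupancy (ties: file order)."""
    best: dict[str, Atom] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in best:
            best[a.name] = a
            order.append(a.name)
        elif a.occupancy > best[a.name].occupancy:
            best[a.name] = a
    return [best[n] for n in order]


def read_structure(pdb_text: str, assembly: str | None = None) -> Structure:
    """Parse PDB text into a :class:`Structure`.

    Parameters
    ----------
    pdb_text:
        Contents of a PDB file (fixed-column v3.3).
    assembly:
        Optional biological-assembly name (e.g. ``"1"``); when given, the
        BIOMT operators of that assembly are applied before conversion, so a
        coordination census can be run on the first biological assembly
        rather than the asymmetric unit.
    """
    if not pdb_text.strip():
        raise PDBParseError("empty input: no PDB records found")
    _validate_fixed_columns(pdb_text)

    st = gemmi.read_pdb_string(pdb_text)
    if assembly is not None:
        st.transform_to_assembly(assembly, gemmi.HowToNameCopiedChain.AddNumber)
    if len(st) == 0:
        raise PDBParseError("no ATOM or HETATM records found")
    model = st[0]  # first model only

    residues: list[Residue] = []
    metals: list[MetalIon] = []
    n_atom_records = 0
    for chain in model:
        for gres in chain:
            atoms: list[Atom] = []
            for ga in gres:
                n_atom_records += 1
                el = ga.element.name.upper()
                if el == "H" or el == "D":
                    continue
                altloc = ga.altloc if ga.altloc not in ("\0", " ", "") else ""
                atoms.append(
                    Atom(
                        name=ga.name,
                        element=el,
                        coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        occupancy=ga.occ,
                        altloc=altloc,
                    )
                )
            atoms = _resolve_altlocs(atoms)
            if not atoms:
                continue
            res_name = gres.name.strip().upper()
            # single-atom HETATM metals become MetalIon entries
            if len(atoms) == 1 and atoms[0].element in METAL_ELEMENTS and (
                gres.het_flag == "H" or res_name in METAL_ELEMENTS
            ):
                a = atoms[0]
                metals.append(
                    MetalIon(
                        element=a.element,
                        coords=a.coords,
                        source="observed",
                        id=f"{chain.name}:{gres.seqid.num}",
                    )
                )
                continue
            residues.append(
                Residue(
                    chain_id=chain.name,
                    seq_pos=gres.seqid.num,
                    res_type=res_name,
                    atoms=atoms,
                    icode=(gres.seqid.icode or "").strip(),
                )
            )
    if n_atom_records == 0:
        raise PDBParseError("no ATOM or HETATM records found")
    title = st.info["_struct.title"] if "_struct.title" in st.info else ""
    return Structure(residues=residues, metals=metals, title=title)


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def _format_atom_name(name: str, element: str) -> str:
    # PDB convention: element symbol occupies columns 13-14, so 1-letter
    # elements with short names are indented by one space.
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def _check_coord_range(coords: np.ndarray) -> None:
    if np.any(coords < _PDB_COORD_MIN) or np.any(coords > _PDB_COORD_MAX):
        raise ValueError(
            "coordinates outside the representable PDB column range "
            f"[{_PDB_COORD_MIN}, {_PDB_COORD_MAX}]"
        )


def write_structure(s: Structure) -> str:
    """Serialize a :class:`Structure` to fixed-column PDB text.

    Metals are emitted as single-atom HETATM records; waters as HETATM
    residues.  Round-trips with :func:`read_structure` to the PDB column
    precision of 1e-3 Å.
    """
    if not s.residues and not s.metals:
        raise ValueError("cannot write an empty structure")
    lines: list[str] = []
    if s.title:
        lines.append(f"TITLE     {s.title[:70]}")
    serial = 0
    for res in s.residues:
        record = "HETATM" if res.is_water else "ATOM  "
        for a in res.atoms:
            serial += 1
            _check_coord_range(a.coords)
            x, y, z = a.coords
            lines.append(
                f"{record}{serial:5d} {_format_atom_name(a.name, a.element)}"
                f"{a.altloc or ' '}{res.res_type:>3s} {res.chain_id[:1] or 'A'}"
                f"{res.seq_pos:4d}{res.icode or ' '}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}"
                f"          {a.element:>2s}"
            )
    for i, m in enumerate(s.metals, start=1):
        serial += 1
        _check_coord_range(m.coords)
        x, y, z = m.coords
        lines.append(
            f"HETATM{serial:5d} {m.element:<4s} {m.element:>3s} M{i:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {m.element:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(
    mobile: Sequence[Sequence[float]] | np.ndarray,
    reference: Sequence[Sequence[float]] | np.ndarray,
) -> Superposition:
    """Least-squares optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns the proper rotation R and translation t minimizing
    RMS(R·mobile + t − reference), together with the minimized RMSD.
    Requires at least 3 non-collinear point pairs.
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise ValueError("mobile and reference must be equal-shape (n, 3) arrays")
    n = mob.shape[0]
    if n < 3:
        raise ValueError("at least 3 point pairs are required")
    mob_c = mob - mob.mean(axis=0)
    ref_c = ref - ref.mean(axis=0)
    # collinearity check: rank of the centered point cloud
    if np.linalg.matrix_rank(mob_c, tol=1e-8) < 2 or np.linalg.matrix_rank(ref_c, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) input points")
    rot, _ = Rotation.align_vectors(ref_c, mob_c)
    R = rot.as_matrix()
    t = ref.mean(axis=0) - R @ mob.mean(axis=0)
    # recompute the RMSD from the transform itself: align_vectors' reported
    # residual loses precision to cancellation when the fit is near-exact
    rmsd = float(np.sqrt(np.mean(np.sum((mob @ R.T + t - ref) ** 2, axis=1))))
    return Superposition(rotation=R, translation=t, rmsd=rmsd)


def transform_point(sp: Superposition, p: Sequence[float] | np.ndarray) -> np.ndarray:
    """Apply a superposition to a single 3-vector: rotation·p + translation."""
    return sp.rotation @ np.asarray(p, dtype=float) + sp.translation


def _paired_ca(
    model: Structure,
    experimental: Structure,
    pairing: Iterable[tuple[tuple[str, str], tuple[str, str]]] | None,
) -> tuple[np.ndarray, np.ndarray]:
    if pairing is None:
        exp_keys = {r.key for r in experimental.protein_residues}
        pairing = [(r.key, r.key) for r in model.protein_residues if r.key in exp_keys]
        if not pairing:
            raise ValueError(
                "no residues share (chain, seq_pos) between model and "
                "experimental structure; provide an explicit pairing"
            )
    mob, ref, missing = [], [], []
    for mkey, ekey in pairing:
        mres = model.residue_by_key(tuple(mkey))
        eres = experimental.residue_by_key(tuple(ekey))
        for res, key, which in ((mres, mkey, "model"), (eres, ekey, "experimental")):
            if res is None:
                missing.append(f"{which} residue {key} not found")
            elif res.atom("CA") is None:
                missing.append(f"{which} residue {key} has no CA atom")
        if mres is not None and eres is not None:
            ca_m, ca_e = mres.atom("CA"), eres.atom("CA")
            if ca_m is not None and ca_e is not None:
                mob.append(ca_m.coords)
                ref.append(ca_e.coords)
    if missing:
        raise ValueError("; ".join(missing))
    return np.array(mob), np.array(ref)


def ca_rmsd(
    model: Structure,
    experimental: Structure,
    pairing: Iterable[tuple[tuple[str, str], tuple[str, str]]] | None = None,
) -> float:
    """Cα-RMSD between a design model and an experimental structure.

    Pairs residues by identical ``(chain, seq_pos)`` when ``pairing`` is
    omitted, superposes the paired Cα atoms and returns the minimized RMSD.
    """
    mob, ref = _paired_ca(model, experimental, pairing)
    return kabsch_superpose(mob, ref).rmsd


def superpose_ca(
    model: Structure,
    experimental: Structure,
    pairing: Iterable[tuple[tuple[str, str], tuple[str, str]]] | None = None,
) -> Superposition:
    """Full Cα superposition (model -> experimental frame), for metal mapping."""
    mob, ref = _paired_ca(model, experimental, pairing)
    return kabsch_superpose(mob, ref)
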