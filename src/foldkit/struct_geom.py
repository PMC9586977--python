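"""Coordinate-level validation of BIR-like modules and the tandem fold.

Provides the geometric measurements used to compare a zf-C3HC or Rsm1
module against canonical BIR domains: optimal rigid-body (Kabsch)
superposition and RMSD, helix axes and inter-helix tilt angles,
tetrahedral Zn-coordination geometry, and the hydrophobic inter-module
contact interface.

Structures are read from PDB or mmCIF through gemmi into a lightweight
in-memory model keyed by author residue numbering (with insertion
codes), which is the numbering used throughout the sequence analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "StructureModel",
    "Superposition",
    "HelixAxis",
    "ZnSite",
    "ContactPair",
    "GeometryError",
    "HYDROPHOBIC_RESIDUES",
    "load_structure",
    "kabsch_superpose",
    "helix_axis",
    "interhelix_angle",
    "superpose_modules",
    "zn_coordination",
    "interface_contacts",
]

logger = logging.getLogger(__name__)

#: Residues counted as hydrophobic at the inter-module interface.
HYDROPHOBIC_RESIDUES = frozenset(
    {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "TYR", "PRO"}
)

#: Donor atom names accepted as Zn ligands, per residue type.
_ZN_DONORS = {
    "CYS": ("SG",),
    "HIS": ("ND1", "NE2"),
}


class GeometryError(ValueError):
    """Raised on inputs that violate a geometric contract."""


@dataclass
class Atom:
    name: str
    element: str
    xyz: np.ndarray  # shape (3,), Å
    occupancy: float = 1.0
    b_iso: float = 0.0
    low_occupancy: bool = False  # occupancy < 0.5: retained but flagged

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise GeometryError(f"atom {self.name}: coordinates must be finite 3-vectors")


@dataclass
class Residue:
    chain: str
    seqid: int            # author residue number
    icode: str            # insertion code, "" if none
    name: str             # three-letter residue name
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.seqid, self.icode)

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_coords(self) -> np.ndarray:
        xyz = [a.xyz for a in self.atoms if a.element.upper() != "H"]
        return np.array(xyz) if xyz else np.empty((0, 3))


@dataclass
class StructureModel:
    """Chains of residues plus separately listed metal atoms."""

    name: str = ""
    residues: list[Residue] = field(default_factory=list)
    # metal atoms as (chain, seqid, element, xyz)
    metals: list[tuple[str, int, str, np.ndarray]] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [r.key for r in self.residues]
        if len(keys) != len(set(keys)):
            raise GeometryError("duplicate residue (chain, number, icode) keys")

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.residues:
            seen.setdefault(r.chain, None)
        return list(seen)

    def residue(self, seqid: int, chain: Optional[str] = None, icode: str = "") -> Optional[Residue]:
        for r in self.residues:
            if r.seqid == seqid and r.icode == icode and (chain is None or r.chain == chain):
                return r
        return None

    def span(self, start: int, end: int, chain: Optional[str] = None) -> list[Residue]:
        return [
            r for r in self.residues
            if start <= r.seqid <= end and (chain is None or r.chain == chain)
        ]

    def ca_coords(self, seqids: Sequence[int], chain: Optional[str] = None) -> dict[int, np.ndarray]:
        out = {}
        for sid in seqids:
            res = self.residue(sid, chain)
            if res is not None:
                ca = res.atom("CA")
                if ca is not None:
                    out[sid] = ca.xyz
        return out

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Return a copy with every coordinate mapped through x' = R x + t."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        new_res = []
        for r in self.residues:
            new_res.append(
                Residue(
                    chain=r.chain, seqid=r.seqid, icode=r.icode, name=r.name,
                    atoms=[
                        Atom(a.name, a.element, R @ a.xyz + t, a.occupancy,
                             a.b_iso, a.low_occupancy)
                        for a in r.atoms
                    ],
                )
            )
        new_metals = [(c, s, e, R @ xyz + t) for c, s, e, xyz in self.metals]
        return StructureModel(name=self.name, residues=new_res, metals=new_metals)

    # -- gemmi interop -----------------------------------------------------

    def to_gemmi(self) -> gemmi.Structure:
        st = gemmi.Structure()
        st.name = self.name or "model"
        model = gemmi.Model("1")
        chains: dict[str, gemmi.Chain] = {}
        for r in self.residues:
            ch = chains.setdefault(r.chain, gemmi.Chain(r.chain))
            res = gemmi.Residue()
            res.name = r.name
            res.seqid = gemmi.SeqId(r.seqid, r.icode or " ")
            for a in r.atoms:
                at = gemmi.Atom()
                at.name = a.name
                at.element = gemmi.Element(a.element)
                at.pos = gemmi.Position(*a.xyz)
                at.occ = a.occupancy
                at.b_iso = a.b_iso
                res.add_atom(at)
            ch.add_residue(res)
        for chain_name, seqid, element, xyz in self.metals:
            ch = chains.setdefault(chain_name, gemmi.Chain(chain_name))
            res = gemmi.Residue()
            res.name = element.upper()
            res.seqid = gemmi.SeqId(seqid, " ")
            res.het_flag = "H"
            at = gemmi.Atom()
            at.name = element.upper()
            at.element = gemmi.Element(element)
            at.pos = gemmi.Position(*xyz)
            res.add_atom(at)
            ch.add_residue(res)
        for ch in chains.values():
            model.add_chain(ch)
        st.add_model(model)
        st.setup_entities()
        return st

    def write_pdb(self, path: str | Path) -> None:
        self.to_gemmi().write_pdb(str(path))


_METAL_ELEMENTS = {"ZN", "MG", "MN", "FE", "CU", "NI", "CO", "CA", "CD", "NA", "K"}
_WATER_NAMES = {"HOH", "WAT", "DOD"}


def load_structure(
    path: str | Path,
    fmt: Optional[str] = None,
    altloc: str = "A",
    keep_waters: bool = False,
) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    The format is inferred from the extension unless ``fmt`` ("pdb" or
    "mmcif") is given.  Alternate locations other than '' or ``altloc``
    are dropped; waters are dropped by default; atoms with occupancy
    below 0.5 are retained but flagged.  Metal atoms are listed
    separately from polymer residues.
    """
    path = Path(path)
    if not path.exists():
        raise GeometryError(f"no such file: {path}")
    try:
        if fmt is None:
            st = gemmi.read_structure(str(path))
        elif fmt.lower() == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt.lower() in ("mmcif", "cif"):
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            raise GeometryError(f"unknown format {fmt!r}; expected PDB or mmCIF")
    except (RuntimeError, ValueError) as exc:
        raise GeometryError(f"failed to parse {path.name}: {exc}") from exc

    if len(st) == 0:
        raise GeometryError(f"{path.name}: file contains no models")

    model = st[0]
    residues: list[Residue] = []
    metals: list[tuple[str, int, str, np.ndarray]] = []
    for chain in model:
        for res in chain:
            rname = res.name.upper()
            if not keep_waters and rname in _WATER_NAMES:
                continue
            if rname in _METAL_ELEMENTS and len(res) == 1:
                at = res[0]
                metals.append(
                    (chain.name, res.seqid.num, at.element.name,
                     np.array([at.pos.x, at.pos.y, at.pos.z]))
                )
                continue
            atoms = []
            for at in res:
                if at.altloc not in ("", "\0") and at.altloc != altloc:
                    continue
                atoms.append(
                    Atom(
                        name=at.name,
                        element=at.element.name,
                        xyz=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        occupancy=at.occ,
                        b_iso=at.b_iso,
                        low_occupancy=at.occ < 0.5,
                    )
                )
            if atoms:
                icode = res.seqid.icode.strip()
                residues.append(
                    Residue(chain.name, res.seqid.num, icode, rname, atoms)
                )
    return StructureModel(name=st.name or path.stem, residues=residues, metals=metals)


# ---------------------------------------------------------------------------
# Rigid-body superposition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Superposition:
    """Least-squares rigid motion mapping a mobile set onto a reference:
    ``x' = rotation @ x + translation``."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_pairs: int

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, float)
        if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise GeometryError("rotation must be a 3x3 orthonormal matrix")
        if np.linalg.det(R) < 0:
            raise GeometryError("rotation must be proper (det = +1)")
        if self.rmsd < 0 or self.n_pairs < 3:
            raise GeometryError("rmsd must be >= 0 and n_pairs >= 3")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ np.asarray(self.rotation).T + self.translation


def kabsch_superpose(P: np.ndarray, Q: np.ndarray) -> Superposition:
    """Optimal proper rotation + translation mapping Q onto P (Kabsch).

    Both inputs are N×3 with paired rows.  Degenerate (collinear or
    fewer than 3) point sets are rejected since the optimal rotation is
    then not unique.
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise GeometryError("P and Q must be N×3 arrays of equal shape")
    n = P.shape[0]
    if n < 3:
        raise GeometryError("need at least 3 paired points")
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    if np.linalg.matrix_rank(Pc, tol=1e-8) < 2 or np.linalg.matrix_rank(Qc, tol=1e-8) < 2:
        raise GeometryError("degenerate (collinear) point set")
    H = Qc.T @ Pc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = P.mean(axis=0) - R @ Q.mean(axis=0)
    diff = (Q @ R.T + t) - P
    rmsd = float(np.sqrt((diff ** 2).sum() / n))
    return Superposition(rotation=R, translation=t, rmsd=rmsd, n_pairs=n)


# ---------------------------------------------------------------------------
# Helix axes and tilt angles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HelixAxis:
    """Principal axis of a helical Cα trace, oriented N→C."""

    direction: np.ndarray
    centroid: np.ndarray
    n_res: int

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, float)
        if not math.isclose(float(np.linalg.norm(d)), 1.0, abs_tol=1e-8):
            raise GeometryError("direction must be a unit vector")
        if self.n_res < 5:
            raise GeometryError("a helix axis needs >= 5 residues")


def helix_axis(ca_coords: np.ndarray) -> HelixAxis:
    """Axis of an ordered helical Cα trace.

    For a helix the second-difference (local curvature) vectors
    ``P[i+1] − 2 P[i] + P[i−1]`` point radially toward the axis and lie
    exactly in the plane perpendicular to it, so the axis is recovered
    as the smallest principal component of those vectors.  Unlike the
    principal axis of the Cα cloud, this is unbiased for the short
    (5–16 residue) helices of BIR-like modules, whose traces cover only
    partial turns.  Degenerate (near-straight) traces fall back to the
    principal axis of the centered coordinates.  The sign is fixed so
    the direction points from the first toward the last residue (N→C).
    """
    X = np.asarray(ca_coords, float)
    if X.ndim != 2 or X.shape[1] != 3:
        raise GeometryError("ca_coords must be N×3")
    n = X.shape[0]
    if n < 5:
        raise GeometryError("need >= 5 consecutive Cα positions")
    centroid = X.mean(axis=0)
    curvature = X[2:] - 2.0 * X[1:-1] + X[:-2]
    if np.linalg.matrix_rank(curvature, tol=1e-8) >= 2:
        _, _, Vt = np.linalg.svd(curvature)
        d = Vt[-1]  # normal of the curvature plane = helix axis
    else:
        _, _, Vt = np.linalg.svd(X - centroid)
        d = Vt[0]
    if float(d @ (X[-1] - X[0])) < 0:
        d = -d
    return HelixAxis(direction=d / np.linalg.norm(d), centroid=centroid, n_res=n)


def interhelix_angle(a: HelixAxis, b: HelixAxis, signed: bool = False) -> float:
    """Angle between two helix axes in degrees.

    Default is the unsigned line–line angle in [0°, 90°]; with
    ``signed=True`` the oriented angle in [0°, 180°] between the N→C
    direction vectors is returned.
    """
    dot = float(np.clip(np.dot(a.direction, b.direction), -1.0, 1.0))
    if not signed:
        dot = abs(dot)
    return math.degrees(math.acos(dot))


def superpose_modules(
    struct_ref: StructureModel,
    struct_mov: StructureModel,
    pairing: Sequence[tuple[int, int]],
    helix_map: Sequence[tuple[tuple[int, int], tuple[int, int]]] = (),
    chain_ref: Optional[str] = None,
    chain_mov: Optional[str] = None,
    signed_tilt: bool = False,
) -> tuple[Superposition, list[float]]:
    """Superpose a mobile module onto a reference via paired Cα atoms.

    ``pairing`` lists (reference residue number, mobile residue number)
    pairs; pairs whose Cα is missing in either structure are dropped
    with a warning.  For each ``((ref_start, ref_end), (mov_start,
    mov_end))`` entry of ``helix_map``, both helix axes are computed in
    the reference frame after superposition and the tilt angle between
    them is reported.
    """
    ref_ca = struct_ref.ca_coords([p[0] for p in pairing], chain_ref)
    mov_ca = struct_mov.ca_coords([p[1] for p in pairing], chain_mov)
    P, Q = [], []
    for rref, rmov in pairing:
        if rref not in ref_ca or rmov not in mov_ca:
            logger.warning(
                "dropping pair (%s, %s): Cα missing", rref, rmov
            )
            continue
        P.append(ref_ca[rref])
        Q.append(mov_ca[rmov])
    if len(P) < 3:
        raise GeometryError(
            f"only {len(P)} usable Cα pairs survive; need >= 3"
        )
    sup = kabsch_superpose(np.array(P), np.array(Q))

    tilts: list[float] = []
    for (ra, rb), (ma, mb) in helix_map:
        ref_h = struct_ref.ca_coords(range(ra, rb + 1), chain_ref)
        mov_h = struct_mov.ca_coords(range(ma, mb + 1), chain_mov)
        axis_ref = helix_axis(np.array([ref_h[k] for k in sorted(ref_h)]))
        mov_xyz = sup.apply(np.array([mov_h[k] for k in sorted(mov_h)]))
        axis_mov = helix_axis(mov_xyz)
        tilts.append(interhelix_angle(axis_ref, axis_mov, signed=signed_tilt))
    return sup, tilts


# ---------------------------------------------------------------------------
# Zn coordination
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ZnSite:
    """One Zn ion and its donor-atom ligands within the cutoff."""

    zn_xyz: np.ndarray
    # (chain, residue number, residue type, donor atom name, distance Å)
    ligands: tuple[tuple[str, int, str, str, float], ...]

    @property
    def ligand_residues(self) -> set[int]:
        return {seqid for _, seqid, _, _, _ in self.ligands}


def zn_coordination(struct: StructureModel, cutoff: float = 2.8) -> list[ZnSite]:
    """Identify Zn coordination spheres.

    For every Zn atom, reports the Cys Sγ and His Nδ1/Nε2 donor atoms
    within ``cutoff`` Å (default 2.8 Å, a typical upper bound on Zn–S/N
    bonds), sorted by distance.  The ligand count is reported as found,
    even when it differs from the tetrahedral 4.
    """
    sites = []
    zns = [(c, s, xyz) for c, s, e, xyz in struct.metals if e.upper() == "ZN"]
    for chain, seqid, zn_xyz in zns:
        ligands = []
        for res in struct.residues:
            donors = _ZN_DONORS.get(res.name.upper())
            if not donors:
                continue
            for atom_name in donors:
                at = res.atom(atom_name)
                if at is None:
                    continue
                d = float(np.linalg.norm(at.xyz - zn_xyz))
                if d <= cutoff:
                    ligands.append((res.chain, res.seqid, res.name, atom_name, d))
        ligands.sort(key=lambda x: x[4])
        sites.append(ZnSite(zn_xyz=np.asarray(zn_xyz, float), ligands=tuple(ligands)))
    return sites


# ---------------------------------------------------------------------------
# Inter-module interface
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContactPair:
    """A residue pair across the module boundary in van der Waals contact."""

    res_a: tuple[str, int, str]   # (chain, number, name), module 1
    res_b: tuple[str, int, str]   # module 2
    min_distance: float
    hydrophobic_a: bool
    hydrophobic_b: bool


def interface_contacts(
    struct: StructureModel,
    span_a: tuple[int, int],
    span_b: tuple[int, int],
    cutoff: float = 4.5,
    chain: Optional[str] = None,
) -> list[ContactPair]:
    """All residue pairs across two disjoint spans whose minimum
    heavy-atom distance is within ``cutoff`` Å (default 4.5 Å).

    Each residue carries a hydrophobic flag from the fixed set
    {A, V, L, I, M, F, W, Y, P}.
    """
    (a0, a1), (b0, b1) = span_a, span_b
    if a1 < a0 or b1 < b0:
        raise GeometryError("spans must be non-empty (start <= end)")
    if not (a1 < b0 or b1 < a0):
        raise GeometryError(f"spans {span_a} and {span_b} overlap")

    res_a = struct.span(a0, a1, chain)
    res_b = struct.span(b0, b1, chain)
    contacts = []
    coords_b = [(r, r.heavy_coords()) for r in res_b]
    for ra in res_a:
        xa = ra.heavy_coords()
        if xa.size == 0:
            continue
        for rb, xb in coords_b:
            if xb.size == 0:
                continue
            d2 = ((xa[:, None, :] - xb[None, :, :]) ** 2).sum(axis=2)
            dmin = float(np.sqrt(d2.min()))
            if dmin <= cutoff:
                contacts.append(
                    ContactPair(
                        res_a=(ra.chain, ra.seqid, ra.name),
                        res_b=(rb.chain, rb.seqid, rb.name),
                        min_distance=dmin,
                        hydrophobic_a=ra.name.upper() in HYDROPHOBIC_RESIDUES,
                        hydrophobic_b=rb.name.upper() in HYDROPHOBIC_RESIDUES,
                    )
                )
    contacts.sort(key=lambda c: (c.res_a[1], c.res_b[1]))
    return contacts
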