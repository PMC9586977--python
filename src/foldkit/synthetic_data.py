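"""Ground-truth generators for every input class of the pipeline.

Each generator takes an explicit seed, emits the artifact together with
a :class:`PlantedTruth` sidecar recording exactly what was planted, and
is deterministic: the same seed reproduces the same artifact byte for
byte.  Defaults reproduce the study conditions of the reference
experiments (module spacings of the ScPml39 zinc fingers, canonical
α-helix geometry, the 2 µL × 1.6 mM into 350 µL × 70 µM titration
protocol at 4 °C, and the 41/80 kDa monomer–dimer MALS pair).

Sequence backgrounds are drawn from an alphabet that excludes the
anchor-forming letters (C, H, aromatics, R, G, S, T) so that planted
motifs are the only matches and recovery can be asserted exactly; a
``realistic_background`` flag re-enables the full alphabet for stress
tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .biophys import ITCExperiment, ITCProtocol, MALSSlice, predict_isotherm
from .struct_geom import Atom, Residue, StructureModel

__all__ = [
    "PlantedTruth",
    "SyntheticDataError",
    "gen_module_sequence",
    "gen_tandem_sequence",
    "gen_ideal_helix",
    "gen_helix_pair",
    "gen_zn_site",
    "gen_itc_data",
    "gen_mals_trace",
    "rotation_about_axis",
    "BACKGROUND_ALPHABET",
]


class SyntheticDataError(ValueError):
    """Raised when a generator request is internally inconsistent."""


#: Background letters that can never form a ligand or anchor position.
BACKGROUND_ALPHABET = "ADEIKLMNPQV"
_FULL_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class PlantedTruth:
    """What a generator planted, for exact recovery assertions."""

    kind: str
    seed: int
    truth: dict

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            raise TypeError(f"unserializable {type(o)}")
        return json.dumps(asdict(self), indent=2, sort_keys=True, default=default)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

def _background(rng: np.random.Generator, n: int, realistic: bool) -> list[str]:
    alphabet = _FULL_ALPHABET if realistic else BACKGROUND_ALPHABET
    return [alphabet[i] for i in rng.integers(0, len(alphabet), size=n)]


def gen_module_sequence(
    seed: int,
    family: str = "zf_C3HC",
    spacers: tuple[int, int, int] = (2, 34, 3),
    anchors_present: dict[str, bool] | None = None,
    length: Optional[int] = None,
    lead: int = 10,
    r_to_g: Optional[int] = None,
    g_to_c1: int = 16,
    tail: int = 12,
    realistic_background: bool = False,
) -> tuple[str, PlantedTruth]:
    """Plant one BIR-like module in a random background sequence.

    Layout (1-based): Arg at ``lead + 1``, Ser/Thr at +3, optional
    aromatic at +4, the GΩ dipeptide ``r_to_g`` residues downstream of
    the Arg (default 29 for zf-C3HC, 54 for Rsm1 — the two reference
    distances straddling the insertion threshold), C1 at ``g_to_c1``
    after the Gly, then C2/H/C3 per ``spacers`` and the final aromatic
    at C3 + 2.  Spacers may deliberately violate a family grammar for
    negative controls.  Anchors can be switched off individually via
    ``anchors_present`` keys ``r``, ``st``, ``omega_a``, ``g_omega``,
    ``final_omega``.
    """
    rng = np.random.default_rng(seed)
    flags = {"r": True, "st": True, "omega_a": True, "g_omega": True,
             "final_omega": True}
    if anchors_present:
        unknown = set(anchors_present) - set(flags)
        if unknown:
            raise SyntheticDataError(f"unknown anchor flags {sorted(unknown)}")
        flags.update(anchors_present)
    if r_to_g is None:
        r_to_g = 54 if family == "Rsm1" else 29

    s1, s2, s3 = spacers
    if min(s1, s2, s3) < 0:
        raise SyntheticDataError("spacers must be non-negative")
    r = lead + 1
    g = r + r_to_g
    c1 = g + g_to_c1
    c2 = c1 + s1 + 1
    h = c2 + s2 + 1
    c3 = h + s3 + 1
    omega_f = c3 + 2
    needed = omega_f + tail
    if length is None:
        length = needed
    if length < needed:
        raise SyntheticDataError(
            f"length {length} too short for the requested layout (needs {needed})"
        )

    seq = _background(rng, length, realistic_background)
    if flags["r"]:
        seq[r - 1] = "R"
    if flags["st"]:
        seq[r + 2] = "S" if rng.integers(0, 2) == 0 else "T"
    if flags["omega_a"]:
        seq[r + 3] = "W"
    if flags["g_omega"]:
        seq[g - 1] = "G"
        seq[g] = "W"
    seq[c1 - 1] = "C"
    seq[c2 - 1] = "C"
    seq[h - 1] = "H"
    seq[c3 - 1] = "C"
    if flags["final_omega"]:
        seq[omega_f - 1] = "W" if family != "Rsm1" else "Y"

    truth = PlantedTruth(
        kind="module_sequence",
        seed=seed,
        truth={
            "family": family,
            "spacers": list(spacers),
            "r": r if flags["r"] else None,
            "st": r + 3 if flags["st"] else None,
            "g": g if flags["g_omega"] else None,
            "omega_g": g + 1 if flags["g_omega"] else None,
            "c1": c1, "c2": c2, "h": h, "c3": c3,
            "final_omega": omega_f if flags["final_omega"] else None,
            "length": length,
        },
    )
    return "".join(seq), truth


def gen_tandem_sequence(
    seed: int,
    linker: int = 5,
    realistic_background: bool = False,
) -> tuple[str, PlantedTruth]:
    """Plant a full tandem zf-C3HC + Rsm1 architecture in one sequence.

    The zf-C3HC module (spacers 2/34/3, Arg→Gly 29) is followed after
    ``linker`` background residues by an Rsm1 module (spacers 2/16/3,
    Arg→Gly 54).
    """
    seq1, t1 = gen_module_sequence(
        seed, family="zf_C3HC", spacers=(2, 34, 3), r_to_g=29,
        realistic_background=realistic_background,
    )
    seq2, t2 = gen_module_sequence(
        seed + 1, family="Rsm1", spacers=(2, 16, 3), r_to_g=54, lead=linker,
        realistic_background=realistic_background,
    )
    offset = len(seq1)
    shifted = {
        k: (v + offset if isinstance(v, int) else v)
        for k, v in t2.truth.items()
        if k in ("r", "st", "g", "omega_g", "c1", "c2", "h", "c3", "final_omega")
    }
    truth = PlantedTruth(
        kind="tandem_sequence",
        seed=seed,
        truth={"zf_C3HC": t1.truth, "Rsm1": {**t2.truth, **shifted},
               "offset": offset, "length": offset + len(seq2)},
    )
    return seq1 + seq2, truth


# ---------------------------------------------------------------------------
# Coordinates
# ---------------------------------------------------------------------------

def rotation_about_axis(axis: Sequence[float], angle_deg: float) -> np.ndarray:
    """Rotation matrix about an arbitrary axis (Rodrigues)."""
    k = np.asarray(axis, float)
    k = k / np.linalg.norm(k)
    a = np.radians(angle_deg)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)


def gen_ideal_helix(
    seed: int,
    n_res: int = 12,
    rise: float = 1.5,
    radius: float = 2.3,
    twist: float = 100.0,
    rotation: Optional[np.ndarray] = None,
    translation: Optional[np.ndarray] = None,
    jitter: float = 0.0,
) -> tuple[np.ndarray, PlantedTruth]:
    """Cα trace of an ideal α-helix with known axis.

    Canonical parameters (1.5 Å rise, 2.3 Å radius, 100°/residue twist)
    give the 3.8 Å consecutive Cα–Cα distance of real α-helices.  The
    helix is built along +z then mapped through the optional rigid
    frame; the true axis is the frame-rotated z.  ``jitter`` adds
    isotropic Gaussian displacement (Å) to each Cα.
    """
    if n_res < 5:
        raise SyntheticDataError("need >= 5 residues for a helix")
    rng = np.random.default_rng(seed)
    i = np.arange(n_res)
    phi = np.radians(twist) * i
    coords = np.column_stack(
        [radius * np.cos(phi), radius * np.sin(phi), rise * i]
    )
    if jitter > 0:
        coords = coords + rng.normal(0.0, jitter, coords.shape)
    R = np.eye(3) if rotation is None else np.asarray(rotation, float)
    t = np.zeros(3) if translation is None else np.asarray(translation, float)
    coords = coords @ R.T + t
    axis = R @ np.array([0.0, 0.0, 1.0])
    truth = PlantedTruth(
        kind="ideal_helix",
        seed=seed,
        truth={"axis": axis, "n_res": n_res, "rise": rise,
               "radius": radius, "twist": twist, "jitter": jitter},
    )
    return coords, truth


def gen_helix_pair(
    seed: int,
    angle_deg: float,
    n_res: int = 12,
    separation: float = 10.0,
    **helix_kwargs,
) -> tuple[np.ndarray, np.ndarray, PlantedTruth]:
    """Two ideal helices whose axes meet at a planted angle.

    The first runs along +z; the second is rotated about x by
    ``angle_deg`` and displaced ``separation`` Å along +x.
    """
    a, ta = gen_ideal_helix(seed, n_res=n_res, **helix_kwargs)
    R = rotation_about_axis([1.0, 0.0, 0.0], angle_deg)
    b, _ = gen_ideal_helix(
        seed + 1, n_res=n_res, rotation=R,
        translation=np.array([separation, 0.0, 0.0]), **helix_kwargs,
    )
    truth = PlantedTruth(
        kind="helix_pair",
        seed=seed,
        truth={"angle_deg": angle_deg, "axis_a": ta.truth["axis"],
               "axis_b": R @ np.array([0.0, 0.0, 1.0]), "n_res": n_res},
    )
    return a, b, truth


_TETRAHEDRON = np.array(
    [[1.0, 1.0, 1.0], [1.0, -1.0, -1.0], [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]]
) / np.sqrt(3.0)


def gen_zn_site(
    seed: int,
    distances: float | Sequence[float] = 2.3,
    jitter: float = 0.0,
    center: Sequence[float] = (0.0, 0.0, 0.0),
    residue_numbers: Sequence[int] = (1, 2, 3, 4),
    chain: str = "A",
) -> tuple[StructureModel, PlantedTruth]:
    """A tetrahedral Zn site with four Cys Sγ donors at known distances.

    Donor atoms sit on tetrahedral vertices scaled to ``distances``
    (scalar or one per vertex) from the Zn, each displaced by isotropic
    Gaussian ``jitter`` (Å).  Returned as a structure fragment with one
    Sγ-only Cys residue per donor plus the Zn listed as a metal.
    """
    rng = np.random.default_rng(seed)
    center = np.asarray(center, float)
    d = np.broadcast_to(np.asarray(distances, float), (4,)).copy()
    if np.any(d <= 0):
        raise SyntheticDataError("donor distances must be positive")
    if len(residue_numbers) != 4:
        raise SyntheticDataError("need exactly 4 residue numbers")
    residues = []
    positions = []
    for num, vertex, dist in zip(residue_numbers, _TETRAHEDRON, d):
        pos = center + vertex * dist
        if jitter > 0:
            pos = pos + rng.normal(0.0, jitter, 3)
        positions.append(pos)
        residues.append(
            Residue(chain=chain, seqid=int(num), icode="", name="CYS",
                    atoms=[Atom("SG", "S", pos)])
        )
    model = StructureModel(
        name=f"zn_site_{seed}",
        residues=residues,
        metals=[(chain, max(residue_numbers) + 1, "Zn", center)],
    )
    truth = PlantedTruth(
        kind="zn_site",
        seed=seed,
        truth={"center": center, "distances": d,
               "ligand_residues": list(residue_numbers), "jitter": jitter},
    )
    return model, truth


# ---------------------------------------------------------------------------
# ITC and MALS
# ---------------------------------------------------------------------------

def gen_itc_data(
    seed: int,
    n: float = 1.0,
    k_d: float = 13e-6,
    dh: float = -10.0,
    protocol: Optional[ITCProtocol] = None,
    noise_frac: float = 0.0,
) -> tuple[ITCExperiment, PlantedTruth]:
    """Synthetic 1:1 titration with multiplicative Gaussian heat noise.

    Defaults plant the reference interaction (K_D = 13 µM, 1:1
    stoichiometry) on the reference protocol geometry; ``noise_frac``
    is the relative standard deviation applied per injection heat
    (0.02 = 2% heat noise).
    """
    rng = np.random.default_rng(seed)
    if protocol is None:
        protocol = ITCProtocol()
    heats = predict_isotherm(n, k_d, dh, protocol)
    if noise_frac > 0:
        heats = heats * (1.0 + rng.normal(0.0, noise_frac, heats.shape))
    exp = ITCExperiment(protocol=protocol, heats=tuple(float(q) for q in heats))
    truth = PlantedTruth(
        kind="itc",
        seed=seed,
        truth={"n": n, "k_d": k_d, "dh": dh, "noise_frac": noise_frac,
               "temperature": protocol.temperature},
    )
    return exp, truth


def gen_mals_trace(
    seed: int,
    species: Sequence[tuple[float, float, float, float]] = (
        (80000.0, 600.0, 30.0, 0.5e-3),
    ),
    angles: Sequence[float] = tuple(range(30, 150, 7)),
    k_optical: float = 2.0e-7,
    noise_frac: float = 0.0,
    t_start: float = 400.0,
    t_end: float = 1000.0,
    dt: float = 1.0,
) -> tuple[list[MALSSlice], PlantedTruth]:
    """Synthetic SEC-MALS trace of one or more eluting species.

    ``species`` lists (MW g/mol, peak center s, peak sigma s, peak-top
    concentration g/mL); concentration profiles are Gaussian in time,
    Rayleigh ratios are ideal (Rθ = K·c·MW, no angular dependence,
    matching the point-scatterer limit for proteins far below the light
    wavelength) with optional multiplicative Gaussian noise.  The
    default 18-angle set mirrors a multi-angle detector.
    """
    if len(set(angles)) < 2:
        raise SyntheticDataError("need >= 2 distinct detector angles")
    rng = np.random.default_rng(seed)
    times = np.arange(t_start, t_end + dt / 2, dt)
    slices = []
    for t in times:
        conc = 0.0
        rayleigh_per_mw = 0.0
        for mw, center, sigma, peak_conc in species:
            c = peak_conc * np.exp(-0.5 * ((t - center) / sigma) ** 2)
            conc += c
            rayleigh_per_mw += c * mw
        r = np.full(len(angles), k_optical * rayleigh_per_mw)
        if noise_frac > 0:
            r = r * (1.0 + rng.normal(0.0, noise_frac, r.shape))
        slices.append(
            MALSSlice(
                time=float(t),
                concentration=float(conc),
                angles=tuple(float(a) for a in angles),
                r_theta=tuple(float(x) for x in r),
                k_optical=k_optical,
            )
        )
    truth = PlantedTruth(
        kind="mals",
        seed=seed,
        truth={
            "species": [
                {"mw": mw, "center": c, "sigma": s, "peak_conc": pc}
                for mw, c, s, pc in species
            ],
            "noise_frac": noise_frac,
            "k_optical": k_optical,
        },
    )
    return slices, truth
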