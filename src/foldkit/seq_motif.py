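"""CCHC zinc-finger motif grammar for the BIR-like clan.

The BIR-like clan comprises three families that share a Cys-Cys-His-Cys
(CCHC) zinc finger and a small set of conserved anchor motifs:

* canonical BIR domains: ``Rxx(S/T)Ω ... GΩ ... C-x2-C-x16-H-x6-C-x-Ω``
* zf-C3HC and Rsm1 domains: same anchors but a shortened His→Cys spacer,
  ``C-x2-C-xn-H-x3-C``.

The two BIR-like families are distinguished not by the zinc finger itself
(both have the 3-residue His→Cys spacer) but by a long insertion between
the N-terminal anchor helix and the GΩ turn that only the Rsm1 module
carries.  A protein carrying a zf-C3HC module immediately followed by an
Rsm1 module forms a single integrated domain, the "Pml39 fold", the
architecture shared by ScPml39, SpRsm1 and human NIPA/ZC3HC1.

This module encodes that grammar: scanning sequences for CCHC quadruples
under family-specific spacer constraints, locating the anchor motifs,
classifying modules, detecting the tandem architecture, and scoring the
18-point conserved-residue checklist used as the evidence standard for
calling structural orthologs.

Residue indexing is 1-based throughout; a spacer between residues i < j
counts the residues strictly between them, ``j - i - 1``.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "AMINO_ACIDS",
    "DEFAULT_AROMATIC",
    "FAMILIES",
    "ZnfSpacing",
    "AnchorSet",
    "MotifMatch",
    "ModuleAnnotation",
    "FoldCall",
    "ChecklistReport",
    "GrammarError",
    "compile_family_grammar",
    "spacer_length",
    "scan_znf",
    "find_anchors",
    "classify_module",
    "detect_pml39_fold",
    "ortholog_checklist",
    "build_residue_map",
    "scan_fasta",
    "fold_call_fasta",
    "CHECKLIST_CRITERIA",
]

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: Aromatic alphabet for the Ω positions.  His is deliberately excluded.
DEFAULT_AROMATIC = frozenset("FWY")

FAMILIES = ("canonical_BIR", "zf_C3HC", "Rsm1")

_FAMILY_ALIASES = {
    "canonical_bir": "canonical_BIR",
    "bir": "canonical_BIR",
    "zf_c3hc": "zf_C3HC",
    "zfc3hc": "zf_C3HC",
    "rsm1": "Rsm1",
}


class GrammarError(ValueError):
    """Raised on inputs that violate the motif grammar contract."""


def _canon_family(family: str) -> str:
    key = family.strip().lower().replace("-", "_")
    if key not in _FAMILY_ALIASES:
        raise GrammarError(
            f"unknown family {family!r}; expected one of {FAMILIES}"
        )
    return _FAMILY_ALIASES[key]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ZnfSpacing:
    """Spacer constraints of one family's CCHC zinc-finger motif.

    Spacers count residues strictly between consecutive Zn ligands.
    ``c1_c2`` and ``c2_h`` are inclusive ranges; ``h_c3`` is exact
    (6 for canonical BIR, 3 for zf-C3HC/Rsm1 — the clan's hallmark).
    """

    family: str
    c1_c2: tuple[int, int] = (1, 3)
    c2_h: tuple[int, int] = (10, 160)
    h_c3: int = 3

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise GrammarError(f"unknown family {self.family!r}")
        for lo, hi in (self.c1_c2, self.c2_h):
            if lo < 0 or hi < lo:
                raise GrammarError(
                    f"invalid spacer range ({lo}, {hi}): need 0 <= min <= max"
                )
        if self.h_c3 < 0:
            raise GrammarError("h_c3 spacer must be >= 0")
        expected = 6 if self.family == "canonical_BIR" else 3
        if self.h_c3 != expected:
            raise GrammarError(
                f"{self.family} requires h_c3 = {expected}, got {self.h_c3}"
            )

    def admits(self, spacers: tuple[int, int, int]) -> bool:
        s1, s2, s3 = spacers
        return (
            self.c1_c2[0] <= s1 <= self.c1_c2[1]
            and self.c2_h[0] <= s2 <= self.c2_h[1]
            and s3 == self.h_c3
        )


@dataclass(frozen=True)
class AnchorSet:
    """Positions of the clan's conserved anchor motifs around one ZnF.

    All indices are 1-based; ``None`` marks an anchor that was searched
    for but not found (absence is a result state, not an error).
    """

    r_pos: Optional[int] = None          # Arg of Rxx(S/T)Ω, helix αA
    st_pos: Optional[int] = None         # Ser/Thr at r_pos + 3
    omega_a_pos: Optional[int] = None    # aromatic completing Rxx(S/T)Ω
    g_pos: Optional[int] = None          # Gly of the GΩ β-turn dipeptide
    omega_g_pos: Optional[int] = None    # aromatic of GΩ (g_pos + 1)
    final_omega_pos: Optional[int] = None  # aromatic shortly after C3

    def __post_init__(self) -> None:
        if self.r_pos is not None and self.st_pos is not None:
            if self.st_pos != self.r_pos + 3:
                raise GrammarError("st_pos must equal r_pos + 3")
        if self.g_pos is not None and self.omega_g_pos is not None:
            if self.omega_g_pos != self.g_pos + 1:
                raise GrammarError("omega_g_pos must equal g_pos + 1")


@dataclass(frozen=True)
class MotifMatch:
    """One CCHC quadruple satisfying a family grammar."""

    c1: int
    c2: int
    h: int
    c3: int
    spacers: tuple[int, int, int]
    family: str
    anchors: Optional[AnchorSet] = None
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.c1 < self.c2 < self.h < self.c3):
            raise GrammarError("ligand indices must satisfy c1 < c2 < h < c3")
        expect = (
            spacer_length(self.c1, self.c2),
            spacer_length(self.c2, self.h),
            spacer_length(self.h, self.c3),
        )
        if tuple(self.spacers) != expect:
            raise GrammarError(
                f"spacers {self.spacers} inconsistent with indices (expected {expect})"
            )


@dataclass(frozen=True)
class ModuleAnnotation:
    """A classified BIR-like module with its sequence span (inclusive)."""

    kind: str
    span: tuple[int, int]
    match: MotifMatch

    def __post_init__(self) -> None:
        lo, hi = self.span
        if hi < lo:
            raise GrammarError("span must be non-empty")
        for idx in (self.match.c1, self.match.c2, self.match.h, self.match.c3):
            if not lo <= idx <= hi:
                raise GrammarError("span must contain all ligand indices")

    @property
    def length(self) -> int:
        """Number of residues in the inclusive span."""
        return self.span[1] - self.span[0] + 1


#: The nine per-module checklist criteria, in report order.
CHECKLIST_CRITERIA = (
    "arg_anchor",        # Arg of Rxx(S/T)Ω present
    "st_plus3",          # Ser/Thr exactly 3 residues after the Arg
    "g_omega",           # GΩ dipeptide present
    "c1",                # first Zn-coordinating Cys
    "c2",                # second Cys at family C1→C2 spacing
    "h",                 # Zn-coordinating His at family C2→H spacing
    "c3",                # last Zn-coordinating Cys
    "h_c3_spacer",       # His→C3 spacer matches the family (3 or 6)
    "post_c3_aromatic",  # aromatic within 3 residues after C3
)

_MAP_KEYS = ("r", "st", "g", "omega_g", "c1", "c2", "h", "c3", "omega_f")


@dataclass(frozen=True)
class ChecklistReport:
    """Per-criterion outcome of the 18-point conserved-residue checklist."""

    criteria: Mapping[tuple[str, str], bool]
    satisfied_count: int
    total: int = 18

    def __post_init__(self) -> None:
        if self.satisfied_count != sum(bool(v) for v in self.criteria.values()):
            raise GrammarError("satisfied_count inconsistent with criteria")

    @property
    def fraction(self) -> float:
        return self.satisfied_count / self.total if self.total else 0.0


@dataclass(frozen=True)
class FoldCall:
    """Tandem zf-C3HC + Rsm1 architecture call for one sequence."""

    sequence_id: str
    zf_module: Optional[ModuleAnnotation]
    rsm1_module: Optional[ModuleAnnotation]
    checklist: Optional[ChecklistReport]
    is_pml39_fold: bool

    def __post_init__(self) -> None:
        if self.is_pml39_fold:
            if self.zf_module is None or self.rsm1_module is None:
                raise GrammarError("fold call requires both modules")
            if self.zf_module.span[1] >= self.rsm1_module.match.c1:
                raise GrammarError(
                    "zf-C3HC span must end before the Rsm1 zinc finger"
                )


# ---------------------------------------------------------------------------
# Grammar operations
# ---------------------------------------------------------------------------

def compile_family_grammar(
    family: str,
    c1_c2: Optional[tuple[int, int]] = None,
    c2_h: Optional[tuple[int, int]] = None,
) -> ZnfSpacing:
    """Build the spacer specification for one clan family.

    Defaults: C1→C2 spacer 1–3 (the human NIPA zf-C3HC pair implies a
    spacer of 1, so exactly-2 would reject a known ortholog), C2→H spacer
    10–160 (the NIPA Rsm1 module carries a ~135-residue insertion giving
    a 149-residue spacer), H→C3 exact 6 (canonical BIR) or 3 (zf-C3HC and
    Rsm1).  The H→C3 spacer is fixed per family and not overridable.
    """
    fam = _canon_family(family)
    return ZnfSpacing(
        family=fam,
        c1_c2=tuple(c1_c2) if c1_c2 is not None else (1, 3),
        c2_h=tuple(c2_h) if c2_h is not None else (10, 160),
        h_c3=6 if fam == "canonical_BIR" else 3,
    )


def spacer_length(i: int, j: int) -> int:
    """Residues strictly between 1-based positions i < j, i.e. ``j - i - 1``."""
    if j <= i:
        raise GrammarError(f"need j > i, got i={i}, j={j}")
    return j - i - 1


def _validate_sequence(sequence: str) -> str:
    seq = sequence.upper()
    bad = set(seq) - AMINO_ACIDS - {"X"}
    if bad:
        raise GrammarError(
            f"non-amino-acid characters in sequence: {sorted(bad)}"
        )
    return seq


def scan_znf(sequence: str, grammar: ZnfSpacing) -> list[MotifMatch]:
    """Find every CCHC quadruple satisfying the grammar's spacers.

    All candidates are reported in ascending ``c1`` (then c2, then h);
    overlap resolution is the caller's concern.  ``X`` is tolerated in
    the sequence but never matches a ligand position.
    """
    seq = _validate_sequence(sequence)
    if not seq:
        return []
    cys = [i + 1 for i, aa in enumerate(seq) if aa == "C"]
    his = [i + 1 for i, aa in enumerate(seq) if aa == "H"]
    matches: list[MotifMatch] = []
    for c1 in cys:
        for c2 in cys:
            if c2 <= c1:
                continue
            s1 = spacer_length(c1, c2)
            if s1 > grammar.c1_c2[1]:
                break  # cys sorted ascending: spacer only grows
            if s1 < grammar.c1_c2[0]:
                continue
            for h in his:
                if h <= c2:
                    continue
                s2 = spacer_length(c2, h)
                if s2 > grammar.c2_h[1]:
                    break
                if s2 < grammar.c2_h[0]:
                    continue
                c3 = h + grammar.h_c3 + 1
                if c3 <= len(seq) and seq[c3 - 1] == "C":
                    matches.append(
                        MotifMatch(
                            c1=c1, c2=c2, h=h, c3=c3,
                            spacers=(s1, s2, grammar.h_c3),
                            family=grammar.family,
                        )
                    )
    matches.sort(key=lambda m: (m.c1, m.c2, m.h))
    return matches


def find_anchors(
    sequence: str,
    match: MotifMatch,
    upstream_window: int = 80,
    aromatic: frozenset[str] = DEFAULT_AROMATIC,
    post_c3_window: int = 3,
) -> AnchorSet:
    """Locate the conserved anchor motifs around a CCHC match.

    Searches, in order: the nearest ``Rxx(S/T)`` upstream of C1 within
    ``upstream_window`` residues (an Arg lacking the +3 Ser/Thr is used
    as fallback so a degraded anchor is still reported); the last GΩ
    dipeptide between that Arg (or the window start) and C1; the first
    aromatic within ``post_c3_window`` residues after C3.  Absent anchors
    come back as ``None`` — absence is a result, not an error.
    """
    seq = _validate_sequence(sequence)
    if match.c3 > len(seq):
        raise GrammarError("match does not lie within the sequence")

    lo = max(1, match.c1 - upstream_window)
    r_pos = st_pos = omega_a = None
    fallback_r = None
    for pos in range(match.c1 - 1, lo - 1, -1):
        if seq[pos - 1] != "R":
            continue
        if fallback_r is None:
            fallback_r = pos
        if pos + 3 <= len(seq) and seq[pos + 2] in "ST":
            r_pos = pos
            st_pos = pos + 3
            if pos + 4 <= len(seq) and seq[pos + 3] in aromatic:
                omega_a = pos + 4
            break
    if r_pos is None:
        r_pos = fallback_r

    g_pos = omega_g = None
    g_lo = (r_pos + 1) if r_pos is not None else lo
    for pos in range(match.c1 - 2, g_lo - 1, -1):  # need pos+1 < c1
        if seq[pos - 1] == "G" and seq[pos] in aromatic:
            g_pos = pos
            omega_g = pos + 1
            break

    final_omega = None
    for pos in range(match.c3 + 1, min(len(seq), match.c3 + post_c3_window) + 1):
        if seq[pos - 1] in aromatic:
            final_omega = pos
            break

    return AnchorSet(
        r_pos=r_pos, st_pos=st_pos, omega_a_pos=omega_a,
        g_pos=g_pos, omega_g_pos=omega_g, final_omega_pos=final_omega,
    )


def classify_module(
    sequence: str,
    match: MotifMatch,
    anchors: Optional[AnchorSet] = None,
    insertion_threshold: int = 40,
    span_tail: int = 11,
    no_anchor_offset: int = 45,
    no_omega_tail: int = 20,
) -> ModuleAnnotation:
    """Assign a family to one CCHC match and delimit its module span.

    An H→C3 spacer of 6 is a canonical BIR domain.  With the shortened
    spacer of 3, zf-C3HC and Rsm1 are separated by the length of the
    segment between the Arg anchor and the GΩ turn: the Rsm1 module is
    the only family carrying the long αAB′/Ser-rich insertion there, so
    a distance above ``insertion_threshold`` (default 40; the reference
    modules measure 29 and 54) calls Rsm1.  When the Arg anchor is
    missing the C2→H spacer is compared against the same threshold.

    The span runs from the Arg anchor (or C1 − ``no_anchor_offset``) to
    the post-C3 aromatic + ``span_tail`` (or C3 + ``no_omega_tail``),
    clamped to the sequence.
    """
    seq = _validate_sequence(sequence)
    if anchors is None:
        anchors = find_anchors(seq, match)

    if match.spacers[2] == 6:
        kind = "canonical_BIR"
    elif match.spacers[2] == 3:
        if anchors.r_pos is not None and anchors.g_pos is not None:
            kind = "Rsm1" if anchors.g_pos - anchors.r_pos > insertion_threshold else "zf_C3HC"
        else:
            kind = "Rsm1" if match.spacers[1] > insertion_threshold else "zf_C3HC"
    else:
        raise GrammarError(
            f"match H→C3 spacer {match.spacers[2]} fits no clan family"
        )

    start = anchors.r_pos if anchors.r_pos is not None else match.c1 - no_anchor_offset
    if anchors.final_omega_pos is not None:
        end = anchors.final_omega_pos + span_tail
    else:
        end = match.c3 + no_omega_tail
    start = max(1, min(start, match.c1))
    end = min(len(seq), max(end, match.c3))
    enriched = MotifMatch(
        c1=match.c1, c2=match.c2, h=match.h, c3=match.c3,
        spacers=match.spacers, family=kind, anchors=anchors,
    )
    return ModuleAnnotation(kind=kind, span=(start, end), match=enriched)


# ---------------------------------------------------------------------------
# Checklist and fold call
# ---------------------------------------------------------------------------

def build_residue_map(
    sequence: str, annotation: ModuleAnnotation
) -> dict[str, Optional[tuple[int, str]]]:
    """Extract the nine checklist positions of one module as
    ``{key: (1-based index, residue letter) | None}``."""
    seq = _validate_sequence(sequence)
    a = annotation.match.anchors or AnchorSet()
    m = annotation.match

    def at(pos: Optional[int]) -> Optional[tuple[int, str]]:
        if pos is None or not 1 <= pos <= len(seq):
            return None
        return (pos, seq[pos - 1])

    return {
        "r": at(a.r_pos),
        "st": at(a.st_pos),
        "g": at(a.g_pos),
        "omega_g": at(a.omega_g_pos),
        "c1": at(m.c1),
        "c2": at(m.c2),
        "h": at(m.h),
        "c3": at(m.c3),
        "omega_f": at(a.final_omega_pos),
    }


def _eval_module_checklist(
    entries: Mapping[str, Optional[tuple[int, str]]],
    grammar: ZnfSpacing,
    aromatic: frozenset[str] = DEFAULT_AROMATIC,
) -> dict[str, bool]:
    def get(key: str) -> Optional[tuple[int, str]]:
        v = entries.get(key)
        if v is None:
            return None
        pos, aa = v
        aa = aa.upper()
        if aa in ("X", "-"):
            return None  # unknown/gap residues never satisfy a criterion
        return int(pos), aa

    r, st = get("r"), get("st")
    g, og = get("g"), get("omega_g")
    c1, c2, h, c3 = get("c1"), get("c2"), get("h"), get("c3")
    of = get("omega_f")

    out = {
        "arg_anchor": r is not None and r[1] == "R",
        "st_plus3": (
            r is not None and st is not None
            and st[1] in "ST" and st[0] == r[0] + 3
        ),
        "g_omega": (
            g is not None and og is not None
            and g[1] == "G" and og[1] in aromatic and og[0] == g[0] + 1
        ),
        "c1": c1 is not None and c1[1] == "C",
        "c2": (
            c1 is not None and c2 is not None and c2[1] == "C"
            and grammar.c1_c2[0] <= spacer_length(c1[0], c2[0]) <= grammar.c1_c2[1]
        ),
        "h": (
            c2 is not None and h is not None and h[1] == "H"
            and grammar.c2_h[0] <= spacer_length(c2[0], h[0]) <= grammar.c2_h[1]
        ),
        "c3": c3 is not None and c3[1] == "C",
        "h_c3_spacer": (
            h is not None and c3 is not None
            and spacer_length(h[0], c3[0]) == grammar.h_c3
        ),
        "post_c3_aromatic": (
            c3 is not None and of is not None
            and of[1] in aromatic and 1 <= of[0] - c3[0] <= 3
        ),
    }
    return out


def ortholog_checklist(
    residue_map: Mapping[str, Mapping[str, Optional[tuple[int, str]]]]
    | Iterable[tuple[str, Mapping[str, Optional[tuple[int, str]]]]],
    aromatic: frozenset[str] = DEFAULT_AROMATIC,
) -> ChecklistReport:
    """Score the 18-point conserved-residue checklist.

    ``residue_map`` maps the two module kinds (``zf_C3HC`` and ``Rsm1``)
    to their nine checklist positions (see :func:`build_residue_map`);
    missing or ``None`` entries simply fail their criteria.  A list of
    pairs is also accepted; duplicate module or criterion keys are
    rejected, since a duplicated entry would make the count ambiguous.
    """
    if isinstance(residue_map, Mapping):
        items = list(residue_map.items())
    else:
        items = list(residue_map)
        seen = [k for k, _ in items]
        if len(seen) != len(set(seen)):
            raise GrammarError("duplicate module keys in residue map")

    modules: dict[str, Mapping[str, Optional[tuple[int, str]]]] = {}
    for kind, entries in items:
        fam = _canon_family(kind)
        if fam in modules:
            raise GrammarError(f"duplicate module key {kind!r}")
        if not isinstance(entries, Mapping):
            entries = dict(entries)
        unknown = set(entries) - set(_MAP_KEYS)
        if unknown:
            raise GrammarError(f"unknown criterion keys {sorted(unknown)}")
        modules[fam] = entries

    for required in ("zf_C3HC", "Rsm1"):
        modules.setdefault(required, {})

    criteria: dict[tuple[str, str], bool] = {}
    for kind in ("zf_C3HC", "Rsm1"):
        grammar = compile_family_grammar(kind)
        per = _eval_module_checklist(modules[kind], grammar, aromatic)
        for crit in CHECKLIST_CRITERIA:
            criteria[(kind, crit)] = per[crit]

    return ChecklistReport(
        criteria=criteria,
        satisfied_count=sum(criteria.values()),
        total=len(criteria),
    )


def _dedupe_overlapping(
    sequence: str, annotations: Sequence[ModuleAnnotation]
) -> list[ModuleAnnotation]:
    """Resolve overlapping modules: keep the higher checklist score,
    ties broken by smaller c1."""

    def module_score(ann: ModuleAnnotation) -> float:
        grammar = compile_family_grammar(
            ann.kind if ann.kind != "canonical_BIR" else "canonical_BIR"
        )
        entries = build_residue_map(sequence, ann)
        per = _eval_module_checklist(entries, grammar)
        return sum(per.values()) / len(per)

    ranked = sorted(
        annotations,
        key=lambda a: (-module_score(a), a.match.c1),
    )
    kept: list[ModuleAnnotation] = []
    for ann in ranked:
        if all(
            ann.span[1] < k.span[0] or ann.span[0] > k.span[1] for k in kept
        ):
            kept.append(ann)
    kept.sort(key=lambda a: a.match.c1)
    return kept


def detect_pml39_fold(
    sequence_id: str,
    annotations: Sequence[ModuleAnnotation],
    sequence: Optional[str] = None,
) -> FoldCall:
    """Call the tandem zf-C3HC→Rsm1 architecture from module annotations.

    The call is positive iff a zf-C3HC module is followed, N- to
    C-terminal, by an Rsm1 module (the order shared by all known members
    of the family; reversed arrangements are reported but not called).
    When ``sequence`` is supplied the 18-point checklist is evaluated
    over both modules.
    """
    if sequence is not None:
        annotations = _dedupe_overlapping(sequence, annotations)
    zf = next((a for a in annotations if a.kind == "zf_C3HC"), None)
    rsm1 = None
    if zf is not None:
        rsm1 = next(
            (
                a
                for a in annotations
                if a.kind == "Rsm1" and a.match.c1 > zf.span[1]
            ),
            None,
        )
    is_fold = zf is not None and rsm1 is not None

    checklist = None
    if sequence is not None:
        rmap = {}
        if zf is not None:
            rmap["zf_C3HC"] = build_residue_map(sequence, zf)
        if rsm1 is not None:
            rmap["Rsm1"] = build_residue_map(sequence, rsm1)
        checklist = ortholog_checklist(rmap)

    if not is_fold:
        rsm1 = rsm1 or next((a for a in annotations if a.kind == "Rsm1"), None)
    return FoldCall(
        sequence_id=sequence_id,
        zf_module=zf,
        rsm1_module=rsm1,
        checklist=checklist,
        is_pml39_fold=is_fold,
    )


# ---------------------------------------------------------------------------
# FASTA-level drivers
# ---------------------------------------------------------------------------

def _iter_fasta(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        with gzip.open(path, "rt") as fh:
            yield from SeqIO.parse(fh, "fasta")
    else:
        yield from SeqIO.parse(str(path), "fasta")


def _annotate_sequence(seq: str, families: Sequence[str], **cfg) -> list[ModuleAnnotation]:
    anns: list[ModuleAnnotation] = []
    scan_cfg = {k: cfg[k] for k in ("c1_c2", "c2_h") if k in cfg}
    anchor_cfg = {
        k: cfg[k]
        for k in ("upstream_window", "aromatic", "post_c3_window")
        if k in cfg
    }
    cls_cfg = {
        k: cfg[k]
        for k in ("insertion_threshold", "span_tail", "no_anchor_offset", "no_omega_tail")
        if k in cfg
    }
    grammars = []
    for fam in families:
        fam = _canon_family(fam)
        grammars.append(compile_family_grammar(fam, **scan_cfg))
    seen: set[tuple[int, int, int, int]] = set()
    for grammar in grammars:
        for match in scan_znf(seq, grammar):
            key = (match.c1, match.c2, match.h, match.c3)
            if key in seen:
                continue
            seen.add(key)
            anchors = find_anchors(seq, match, **anchor_cfg)
            anns.append(classify_module(seq, match, anchors, **cls_cfg))
    anns.sort(key=lambda a: a.match.c1)
    return anns


def scan_fasta(
    path: str | Path, families: Sequence[str] = FAMILIES, **cfg
) -> pd.DataFrame:
    """Scan every FASTA record and tabulate all classified module hits."""
    rows = []
    for rec in _iter_fasta(path):
        seq = str(rec.seq).upper()
        for ann in _annotate_sequence(seq, families, **cfg):
            a = ann.match.anchors or AnchorSet()
            rows.append(
                {
                    "sequence_id": rec.id,
                    "kind": ann.kind,
                    "span_start": ann.span[0],
                    "span_end": ann.span[1],
                    "c1": ann.match.c1,
                    "c2": ann.match.c2,
                    "h": ann.match.h,
                    "c3": ann.match.c3,
                    "spacer_c1_c2": ann.match.spacers[0],
                    "spacer_c2_h": ann.match.spacers[1],
                    "spacer_h_c3": ann.match.spacers[2],
                    "r_pos": a.r_pos,
                    "st_pos": a.st_pos,
                    "g_pos": a.g_pos,
                    "omega_g_pos": a.omega_g_pos,
                    "final_omega_pos": a.final_omega_pos,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "sequence_id", "kind", "span_start", "span_end",
            "c1", "c2", "h", "c3",
            "spacer_c1_c2", "spacer_c2_h", "spacer_h_c3",
            "r_pos", "st_pos", "g_pos", "omega_g_pos", "final_omega_pos",
        ],
    )


def fold_call_fasta(path: str | Path, **cfg) -> list[FoldCall]:
    """Run the full module scan and tandem-architecture call per record."""
    calls = []
    for rec in _iter_fasta(path):
        seq = str(rec.seq).upper()
        anns = _annotate_sequence(seq, ("zf_C3HC", "Rsm1"), **cfg)
        calls.append(detect_pml39_fold(rec.id, anns, sequence=seq))
    return calls


def fold_calls_to_json(calls: Sequence[FoldCall]) -> str:
    """Serialize fold calls (with checklist breakdown) to JSON."""
    payload = []
    for call in calls:
        d: dict = {
            "sequence_id": call.sequence_id,
            "is_pml39_fold": call.is_pml39_fold,
        }
        for label, mod in (("zf_C3HC", call.zf_module), ("Rsm1", call.rsm1_module)):
            d[label] = None if mod is None else {
                "span": list(mod.span),
                "ligands": [mod.match.c1, mod.match.c2, mod.match.h, mod.match.c3],
                "spacers": list(mod.match.spacers),
                "anchors": asdict(mod.match.anchors) if mod.match.anchors else None,
            }
        if call.checklist is not None:
            d["checklist"] = {
                f"{kind}.{crit}": bool(v)
                for (kind, crit), v in call.checklist.criteria.items()
            }
            d["checklist_satisfied"] = call.checklist.satisfied_count
            d["checklist_total"] = call.checklist.total
        payload.append(d)
    return json.dumps(payload, indent=2, sort_keys=True)
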