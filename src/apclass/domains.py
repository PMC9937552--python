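"""Domain-architecture and active-site annotation.

The group/subgroup rules consume a handful of structural features: the two
catalytic tetrads (canonically D[TS]G[ST] in each lobe of the pepsin fold),
a transmembrane helix in the prosegment, the saposin-like domain (a nested
triple of disulfides on six consecutive cysteines), the NAP1-fold insert in
the N-terminal subdomain (disulfides among canonical cysteines C4-C7), a
C-terminal extension beyond the protease core, and the strand count of the
interdomain β-sheet.  Everything here is computed from sequence plus Cα/SG
geometry only — AlphaFold models carry no hydrogens, so secondary structure
uses Cα pseudo-geometry rather than hydrogen-bond assignment.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .disulfide import DisulfideBond, DisulfideTopology
from .struct_io import StructureModel

__all__ = [
    "DomainSegment",
    "ActiveSiteCall",
    "scan_active_sites",
    "detect_tm_helix",
    "detect_saposin_like",
    "detect_nap1_fold",
    "detect_c_extend",
    "count_interdomain_strands",
    "annotate_architecture",
]

CANONICAL_MOTIF = re.compile(r"D[TS]G[ST]")
RELAXED_MOTIF = re.compile(r"D.G.")

SEGMENT_KINDS = {"signal_peptide", "propeptide", "protease_N", "protease_C",
                 "saposin_like", "NAP1_fold", "C_extend", "TM_helix",
                 "interdomain_sheet", "IIC_motif"}


@dataclass(frozen=True)
class DomainSegment:
    """A typed 1-based inclusive residue range."""

    kind: str
    start: int
    end: int
    very_long: bool = False

    def __post_init__(self) -> None:
        if self.kind not in SEGMENT_KINDS:
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if not 1 <= self.start <= self.end:
            raise ValueError("require 1 <= start <= end")


@dataclass(frozen=True)
class ActiveSiteCall:
    """The two catalytic tetrads; canonical iff both match D[TS]G[ST]."""

    motif_1: str
    pos_1: int | None
    motif_2: str
    pos_2: int | None
    canonical: bool


def scan_active_sites(seq: str, model: StructureModel | None = None) -> ActiveSiteCall:
    """Locate the two catalytic tetrads.

    Rule: the first D[TS]G[ST] in the N-half and the first in the C-half.
    When a half has no canonical match, fall back to a relaxed D-x-G-x tetrad
    in that half; when the C-half has neither and a structure is supplied,
    take the C-half tetrad whose Cα sits closest in space to the motif-1
    aspartate — in the pepsin fold the two catalytic motifs face each other
    across the cleft, so spatial proximity recovers degenerate second motifs
    (e.g. SSVN) that no sequence pattern can.
    """
    if len(seq) < 50:
        raise ValueError("sequence too short for an aspartic protease domain")
    half = len(seq) // 2

    def first_match(pattern, lo, hi):
        m = pattern.search(seq, lo, hi)
        return (m.group(0), m.start() + 1) if m else (None, None)

    motif_1, pos_1 = first_match(CANONICAL_MOTIF, 0, half)
    canon_1 = motif_1 is not None
    if motif_1 is None:
        motif_1, pos_1 = first_match(RELAXED_MOTIF, 0, half)

    motif_2, pos_2 = first_match(CANONICAL_MOTIF, half, len(seq) - 3)
    canon_2 = motif_2 is not None
    if motif_2 is None and model is not None and pos_1 is not None:
        ca = model.ca_coords()
        anchor = None
        if pos_1 <= len(model.residues):
            anchor = ca.get(model.residues[pos_1 - 1].seq_index)
        if anchor is not None:
            best = None
            for ordinal in range(half + 1, len(seq) - 2):
                if ordinal > len(model.residues):
                    break
                coord = ca.get(model.residues[ordinal - 1].seq_index)
                if coord is None:
                    continue
                d = float(np.linalg.norm(coord - anchor))
                if best is None or d < best[0]:
                    best = (d, ordinal)
            if best is not None and best[0] <= 15.0:
                pos_2 = best[1]
                motif_2 = seq[pos_2 - 1:pos_2 + 3]
    if motif_2 is None:
        motif_2, pos_2 = first_match(RELAXED_MOTIF, half, len(seq) - 3)

    return ActiveSiteCall(motif_1=motif_1 or "", pos_1=pos_1,
                          motif_2=motif_2 or "", pos_2=pos_2,
                          canonical=bool(canon_1 and canon_2))


# Kyte-Doolittle hydropathy scale
_KD = {"A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
       "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
       "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
       "Y": -1.3, "V": 4.2, "X": 0.0}

TM_WINDOW = 19
TM_THRESHOLD = 1.6


def detect_tm_helix(seq: str, window: int = TM_WINDOW,
                    threshold: float = TM_THRESHOLD) -> list[DomainSegment]:
    """Kyte-Doolittle scan: maximal runs of windows with mean hydropathy
    >= threshold are reported as TM_helix segments."""
    n = len(seq)
    if n < window:
        return []
    values = np.array([_KD.get(aa, 0.0) for aa in seq])
    means = np.convolve(values, np.ones(window) / window, mode="valid")
    hits = means >= threshold
    segments = []
    i = 0
    while i < len(hits):
        if hits[i]:
            j = i
            while j + 1 < len(hits) and hits[j + 1]:
                j += 1
            segments.append(DomainSegment("TM_helix", i + 1, j + window))
            i = j + 1
        else:
            i += 1
    return segments


SAPOSIN_PAD = 5


def detect_saposin_like(model: StructureModel,
                        bonds: list[DisulfideBond]) -> DomainSegment | None:
    """Saposin-like (plant-specific insert) detection.

    Looks for three fully nested disulfides a-f, b-e, c-d over six
    consecutive cysteines of the chain; the segment spans the outer bond
    padded by a few residues.
    """
    cys_order = [r.seq_index for r in model.residues if r.aa == "C"]
    pos_rank = {p: i for i, p in enumerate(cys_order)}
    n_res = model.residues[-1].seq_index
    for outer in sorted(bonds, key=lambda b: b.res_j - b.res_i, reverse=True):
        inner = [b for b in bonds
                 if outer.res_i < b.res_i and b.res_j < outer.res_j]
        for b2 in inner:
            for b3 in inner:
                if b2.res_i < b3.res_i and b3.res_j < b2.res_j:
                    members = sorted([outer.res_i, b2.res_i, b3.res_i,
                                      b3.res_j, b2.res_j, outer.res_j])
                    ranks = [pos_rank[p] for p in members]
                    if ranks == list(range(ranks[0], ranks[0] + 6)):
                        return DomainSegment(
                            "saposin_like",
                            max(1, outer.res_i - SAPOSIN_PAD),
                            min(n_res, outer.res_j + SAPOSIN_PAD))
    return None


NAP1_BASES = {4, 5, 6, 7}


def detect_nap1_fold(topology: DisulfideTopology) -> DomainSegment | None:
    """NAP1 fold present iff at least one disulfide joins canonical
    cysteines C4-C7 (insertions included); spans first to last such Cys."""
    involved: list[int] = []
    for bond in topology.bonds:
        if all(lab.base in NAP1_BASES for lab in bond):
            for lab in bond:
                idx = topology.seq_index_of(lab)
                if idx is not None:
                    involved.append(idx)
    if not involved:
        return None
    return DomainSegment("NAP1_fold", min(involved), max(involved))


C_EXTEND_MIN = 40
C_EXTEND_VERY_LONG = 120


def detect_c_extend(model: StructureModel,
                    protease_core_end: int) -> DomainSegment | None:
    """C-terminal extension: >= 40 residues past the last core cysteine;
    flagged very_long at >= 120 (the subgroup II-C signature)."""
    n_res = model.residues[-1].seq_index
    trailing = n_res - protease_core_end
    if trailing < C_EXTEND_MIN:
        return None
    return DomainSegment("C_extend", protease_core_end + 1, n_res,
                         very_long=trailing >= C_EXTEND_VERY_LONG)


# Cα pseudo-geometry secondary structure: distances d(i,i+2) and d(i,i+3)
# separate extended strands (≈6.7 / ≈10 Å) from helices (≈5.4 / ≈5.0 Å).
STRAND_D13_MIN = 6.0
STRAND_D14_MIN = 8.5
MIN_STRAND_LEN = 3


def count_interdomain_strands(model: StructureModel, start: int | None = None,
                              end: int | None = None) -> tuple[int, bool]:
    """Count β-strands (runs of >= 3 extended residues) in a region.

    Defaults to the whole chain.  Returns (count, confident); confidence is
    low when the region's mean pLDDT is under 70.
    """
    residues = [r for r in model.residues
                if (start is None or r.seq_index >= start)
                and (end is None or r.seq_index <= end)]
    ca = [(r.seq_index, r.ca.coord) for r in residues if r.ca is not None]
    extended = np.zeros(len(ca), dtype=bool)
    for k in range(len(ca) - 3):
        idx = [ca[k + o][0] for o in range(4)]
        if idx[3] - idx[0] != 3:
            continue  # chain break in the window
        d13 = float(np.linalg.norm(ca[k][1] - ca[k + 2][1]))
        d14 = float(np.linalg.norm(ca[k][1] - ca[k + 3][1]))
        if d13 >= STRAND_D13_MIN and d14 >= STRAND_D14_MIN:
            extended[k] = True
    count = 0
    run = 0
    for flag in extended:
        if flag:
            run += 1
        else:
            if run >= MIN_STRAND_LEN:
                count += 1
            run = 0
    if run >= MIN_STRAND_LEN:
        count += 1
    mean_plddt = float(np.mean([r.plddt for r in residues])) if residues else 0.0
    return count, mean_plddt >= 70.0


SIGNAL_WINDOW = 12
SIGNAL_THRESHOLD = 1.4


def annotate_architecture(seq: str, model: StructureModel | None = None,
                          bonds: list[DisulfideBond] | None = None,
                          topology: DisulfideTopology | None = None,
                          annotations: list[DomainSegment] | None = None,
                          ) -> list[DomainSegment]:
    """Assemble the full segment list used by the classifier.

    Signal peptide and propeptide calls are heuristic (an N-terminal
    hydrophobic window within residues 1-40, then the stretch up to the
    first catalytic motif); externally supplied ``annotations`` of the same
    kinds take precedence.
    """
    segments: list[DomainSegment] = list(annotations or [])
    have = {s.kind for s in segments}

    site = scan_active_sites(seq, model) if len(seq) >= 50 else None

    if "signal_peptide" not in have:
        head = seq[:40]
        if len(head) >= SIGNAL_WINDOW:
            vals = np.array([_KD.get(aa, 0.0) for aa in head])
            means = np.convolve(vals, np.ones(SIGNAL_WINDOW) / SIGNAL_WINDOW,
                                mode="valid")
            if means.size and means.max() >= SIGNAL_THRESHOLD:
                k = int(np.argmax(means))
                segments.append(DomainSegment("signal_peptide", 1,
                                              min(40, k + SIGNAL_WINDOW)))
    sp_end = max([s.end for s in segments if s.kind == "signal_peptide"], default=0)
    if "propeptide" not in have and site and site.pos_1 and site.pos_1 - 1 > sp_end + 1:
        segments.append(DomainSegment("propeptide", sp_end + 1, site.pos_1 - 1))
    if site and site.pos_1 and site.pos_2:
        mid = (site.pos_1 + site.pos_2) // 2
        segments.append(DomainSegment("protease_N", site.pos_1, mid))
        segments.append(DomainSegment("protease_C", mid + 1,
                                      min(len(seq), site.pos_2 + 30)))
    for tm in detect_tm_helix(seq):
        segments.append(tm)
    if model is not None and bonds:
        sap = detect_saposin_like(model, bonds)
        if sap:
            segments.append(sap)
        core_cys = [b.res_j for b in bonds]
        if core_cys:
            ce = detect_c_extend(model, max(core_cys))
            if ce:
                segments.append(ce)
    if topology is not None:
        nap = detect_nap1_fold(topology)
        if nap:
            segments.append(nap)
    return sorted(segments, key=lambda s: (s.start, s.end, s.kind))
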