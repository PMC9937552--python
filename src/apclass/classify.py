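"""Rule engine: group I-IV and subgroup assignment with an evidence trail.

The family's groups are defined on the phylogeny first; structure is
confirmatory.  Accordingly, a clade label (from anchor-based tree
assignment) dominates structural evidence by default, and structure-only
input degrades the confidence label rather than changing the rules.
Booleans are tri-state (True/False/None); an unknown feature never counts
as absent.

Group-level signatures:

* group I  — saposin-like domain (subgroup I-A) or the group-I disulfide
  topology without a NAP1 fold (I-B); intron-rich.
* group II — NAP1 fold, no saposin, intron-rich (>= 4 introns).
* group III — NAP1 fold, intron-poor (<= 2 introns).
* group IV — non-canonical catalytic motifs (DLGG/SSVN-type), intron-poor.

The intron thresholds (rich >= 4, poor <= 2) are derived cutoffs sitting in
the wide gap between the observed group averages (about 8-10 versus
under 0.5); they are not tuned quantities.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .disulfide import CanonicalLabel, DisulfideTopology

__all__ = ["FeatureVector", "ClassificationRecord", "assign_group",
           "assign_subgroup", "classify_batch"]

GROUPS = ("I", "II", "III", "IV")
SUBGROUPS = {
    "I": ("I-A", "I-B"),
    "II": ("II-A", "II-B", "II-C", "II-D"),
    "III": ("III-A", "III-B", "III-C", "III-D", "III-E", "III-F", "III-G"),
    "IV": (),
}
INTRON_RICH = 4
INTRON_POOR = 2


@dataclass
class FeatureVector:
    """Per-gene evidence consumed by the rules.  None means unknown."""

    gene_id: str
    intron_count: float | None = None
    clade_label: str | None = None          # group or subgroup label from the tree
    has_saposin: bool | None = None
    has_nap1: bool | None = None
    has_c_extend: bool | None = None
    c_extend_very_long: bool | None = None
    has_tm_helix: bool | None = None
    has_interdomain_helix: bool | None = None
    canonical_active_site: bool | None = None
    topology: DisulfideTopology | None = None
    topology_string: str | None = None
    n_cysteines: int | None = None
    interdomain_strands: int | None = None
    external_annotations: dict = field(default_factory=dict)  # e.g. {"GPI": True}
    taxon: str | None = None

    def __post_init__(self) -> None:
        if self.topology is not None and self.topology_string is None:
            self.topology_string = self.topology.topology_string


@dataclass
class ClassificationRecord:
    gene_id: str
    group: str = "unassigned"
    subgroup: str = "none"
    evidence: list[tuple[str, str, object]] = field(default_factory=list)
    confidence: str = "structure-only"
    conflicts: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.group not in GROUPS + ("unassigned",):
            raise ValueError(f"unknown group {self.group!r}")

    def add(self, rule_id: str, feature: str, value) -> None:
        self.evidence.append((rule_id, feature, value))


def _clade_group(label: str | None) -> str | None:
    if label is None or label == "unassigned":
        return None
    base = label.split("-")[0]
    return base if base in GROUPS else None


def _lacking(fv: FeatureVector) -> set[str]:
    if fv.topology is not None:
        return {str(l) for l in fv.topology.lacking}
    if fv.topology_string and "|lacking:" in fv.topology_string:
        part = fv.topology_string.split("|lacking:")[1].split("|")[0]
        return set() if part == "-" else set(part.split(","))
    return set()


def _extra(fv: FeatureVector) -> set[str]:
    if fv.topology is not None:
        return {str(l) for l in fv.topology.extra}
    if fv.topology_string and "|extra:" in fv.topology_string:
        part = fv.topology_string.split("|extra:")[1]
        return set() if part == "-" else set(part.split(","))
    return set()


def _bond_strings(fv: FeatureVector) -> set[str]:
    if fv.topology is None:
        if not fv.topology_string:
            return set()
        part = fv.topology_string.split("|")[0]
        return set() if part == "∅" else set(part.split(";"))
    out = set()
    for bond in fv.topology.bonds:
        a, b = sorted(bond)
        out.add(f"{a}-{b}")
    return out


def _nap1_bond_count(fv: FeatureVector) -> int:
    nap_bases = {4, 5, 6, 7}
    count = 0
    for bond in _bond_strings(fv):
        labels = bond.split("-")
        bases = [int("".join(ch for ch in l[1:] if ch.isdigit())) for l in labels]
        if all(b in nap_bases for b in bases):
            count += 1
    return count


def _structure_group(fv: FeatureVector, rec: ClassificationRecord) -> str:
    """Structure-only group call; fills the evidence trail as rules fire."""
    intron_poor = fv.intron_count is not None and fv.intron_count <= INTRON_POOR
    intron_rich = fv.intron_count is not None and fv.intron_count >= INTRON_RICH

    if fv.canonical_active_site is False and intron_poor:
        rec.add("G-IV.noncanonical", "canonical_active_site", False)
        rec.add("G-IV.intron_poor", "intron_count", fv.intron_count)
        return "IV"
    if fv.has_saposin is True:
        rec.add("G-I.saposin", "has_saposin", True)
        return "I"
    bonds = _bond_strings(fv)
    group_i_topology = (fv.has_nap1 is False and len(bonds) == 3)
    if group_i_topology:
        rec.add("G-I.topology", "bonds", sorted(bonds))
        return "I"
    if fv.has_nap1 is True and intron_rich:
        rec.add("G-II.nap1", "has_nap1", True)
        rec.add("G-II.intron_rich", "intron_count", fv.intron_count)
        return "II"
    if fv.has_nap1 is True and intron_poor:
        rec.add("G-III.nap1", "has_nap1", True)
        rec.add("G-III.intron_poor", "intron_count", fv.intron_count)
        return "III"
    return "unassigned"


def assign_group(fv: FeatureVector) -> ClassificationRecord:
    """Group-level call: clade label wins when present; otherwise the
    structural decision ladder.  Contradictions are logged and downgrade
    confidence, never silently dropped."""
    rec = ClassificationRecord(gene_id=fv.gene_id)
    clade = _clade_group(fv.clade_label)
    probe = ClassificationRecord(gene_id=fv.gene_id)
    structural = _structure_group(fv, probe)

    if clade is not None:
        rec.group = clade
        rec.add("G-clade", "clade_label", fv.clade_label)
        if structural != "unassigned":
            rec.evidence.extend(probe.evidence)
            if structural == clade:
                rec.confidence = "clade+structure"
            else:
                rec.confidence = "clade-only"
                rec.conflicts.append(
                    f"clade says {clade}, structure says {structural}")
        else:
            rec.confidence = "clade-only"
    else:
        rec.group = structural
        rec.evidence.extend(probe.evidence)
        rec.confidence = "structure-only"
    return rec


def _clade_subgroup(fv: FeatureVector, group: str) -> str | None:
    if fv.clade_label in SUBGROUPS.get(group, ()):
        return fv.clade_label
    return None


def assign_subgroup(record: ClassificationRecord,
                    fv: FeatureVector) -> ClassificationRecord:
    """Subgroup call within the assigned group.

    Subgroup pairs that share a structural signature (III-B vs III-G,
    III-C vs III-D) are resolved only by a subgroup-level clade label;
    structure-only input yields an explicit tied call."""
    group = record.group
    if group in ("unassigned", "IV"):
        record.subgroup = "none" if group == "unassigned" else "IV"
        return record
    lacking = _lacking(fv)
    extra = _extra(fv)
    bonds = _bond_strings(fv)

    if group == "I":
        if fv.has_saposin is True:
            record.subgroup = "I-A"
            record.add("SG-I-A", "has_saposin", True)
        elif fv.has_saposin is False:
            record.subgroup = "I-B"
            record.add("SG-I-B", "has_saposin", False)
        else:
            record.subgroup = "none"
        return record

    if group == "II":
        gpi = fv.external_annotations.get("GPI")
        if gpi is True:
            record.subgroup = "II-D"
            record.add("SG-II-D", "GPI", True)
        elif fv.c_extend_very_long is True:
            record.subgroup = "II-C"
            record.add("SG-II-C", "c_extend_very_long", True)
        elif fv.has_c_extend is True:
            record.subgroup = "II-B"
            record.add("SG-II-B", "has_c_extend", True)
        elif fv.has_c_extend is False:
            record.subgroup = "II-A"
            record.add("SG-II-A", "has_c_extend", False)
        else:
            record.subgroup = _clade_subgroup(fv, "II") or "none"
        return record

    # group III decision table over topology deltas
    clade_sub = _clade_subgroup(fv, "III")
    nap1_bonds = _nap1_bond_count(fv)
    if nap1_bonds >= 3 or (fv.n_cysteines == 14 and "C6-C7" in bonds):
        record.subgroup = "III-A"
        record.add("SG-III-A", "nap1_bonds", nap1_bonds)
    elif {"C4", "C5"} <= lacking and any(
            "9a" in b and "11a" in b for b in bonds):
        record.subgroup = "III-G"
        record.add("SG-III-G", "extra_bond", "C9a-C11a")
    elif bonds and "C2-C3" not in bonds:
        if clade_sub in ("III-C", "III-D"):
            record.subgroup = clade_sub
            record.add("SG-clade", "clade_label", clade_sub)
        else:
            record.subgroup = "III-C/III-D"
            record.confidence += "/ambiguous"
            record.add("SG-III-CD", "lacking_bond", "C2-C3")
    elif fv.has_nap1 is True and nap1_bonds == 1 and not extra:
        record.subgroup = "III-F"
        record.add("SG-III-F", "nap1_bonds", 1)
    elif fv.has_interdomain_helix is True:
        record.subgroup = "III-E"
        record.add("SG-III-E", "has_interdomain_helix", True)
    else:
        if clade_sub:
            record.subgroup = clade_sub
            record.add("SG-clade", "clade_label", clade_sub)
        else:
            record.subgroup = "III-B/III-G"
            record.confidence += "/ambiguous"
            record.add("SG-III-BG", "topology", fv.topology_string)
    return record


def classify_batch(features: list[FeatureVector]) -> tuple[list[ClassificationRecord],
                                                           Counter]:
    """Classify a feature table; returns records plus per-group counts."""
    seen = set()
    for fv in features:
        if fv.gene_id in seen:
            raise ValueError(f"duplicate gene_id {fv.gene_id!r}")
        seen.add(fv.gene_id)
    records = []
    for fv in features:
        rec = assign_group(fv)
        rec = assign_subgroup(rec, fv)
        records.append(rec)
    counts = Counter(r.group for r in records)
    return records, counts
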