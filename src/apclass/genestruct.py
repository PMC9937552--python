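"""Intron/exon statistics from GFF3 gene models.

Intron-richness cleanly separates the family's groups (intron-rich groups I
and II versus the near-intronless groups III and IV), so the classifier
needs per-gene intron counts and per-group averages.  GFF3 parsing goes
through gffutils; exon features are resolved to transcripts via Parent
attributes, with a CDS fallback for models annotated without exon features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import gffutils

__all__ = ["GeneModel", "GroupIntronStats", "read_gene_models",
           "count_introns", "group_average", "intron_table"]

logger = logging.getLogger(__name__)

TRANSCRIPT_TYPES = ("mRNA", "transcript")


@dataclass
class GeneModel:
    """A gene with its transcripts as sorted 1-based inclusive exon intervals."""

    gene_id: str
    transcripts: list[tuple[str, list[tuple[int, int]], str]]

    def __post_init__(self) -> None:
        for tid, exons, _strand in self.transcripts:
            ordered = sorted(exons)
            if ordered != exons:
                raise ValueError(f"{tid}: exons must be sorted by start")
            for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
                if s2 <= e1:
                    raise ValueError(f"{tid}: overlapping exons")


@dataclass
class GroupIntronStats:
    group: str
    n_genes: int
    mean_introns: float          # rounded half-up to 2 decimals
    per_gene: dict[str, float]


def read_gene_models(gff_path: str | Path) -> list[GeneModel]:
    """Parse a GFF3 file into GeneModel records (in-memory gffutils db)."""
    db = gffutils.create_db(str(gff_path), ":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    models = []
    for gene in db.features_of_type("gene", order_by="start"):
        transcripts = []
        for tx in db.children(gene, featuretype=TRANSCRIPT_TYPES, order_by="start"):
            exons = [(f.start, f.end) for f in
                     db.children(tx, featuretype="exon", order_by="start")]
            if not exons:
                exons = [(f.start, f.end) for f in
                         db.children(tx, featuretype="CDS", order_by="start")]
                if exons:
                    logger.info("%s: no exon features; using CDS intervals", tx.id)
            if not exons:
                raise ValueError(f"transcript {tx.id} has no exon or CDS features")
            transcripts.append((tx.id, exons, tx.strand))
        if transcripts:
            models.append(GeneModel(gene_id=gene.id, transcripts=transcripts))
    return models


def count_introns(model: GeneModel, policy: str = "representative") -> float:
    """Introns per gene under a multi-isoform policy.

    A transcript with k exons has k-1 introns.  ``representative`` picks the
    transcript with the longest summed exon length (ties by transcript id);
    ``max`` and ``mean`` aggregate over all transcripts.
    """
    if not model.transcripts:
        raise ValueError(f"gene {model.gene_id} has no transcripts")
    per_tx = {}
    for tid, exons, _ in model.transcripts:
        if not exons:
            raise ValueError(f"transcript {tid} has no exons")
        per_tx[tid] = (len(exons) - 1, sum(e - s + 1 for s, e in exons))
    if policy == "representative":
        best = sorted(per_tx.items(), key=lambda kv: (-kv[1][1], kv[0]))[0]
        return float(best[1][0])
    if policy == "max":
        return float(max(v[0] for v in per_tx.values()))
    if policy == "mean":
        return sum(v[0] for v in per_tx.values()) / len(per_tx)
    raise ValueError(f"unknown policy {policy!r}")


def _round2(value: float) -> float:
    return float(Decimal(repr(value)).quantize(Decimal("0.01"),
                                               rounding=ROUND_HALF_UP))


def group_average(counts: dict[str, float],
                  groups: dict[str, str]) -> list[GroupIntronStats]:
    """Arithmetic mean intron count per group (2-decimal half-up rounding).

    Every counted gene must be assigned to exactly one group; empty groups
    are dropped with a warning.
    """
    unassigned = sorted(set(counts) - set(groups))
    if unassigned:
        raise ValueError(f"genes without group assignment: {unassigned}")
    by_group: dict[str, dict[str, float]] = {}
    for gene, count in counts.items():
        by_group.setdefault(groups[gene], {})[gene] = count
    stats = []
    for group in sorted(by_group):
        per_gene = by_group[group]
        mean = sum(per_gene.values()) / len(per_gene)
        stats.append(GroupIntronStats(group=group, n_genes=len(per_gene),
                                      mean_introns=_round2(mean),
                                      per_gene=per_gene))
    for group in sorted(set(groups.values()) - set(by_group)):
        logger.warning("group %s has no counted genes; omitted", group)
    return stats


def intron_table(models: list[GeneModel], groups: dict[str, str] | None = None,
                 policy: str = "representative") -> list[dict]:
    """Per-gene rows (gene_id, transcript_id, n_exons, n_introns, group)."""
    rows = []
    for model in models:
        for tid, exons, _ in model.transcripts:
            rows.append({
                "gene_id": model.gene_id,
                "transcript_id": tid,
                "n_exons": len(exons),
                "n_introns": len(exons) - 1,
                "group": (groups or {}).get(model.gene_id, ""),
            })
    return rows
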