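"""End-to-end orchestration: identify features, build the tree, classify.

A run consumes protein sequences (FASTA), an alignment (aligned FASTA) or a
ready-made Newick tree, gene models (GFF3), a directory of structure models
(PDB) and an anchor table, and produces per-gene feature vectors, group and
subgroup calls with evidence, per-group intron statistics and a JSON
report.  Missing inputs degrade gracefully: without structures the engine
runs clade-only; without a tree it runs structure-only; per-gene structure
failures mark that gene degraded instead of aborting the batch.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import classify as _classify
from . import disulfide as _disulfide
from . import domains as _domains
from . import genestruct as _genestruct
from . import phylo as _phylo
from . import struct_io as _struct_io
from .disulfide import CanonicalLabel, DisulfideTopology

__all__ = ["RunConfig", "RunResult", "run_pipeline", "load_reference_json",
           "read_fasta", "read_anchors"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths plus per-stage parameters; ``None`` disables a stage."""

    out_dir: str
    fasta: str | None = None
    msa: str | None = None
    tree: str | None = None
    gff: str | None = None
    models_dir: str | None = None
    anchors: str | None = None
    reference: str | None = None      # reference.json for topology numbering
    seed: int = 0
    trim_cutoff: float = _phylo.DEFAULT_ENTROPY_CUTOFF
    max_gap_fraction: float = _phylo.DEFAULT_MAX_GAP_FRACTION
    distance_model: str = "poisson"
    bootstrap_replicates: int = 0     # 0 = point tree only
    max_sg_distance: float = _disulfide.DEFAULT_MAX_SG_DISTANCE
    intron_policy: str = "representative"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
        unknown = set(data) - {f.name for f in cls.__dataclass_fields__.values()}
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        for name in ("fasta", "msa", "tree", "gff", "anchors", "reference"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"config.{name}: {value} does not exist")
        if self.models_dir is not None and not Path(self.models_dir).is_dir():
            raise FileNotFoundError(f"config.models_dir: {self.models_dir}")
        if self.fasta is None and self.msa is None:
            raise ValueError("config needs fasta or msa")

    @property
    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class RunResult:
    records: list
    counts: dict[str, int]
    intron_stats: list
    degraded: list[str] = field(default_factory=list)
    out_dir: str = ""

    @property
    def exit_code(self) -> int:
        return 3 if self.degraded else 0


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_anchors(path: str | Path) -> dict[str, str]:
    anchors = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        leaf, group = line.split("\t")[:2]
        anchors[leaf] = group
    return anchors


def load_reference_json(path: str | Path) -> DisulfideTopology:
    """Reference topology from JSON: id, sequence, cys_positions, bonds."""
    data = json.loads(Path(path).read_text())
    positions = sorted(data["cys_positions"])
    labels = {pos: CanonicalLabel(rank)
              for rank, pos in enumerate(positions, start=1)}
    rank_of = {pos: lab.base for pos, lab in labels.items()}
    bonds = frozenset(
        frozenset({CanonicalLabel(rank_of[i]), CanonicalLabel(rank_of[j])})
        for i, j in (tuple(sorted(b)) for b in data.get("bonds", [])))
    return DisulfideTopology(model_id=data["id"], reference_id=data["id"],
                             labeled_cysteines=labels, bonds=bonds,
                             sequence=data["sequence"])


def _gene_features(gene: str, seq: str, config: RunConfig,
                   reference: DisulfideTopology | None,
                   clades: dict[str, str], introns: dict[str, float],
                   degraded: list[str]) -> _classify.FeatureVector:
    fv = _classify.FeatureVector(gene_id=gene)
    fv.clade_label = clades.get(gene)
    fv.intron_count = introns.get(gene)
    fv.n_cysteines = seq.count("C")

    model = None
    if config.models_dir is not None:
        pdb_path = Path(config.models_dir) / f"{gene}.pdb"
        if pdb_path.exists():
            try:
                model = _struct_io.read_pdb(pdb_path, model_id=gene)
            except Exception as exc:  # one bad model must not sink the batch
                logger.warning("%s: structure stage failed (%s)", gene, exc)
                degraded.append(gene)
        else:
            degraded.append(gene)

    try:
        site = _domains.scan_active_sites(seq, model)
        fv.canonical_active_site = site.canonical
    except ValueError:
        fv.canonical_active_site = None

    if model is not None:
        bonds = _disulfide.detect_disulfides(model, config.max_sg_distance)
        fv.has_saposin = _domains.detect_saposin_like(model, bonds) is not None
        if bonds:
            ce = _domains.detect_c_extend(model, max(b.res_j for b in bonds))
            fv.has_c_extend = ce is not None
            fv.c_extend_very_long = bool(ce and ce.very_long)
        fv.has_tm_helix = bool(_domains.detect_tm_helix(seq))
        if reference is not None:
            topo = _disulfide.canonical_numbering(
                _struct_io.sequence_of(model), bonds, reference, model_id=gene)
            fv.topology = topo
            fv.topology_string = topo.topology_string
            fv.has_nap1 = _domains.detect_nap1_fold(topo) is not None
    return fv


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute all configured stages in dependency order."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = (f"# apclass run\tconfig_hash={config.config_hash}"
              f"\tseed={config.seed}\n")

    sequences = read_fasta(config.fasta or config.msa)
    if config.fasta is None:
        sequences = {k: v.replace("-", "").replace(".", "")
                     for k, v in sequences.items()}

    # --- tree / clades ---
    clades: dict[str, str] = {}
    tree = None
    if config.tree is not None:
        tree = _phylo.read_newick(config.tree)
    elif config.msa is not None:
        msa = read_fasta(config.msa)
        trimmed = _phylo.entropy_trim(msa, cutoff=config.trim_cutoff,
                                      max_gap_fraction=config.max_gap_fraction)
        if config.bootstrap_replicates > 0:
            tree = _phylo.bootstrap_supports(
                trimmed, n_replicates=config.bootstrap_replicates,
                seed=config.seed, model=config.distance_model)
        else:
            labels, dist = _phylo.distance_matrix(trimmed,
                                                  model=config.distance_model)
            tree = _phylo.nj_tree(dist, labels)
        _phylo.write_newick(tree, out / "tree.nwk")
    if tree is not None and config.anchors is not None:
        clades = _phylo.clade_assign(tree, read_anchors(config.anchors))

    # --- gene structure ---
    introns: dict[str, float] = {}
    if config.gff is not None:
        models = _genestruct.read_gene_models(config.gff)
        introns = {m.gene_id: _genestruct.count_introns(m, config.intron_policy)
                   for m in models}

    reference = (load_reference_json(config.reference)
                 if config.reference is not None else None)

    degraded: list[str] = []
    features = [
        _gene_features(gene, seq, config, reference, clades, introns, degraded)
        for gene, seq in sequences.items()
    ]
    records, counts = _classify.classify_batch(features)

    # --- outputs ---
    with open(out / "classes.tsv", "w") as fh:
        fh.write(header)
        fh.write("gene_id\tgroup\tsubgroup\tconfidence\n")
        for rec in records:
            fh.write(f"{rec.gene_id}\t{rec.group}\t{rec.subgroup}"
                     f"\t{rec.confidence}\n")
    with open(out / "evidence.json", "w") as fh:
        json.dump({r.gene_id: {"group": r.group, "subgroup": r.subgroup,
                               "confidence": r.confidence,
                               "evidence": [list(e) for e in r.evidence],
                               "conflicts": r.conflicts}
                   for r in records}, fh, indent=1, sort_keys=True)

    intron_stats = []
    if introns:
        assigned = {r.gene_id: r.group for r in records
                    if r.gene_id in introns}
        counted = {g: c for g, c in introns.items() if g in assigned}
        intron_stats = _genestruct.group_average(counted, assigned)
        with open(out / "introns.tsv", "w") as fh:
            fh.write(header)
            fh.write("group\tn_genes\tmean_introns\n")
            for s in intron_stats:
                fh.write(f"{s.group}\t{s.n_genes}\t{s.mean_introns:.2f}\n")

    report = {
        "config_hash": config.config_hash,
        "seed": config.seed,
        "n_genes": len(records),
        "group_counts": dict(sorted(counts.items())),
        "intron_means": {s.group: s.mean_introns for s in intron_stats},
        "degraded": sorted(set(degraded)),
    }
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return RunResult(records=records, counts=dict(counts),
                     intron_stats=intron_stats,
                     degraded=sorted(set(degraded)), out_dir=str(out))
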