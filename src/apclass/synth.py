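"""Synthetic fixtures with known ground truth.

Every stage of the pipeline is testable offline against data this module
generates: structure models with planted disulfide bonds and idealized
backbone geometry, a four-group protein family evolved along a known tree
with planted catalytic motifs and cysteine patterns, and GFF3 gene models
with planted exon counts.  Same seed, same bytes.

The family emulates the study conditions of the published census: group
proportions 90/275/682/153 out of 1200, canonical D[TS]G[ST] motifs in
groups I-III versus DLGG/SSVN in group IV, intron-rich groups I/II versus
intron-poor groups III/IV (Poisson means 10.33, 8.53, 0.45, 0.33).

Backbones are idealized, not physically relaxed: chains are laid out as a
two-arm hairpin (mimicking the bilobed protease fold closely enough that
residue i and residue L+1-i face each other, which is what the
active-site-proximity rule needs), bonded cysteine SG pairs are placed
2.05 Å apart, and Gaussian jitter emulates model error.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .struct_io import Atom, Residue, StructureModel, write_pdb

__all__ = ["SynthConfig", "GROUP_PLANS", "make_structure", "make_sheet_model",
           "make_helix_model", "make_family", "make_gff", "make_decoys",
           "make_bundle", "validate_bundle"]

AA_NO_C = "ADEFGHIKLMNPQRSTVWY"
CANONICAL_RE = re.compile(r"D[TS]G[ST]")
RELAXED_RE = re.compile(r"D.G.")

# Published census proportions: 90/275/682/153 of 1200
DEFAULT_PROPORTIONS = {"I": 90 / 1200, "II": 275 / 1200,
                       "III": 682 / 1200, "IV": 153 / 1200}
# Published per-group intron averages drive the planted Poisson means
DEFAULT_INTRON_MEANS = {"I": 10.33, "II": 8.53, "III": 0.45, "IV": 0.33}

SCAFFOLD_LENGTH = 220
CA_STEP = 3.5          # Å between consecutive Cα along an arm
ARM_OFFSET = 4.8       # Å between the two hairpin arms
SS_BOND_LENGTH = 2.05  # Å, covalent S-S


@dataclass
class SynthConfig:
    """Generator conditions.  Defaults are the emulated study conditions."""

    seed: int = 42
    n_genes: int = 200
    group_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS))
    intron_means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INTRON_MEANS))
    jitter_sigma: float = 0.2          # Å coordinate noise on structures
    between_group_branch: float = 0.6  # substitutions/site to each group ancestor
    within_group_branch: float = 0.08  # mean branch length inside a group
    plddt: float = 90.0

    def __post_init__(self) -> None:
        total = sum(self.group_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("group proportions must sum to 1")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be >= 0")


# Per-group scaffold plans: cysteine positions, planted bonds, motifs.
# Cysteine patterns follow the family architecture — group I carries the
# pepsin core plus the nested saposin triple; groups II/III the
# nucellin/nepenthesin pattern with the NAP1-fold bonds; group IV drops the
# C2-C3 bond and inserts the extra C5a-C5b pair next to the NAP1 fold.
GROUP_PLANS = {
    "I": {
        "length": SCAFFOLD_LENGTH,
        "cys": [30, 36, 95, 99, 120, 130, 135, 150, 155, 170, 190, 205],
        "bonds": [(30, 36), (95, 99), (120, 170), (130, 155), (135, 150),
                  (190, 205)],
        "motifs": [("DTGS", 70), ("DSGT", 160)],
        "reference": "groupI",
    },
    "II": {
        "length": SCAFFOLD_LENGTH,
        "cys": [30, 40, 44, 60, 66, 74, 82, 100, 130, 160, 180, 200],
        "bonds": [(30, 100), (40, 44), (60, 74), (66, 82), (130, 200),
                  (160, 180)],
        "motifs": [("DTGS", 90), ("DSGT", 150)],
        "reference": "groupII",
    },
    "III": {
        "length": SCAFFOLD_LENGTH,
        "cys": [30, 40, 44, 60, 66, 74, 82, 100, 130, 160, 180, 200],
        "bonds": [(30, 100), (40, 44), (60, 74), (66, 82), (130, 200),
                  (160, 180)],
        "motifs": [("DTGS", 90), ("DSGT", 150)],
        "reference": "groupIII",
    },
    "IV": {
        "length": SCAFFOLD_LENGTH,
        "cys": [30, 40, 44, 60, 66, 68, 71, 74, 82, 100, 130, 200],
        "bonds": [(30, 100), (60, 74), (66, 82), (68, 71), (130, 200)],
        "motifs": [("DLGG", 88), ("SSVN", 133)],  # 133 mirrors 88 on the hairpin
        "reference": "groupIV",
    },
}

# Subgroup variants as deltas on the group III plan (used by targeted tests)
SUBGROUP_VARIANTS = {
    "III-A": {"add_cys_bonds": [(78, 86)]},
    "III-C": {"drop_cys": [40, 44]},
    "III-F": {"drop_bonds": [(60, 74)]},
    "III-G": {"drop_cys": [60, 66], "drop_bonds": [(60, 74), (66, 82)],
              "add_cys_bonds": [(74, 82), (135, 185)]},
}


def apply_variant(plan: dict, variant: str) -> dict:
    """Derive a subgroup plan from its group plan."""
    delta = SUBGROUP_VARIANTS[variant]
    plan = {k: (list(v) if isinstance(v, list) else v) for k, v in plan.items()}
    for pos in delta.get("drop_cys", []):
        plan["cys"].remove(pos)
        plan["bonds"] = [b for b in plan["bonds"] if pos not in b]
    for bond in delta.get("drop_bonds", []):
        if bond in plan["bonds"]:
            plan["bonds"].remove(bond)
    for i, j in delta.get("add_cys_bonds", []):
        plan["cys"].extend(p for p in (i, j) if p not in plan["cys"])
        plan["bonds"].append((i, j))
    plan["cys"].sort()
    plan["bonds"] = sorted(tuple(sorted(b)) for b in plan["bonds"])
    return plan


def _hairpin_backbone(length: int) -> np.ndarray:
    """Cα trace: outgoing arm then returning arm; residue i faces L+1-i."""
    half = (length + 1) // 2
    coords = np.zeros((length, 3))
    for i in range(1, length + 1):
        if i <= half:
            coords[i - 1] = (CA_STEP * i, 0.0, 0.0)
        else:
            coords[i - 1] = (CA_STEP * (length + 1 - i), ARM_OFFSET, 0.0)
    return coords


def _plant_sequence(plan: dict, rng: np.random.Generator,
                    sequence: str | None = None) -> str:
    length = plan["length"]
    if sequence is None:
        seq = list(rng.choice(list(AA_NO_C), size=length))
    else:
        if len(sequence) != length:
            raise ValueError("sequence length does not match plan")
        seq = list(sequence)
    for pos in plan["cys"]:
        seq[pos - 1] = "C"
    for motif, pos in plan.get("motifs", []):
        seq[pos - 1:pos - 1 + len(motif)] = list(motif)
    return scrub_motifs("".join(seq), plan)


def scrub_motifs(seq: str, plan: dict) -> str:
    """Remove accidental catalytic-motif matches outside the planted sites.

    Any stray D[TS]G[ST] is degraded; for non-canonical plans (group IV) any
    stray D-x-G-x ahead of the planted motif-1 is degraded too, so the
    planted tetrad is always the first candidate the scanner sees.
    """
    protected: set[int] = set()
    for motif, pos in plan.get("motifs", []):
        protected.update(range(pos - 1, pos - 1 + len(motif)))
    protected.update(p - 1 for p in plan["cys"])
    chars = list(seq)
    noncanonical = not any(CANONICAL_RE.fullmatch(m) for m, _ in plan.get("motifs", []))

    def degrade(match_iterable, replacement_offset, replacement):
        changed = False
        for m in match_iterable:
            span = set(range(m.start(), m.start() + 4))
            if span & protected:
                continue
            chars[m.start() + replacement_offset] = replacement
            changed = True
        return changed

    for _ in range(8):  # degrade until stable
        changed = degrade(CANONICAL_RE.finditer("".join(chars)), 1, "A")
        if noncanonical:
            changed |= degrade(RELAXED_RE.finditer("".join(chars)), 0, "E")
        if not changed:
            break
    return "".join(chars)


def make_structure(plan: dict, jitter_sigma: float = 0.0, seed: int = 0,
                   sequence: str | None = None, model_id: str = "synthetic",
                   plddt: float = 90.0) -> tuple[StructureModel, dict]:
    """Build an idealized structure from a plan; returns (model, truth).

    Bonded cysteine SG pairs sit exactly 2.05 Å apart before jitter;
    unbonded cysteines carry an SG well away from every other SG.
    """
    bonds = [tuple(sorted(b)) for b in plan["bonds"]]
    flat = [p for b in bonds for p in b]
    if len(flat) != len(set(flat)):
        raise ValueError("infeasible template: overlapping bonds")
    for i, j in bonds:
        if i not in plan["cys"] or j not in plan["cys"]:
            raise ValueError(f"bond ({i},{j}) references a non-cysteine position")
    rng = np.random.default_rng(seed)
    seq = _plant_sequence(plan, rng, sequence)
    length = plan["length"]
    ca = _hairpin_backbone(length)
    sg: dict[int, np.ndarray] = {}
    for k, (i, j) in enumerate(bonds):
        a, b = ca[i - 1], ca[j - 1]
        u = (b - a) / np.linalg.norm(b - a)
        mid = (a + b) / 2.0
        # distinct z-offset per bond: nested bonds on one arm share midpoints,
        # so without this the SG pairs of different bonds would collide
        lift = np.array([0.0, 0.0, 3.0 * (k + 1)])
        # jitter moves a bonded pair rigidly: predicted models keep covalent
        # S-S geometry locally exact even when globally uncertain
        pair_noise = rng.normal(0, jitter_sigma, 3)
        sg[i] = mid - (SS_BOND_LENGTH / 2.0) * u + lift + pair_noise
        sg[j] = mid + (SS_BOND_LENGTH / 2.0) * u + lift + pair_noise
    for pos in plan["cys"]:
        if pos not in sg:
            sg[pos] = (ca[pos - 1] + np.array([0.0, 0.0, -1.8])
                       + rng.normal(0, jitter_sigma, 3))
    residues = []
    for i in range(1, length + 1):
        atoms = [Atom("CA", "C", ca[i - 1] + rng.normal(0, jitter_sigma, 3))]
        if i in sg:
            atoms.append(Atom("SG", "S", sg[i]))
        residues.append(Residue(seq_index=i, aa=seq[i - 1], atoms=atoms,
                                plddt=plddt))
    model = StructureModel(id=model_id, residues=residues, source="predicted")
    truth = {"bonds": bonds, "cys": sorted(plan["cys"]),
             "motifs": plan.get("motifs", []), "sequence": seq}
    return model, truth


def make_sheet_model(n_strands: int, strand_len: int = 8, seed: int = 0,
                     model_id: str = "sheet") -> StructureModel:
    """Idealized antiparallel β-sheet with a planted strand count.

    Turns are three tightly clustered residues so extended-geometry runs
    break between strands.
    """
    coords = []
    for k in range(n_strands):
        xs = range(strand_len) if k % 2 == 0 else range(strand_len - 1, -1, -1)
        for x in xs:
            coords.append((CA_STEP * x, ARM_OFFSET * k, 0.0))
        if k < n_strands - 1:
            edge_x = coords[-1][0]
            for t in range(1, 4):
                coords.append((edge_x + (1.0 if k % 2 == 0 else -1.0) * t,
                               ARM_OFFSET * k + ARM_OFFSET * t / 4.0, 1.5))
    rng = np.random.default_rng(seed)
    residues = [Residue(i + 1, str(rng.choice(list(AA_NO_C))),
                        [Atom("CA", "C", np.array(c))], plddt=90.0)
                for i, c in enumerate(coords)]
    return StructureModel(id=model_id, residues=residues)


def make_helix_model(length: int = 30, seed: int = 0,
                     model_id: str = "helix") -> StructureModel:
    """Ideal α-helix Cα trace (rise 1.5 Å, 100°/residue, radius 2.3 Å)."""
    rng = np.random.default_rng(seed)
    residues = []
    for i in range(length):
        angle = np.deg2rad(100.0 * i)
        coord = np.array([2.3 * np.cos(angle), 2.3 * np.sin(angle), 1.5 * i])
        residues.append(Residue(i + 1, str(rng.choice(list(AA_NO_C))),
                                [Atom("CA", "C", coord)], plddt=90.0))
    return StructureModel(id=model_id, residues=residues)


# ---------------------------------------------------------------------------
# Family simulation
# ---------------------------------------------------------------------------

def _simulate_branch(seq: str, branch_length: float, masked: set[int],
                     rng: np.random.Generator) -> str:
    p_sub = 1.0 - np.exp(-branch_length)
    chars = list(seq)
    for i in range(len(chars)):
        if i in masked:
            continue
        if rng.random() < p_sub:
            choices = AA_NO_C.replace(chars[i], "") if chars[i] in AA_NO_C else AA_NO_C
            chars[i] = str(rng.choice(list(choices)))
    return "".join(chars)


def _random_subtree(leaves: list[str], rng: np.random.Generator,
                    mean_branch: float):
    """Random binary topology as nested tuples (name or (left, right), length)."""
    length = float(rng.exponential(mean_branch))
    if len(leaves) == 1:
        return (leaves[0], length)
    k = int(rng.integers(1, len(leaves)))
    return ((_random_subtree(leaves[:k], rng, mean_branch),
             _random_subtree(leaves[k:], rng, mean_branch)), length)


def _newick(subtree) -> str:
    node, length = subtree
    if isinstance(node, str):
        return f"{node}:{length:.6f}"
    left, right = node
    return f"({_newick(left)},{_newick(right)}):{length:.6f}"


def make_family(config: SynthConfig | None = None, n_leaves: int | None = None,
                seed: int | None = None) -> dict:
    """Simulate the four-group family; returns a truth bundle.

    Keys: ``sequences`` (gap-free equal-length FASTA dict, which is also the
    true alignment), ``labels`` (leaf -> group), ``newick`` (true tree),
    ``anchors`` (leaf -> group; two leaves per group whose MRCA is the group
    ancestor), ``plans`` (per-group scaffold plans), ``masked`` (per-group
    immutable site sets).
    """
    config = config or SynthConfig()
    if n_leaves is not None or seed is not None:
        config = SynthConfig(seed=seed if seed is not None else config.seed,
                             n_genes=n_leaves if n_leaves is not None else config.n_genes,
                             group_proportions=config.group_proportions,
                             intron_means=config.intron_means,
                             jitter_sigma=config.jitter_sigma,
                             between_group_branch=config.between_group_branch,
                             within_group_branch=config.within_group_branch)
    if config.n_genes < 4:
        raise ValueError("need at least 4 leaves")
    rng = np.random.default_rng(config.seed)
    groups = list(config.group_proportions)
    counts = {g: max(1, int(round(config.group_proportions[g] * config.n_genes)))
              for g in groups}
    # adjust rounding drift on the largest group
    drift = config.n_genes - sum(counts.values())
    largest = max(groups, key=lambda g: counts[g])
    counts[largest] += drift

    root = "".join(rng.choice(list(AA_NO_C), size=SCAFFOLD_LENGTH))
    sequences: dict[str, str] = {}
    labels: dict[str, str] = {}
    anchors: dict[str, str] = {}
    ancestors: dict[str, str] = {}
    newick_parts = []
    masked_by_group = {}
    for group in groups:
        plan = GROUP_PLANS[group]
        ancestor = _plant_sequence(plan, rng, sequence=root)
        masked = {p - 1 for p in plan["cys"]}
        for motif, pos in plan["motifs"]:
            masked.update(range(pos - 1, pos - 1 + len(motif)))
        masked_by_group[group] = masked
        ancestor = _simulate_branch(ancestor, config.between_group_branch,
                                    masked, rng)
        ancestor = scrub_motifs(ancestor, plan)
        ancestors[group] = ancestor
        leaf_names = [f"{group}_{i:03d}" for i in range(1, counts[group] + 1)]
        subtree = _random_subtree(leaf_names, rng, config.within_group_branch)

        def emit(node, seq):
            inner, length = node
            seq = scrub_motifs(
                _simulate_branch(seq, length, masked, rng), plan)
            if isinstance(inner, str):
                sequences[inner] = seq
                labels[inner] = group
            else:
                emit(inner[0], seq)
                emit(inner[1], seq)

        emit(subtree, ancestor)
        # anchors: first leaf of each child of the group ancestor -> MRCA
        # of the two anchors is the whole group clade
        inner, _ = subtree
        if isinstance(inner, str):
            anchors[inner] = group
        else:
            for child in inner:
                node = child
                while not isinstance(node[0], str):
                    node = node[0][0]
                anchors[node[0]] = group
        # group subtree hangs off the root by the between-group branch
        newick_parts.append(_newick((subtree[0], config.between_group_branch)))
    newick = "(" + ",".join(newick_parts) + ");"
    return {"sequences": sequences, "labels": labels, "anchors": anchors,
            "ancestors": ancestors, "newick": newick, "plans": GROUP_PLANS,
            "counts": counts, "masked": masked_by_group, "config": config}


def make_decoys(n: int, length: int = SCAFFOLD_LENGTH, seed: int = 0,
                ) -> dict[str, str]:
    """Random background sequences (no planted motifs, no cysteines)."""
    rng = np.random.default_rng(seed)
    return {f"decoy_{i:04d}": "".join(rng.choice(list(AA_NO_C), size=length))
            for i in range(n)}


def make_profile_family(seed: int = 0, motif_len: int = 30, n_family: int = 20,
                        n_divergent: int = 5, n_decoys: int = 100,
                        seq_len: int = 150) -> dict:
    """Planted-motif family for the iterative profile search.

    Emulates the two-round identification setting: the seed alignment
    derives from a *generic* variant of the domain (a 5-substitution offset
    from the true family motif, like a cross-family seed profile), the
    family carries the true motif with light variation (2 substitutions),
    and a divergent subfamily sits between the two (6 substitutions) —
    below the seed profile's reach but within reach of a profile rebuilt
    from the family itself.  Build the profile with pseudocount weight 1.0
    (``recommended_pseudocount``) so single-observation columns are not
    over-penalized.

    Returns seed_alignment, database, family/divergent id lists and true
    motif offsets (1-based).
    """
    rng = np.random.default_rng(seed)

    def mutate(s: str, k: int) -> str:
        chars = list(s)
        for i in rng.choice(len(chars), size=k, replace=False):
            chars[i] = str(rng.choice(list(AA_NO_C.replace(chars[i], ""))))
        return "".join(chars)

    motif = "".join(rng.choice(list(AA_NO_C), size=motif_len))
    generic = mutate(motif, 5)
    seed_alignment = [mutate(generic, 3) for _ in range(5)]
    database: dict[str, str] = {}
    offsets: dict[str, int] = {}

    def plant(name: str, core: str) -> None:
        bg = "".join(rng.choice(list(AA_NO_C), size=seq_len))
        off = int(rng.integers(0, seq_len - motif_len))
        database[name] = bg[:off] + core + bg[off + motif_len:]
        offsets[name] = off + 1

    family_ids = [f"fam_{i:03d}" for i in range(n_family)]
    divergent_ids = [f"div_{i:03d}" for i in range(n_divergent)]
    for name in family_ids:
        plant(name, mutate(motif, 2))
    for name in divergent_ids:
        plant(name, mutate(motif, 6))
    database.update(make_decoys(n_decoys, seq_len, seed=seed + 1))
    return {"seed_alignment": seed_alignment, "database": database,
            "family": family_ids, "divergent": divergent_ids,
            "offsets": offsets, "motif": motif,
            "recommended_pseudocount": 1.0}


# ---------------------------------------------------------------------------
# GFF3 emission
# ---------------------------------------------------------------------------

def make_gff(plan: list[dict], seed: int = 0) -> tuple[str, dict]:
    """Emit GFF3 text from a gene plan; returns (text, truth).

    Each plan entry: {"gene_id": str, "exon_counts": [int, ...]} with one
    transcript per count; optional "exon_len" and "intron_len".
    Truth maps gene_id -> representative intron count (first transcript).
    """
    rng = np.random.default_rng(seed)
    lines = ["##gff-version 3"]
    truth = {}
    cursor = 1000
    for entry in plan:
        gene_id = entry["gene_id"]
        exon_counts = entry["exon_counts"]
        exon_len = entry.get("exon_len", 150)
        intron_len = entry.get("intron_len", 100)
        if any(c < 1 for c in exon_counts):
            raise ValueError(f"{gene_id}: exon counts must be >= 1")
        strand = "+" if rng.random() < 0.5 else "-"
        spans = []
        tx_lines = []
        for t, n_exons in enumerate(exon_counts, start=1):
            start = cursor
            exons = []
            pos = start
            for _ in range(n_exons):
                exons.append((pos, pos + exon_len - 1))
                pos += exon_len + intron_len
            end = exons[-1][1]
            spans.append((start, end))
            tid = f"{gene_id}.{t}"
            tx_lines.append(f"chr1\tapsynth\tmRNA\t{start}\t{end}\t.\t{strand}\t."
                            f"\tID={tid};Parent={gene_id}")
            for k, (s, e) in enumerate(exons, start=1):
                tx_lines.append(f"chr1\tapsynth\texon\t{s}\t{e}\t.\t{strand}\t."
                                f"\tID={tid}.exon{k};Parent={tid}")
            cursor = max(cursor, end + 500)
        gene_start = min(s for s, _ in spans)
        gene_end = max(e for _, e in spans)
        lines.append(f"chr1\tapsynth\tgene\t{gene_start}\t{gene_end}\t.\t{strand}"
                     f"\t.\tID={gene_id}")
        lines.extend(tx_lines)
        truth[gene_id] = exon_counts[0] - 1
        cursor += 500
    return "\n".join(lines) + "\n", truth


def intron_plan_for_family(labels: dict[str, str], config: SynthConfig,
                           rng: np.random.Generator) -> list[dict]:
    """Per-gene exon-count plan drawn from the group Poisson means."""
    plan = []
    for gene, group in labels.items():
        introns = int(rng.poisson(config.intron_means[group]))
        plan.append({"gene_id": gene, "exon_counts": [introns + 1]})
    return plan


# ---------------------------------------------------------------------------
# Full bundle
# ---------------------------------------------------------------------------

def make_bundle(config: SynthConfig, out_dir: str | Path) -> dict:
    """Write a complete synthetic run directory.

    Emits proteins.fasta, alignment.fasta, tree.nwk (true tree), models/
    (one PDB per gene), genes.gff3, anchors.tsv and truth.json; returns the
    truth dict.
    """
    out = Path(out_dir)
    (out / "models").mkdir(parents=True, exist_ok=True)
    family = make_family(config)
    rng = np.random.default_rng(config.seed + 1)

    fasta = "".join(f">{name}\n{seq}\n" for name, seq in family["sequences"].items())
    (out / "proteins.fasta").write_text(fasta)
    (out / "alignment.fasta").write_text(fasta)  # gap-free simulation: MSA = FASTA
    (out / "tree.nwk").write_text(family["newick"] + "\n")
    (out / "anchors.tsv").write_text(
        "".join(f"{leaf}\t{group}\n" for leaf, group in family["anchors"].items()))

    bonds_truth = {}
    for name, seq in family["sequences"].items():
        group = family["labels"][name]
        plan = dict(GROUP_PLANS[group])
        model, truth = make_structure(plan, jitter_sigma=config.jitter_sigma,
                                      seed=int(rng.integers(0, 2**31)),
                                      sequence=seq, model_id=name,
                                      plddt=config.plddt)
        write_pdb(model, out / "models" / f"{name}.pdb")
        bonds_truth[name] = truth["bonds"]

    # topology-numbering reference for the run: the nucellin-type group III
    # ancestor, whose cysteines define C1..C12 for the whole bundle
    reference = {
        "id": "nucellin_synthetic",
        "sequence": family["ancestors"]["III"],
        "cys_positions": sorted(GROUP_PLANS["III"]["cys"]),
        "bonds": [list(b) for b in GROUP_PLANS["III"]["bonds"]],
    }
    (out / "reference.json").write_text(json.dumps(reference, indent=1))

    gff_plan = intron_plan_for_family(family["labels"], config, rng)
    gff_text, intron_truth = make_gff(gff_plan, seed=config.seed + 2)
    (out / "genes.gff3").write_text(gff_text)

    truth = {
        "seed": config.seed,
        "n_genes": config.n_genes,
        "labels": family["labels"],
        "anchors": family["anchors"],
        "counts": family["counts"],
        "introns": intron_truth,
        "bonds": bonds_truth,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    return truth


def validate_bundle(out_dir: str | Path) -> bool:
    """Cross-check emitted files against truth.json (counts and file presence)."""
    out = Path(out_dir)
    truth = json.loads((out / "truth.json").read_text())
    fasta = (out / "proteins.fasta").read_text()
    n_seqs = fasta.count(">")
    if n_seqs != truth["n_genes"]:
        raise ValueError(f"fasta has {n_seqs} sequences, truth says {truth['n_genes']}")
    for name in truth["labels"]:
        if not (out / "models" / f"{name}.pdb").exists():
            raise ValueError(f"missing model for {name}")
    gff = (out / "genes.gff3").read_text()
    for name in truth["introns"]:
        if f"ID={name}" not in gff:
            raise ValueError(f"gene {name} missing from GFF3")
    return True
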