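# Methods

This note documents the models, parameters and design decisions behind
`apclass`, in the order the pipeline runs.

## Structure models

A `StructureModel` is a single ordered protein chain. AlphaFold-style
files carry per-residue pLDDT in the B-factor column; parsing takes the
residue-mean B-factor, clipped to [0, 100]. Experimental entries get a
fixed confidence of 100. HETATM records are skipped everywhere — in
particular the pepstatin inhibitor of the human pepsin entry never enters a
superposition, which uses Cα atoms only. Altloc duplicates resolve to the
highest-occupancy conformer (ties to file order); insertion-coded or
non-monotonic residue numbers are renumbered sequentially so downstream
indices are unambiguous. Multi-chain files default to the first chain.

## Disulfide detection and canonical numbering

Detection is purely geometric: every Cys pair whose Sγ–Sγ distance is
within `max_sg_distance` (default **2.5 Å**; the covalent bond is ≈ 2.05 Å,
the slack absorbs model error) becomes a candidate edge, and the bond set
is the maximum-cardinality matching of minimum total distance
(`networkx.min_weight_matching`, with an index-based epsilon making exact
ties resolve to the smallest residue pair). Each cysteine therefore joins
at most one bridge. Bonds touching a residue with pLDDT < 50 are flagged,
not dropped. Cysteines lacking an Sγ atom are skipped with a warning.

Canonical numbering transfers a reference's C1…CN labels by global
Needleman–Wunsch alignment (BLOSUM62, gap open 10, extend 0.5 — the paper
trail never states how labels move between proteins, so these package
defaults are documented here and overridable). A query cysteine aligned to
a labeled reference cysteine inherits its rank; any other query cysteine
becomes an insertion, taking the rank of the nearest preceding reference
cysteine plus letters a, b, c in sequence order (C6a; C5a-C5b; C9a-C11a);
unmatched reference ranks are reported *lacking*. The serialization
`C1-C8;C2-C3;…|lacking:…|extra:…` is order-independent and is what the
classifier consumes.

Three reference numberings ship with the package (group I pepsin+saposin
pattern under the APA1 scheme; the nucellin/nepenthesin pattern under the
mp4g19220 scheme for group II and the ASPR1 scheme for groups III/IV). The
reference *bond patterns and cysteine spacings* follow the family's
published architecture, but the reference *sequences* are synthetic
stand-ins generated deterministically in code — the real sequences are not
redistributable here, and label transfer only needs cysteine spacing on a
homologous scaffold. Pipelines on real data should supply their own
`reference.json` (id, sequence, cysteine positions, bonds), which is what
the synthetic bundle does. The group II reference id appears in the
source literature under three spellings (mp4g19220 / mp4g19920 /
mp4g12920); this package uses "mp4g19220" throughout and makes no claim
about which spelling is the typo.

## Superposition

`kabsch` is the standard SVD solution with reflection correction
(det(R) = +1); collinear point sets are fitted but flagged degenerate.
`superpose_models` mirrors a viewer's `align`: correspondence from global
sequence alignment restricted to Cα-bearing match columns, then up to
**5 cycles** of fit → reject pairs deviating > **2.0 Å** → refit, stopping
early when nothing is rejected. RMSD is reported over retained pairs; the
all-pair RMSD under the final transform is logged alongside. Since the
original viewer parameters behind the published RMSDs are unstated, the
benchmark harness (`apclass.reproduce`) prints the parameters it used with
every number, and the acceptance tolerance on those benchmarks is
deliberately wide (±15%).

## Domain annotation

* **Active sites.** First D[TS]G[ST] in the N-half and first in the
  C-half; `canonical` is true only if both match. If the C-half has no
  canonical tetrad and a structure is available, the fallback takes the
  C-half tetrad whose Cα lies closest (≤ 15 Å) to the motif-1 aspartate —
  in the bilobed pepsin fold the two catalytic motifs face each other
  across the cleft, and this is the only way to recover fully degenerate
  second motifs such as SSVN, which no sequence pattern can match. A
  relaxed D-x-G-x scan is the last resort. (The structural rule is this
  package's own resolution; a pure D-x-G-x fallback cannot produce an
  Asp-free motif-2.)
* **TM helices.** Kyte–Doolittle, window 19, mean ≥ 1.6; maximal runs of
  qualifying windows become segments.
* **Saposin-like domain.** Three fully nested disulfides a-f, b-e, c-d over
  six *consecutive* cysteines, outside influence of the core pattern;
  the segment spans the outer bond padded by 5 residues.
* **NAP1 fold.** Present iff at least one bond joins canonical cysteines
  C4–C7 (insertions included); this keeps topologies that lack one of the
  two bonds (the III-F signature) recognizable as NAP1-bearing.
* **C-extension.** ≥ 40 residues past the last disulfide-bonded cysteine;
  "very long" (the II-C signature) at ≥ 120.
* **Strand counting.** AlphaFold models have no hydrogens, so secondary
  structure is Cα pseudo-geometry: a residue is "extended" when
  d(i,i+2) ≥ 6.0 Å and d(i,i+3) ≥ 8.5 Å (idealized strands give ≈ 7.0 /
  10.5, helices ≈ 5.4 / 5.0), and a strand is ≥ 3 consecutive extended
  residues. The count carries a low-confidence flag below mean pLDDT 70.
* **Signal peptide / propeptide** calls are heuristics (N-terminal
  hydrophobic window within residues 1–40; the stretch from there to
  motif 1) and are overridden by supplied annotations. The "II-C specific
  motif" of the C-extension has no reconstructable sequence signature; the
  engine keys subgroup II-C on the very-long extension alone.

## Profile search

The two-round identification procedure is implemented as a PSSM, not a
profile HMM: per-column log-odds (bits) against Robinson–Robinson
background frequencies with background-proportional pseudocounts
(p = (c + w·q)/(n + w)); columns > 50% gaps are dropped. Search slides the
profile ungapped and keeps the best window per sequence; the default
threshold is 60% of the profile's self-score (no E-value model). Round 2
rebuilds the profile from the round-1 hit windows — ungapped hits all span
the profile length, so the windows stack into an aligned block without a
new MSA step — and re-searches, reporting gained/lost identifiers. This
preserves the logic that matters (a family-derived profile recovers
divergent members a generic seed misses) while making no attempt to
reproduce HMMER scores. Candidate curation is advisory only: truncated
cores or motif-less, cysteine-poor hits are flagged, never auto-dropped.

## Trimming, distances, trees, clades

Entropy trimming is a BMGE-style stand-in, not a BMGE reimplementation:
per-column Shannon entropy over non-gap residues normalized by log2(20)
(all-gap columns count as 1), dropped above the cutoff (default **0.8**,
the middle of the published 0.7–0.9 window) or above a gap fraction
(default 0.2). Distances use pairwise deletion; the Poisson correction
−ln(1−p) clamps p at 0.95 to stay finite at saturation. Neighbor joining
follows Saitou–Nei with ties in the Q-matrix resolved to the smallest
active index pair and negative branch estimates clamped to zero; trees are
dendropy objects and Newick round-trips are byte-stable. Bootstrap
resamples trimmed columns (default 100 replicates; 1000 supported) and
writes bipartition frequencies as internal labels.

The in-repo tree is NJ rather than maximum likelihood: classification
consumes clade membership, not likelihoods, and the pipeline accepts an
externally computed Newick tree wherever it accepts an MSA. Clade
labelling is anchor-based: each leaf takes the group of its nearest anchor
by patristic distance, with equidistant leaves (relative tolerance 1e-6)
left `unassigned`. This distance form was chosen over "smallest containing
clade" because it is robust to NJ rearranging within-group structure while
still collapsing to clade membership whenever the groups are clean clades.

## Gene structure

Intron count per transcript is exon count − 1; exon features resolve
through Parent attributes, with CDS intervals as a logged fallback. The
default multi-isoform policy is *representative* (longest summed exon
length, ties by transcript id), since the original analysis does not state
its handling; `max` and `mean` are available, and per-transcript tables
are emitted alongside per-gene ones. Group means are arithmetic, rounded
half-up to 2 decimals.

## Classification rules

Clade evidence dominates structural evidence (the groups are defined on
the tree; structure is confirmatory); on conflict the record keeps the
clade call, logs the conflict, and downgrades confidence. Structure-only
order: non-canonical active site + intron-poor → IV; saposin (or group-I
topology: 3 bonds, no NAP1) → I; NAP1 + intron-rich → II; NAP1 +
intron-poor → III; otherwise unassigned. The intron thresholds (rich ≥ 4,
poor ≤ 2) are derived cutoffs sitting in the wide gap between the observed
group averages (≈ 8–10 vs < 0.5), not published statements. Unknown is a
first-class value: a rule that needs a feature does not fire on unknown.
Subgroups route on saposin (I-A/I-B), GPI → II-D, very-long C-extension →
II-C, C-extension → II-B, else II-A; and for group III on topology deltas
(3 NAP1 bonds → III-A; lacking C4+C5 with a C9a-C11a bond → III-G; missing
C2-C3 bond → III-C/III-D; single NAP1 bond → III-F; interdomain helix →
III-E; reference-like → III-B/III-G). The pairs III-B/III-G and
III-C/III-D are structurally identical by construction and resolve only
through a subgroup-level clade label; without one the engine emits the
tied call with an "/ambiguous" confidence suffix rather than guessing.
Species-distribution facts (e.g. a Brassicaceae-only subgroup) are
recorded as evidence when a taxon is supplied, never enforced.

## Synthetic data: what it emulates, and what it does not

The generator defines the study conditions: 200 genes at the census
proportions 90/275/682/153 of 1200; group intron counts drawn Poisson at
the published means 10.33/8.53/0.45/0.33; canonical motifs in groups I–III
versus DLGG/SSVN in group IV; per-group cysteine/bond plans carrying each
group's topology (and subgroup variants as deltas); divergence simulated
along a known tree (between-group branches 0.6 substitutions/site,
within-group mean 0.08 — large enough to separate clades cleanly at
sequence length 220, small enough that NJ recovery is non-trivial); and
coordinate jitter σ = 0.2 Å on idealized backbones.

Geometry is idealized, not physically relaxed: chains are hairpins whose
two arms face each other (enough bilobed realism for the active-site
proximity rule), bonded Sγ pairs are placed at exactly 2.05 Å and jittered
*rigidly* — predicted models preserve local covalent geometry even when
globally uncertain, so noise moves a bonded pair together rather than
stretching the bond. Planted motifs and cysteines are masked from
mutation, and stray canonical motifs arising in random background are
scrubbed so ground truth stays exact. Consequences for interpretation:
passing tests show the operations are correct on data satisfying their
geometric and evolutionary assumptions; they do not show robustness to
real AlphaFold error profiles, indels/alignment error (the simulated MSA
is gap-free), annotation noise in GFF3, or pseudogenes. The profile-search
fixture plants a family (2 substitutions from the true motif), a generic
seed (5 away) and a divergent subfamily (6 away) with pseudocount weight
1.0 — conditions under which the two-round property (round 1 misses the
divergent members, round 2 recovers some) holds by construction.

## Problem sizes and determinism

The standard runs are desk-scale by design: 200-gene family, 220-residue
scaffolds, 100 bootstrap replicates maximum in tests, 100-replicate
Monte-Carlo recoveries. Every stochastic step takes an explicit seed; the
bundle writer is byte-deterministic per seed, every output carries the
run-config hash, and reruns of the pipeline are byte-identical.

## Known limitations

* The published pairwise-RMSD and disulfide benchmarks require the pinned
  AlphaFold-DB/RCSB downloads; without them the corresponding acceptance
  tests fail by design with a pointer to the download instructions.
* PSSM scores are not HMMER bit scores; thresholds are self-score
  fractions, not E-values.
* The BMGE stand-in ignores BLOSUM-similarity smoothing; trimmed column
  sets will differ from real BMGE output.
* Cα-based secondary structure under-resolves distorted sheets; the
  strand count is advisory (and whether an "eight-sheet" interdomain
  description counts strands or sheets is ambiguous — this package counts
  strands).
* Signal/propeptide heuristics are not a substitute for dedicated
  predictors; supply annotations where they matter.
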