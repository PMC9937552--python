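"""Active-site scanning, TM/saposin/NAP1/C-extend detection, strand counts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apclass.disulfide import canonical_numbering, detect_disulfides, \
    reference_topology
from apclass.domains import (annotate_architecture, count_interdomain_strands,
                             detect_c_extend, detect_nap1_fold,
                             detect_saposin_like, detect_tm_helix,
                             scan_active_sites)
from apclass.synth import (GROUP_PLANS, apply_variant, make_helix_model,
                           make_sheet_model, make_structure)

BG = "".join(c for c in "ADEFHIKMNPQRVWY")  # polar-ish, no D[TS]G[ST] parts


def pad(seq, n=120, ch="N"):
    return seq + ch * max(0, n - len(seq))


def test_canonical_motifs_found_in_each_half():
    seq = pad("M" * 30 + "DTGS" + "K" * 40 + "QQQ" + "DSGT" + "E" * 30, 120)
    call = scan_active_sites(seq)
    assert call.canonical
    assert call.motif_1 == "DTGS" and call.pos_1 == 31
    assert call.motif_2 == "DSGT"


def test_flanking_context_of_atypical_first_motif():
    # nucellin-style acidic-hydrophobic context: EIDTGSD
    seq = pad("K" * 20 + "EIDTGSD" + "Q" * 40 + "DSGT" + "E" * 30, 110)
    call = scan_active_sites(seq)
    assert call.motif_1 == "DTGS"
    assert seq[call.pos_1 - 3:call.pos_1 + 4] == "EIDTGSD"


def test_noncanonical_pair_via_structural_proximity():
    """A degenerate second motif (SSVN-type, no Asp) is only reachable through
    spatial proximity to motif 1 across the catalytic cleft."""
    model, truth = make_structure(GROUP_PLANS["IV"], jitter_sigma=0.1, seed=5)
    call = scan_active_sites(truth["sequence"], model)
    assert not call.canonical
    assert call.motif_1 == "DLGG"
    assert call.motif_2 == "SSVN"


def test_no_candidates_yields_empty_noncanonical_call():
    call = scan_active_sites("K" * 80)
    assert call.motif_1 == "" and call.motif_2 == "" and not call.canonical


@settings(derandomize=True, max_examples=25)
@given(st.integers(0, 2**31 - 1))
def test_single_planted_motifs_always_recovered(seed):
    rng = np.random.default_rng(seed)
    bg = "".join(rng.choice(list(BG), size=160))
    p1, p2 = int(rng.integers(0, 60)), int(rng.integers(90, 150))
    seq = bg[:p1] + "DTGS" + bg[p1:p2] + "DSGT" + bg[p2:]
    call = scan_active_sites(seq)
    assert call.canonical
    assert call.pos_1 == p1 + 1
    assert call.pos_2 == p2 + 5


def test_tm_helix_on_hydrophobic_stretch():
    seq = "N" * 30 + "L" * 19 + "N" * 30
    segments = detect_tm_helix(seq)
    assert len(segments) == 1
    seg = segments[0]
    assert seg.start <= 31 and seg.end >= 49


def test_all_polar_sequence_has_no_tm():
    assert detect_tm_helix("NQSTED" * 20) == []


def test_two_separated_hydrophobic_stretches():
    seq = "N" * 25 + "I" * 21 + "Q" * 40 + "L" * 21 + "N" * 25
    segments = detect_tm_helix(seq)
    assert len(segments) == 2
    assert segments[0].end < segments[1].start


def test_saposin_nested_triple_detected_in_group_I():
    model, truth = make_structure(GROUP_PLANS["I"], jitter_sigma=0.2, seed=8)
    bonds = detect_disulfides(model)
    seg = detect_saposin_like(model, bonds)
    assert seg is not None
    assert seg.start <= 120 and seg.end >= 170  # spans the nested triple


def test_no_saposin_in_nucellin_pattern():
    model, _ = make_structure(GROUP_PLANS["II"], jitter_sigma=0.2, seed=9)
    assert detect_saposin_like(model, detect_disulfides(model)) is None


@pytest.mark.parametrize("seed", range(50))
def test_saposin_recovery_on_planted_models(seed):
    model, _ = make_structure(GROUP_PLANS["I"], jitter_sigma=0.2, seed=seed)
    assert detect_saposin_like(model, detect_disulfides(model)) is not None


# one neutral cysteine-free scaffold shared by reference and queries, so
# label transfer runs on a homologous background (as in a real gene family)
_SCAFFOLD = "".join(
    np.random.default_rng(2024).choice(list("ADEFGHIKLMNPQRSTVWY"), size=220))


def _topology_for(plan, seed=3):
    ref = _family_reference()
    model, truth = make_structure(plan, jitter_sigma=0.1, seed=seed,
                                  sequence=_SCAFFOLD)
    bonds = detect_disulfides(model)
    return canonical_numbering(truth["sequence"], bonds, ref)


def _family_reference():
    from apclass.disulfide import CanonicalLabel, DisulfideTopology
    plan = GROUP_PLANS["III"]
    model, truth = make_structure(plan, seed=0, sequence=_SCAFFOLD)
    labels = {pos: CanonicalLabel(rank)
              for rank, pos in enumerate(sorted(plan["cys"]), start=1)}
    rank = {pos: lab for pos, lab in labels.items()}
    bonds = frozenset(frozenset({rank[i], rank[j]}) for i, j in plan["bonds"])
    return DisulfideTopology(model_id="ref", reference_id="ref",
                             labeled_cysteines=labels, bonds=bonds,
                             sequence=truth["sequence"])


def test_nap1_fold_present_with_two_bonds():
    topo = _topology_for(GROUP_PLANS["III"])
    seg = detect_nap1_fold(topo)
    assert seg is not None
    assert (seg.start, seg.end) == (60, 82)


def test_nap1_fold_survives_with_single_bond():
    topo = _topology_for(apply_variant(GROUP_PLANS["III"], "III-F"))
    seg = detect_nap1_fold(topo)
    assert seg is not None  # C5-C7 remains


def test_nap1_fold_absent_without_bonds_in_window():
    plan = apply_variant(GROUP_PLANS["III"], "III-F")
    plan["bonds"] = [b for b in plan["bonds"] if b != (66, 82)]
    topo = _topology_for(plan)
    assert detect_nap1_fold(topo) is None


def test_c_extend_boundaries():
    plan = dict(GROUP_PLANS["II"])
    model, _ = make_structure(plan, seed=4)
    assert detect_c_extend(model, protease_core_end=200) is None  # 20 trailing
    long_plan = {**plan, "length": 240 + plan["length"] - 220}
    # exactly 40 trailing residues after the last core cysteine
    long_plan["length"] = 240
    model40, _ = make_structure(long_plan, seed=4)
    seg = detect_c_extend(model40, protease_core_end=200)
    assert seg is not None and not seg.very_long
    vl_plan = {**plan, "length": 380}
    model_vl, _ = make_structure(vl_plan, seed=4)
    seg_vl = detect_c_extend(model_vl, protease_core_end=200)
    assert seg_vl is not None and seg_vl.very_long


@pytest.mark.parametrize("n_strands", [5, 6, 8])
def test_planted_strand_counts_recovered(n_strands):
    count, confident = count_interdomain_strands(make_sheet_model(n_strands))
    assert count == n_strands
    assert confident


def test_helix_contains_no_strands():
    count, _ = count_interdomain_strands(make_helix_model(40))
    assert count == 0


def test_architecture_is_deterministic_and_in_bounds():
    model, truth = make_structure(GROUP_PLANS["I"], jitter_sigma=0.2, seed=2)
    bonds = detect_disulfides(model)
    segs1 = annotate_architecture(truth["sequence"], model, bonds)
    segs2 = annotate_architecture(truth["sequence"], model, bonds)
    assert segs1 == segs2
    for seg in segs1:
        assert 1 <= seg.start <= seg.end <= len(truth["sequence"])
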