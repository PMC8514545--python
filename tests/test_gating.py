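"""Gate-tree structure, compensation, threshold placement, partition laws."""

import dataclasses

import numpy as np
import pytest

import idarcyto as ic
from idarcyto.gating import find_density_valley, terminal_populations
from idarcyto.panel import FLUORO_CHANNELS, MONOCYTE_SUBSETS, TERMINAL_POPULATIONS


# --- compensation -----------------------------------------------------------

def test_identity_compensation_is_noop(healthy_sample):
    out = ic.apply_compensation(healthy_sample.events, np.eye(8))
    np.testing.assert_array_equal(out.to_numpy(), healthy_sample.events.to_numpy())


def test_singular_matrix_rejected(healthy_sample):
    s = np.eye(8)
    s[3] = s[2]
    with pytest.raises(ValueError, match="singular"):
        ic.apply_compensation(healthy_sample.events, s)


def test_compensation_leaves_scatter_untouched(healthy_sample):
    out = ic.apply_compensation(healthy_sample.events, ic.example_spillover())
    for ch in ("FSC-A", "FSC-H", "SSC-A"):
        np.testing.assert_array_equal(out[ch], healthy_sample.events[ch])


# --- tree structure ---------------------------------------------------------

def test_default_tree_has_twelve_terminal_populations(tree):
    assert len(terminal_populations(tree)) == 12
    assert set(terminal_populations(tree)) == set(TERMINAL_POPULATIONS)


def test_m1_to_m5_share_the_cd14pos_cd91pos_parent(tree):
    parents = {tree.gate(m).parent for m in ("M1", "M2", "M3", "M4", "M5")}
    assert parents == {"CD14POS_CD91POS"}


def test_degenerate_gate_geometry_rejected():
    with pytest.raises(ValueError, match="degenerate"):
        ic.build_default_gate_tree(thresholds={"cd16_low": 3.5})  # == cd16_pos


# --- automated threshold placement -----------------------------------------

def test_valley_lands_in_the_intercomponent_gap():
    rng = np.random.default_rng(0)
    vals = np.concatenate([rng.normal(1.0, 0.3, 3000), rng.normal(4.0, 0.3, 3000)])
    thr, fallback = find_density_valley(vals, (1.5, 3.5), default=2.0)
    assert not fallback
    assert 1.9 < thr < 3.1  # inside the true gap between component means


def test_unimodal_marginal_falls_back_to_quantile():
    rng = np.random.default_rng(1)
    vals = rng.normal(2.5, 0.4, 5000)
    thr, fallback = find_density_valley(vals, (1.5, 3.5), default=2.0,
                                        fallback_quantile=0.5)
    assert fallback
    assert thr == pytest.approx(np.median(vals), abs=0.1)


def test_empty_parent_uses_default_and_flags(calib, tree):
    cfg = dataclasses.replace(
        calib,
        abundance={**calib.abundance, "HEALTHY": {"FILLER": 1.0}},
        max_events=4000,
    )
    with pytest.warns(Warning):
        s = ic.sample_subject("HEALTHY", cfg, seed=0)
    adj = ic.auto_adjust_gates(s.events, tree)
    assert any(f.startswith("auto_threshold_empty_parent") for f in adj.flags)
    assert adj.thresholds["cd91_low"] == tree.auto["cd91_low"].default
    # and the gated sample has no monocytes at all
    pops = ic.apply_gate_tree(s.events, adj)
    for m in MONOCYTE_SUBSETS:
        assert pops.count(m) == 0


# --- application ------------------------------------------------------------

def test_monocyte_recall_against_generator_truth(healthy_sample, healthy_pops):
    truth_mono = set(np.flatnonzero(np.isin(healthy_sample.truth, MONOCYTE_SUBSETS)))
    gated = set(healthy_pops["MONOCYTES_TOTAL"])
    recall = len(gated & truth_mono) / len(truth_mono)
    assert recall >= 0.90


@pytest.mark.parametrize("condition,seed", [("HEALTHY", 1), ("H24", 5), ("BSI", 11)])
def test_per_population_recall_and_precision(calib, tree, condition, seed):
    s = ic.sample_subject(condition, calib, seed=seed)
    adj = ic.auto_adjust_gates(s.events, tree)
    pops = ic.apply_gate_tree(s.events, adj)
    for pop in (*MONOCYTE_SUBSETS, "MDC", "PDC", "NEUTROPHILS"):
        truth = set(np.flatnonzero(s.truth == pop))
        gated = set(pops[pop])
        if len(truth) < 30:  # tiny populations judged only on count scale
            continue
        assert len(gated & truth) / len(truth) >= 0.95, pop
        assert len(gated & truth) / max(1, len(gated)) >= 0.95, pop


def test_partition_properties(healthy_pops):
    sets = [set(healthy_pops[m]) for m in MONOCYTE_SUBSETS]
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            assert not sets[i] & sets[j]
    union = set().union(*sets)
    total = set(healthy_pops["MONOCYTES_TOTAL"])
    assert union <= total
    cd14pos = set(healthy_pops["CD14POS_CD91POS"])
    for m in ("M1", "M2", "M3", "M4", "M5"):
        assert set(healthy_pops[m]) <= cd14pos
    assert cd14pos <= total
    assert not set(healthy_pops["MDC"]) & set(healthy_pops["PDC"])
    n = healthy_pops.n_events
    for idx in healthy_pops.populations.values():
        assert (idx < n).all()


def test_gating_is_idempotent(healthy_sample, tree):
    adj = ic.auto_adjust_gates(healthy_sample.events, tree)
    a = ic.apply_gate_tree(healthy_sample.events, adj)
    b = ic.apply_gate_tree(healthy_sample.events, adj)
    for name in a.populations:
        np.testing.assert_array_equal(a[name], b[name])


def test_raising_cd16_threshold_never_grows_cd16pos_subsets(healthy_sample, tree):
    base = ic.apply_gate_tree(healthy_sample.events, tree)
    raised = ic.build_default_gate_tree(thresholds={"cd16_pos": 3.9})
    higher = ic.apply_gate_tree(healthy_sample.events, raised)
    for pop in ("M3", "M5"):
        assert higher.count(pop) <= base.count(pop)


def test_exclusion_gate_removes_lymphoid_from_monocyte_subsets(calib, tree):
    s = ic.sample_subject("HEALTHY", calib, seed=2)
    pops = ic.apply_gate_tree(s.events, ic.auto_adjust_gates(s.events, tree))
    filler = set(np.flatnonzero(s.truth == "FILLER"))
    for m in MONOCYTE_SUBSETS:
        overlap = len(set(pops[m]) & filler)
        assert overlap <= 0.01 * max(1, len(pops[m]))


def test_tree_yaml_roundtrip(tree, tmp_path, healthy_sample):
    from idarcyto.gating import tree_from_yaml, tree_to_yaml
    p = tmp_path / "gates.yaml"
    tree_to_yaml(tree, p)
    loaded = tree_from_yaml(p)
    a = ic.apply_gate_tree(healthy_sample.events, tree)
    b = ic.apply_gate_tree(healthy_sample.events, loaded)
    for name in a.populations:
        np.testing.assert_array_equal(a[name], b[name])
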