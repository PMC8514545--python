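"""Generator contracts: acquisition rule, calibration anchors, determinism."""

import numpy as np
import pandas as pd
import pytest

import idarcyto as ic
from idarcyto.calibration import population_concentrations, total_wbc
from idarcyto.panel import FLUORO_CHANNELS, MONOCYTE_SUBSETS
from idarcyto.synth import DegenerateSampleWarning


def test_healthy_sample_records_exactly_6000_monocytes(calib):
    s = ic.sample_subject("HEALTHY", calib, seed=1)
    n_mono = int(np.isin(s.truth, MONOCYTE_SUBSETS).sum())
    assert n_mono == 6000
    # the last recorded event is the 6000th monocyte
    assert s.truth[-1] in MONOCYTE_SUBSETS


def test_calibration_fold_change_anchors(calib):
    """Config-level expectations: the prose-stated count and MFI folds."""
    ab = calib.abundance
    wbc = calib.wbc_mu
    conc = lambda cond, pop: ab[cond][pop] * wbc[cond]
    assert conc("H24", "M7") / conc("HEALTHY", "M7") == pytest.approx(20.0)
    assert conc("BSI", "M7") / conc("HEALTHY", "M7") > 10.0
    assert conc("BSI", "M5") / conc("HEALTHY", "M5") == pytest.approx(7.0)
    assert conc("H24", "M2") / conc("HEALTHY", "M2") == pytest.approx(6.0)
    assert conc("H48", "M3") / conc("HEALTHY", "M3") == pytest.approx(10.0)
    assert conc("BSI", "MDC") / conc("HEALTHY", "MDC") == pytest.approx(0.25)
    assert conc("BSI", "PDC") / conc("HEALTHY", "PDC") == pytest.approx(0.25)
    mu = calib.marker_mu
    assert mu["BSI"]["NEUTROPHILS"]["CD64"] / mu["HEALTHY"]["NEUTROPHILS"]["CD64"] == pytest.approx(3.0)
    assert mu["BSI"]["M6"]["CD64"] / mu["HEALTHY"]["M6"]["CD64"] == pytest.approx(6.0)
    assert mu["H48"]["M7"]["HLADR"] < mu["HEALTHY"]["M7"]["HLADR"]
    assert mu["BSI"]["M7"]["HLADR"] < mu["HEALTHY"]["M7"]["HLADR"]


def test_calibration_matches_healthy_monocyte_concentration(calib):
    total_mono = sum(
        calib.abundance["HEALTHY"][p] for p in MONOCYTE_SUBSETS
    ) * calib.wbc_mu["HEALTHY"]
    assert total_mono == pytest.approx(561.0)
    # and every condition's monocyte total matches its anchor
    for cond, expected in [("H2", 682), ("H24", 1071), ("H48", 1173), ("BSI", 1040)]:
        got = sum(calib.abundance[cond][p] for p in MONOCYTE_SUBSETS) * calib.wbc_mu[cond]
        assert got == pytest.approx(expected)


def test_monocyte_concentration_monte_carlo_recovery(calib):
    """Truth-label monocyte fraction x WBC averages to ~561 cells/ul."""
    vals = []
    for seed in range(30):
        s = ic.sample_subject("HEALTHY", calib, seed=seed)
        frac = np.isin(s.truth, MONOCYTE_SUBSETS).mean()
        vals.append(frac * s.wbc)
    vals = np.asarray(vals)
    se = vals.std(ddof=1) / np.sqrt(len(vals))
    assert abs(vals.mean() - 561.0) < 3 * se + 1e-9


def test_identity_spillover_records_true_intensities(calib, healthy_sample):
    rec = healthy_sample.events[list(FLUORO_CHANNELS)].to_numpy()
    true = healthy_sample.true_fluorescence.to_numpy()
    assert np.array_equal(rec, true)


def test_spillover_roundtrip_recovers_truth(calib):
    import dataclasses
    cfg = dataclasses.replace(calib, spillover=ic.example_spillover())
    s = ic.sample_subject("BSI", cfg, seed=4)
    comp = ic.apply_compensation(s.events, cfg.spillover)
    np.testing.assert_allclose(
        comp[list(FLUORO_CHANNELS)].to_numpy(),
        s.true_fluorescence.to_numpy(),
        rtol=1e-8, atol=1e-8,
    )


def test_recorded_intensities_nonnegative(calib):
    import dataclasses
    cfg = dataclasses.replace(calib, spillover=ic.example_spillover())
    s = ic.sample_subject("H48", cfg, seed=2)
    assert (s.events.to_numpy() >= 0).all()


def test_unknown_condition_raises(calib):
    with pytest.raises(ValueError, match="unknown condition"):
        ic.sample_subject("MALARIA", calib, seed=0)


def test_unreachable_acquisition_target_flags_not_raises(calib):
    import dataclasses
    cfg = dataclasses.replace(calib, max_events=5000)
    with pytest.warns(DegenerateSampleWarning):
        s = ic.sample_subject("HEALTHY", cfg, seed=0)
    assert "acquisition_target_unreached" in s.flags
    assert len(s.events) == 5000


def test_cohort_counts_and_determinism(calib):
    design = ic.CohortDesign(n_subjects={"HEALTHY": 2, "BSI": 2}, seed=9)
    a = ic.generate_cohort(design, calib)
    b = ic.generate_cohort(design, calib)
    assert [s.condition for s in a] == ["HEALTHY", "HEALTHY", "BSI", "BSI"]
    for sa, sb in zip(a, b):
        pd.testing.assert_frame_equal(sa.events, sb.events)
        assert sa.wbc == sb.wbc
        assert np.array_equal(sa.truth, sb.truth)


def test_empty_design_yields_empty_cohort(calib):
    assert ic.generate_cohort(ic.CohortDesign(n_subjects={}), calib) == []


def test_surgery_series_shares_subject_across_times(calib):
    design = ic.CohortDesign(n_subjects={}, surgery_series=2, seed=5)
    cohort = ic.generate_cohort(design, calib)
    assert len(cohort) == 6
    by_subject = {}
    for s in cohort:
        by_subject.setdefault(s.subject_id, []).append((s.condition, s.sampling_time))
    assert len(by_subject) == 2
    for series in by_subject.values():
        assert series == [("H2", 2.0), ("H24", 24.0), ("H48", 48.0)]


def test_calibration_yaml_roundtrip(calib, tmp_path):
    p = tmp_path / "calib.yaml"
    calib.to_yaml(p)
    loaded = ic.GeneratorConfig.from_yaml(p)
    assert loaded.abundance == calib.abundance
    assert loaded.wbc_mu == calib.wbc_mu
    np.testing.assert_array_equal(loaded.spillover, calib.spillover)


def test_invalid_calibration_rejected(calib):
    import dataclasses
    bad = dataclasses.replace(calib, spillover=np.eye(8) * 2)
    with pytest.raises(ValueError, match="diagonal"):
        bad.validate()
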