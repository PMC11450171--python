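"""Ground-truth activity models and replicate count simulation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from starrpairs import (SimulationConfig, TrueActivityModel, combined_activity,
                        emit_reads, enumerate_pairs, make_pool, simulate_counts,
                        simulate_dataset, simulate_pair_activities,
                        simulate_true_activities)
from starrpairs.pool import build_reference
from conftest import random_pool


def test_model_validation():
    with pytest.raises(ValueError, match="regime"):
        TrueActivityModel(regime="quadratic")
    with pytest.raises(ValueError, match="cap"):
        TrueActivityModel(regime="saturating")
    with pytest.raises(ValueError, match="noise_sd"):
        TrueActivityModel(noise_sd=-1)


def test_controls_only_pool_has_zero_activity():
    config = SimulationConfig(n_enhancers=0, n_controls=5, seed=0)
    pool = make_pool(config)
    act = simulate_true_activities(pool, config)
    assert (act == 0.0).all()


def test_point_mass_law():
    config = SimulationConfig(n_enhancers=8, n_controls=2, activity_law=("point", 2.0), seed=0)
    pool = make_pool(config)
    act = simulate_true_activities(pool, config)
    assert (act[pool.enhancer_ids] == 2.0).all()
    assert (act[pool.control_ids] == 0.0).all()


def test_uniform_law_mean_within_clt_band():
    config = SimulationConfig(n_enhancers=10_000, n_controls=0,
                              activity_law=("uniform", 1.0, 3.0), seed=1)
    pool = make_pool(config)
    act = simulate_true_activities(pool, config)
    se = np.sqrt(4 / 12) / np.sqrt(10_000)
    assert abs(act.mean() - 2.0) < 3 * se


@pytest.mark.parametrize("a5,a3,regime,expected", [
    (1.0, 1.0, "multiplicative", 2.0),
    (0.0, 0.0, "additive", 0.0),
    (0.5, 0.0, "additive", 0.5),
    (2.0, 0.0, "additive", 2.0),
    (1.0, 1.0, "additive", np.log2(3)),
])
def test_combined_activity_fixed_regimes(a5, a3, regime, expected):
    model = TrueActivityModel(regime=regime)
    assert combined_activity(a5, a3, model) == pytest.approx(expected, abs=1e-12)


def test_combined_activity_interaction_at_reported_coefficients():
    # two basal partners under the fitted coefficient map sit at the intercept
    model = TrueActivityModel(regime="interaction", beta0=0.11, beta1=1.12,
                              beta2=1.06, beta3=-0.096)
    assert combined_activity(0.0, 0.0, model) == pytest.approx(0.11, abs=1e-12)
    assert combined_activity(1.0, 1.0, model) == pytest.approx(0.11 + 1.12 + 1.06 - 0.096)


def test_saturating_regime_monotone_and_bounded():
    model = TrueActivityModel(regime="saturating", cap=4.0)
    grid = np.linspace(-1, 6, 40)
    for a3 in (0.0, 2.0, 5.0):
        vals = combined_activity(grid, np.full_like(grid, a3), model)
        assert np.all(np.diff(vals) >= -1e-12)
        assert np.all(vals <= 4.0 + 1.0)
    # far below the cap it reduces to multiplicative
    assert combined_activity(-2.0, -2.0, model) == pytest.approx(-4.0, abs=0.01)


def test_interaction_regime_keeps_control_pairs_at_basal():
    """Control-containing pairs combine neutrally so the assay zero is preserved."""
    config = SimulationConfig(n_enhancers=3, n_controls=3, activity_law=("point", 2.0), seed=0)
    model = TrueActivityModel(regime="interaction", beta0=0.1, beta1=1.1, beta2=1.0,
                              beta3=-0.1)
    pool = make_pool(config)
    design = enumerate_pairs(pool)
    act = simulate_true_activities(pool, config)
    pair_act = simulate_pair_activities(design, act, model, pool)
    tab = design.table.set_index("pair_id")
    is_ctrl = tab["id5"].str.startswith("CTL") | tab["id3"].str.startswith("CTL")
    both_ctrl = tab["id5"].str.startswith("CTL") & tab["id3"].str.startswith("CTL")
    assert np.allclose(pair_act[both_ctrl], 0.0)
    enh_ctrl = is_ctrl & ~both_ctrl
    assert np.allclose(pair_act[enh_ctrl], 2.0)  # the enhancer's own activity
    assert np.allclose(pair_act[~is_ctrl], 0.1 + 1.1 * 2 + 1.0 * 2 - 0.1 * 4)


def test_rna_to_input_ratio_tracks_depth_ratio():
    """With all activities zero, mean RNA/input counts match the depth ratio."""
    pool = random_pool(0, 317, length=30, seed=5)  # 317^2 > 1e5 pairs
    design = enumerate_pairs(pool)
    act = pd.Series(0.0, index=design.table["pair_id"])
    config = SimulationConfig(n_enhancers=0, n_controls=317, mean_input_depth=50.0,
                              mean_rna_depth=100.0, abundance_sd=0.0,
                              nb_dispersion=0.1, seed=6)
    counts = simulate_counts(design, act, config)
    mean = counts.groupby("channel")["umi_count"].mean()
    assert mean["rna"] / mean["input"] == pytest.approx(2.0, rel=0.02)


def test_zero_dispersion_is_poisson():
    pool = random_pool(0, 100, length=30, seed=7)
    design = enumerate_pairs(pool)
    act = pd.Series(0.0, index=design.table["pair_id"])
    config = SimulationConfig(n_enhancers=0, n_controls=100, mean_input_depth=50.0,
                              abundance_sd=0.0, nb_dispersion=0.0, seed=8)
    counts = simulate_counts(design, act, config)
    inputs = counts[counts["channel"] == "input"]["umi_count"]
    ratio = inputs.var() / inputs.mean()
    assert ratio == pytest.approx(1.0, abs=0.05)


def test_activity_three_doubles_rna_eightfold():
    """Monte-Carlo moment check: activity 3 at depth ratio 1 -> RNA ~ 8x input."""
    pool = random_pool(100, 0, length=30, seed=9)
    design = enumerate_pairs(pool)  # 10^4 pairs
    act = pd.Series(3.0, index=design.table["pair_id"])
    config = SimulationConfig(n_enhancers=100, n_controls=0, mean_input_depth=50.0,
                              abundance_sd=0.0, nb_dispersion=0.05, seed=10)
    counts = simulate_counts(design, act, config)
    mean = counts.groupby("channel")["umi_count"].mean()
    assert mean["rna"] / mean["input"] == pytest.approx(8.0, rel=0.03)


def test_full_determinism_counts_and_fastq(tmp_path):
    config = SimulationConfig(n_enhancers=5, n_controls=3, candidate_length=40,
                              spacer_length=30, mean_input_depth=20.0, seed=13)
    model = TrueActivityModel(regime="multiplicative", noise_sd=0.2)
    ds1 = simulate_dataset(config, model)
    ds2 = simulate_dataset(config, model)
    assert ds1.counts.equals(ds2.counts)
    assert (ds1.activities == ds2.activities).all()
    ref = build_reference(ds1.design, ds1.pool)
    p1 = emit_reads(ds1.counts, ref, tmp_path / "a", read_length=30, seed=99)
    p2 = emit_reads(ds2.counts, ref, tmp_path / "b", read_length=30, seed=99)
    for key in p1:
        assert p1[key][0].read_bytes() == p2[key][0].read_bytes()
        assert p1[key][1].read_bytes() == p2[key][1].read_bytes()


def test_emit_reads_duplicate_accounting(tmp_path):
    config = SimulationConfig(n_enhancers=3, n_controls=2, candidate_length=40,
                              spacer_length=30, mean_input_depth=10.0, seed=14)
    model = TrueActivityModel()
    ds = simulate_dataset(config, model)
    ref = build_reference(ds.design, ds.pool)
    paths = emit_reads(ds.counts, ref, tmp_path, read_length=30, duplicates=3, seed=1)
    total_umis = int(ds.counts["umi_count"].sum())
    total_reads = 0
    for r1, _r2 in paths.values():
        total_reads += sum(1 for line in open(r1) if line.startswith("@"))
    assert total_reads == 3 * total_umis


def test_emit_reads_rejects_long_reads(tmp_path):
    config = SimulationConfig(n_enhancers=2, n_controls=2, candidate_length=20,
                              spacer_length=10, mean_input_depth=5.0, seed=15)
    ds = simulate_dataset(config, TrueActivityModel())
    ref = build_reference(ds.design, ds.pool)
    with pytest.raises(ValueError, match="read length"):
        emit_reads(ds.counts, ref, tmp_path, read_length=100, seed=0)


def test_assignment_rate_matches_binomial_oracle(tmp_path):
    """At substitution rate 0.05 and budget 3, the fraction of assigned read
    pairs matches P(Binomial(36, 0.05) <= 3)^2."""
    from starrpairs.quantify import ConstructReference, assign_fastq

    config = SimulationConfig(n_enhancers=10, n_controls=5, candidate_length=60,
                              spacer_length=40, mean_input_depth=60.0, seed=16)
    ds = simulate_dataset(config, TrueActivityModel())
    ref_seqs = build_reference(ds.design, ds.pool)
    paths = emit_reads(ds.counts, ref_seqs, tmp_path, read_length=36,
                       error_rate=0.05, seed=17)
    ref = ConstructReference(ref_seqs, ds.design, read_length=36)
    assigned = total = 0
    for (channel, rep), (r1, r2) in paths.items():
        recs = list(assign_fastq(r1, r2, ref, channel, rep, max_mismatches=3))
        assigned += len(recs)
        total += sum(1 for line in open(r1) if line.startswith("@"))
    expected = stats.binom.cdf(3, 36, 0.05) ** 2
    assert assigned / total == pytest.approx(expected, abs=0.01)


def test_dataset_write_outputs(tmp_path):
    config = SimulationConfig(n_enhancers=3, n_controls=2, candidate_length=30,
                              spacer_length=20, mean_input_depth=10.0, seed=18)
    ds = simulate_dataset(config, TrueActivityModel())
    ds.write(tmp_path)
    for name in ("pool.fa", "pool.tsv", "design.tsv", "counts.tsv",
                 "true_activities.tsv", "provenance.yaml"):
        assert (tmp_path / name).exists()
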