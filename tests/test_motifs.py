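"""PWM scanning with exact-p-value thresholds, enrichment, grids and LASSO."""

import numpy as np
import pandas as pd
import pytest

from starrpairs import (PWM, count_matrix, l1_regression, pair_motif_effect,
                        read_pwm_file, scan_motifs, score_threshold,
                        select_informative_motifs, synthetic_pwm_collection,
                        write_pwm_file)
from starrpairs.motifs import (default_lambda_grid, null_score_distribution,
                               reverse_complement)


def brute_force_exceedance(pwm: PWM, threshold: int) -> float:
    """Exhaustive enumeration over all 4^k windows of the null exceedance."""
    q = pwm.quantized_log_odds()
    k = len(pwm)
    idx = np.indices((4,) * k).reshape(k, -1)
    scores = q[np.arange(k)[:, None], idx].sum(axis=0)
    probs = np.prod(pwm.background[idx], axis=0)
    return float(probs[scores >= threshold].sum())


def test_single_position_pwm_counts_both_strands():
    # P(A)=1 at one position: matches A forward and T on the reverse strand
    pwm = PWM("polyA", np.array([[1.0, 0.0, 0.0, 0.0]]))
    assert scan_motifs("AACGT", pwm, p_cutoff=0.3) == 3


def test_p_cutoff_one_matches_every_window():
    rng = np.random.default_rng(0)
    seq = "".join(rng.choice(list("ACGT"), 40))
    pwm = synthetic_pwm_collection(1, seed=1)[2]
    assert scan_motifs(seq, pwm, p_cutoff=1.0) == 2 * (len(seq) - len(pwm) + 1)


@pytest.mark.parametrize("seed", range(5))
def test_strand_symmetry(seed):
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), 120))
    for pwm in synthetic_pwm_collection(2, seed=seed)[:3]:
        assert scan_motifs(seq, pwm, 1e-3) == scan_motifs(reverse_complement(seq), pwm, 1e-3)


def test_count_monotone_in_p_cutoff():
    rng = np.random.default_rng(3)
    seq = "".join(rng.choice(list("ACGT"), 200))
    pwm = synthetic_pwm_collection(1, seed=3)[2]
    cutoffs = [1.0, 0.3, 0.1, 0.01, 1e-3, 1e-4]
    counts = [scan_motifs(seq, pwm, p) for p in cutoffs]
    assert counts == sorted(counts, reverse=True)


@pytest.mark.parametrize("k", [1, 2, 4, 6, 8])
def test_threshold_null_probability_matches_enumeration(k):
    """DP null exceedance equals brute-force 4^k enumeration to 1e-12."""
    rng = np.random.default_rng(k)
    mat = rng.dirichlet(np.ones(4) * 0.5, size=k)
    bg = rng.dirichlet(np.ones(4) * 5)
    pwm = PWM(f"rand{k}", mat, background=bg)
    thr, exceed = score_threshold(pwm, p_cutoff=5e-4)
    assert abs(exceed - brute_force_exceedance(pwm, thr)) < 1e-12
    # and the whole distribution sums to 1
    _, dist = null_score_distribution(pwm)
    assert abs(dist.sum() - 1.0) < 1e-12


def test_pwm_text_round_trip(tmp_path):
    pwms = synthetic_pwm_collection(3, seed=2)
    path = tmp_path / "pwms.txt"
    write_pwm_file(pwms, path)
    back = read_pwm_file(path)
    assert [p.name for p in back] == [p.name for p in pwms]
    for a, b in zip(pwms, back):
        assert np.allclose(a.matrix, b.matrix, atol=1e-6)


def test_pwm_validation():
    with pytest.raises(ValueError, match="sum to 1"):
        PWM("bad", np.array([[0.5, 0.5, 0.5, 0.5]]))


def _counts_frame(ids, hits):
    return pd.DataFrame({"m": hits}, index=pd.Index(ids, name="candidate_id"))


def test_select_informative_maximal_enrichment_retained():
    n = 50
    counts = _counts_frame([f"g{i}" for i in range(n)], [1] * n)
    ctrl = _counts_frame([f"c{i}" for i in range(n)], [0] * n)
    labels = {f"g{i}": "dev" for i in range(n)}
    assert select_informative_motifs(counts, labels, ctrl) == {"m"}


def test_select_informative_min_total_excludes():
    n = 50
    hits = [1] * 4 + [0] * (n - 4)  # total count 4 < 5, however significant
    counts = _counts_frame([f"g{i}" for i in range(n)], hits)
    ctrl = _counts_frame([f"c{i}" for i in range(n)], [0] * n)
    labels = {f"g{i}": "dev" for i in range(n)}
    assert select_informative_motifs(counts, labels, ctrl, fdr_cutoff=0.5) == set()


def test_select_informative_equal_frequencies_excluded():
    n = 40
    hits = [1] * 20 + [0] * 20
    counts = _counts_frame([f"g{i}" for i in range(n)], hits)
    ctrl = _counts_frame([f"c{i}" for i in range(n)], hits)
    labels = {f"g{i}": "dev" for i in range(n)}
    assert select_informative_motifs(counts, labels, ctrl, fdr_cutoff=0.99) == set()


def _random_grid_inputs(n_pairs=400, seed=0, effect=0.0):
    rng = np.random.default_rng(seed)
    cands = [f"c{i}" for i in range(40)]
    counts = pd.DataFrame({"mA": rng.integers(0, 2, 40), "mB": rng.integers(0, 2, 40)},
                          index=pd.Index(cands, name="candidate_id"))
    id5 = rng.choice(cands, n_pairs)
    id3 = rng.choice(cands, n_pairs)
    act = rng.normal(0, 0.3, n_pairs)
    act += effect * counts.loc[id5, "mA"].to_numpy()
    pairs = pd.DataFrame({"id5": id5, "id3": id3, "log2_activity": act,
                          "residual": rng.normal(0, 0.3, n_pairs)})
    return pairs, counts


def test_grid_effect_zero_when_activity_constant():
    pairs, counts = _random_grid_inputs(seed=1)
    pairs["log2_activity"] = 2.5
    grid = pair_motif_effect(pairs, counts, counts, ["mA", "mB"], min_pairs=5)
    defined = grid["activity_effect"].dropna()
    assert len(defined) > 0
    assert np.allclose(defined, 0.0, atol=1e-12)


def test_grid_recovers_planted_5prime_effect():
    """A motif adding +1 to pair activity shows up as ~+1 in the grid."""
    pairs, counts = _random_grid_inputs(n_pairs=3000, seed=2, effect=1.0)
    grid = pair_motif_effect(pairs, counts, counts, ["mA", "mB"], min_pairs=10)
    row = grid[(grid["motif5"] == "mA") & (grid["motif3"] == "mB")].iloc[0]
    se = 0.3 * np.sqrt(1 / row["n_pairs_with"] + 1 / row["n_pairs_without"])
    assert abs(row["activity_effect"] - 1.0) < 3 * se + 0.05


def test_grid_residual_effects_center_on_zero_for_pure_noise():
    pairs, counts = _random_grid_inputs(n_pairs=3000, seed=3)
    grid = pair_motif_effect(pairs, counts, counts, ["mA", "mB"], min_pairs=10)
    defined = grid.dropna(subset=["residual_effect"])
    se = 0.3 * np.sqrt(1 / defined["n_pairs_with"] + 1 / defined["n_pairs_without"])
    assert (np.abs(defined["residual_effect"]) < 3 * se).mean() >= 0.75


def test_grid_undefined_below_min_pairs():
    pairs, counts = _random_grid_inputs(n_pairs=30, seed=4)
    grid = pair_motif_effect(pairs, counts, counts, ["mA"], min_pairs=10_000)
    assert grid["activity_effect"].isna().all()


def test_lasso_zero_target_gives_zero_coefficients():
    rng = np.random.default_rng(0)
    X = pd.DataFrame(rng.integers(0, 4, (60, 5)).astype(float),
                     columns=[f"f{i}" for i in range(5)])
    with pytest.warns(UserWarning, match="constant target"):
        fit = l1_regression(X, np.zeros(60), seed=0)
    assert (fit.coefficients == 0).all()
    assert fit.cv_r2_mean == 0.0


def test_lasso_full_shrinkage_at_max_lambda():
    rng = np.random.default_rng(1)
    X = pd.DataFrame(rng.normal(size=(80, 6)), columns=[f"f{i}" for i in range(6)])
    y = 0.05 * X["f0"] + rng.normal(0, 1.0, 80)  # weak signal
    fit = l1_regression(X, y, lambda_grid=np.array([100.0]), seed=1)
    assert (fit.coefficients == 0).all()


@pytest.mark.parametrize("seed", range(20))
def test_lasso_recovers_planted_motif_signal(seed):
    """target = 2 x (count of one motif): its coefficient lands near 2 and
    at least 90% of the 50 noise features are exactly zero."""
    rng = np.random.default_rng(seed)
    n, p_noise = 200, 50
    signal = rng.integers(0, 4, n).astype(float)
    noise = rng.integers(0, 3, (n, p_noise)).astype(float)
    X = pd.DataFrame(np.column_stack([signal, noise]),
                     columns=["sig"] + [f"n{i}" for i in range(p_noise)])
    y = 2.0 * signal + rng.normal(0, 0.1, n)
    fit = l1_regression(X, y, seed=seed)
    assert 1.5 <= fit.coefficients["sig"] <= 2.5
    noise_coefs = fit.coefficients.drop("sig")
    assert (noise_coefs == 0.0).mean() >= 0.9


def test_lasso_path_sparsity_monotone_in_lambda():
    rng = np.random.default_rng(7)
    X = pd.DataFrame(rng.normal(size=(100, 12)), columns=[f"f{i}" for i in range(12)])
    y = X @ rng.normal(size=12) + rng.normal(0, 0.5, 100)
    from sklearn.linear_model import Lasso
    Xs = (X - X.mean()) / X.std()
    nnz = []
    for lam in sorted(default_lambda_grid()):
        model = Lasso(alpha=lam, max_iter=50_000).fit(Xs, y)
        nnz.append(int((model.coef_ != 0).sum()))
    assert nnz == sorted(nnz, reverse=True)


def test_count_matrix_shape_and_determinism():
    rng = np.random.default_rng(9)
    seqs = {f"s{i}": "".join(rng.choice(list("ACGT"), 80)) for i in range(5)}
    pwms = synthetic_pwm_collection(2, seed=0)
    m1 = count_matrix(seqs, pwms, p_cutoff=1e-3)
    m2 = count_matrix(seqs, pwms, p_cutoff=1e-3)
    assert m1.shape == (5, 4)
    assert m1.equals(m2)
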