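"""Edge-wise fidelity metrics, FDR-corrected group-difference maps,
preservation false-positive rate and cross-scenario prediction."""

import numpy as np
import pytest

from cgvae import (
    EdgeStatsMap,
    cross_scenario_predict,
    edgewise_correlation,
    groupdiff_ttest,
    preservation_fpr,
    recon_metrics,
)
from cgvae.graphs import upper_tri_values

from oracle_utils import (
    bh_adjust,
    bh_reject,
    brute_pearson,
    brute_welch_t,
    random_symmetric,
)


# -- reconstruction metrics ---------------------------------------------------

def test_identical_matrices_have_zero_error_unit_correlation(rng):
    mats = [random_symmetric(rng, 8) for _ in range(4)]
    m = recon_metrics(mats, [x.copy() for x in mats])
    assert m["frobenius"] == (0.0, 0.0)
    assert m["mse"] == (0.0, 0.0)
    assert m["correlation"][0] == pytest.approx(1.0)


def test_recon_metrics_hand_case():
    a = np.zeros((3, 3))
    b = np.zeros((3, 3))
    b[0, 1] = b[1, 0] = 0.2
    m = recon_metrics([a], [b])
    assert m["frobenius"][0] == pytest.approx(np.sqrt(0.08))
    assert m["mse"][0] == pytest.approx(0.08 / 9)


def test_recon_metrics_anticorrelation(rng):
    a = random_symmetric(rng, 6)
    m = recon_metrics([a], [-a])
    assert m["correlation"][0] == pytest.approx(-1.0)


def test_recon_metrics_validation(rng):
    with pytest.raises(ValueError):
        recon_metrics([np.zeros((3, 3))], [])
    with pytest.raises(ValueError):
        recon_metrics([np.zeros((3, 3))], [np.zeros((4, 4))])


# -- group-difference maps ----------------------------------------------------

def test_ttest_matches_welch_oracle(rng):
    mats = [random_symmetric(rng, 6) for _ in range(20)]
    labels = np.array([0, 1] * 10)
    emap = groupdiff_ttest(mats, labels)
    X = np.stack([upper_tri_values(m) for m in mats])
    for e in range(X.shape[1]):
        want = brute_welch_t(X[labels == 1, e], X[labels == 0, e])
        assert emap.table["stat"].iloc[e] == pytest.approx(want, abs=1e-10)


def test_identical_groups_produce_no_flags(rng):
    base = [random_symmetric(rng, 6) for _ in range(5)]
    mats = base + [m.copy() for m in base]
    labels = np.array([0] * 5 + [1] * 5)
    emap = groupdiff_ttest(mats, labels)
    assert not emap.flags.any()
    assert np.allclose(emap.table["stat"], 0.0)


def test_ttest_input_validation(rng):
    mats = [random_symmetric(rng, 5) for _ in range(4)]
    with pytest.raises(ValueError, match="two groups"):
        groupdiff_ttest(mats, np.zeros(4))
    with pytest.raises(ValueError, match="at least two"):
        groupdiff_ttest(mats, np.array([0, 1, 1, 1]))


def test_strong_planted_difference_is_flagged(rng):
    mats = []
    labels = []
    for i in range(40):
        m = random_symmetric(rng, 8, scale=0.1)
        if i % 2:
            m[0, 1] = m[1, 0] = m[0, 1] + 1.5
        mats.append(m)
        labels.append(i % 2)
    emap = groupdiff_ttest(mats, np.array(labels))
    t = emap.table
    top = t.loc[t["stat"].abs().idxmax()]
    assert (top["node_i"], top["node_j"]) == (0, 1)
    assert bool(top["flag"])
    # display value is signed -log10 p
    assert top["display_value"] == pytest.approx(
        -np.sign(top["stat"]) * np.log10(top["p"]))


def test_bh_adjustment_matches_hand_rule(rng):
    """q-values and flags agree with the step-up procedure applied by
    hand, including the all-rejected textbook case."""
    mats = [random_symmetric(rng, 6) for _ in range(30)]
    labels = (rng.random(30) < 0.5).astype(int)
    emap = groupdiff_ttest(mats, labels, q_threshold=0.2)
    p = emap.table["p"].to_numpy()
    np.testing.assert_allclose(emap.table["q"], bh_adjust(p), atol=1e-12)
    np.testing.assert_array_equal(emap.flags, bh_reject(p, 0.2))


def test_bh_textbook_all_rejected_case():
    p = [0.01, 0.02, 0.03, 0.04]
    assert bh_reject(p, 0.05) == [True] * 4
    q = bh_adjust(p)
    assert all(v <= 0.05 for v in q)
    assert q[0] == pytest.approx(0.04)  # min_j m p_(j)/j = 4*0.04/4


# -- edgewise correlation -----------------------------------------------------

def test_edgewise_correlation_matches_oracle(rng):
    mats = [random_symmetric(rng, 6) for _ in range(25)]
    scores = rng.normal(size=25)
    emap = edgewise_correlation(mats, scores)
    X = np.stack([upper_tri_values(m) for m in mats])
    for e in range(X.shape[1]):
        want = brute_pearson(X[:, e], scores)
        assert emap.table["stat"].iloc[e] == pytest.approx(want, abs=1e-10)


def test_edgewise_correlation_perfect_linear_edge(rng):
    scores = np.linspace(0, 13, 30)
    mats = []
    for s in scores:
        m = random_symmetric(rng, 5, scale=0.1)
        m[0, 1] = m[1, 0] = 0.05 * s
        mats.append(m)
    emap = edgewise_correlation(mats, scores)
    assert emap.table["stat"].iloc[0] == pytest.approx(1.0)
    assert emap.table["p"].iloc[0] < 1e-20
    assert bool(emap.table["flag"].iloc[0])


def test_edgewise_correlation_constant_edge_gives_zero(rng):
    mats = []
    for _ in range(10):
        m = random_symmetric(rng, 4)
        m[0, 1] = m[1, 0] = 0.5
        mats.append(m)
    emap = edgewise_correlation(mats, rng.normal(size=10))
    assert emap.table["stat"].iloc[0] == 0.0


def test_edgewise_correlation_validation(rng):
    mats = [random_symmetric(rng, 4) for _ in range(5)]
    with pytest.raises(ValueError, match="constant"):
        edgewise_correlation(mats, np.ones(5))
    with pytest.raises(ValueError, match="three"):
        edgewise_correlation(mats[:2], np.array([1.0, 2.0]))


def test_null_raw_pvalue_calibration(rng):
    """No group effect: raw p < 0.05 on ~5 percent of independent edges,
    within a 4-sigma binomial band over 20 repetitions."""
    flagged = total = 0
    any_bh_flags = 0
    for rep in range(20):
        r = np.random.default_rng(1000 + rep)
        mats = [random_symmetric(r, 20) for _ in range(60)]
        labels = np.array([0, 1] * 30)
        emap = groupdiff_ttest(mats, labels, q_threshold=0.05)
        p = emap.table["p"].to_numpy()
        flagged += int((p < 0.05).sum())
        total += p.size
        any_bh_flags += int(emap.flags.any())
    frac = flagged / total
    margin = 4 * np.sqrt(0.05 * 0.95 / total)
    assert abs(frac - 0.05) < margin
    # BH at q=0.05 under the global null rejects anything at all in only
    # ~5 percent of repetitions
    assert any_bh_flags <= 4


# -- preservation FPR ---------------------------------------------------------

def _map_from_flags(flags, n_nodes):
    n_edges = n_nodes * (n_nodes - 1) // 2
    iu, ju = np.triu_indices(n_nodes, k=1)
    import pandas as pd
    table = pd.DataFrame({
        "node_i": iu, "node_j": ju,
        "stat": np.zeros(n_edges), "p": np.ones(n_edges),
        "q": np.ones(n_edges), "flag": np.asarray(flags, dtype=bool),
        "display_value": np.zeros(n_edges),
    })
    return EdgeStatsMap(table=table, q_threshold=0.05, statistic="t")


def test_preservation_fpr_identical_maps_is_zero():
    flags = [True, False, True, False, False, False]
    m = _map_from_flags(flags, 4)
    assert preservation_fpr(m, _map_from_flags(flags, 4)) == 0.0


def test_preservation_fpr_hand_case():
    # 10 edges (n=5); real flags 3, recon adds 2 new ones among the 7
    # non-flagged -> 2/7
    real = [True, True, True] + [False] * 7
    recon = [True, False, True, True, True] + [False] * 5
    fpr = preservation_fpr(_map_from_flags(real, 5), _map_from_flags(recon, 5))
    assert fpr == pytest.approx(2 / 7)


def test_preservation_fpr_all_real_flagged_defines_zero():
    m = _map_from_flags([True] * 6, 4)
    assert preservation_fpr(m, _map_from_flags([False] * 6, 4)) == 0.0


def test_preservation_fpr_rejects_mismatched_universe():
    with pytest.raises(ValueError, match="universe"):
        preservation_fpr(_map_from_flags([False] * 6, 4),
                         _map_from_flags([False] * 10, 5))


def test_edge_map_csv_roundtrip(tmp_path, rng):
    mats = [random_symmetric(rng, 53) for _ in range(10)]
    emap = groupdiff_ttest(mats, np.array([0, 1] * 5))
    path = tmp_path / "edges.csv"
    emap.to_csv(path)
    back = EdgeStatsMap.from_csv(path, 0.01, "t")
    np.testing.assert_allclose(back.table["stat"], emap.table["stat"])
    np.testing.assert_array_equal(back.flags, emap.flags)
    assert "label_i" in back.table.columns  # 53-node maps carry labels
    M = emap.to_matrix(53)
    assert np.array_equal(M, M.T)


# -- cross-scenario prediction ------------------------------------------------

def _labelled_matrices(rng, n, signal):
    y = np.array([0, 1] * (n // 2), dtype=float)
    mats = []
    for i in range(n):
        m = random_symmetric(rng, 12, scale=0.2)
        m[0, 1] = m[1, 0] = m[0, 1] + signal * y[i]
        m[2, 3] = m[3, 2] = m[2, 3] - signal * y[i]
        mats.append(m)
    return mats, y


def test_identical_real_and_generated_data_collapse_scenarios(rng):
    """If reconstructions equal the originals, training on real and
    evaluating on generated is the same experiment as te->te."""
    mats, y = _labelled_matrices(rng, 40, signal=1.0)
    reports = cross_scenario_predict(mats, [m.copy() for m in mats], y, "sex",
                                     seed=2)
    assert set(reports) == {"te->te", "te->gen", "gen->te"}
    assert reports["te->te"].metrics == reports["te->gen"].metrics
    assert reports["te->te"].metrics == reports["gen->te"].metrics
    scores = rng.integers(0, 14, 40).astype(float)
    rep_fi = cross_scenario_predict(mats, [m.copy() for m in mats], scores,
                                    "fi", seed=2)
    assert rep_fi["te->te"].metrics == rep_fi["te->gen"].metrics


def test_pure_noise_classification_is_at_chance(rng):
    mats, y = _labelled_matrices(rng, 200, signal=0.0)
    noise = [random_symmetric(rng, 12, scale=0.2) for _ in range(200)]
    reports = cross_scenario_predict(mats, noise, y, "sex", seed=5)
    assert 0.4 <= reports["te->te"].metrics["accuracy"] <= 0.6


def test_strong_signal_is_learned_out_of_sample(rng):
    mats, y = _labelled_matrices(rng, 60, signal=1.2)
    reports = cross_scenario_predict(mats, [m.copy() for m in mats], y, "sex",
                                     seed=3)
    assert reports["te->te"].metrics["accuracy"] >= 0.9
    assert reports["te->te"].metrics["roc_auc"] >= 0.9


def test_regression_scenario_metrics(rng):
    scores = np.linspace(0, 13, 50)
    mats = []
    for s in scores:
        m = random_symmetric(rng, 12, scale=0.1)
        m[0, 1] = m[1, 0] = 0.06 * s
        mats.append(m)
    reports = cross_scenario_predict(mats, [m.copy() for m in mats], scores,
                                     "fi", seed=4)
    m = reports["te->te"].metrics
    assert set(m) == {"mse", "r2", "pearson_r"}
    assert m["pearson_r"] > 0.8 and m["r2"] > 0.3


def test_cross_scenario_validation(rng):
    mats, y = _labelled_matrices(rng, 10, signal=0.0)
    with pytest.raises(ValueError, match="task"):
        cross_scenario_predict(mats, mats, y, "age")
    with pytest.raises(ValueError, match="paired"):
        cross_scenario_predict(mats, mats[:5], y, "sex")
    with pytest.raises(ValueError, match="class"):
        cross_scenario_predict(mats, mats, np.zeros(10), "sex")


def test_planted_sex_edges_recovered_from_real_data(study_cohort):
    """End of the statistical chain on the generator itself: the
    flagged edge set recovers the planted mask with high recall and
    modest spill-over."""
    records, sex_mask, _ = study_cohort
    labels = np.array([r.sex for r in records])
    emap = groupdiff_ttest([r.sfnc for r in records], labels)
    ind = sex_mask.indicator(53)
    flags = emap.flags
    recall = (flags & ind).sum() / ind.sum()
    assert recall >= 0.9
    # The per-edge effect factors also perturb endpoint variances, so
    # genuine secondary differences appear off-mask at this sample
    # size; the planted edges still dominate on average.
    t = np.abs(emap.table["stat"].to_numpy())
    assert t[ind].mean() > 5 * t[~ind].mean()


def test_planted_fi_edges_recovered_from_real_data(study_cohort):
    records, _, fi_mask = study_cohort
    scores = np.array([r.fi_score for r in records])
    emap = edgewise_correlation([r.sfnc for r in records], scores)
    ind = fi_mask.indicator(53)
    recall = (emap.flags & ind).sum() / ind.sum()
    assert recall >= 0.8
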