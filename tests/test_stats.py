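import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

import kneedeg as kd


@pytest.mark.parametrize(
    "pos,neg,expected",
    [
        ([3, 4], [1, 2], 1.0),
        ([1, 1, 1], [1, 1], 0.5),
        ([2, 3], [1, 2], 0.875),
    ],
)
def test_auc_pairwise_construction(pos, neg, expected):
    assert kd.auc_mann_whitney(pos, neg).auc == pytest.approx(expected)


def test_auc_matches_trapezoidal_roc():
    """Midrank Mann-Whitney AUC equals trapezoidal ROC integration."""
    rng = np.random.default_rng(12)
    for _ in range(200):
        n_pos = rng.integers(3, 40)
        n_neg = rng.integers(3, 40)
        pos = np.round(rng.normal(0.5, 1.0, n_pos), 1)  # rounding forces ties
        neg = np.round(rng.normal(0.0, 1.0, n_neg), 1)
        labels = np.r_[np.ones(n_pos), np.zeros(n_neg)]
        expected = roc_auc_score(labels, np.r_[pos, neg])
        assert abs(kd.auc_mann_whitney(pos, neg).auc - expected) < 1e-12


def test_auc_rejects_empty_group():
    with pytest.raises(ValueError):
        kd.auc_mann_whitney([], [1.0])


def test_delong_null_case():
    rng = np.random.default_rng(3)
    res = kd.delong_test(rng.normal(size=40), rng.normal(size=40))
    assert 0.35 < res.auc < 0.65
    assert res.p_value > 0.05


def test_delong_label_swap_symmetry():
    rng = np.random.default_rng(5)
    pos = rng.normal(1.0, 1.0, 25)
    neg = rng.normal(0.0, 1.0, 30)
    a = kd.delong_test(pos, neg)
    b = kd.delong_test(neg, pos)
    assert a.auc == pytest.approx(1.0 - b.auc)
    assert a.p_value == pytest.approx(b.p_value, rel=1e-9)


def test_delong_variance_against_bootstrap():
    """Placement-value variance tracks a 10,000-rep bootstrap on a fixed
    seeded 20+20 sample."""
    rng = np.random.default_rng(17)
    pos = rng.normal(0.8, 1.0, 20)
    neg = rng.normal(0.0, 1.0, 20)
    res = kd.delong_test(pos, neg)
    boot_rng = np.random.default_rng(99)
    idx_p = boot_rng.integers(0, 20, size=(10_000, 20))
    idx_n = boot_rng.integers(0, 20, size=(10_000, 20))
    bp = pos[idx_p][:, :, None]
    bn = neg[idx_n][:, None, :]
    aucs = ((bp > bn) + 0.5 * (bp == bn)).mean(axis=(1, 2))
    assert res.variance == pytest.approx(aucs.var(), rel=0.15)


def test_delong_null_p_uniform():
    """Under the null the DeLong p-value is approximately uniform."""
    rng = np.random.default_rng(7)
    pvals = []
    for _ in range(500):
        pvals.append(
            kd.delong_test(rng.normal(size=30), rng.normal(size=30)).p_value
        )
    ks = sps.kstest(pvals, "uniform").statistic
    assert ks < 0.1


def test_delong_degenerate_separation_warns():
    with pytest.warns(UserWarning):
        res = kd.delong_test([3.0, 4.0, 5.0], [0.0, 1.0, 2.0])
    assert res.degenerate
    assert res.p_value == 0.0


def test_delong_paired_null():
    rng = np.random.default_rng(8)
    labels = np.r_[np.ones(30), np.zeros(30)].astype(bool)
    base = rng.normal(size=60) + labels
    out = kd.delong_paired_test(base, base + rng.normal(0, 1e-3, 60), labels)
    assert out["p_value"] > 0.05


def _results_table(rng, n_knees=30, shift=0.0, variants=("a", "b", "c")):
    rows = []
    groups = np.repeat(["KL01", "KL2", "KL34"], n_knees // 3 + 1)[:n_knees]
    for i in range(n_knees):
        for v in variants:
            lat = rng.normal(1.0, 0.3)
            rows.append(
                {
                    "knee_id": f"K{i}",
                    "kl_group": groups[i],
                    "variant": v,
                    "compartment": "lateral",
                    "fraction": lat,
                }
            )
            rows.append(
                {
                    "knee_id": f"K{i}",
                    "kl_group": groups[i],
                    "variant": v,
                    "compartment": "medial",
                    "fraction": lat + shift + rng.normal(0, 0.05),
                }
            )
    return pd.DataFrame(rows)


def test_battery_reports_all_tests_with_bonferroni():
    rng = np.random.default_rng(0)
    out = kd.nonparametric_battery(_results_table(rng))
    names = [c.test for c in out]
    assert names.count("friedman") == 1
    assert names.count("wilcoxon_signed_rank") == 1
    assert names.count("kruskal_wallis") == 3
    kw = [c for c in out if c.test == "kruskal_wallis"]
    assert all(c.bonferroni_adjusted_alpha == pytest.approx(0.05 / 3) for c in kw)


def test_battery_detects_planted_medial_shift():
    rng = np.random.default_rng(1)
    out = kd.nonparametric_battery(_results_table(rng, shift=1.0))
    wil = next(c for c in out if c.test == "wilcoxon_signed_rank")
    assert wil.p_value < 0.01
    assert wil.significant


def test_battery_null_calibration():
    """Kruskal-Wallis on groups from one distribution rarely rejects."""
    rejections = 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        out = kd.nonparametric_battery(_results_table(rng, n_knees=24))
        kw = [c for c in out if c.test == "kruskal_wallis"]
        rejections += any(c.p_value < 0.05 for c in kw)
    assert rejections <= 25  # three tests per replicate; >=90% clean per test


def test_battery_rejects_pairing_mismatch():
    rng = np.random.default_rng(2)
    tbl = _results_table(rng)
    with pytest.raises(ValueError):
        kd.nonparametric_battery(tbl.iloc[:-1])


def test_jsn_regression_perfect_linear():
    n = 50
    frac = np.linspace(0.01, 0.5, n)
    deg = pd.DataFrame(
        {
            "knee_id": [f"K{i}" for i in range(n)],
            "fraction_medial": frac,
            "fraction_lateral": frac / 2,
            "fraction_overall": frac,
        }
    )
    jsn = pd.DataFrame(
        {
            "knee_id": [f"K{i}" for i in range(n)],
            "jsn_medial": 10 + 40 * frac,
            "jsn_lateral": 5 + 20 * frac,
        }
    )
    r2, crosstab = kd.verify_jsn_vs_degeneration(jsn, deg)
    assert r2 > 0.99
    assert crosstab.loc["medial", "medial"] == n


def test_jsn_regression_null():
    rng = np.random.default_rng(4)
    n = 500
    deg = pd.DataFrame(
        {
            "knee_id": [f"K{i}" for i in range(n)],
            "fraction_medial": rng.uniform(0, 0.5, n),
            "fraction_lateral": rng.uniform(0, 0.5, n),
            "fraction_overall": rng.uniform(0, 0.5, n),
        }
    )
    jsn = pd.DataFrame(
        {
            "knee_id": [f"K{i}" for i in range(n)],
            "jsn_medial": rng.normal(10, 5, n),
            "jsn_lateral": rng.normal(10, 5, n),
        }
    )
    r2, _ = kd.verify_jsn_vs_degeneration(jsn, deg)
    assert abs(r2) < 0.05


def test_jsn_regression_needs_three_knees():
    small = pd.DataFrame(
        {
            "knee_id": ["K0", "K1"],
            "fraction_medial": [0.1, 0.2],
            "fraction_lateral": [0.1, 0.1],
            "fraction_overall": [0.1, 0.15],
            "jsn_medial": [5.0, 6.0],
            "jsn_lateral": [4.0, 5.0],
        }
    )
    with pytest.raises(ValueError):
        kd.verify_jsn_vs_degeneration(
            small[["knee_id", "jsn_medial", "jsn_lateral"]],
            small[["knee_id", "fraction_medial", "fraction_lateral", "fraction_overall"]],
        )
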