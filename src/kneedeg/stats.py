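"""Statistical layer: nonparametric battery, ROC/AUC with DeLong inference,
and regression / cross-tabulation verification against joint-space narrowing.

The AUC of a scalar score (a simulated degenerated-volume fraction) equals
the Mann-Whitney statistic with midrank tie handling; a single-predictor
logistic model yields the identical ROC by monotonicity, so the scalar-score
route is used throughout.  DeLong's placement-value (structural-component)
variance estimator is implemented natively; standard nonparametric tests are
delegated to scipy and the OLS fit to statsmodels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps


@dataclass(frozen=True)
class ROCResult:
    auc: float
    variance: float | None
    p_value: float | None
    n_pos: int
    n_neg: int
    comparison_label: str = ""
    degenerate: bool = False


@dataclass(frozen=True)
class GroupComparison:
    test: str
    statistic: float
    p_value: float
    bonferroni_adjusted_alpha: float
    significant: bool
    label: str = ""


def _placements(scores_pos, scores_neg):
    """DeLong placement values: P(pos > neg) per observation, midrank ties."""
    x = np.asarray(scores_pos, dtype=float)
    y = np.asarray(scores_neg, dtype=float)
    cmp = (x[:, None] > y[None, :]).astype(float) + 0.5 * (x[:, None] == y[None, :])
    return cmp.mean(axis=1), cmp.mean(axis=0)


def auc_mann_whitney(scores_pos, scores_neg, label: str = "") -> ROCResult:
    """AUC as the pairwise Mann-Whitney probability (half credit for ties)."""
    x = np.asarray(scores_pos, dtype=float)
    y = np.asarray(scores_neg, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both score groups must be non-empty")
    v10, _ = _placements(x, y)
    return ROCResult(
        auc=float(v10.mean()),
        variance=None,
        p_value=None,
        n_pos=len(x),
        n_neg=len(y),
        comparison_label=label,
    )


def delong_test(
    scores_pos, scores_neg, null_auc: float = 0.5, label: str = ""
) -> ROCResult:
    """AUC with DeLong variance and a two-sided test against ``null_auc``."""
    x = np.asarray(scores_pos, dtype=float)
    y = np.asarray(scores_neg, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("DeLong inference needs at least 2 scores per group")
    v10, v01 = _placements(x, y)
    auc = float(v10.mean())
    var = v10.var(ddof=1) / len(x) + v01.var(ddof=1) / len(y)
    if var <= 0:
        warnings.warn(
            "zero DeLong variance (perfect separation); p reported as limit",
            stacklevel=2,
        )
        p = 0.0 if abs(auc - null_auc) > 0 else 1.0
        return ROCResult(auc, 0.0, p, len(x), len(y), label, degenerate=True)
    z = (auc - null_auc) / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return ROCResult(auc, float(var), float(p), len(x), len(y), label)


def delong_paired_test(
    scores_a, scores_b, labels, label: str = ""
) -> dict:
    """DeLong comparison of two correlated AUCs measured on the same knees.

    ``labels`` is a boolean/0-1 array marking the positive class.  Returns
    the two AUCs, the variance of their difference, and a two-sided p-value.
    """
    labels = np.asarray(labels).astype(bool)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != labels.shape or b.shape != labels.shape:
        raise ValueError("scores and labels must align")
    v10 = np.empty((2, labels.sum()))
    v01 = np.empty((2, (~labels).sum()))
    aucs = np.empty(2)
    for i, s in enumerate((a, b)):
        v10[i], v01[i] = _placements(s[labels], s[~labels])
        aucs[i] = v10[i].mean()
    m, n = v10.shape[1], v01.shape[1]
    s10 = np.cov(v10)  # 2x2
    s01 = np.cov(v01)
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_diff <= 0:
        return {"auc_a": aucs[0], "auc_b": aucs[1], "variance": 0.0, "p_value": 1.0}
    z = (aucs[0] - aucs[1]) / np.sqrt(var_diff)
    return {
        "auc_a": float(aucs[0]),
        "auc_b": float(aucs[1]),
        "variance": float(var_diff),
        "p_value": float(2.0 * sps.norm.sf(abs(z))),
    }


def nonparametric_battery(
    data: pd.DataFrame,
    value: str = "fraction",
    alpha: float = 0.05,
) -> list[GroupComparison]:
    """The study's nonparametric test battery on a long-format results table.

    Expects columns ``knee_id``, ``kl_group``, ``compartment`` ('medial' |
    'lateral') and ``variant`` plus the value column.  Runs:

    * Friedman across model variants (repeated measures per knee, medial and
      lateral summed into a knee value);
    * Wilcoxon signed-rank medial vs lateral (paired within knee x variant);
    * Kruskal-Wallis across KL groups, one test per variant (this family is
      Bonferroni-corrected).
    """
    required = {"knee_id", "kl_group", "compartment", "variant", value}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"results table missing columns: {sorted(missing)}")
    out: list[GroupComparison] = []

    knee_value = (
        data.groupby(["knee_id", "variant"])[value].mean().reset_index()
    )
    wide = knee_value.pivot(index="knee_id", columns="variant", values=value)
    if wide.isna().any().any():
        raise ValueError("pairing mismatch: not every knee has every variant")
    if wide.shape[1] >= 3:
        stat, p = sps.friedmanchisquare(*[wide[c] for c in wide.columns])
        out.append(
            GroupComparison(
                "friedman", float(stat), float(p), alpha, p < alpha,
                label="across variants",
            )
        )

    paired = data.pivot_table(
        index=["knee_id", "variant"], columns="compartment", values=value
    )
    if paired[["medial", "lateral"]].isna().any().any():
        raise ValueError("pairing mismatch: missing compartment values")
    diff = paired["medial"] - paired["lateral"]
    if np.allclose(diff, 0):
        out.append(
            GroupComparison("wilcoxon_signed_rank", 0.0, 1.0, alpha, False,
                            label="medial vs lateral")
        )
    else:
        stat, p = sps.wilcoxon(paired["medial"], paired["lateral"])
        out.append(
            GroupComparison(
                "wilcoxon_signed_rank", float(stat), float(p), alpha, p < alpha,
                label="medial vs lateral",
            )
        )

    groups_tbl = data[["knee_id", "kl_group"]].drop_duplicates().set_index("knee_id")
    variants = sorted(data["variant"].unique())
    adj = alpha / len(variants)
    for variant in variants:
        sub = knee_value[knee_value["variant"] == variant].set_index("knee_id")
        sub = sub.join(groups_tbl)
        samples = [g[value].to_numpy() for _, g in sub.groupby("kl_group")]
        if len(samples) < 2:
            continue
        stat, p = sps.kruskal(*samples)
        out.append(
            GroupComparison(
                "kruskal_wallis", float(stat), float(p), adj, p < adj,
                label=f"KL groups | {variant}",
            )
        )
    return out


def verify_jsn_vs_degeneration(
    jsn_table: pd.DataFrame, degeneration_table: pd.DataFrame
) -> tuple[float, pd.DataFrame]:
    """Adjusted R^2 of max-knee JSN on overall degenerated fraction, plus the
    2x2 cross-tab of (compartment with larger simulated degeneration) x
    (compartment with larger JSN).

    ``jsn_table`` needs columns knee_id, jsn_medial, jsn_lateral;
    ``degeneration_table`` needs knee_id, fraction_medial, fraction_lateral,
    fraction_overall.
    """
    merged = jsn_table.merge(degeneration_table, on="knee_id")
    if len(merged) < 3:
        raise ValueError("need at least 3 matched knees")
    y = merged[["jsn_medial", "jsn_lateral"]].max(axis=1)
    x = sm.add_constant(merged["fraction_overall"])
    fit = sm.OLS(y, x).fit()
    crosstab = pd.crosstab(
        np.where(
            merged["fraction_medial"] >= merged["fraction_lateral"],
            "medial", "lateral",
        ),
        np.where(merged["jsn_medial"] >= merged["jsn_lateral"], "medial", "lateral"),
        rownames=["larger_degeneration"],
        colnames=["larger_jsn"],
    )
    return float(fit.rsquared_adj), crosstab
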