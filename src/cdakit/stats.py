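"""Statistical comparison of tube settings and wedge steps.

Reference-attenuation series (nine limbs per cell) are compared across
settings with one-way repeated-measures ANOVA and Holm-Sidak-adjusted
pairwise paired t tests; %color-pixel series are compared across steps
with the Friedman rank test and Dunn's pairwise z tests (Bonferroni family
correction, the common convention when the correction is unnamed).
Normality is screened with Shapiro-Wilk.  No sphericity correction is
applied to the RM-ANOVA (documented limitation).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .calibration import CalibrationSummary, coverage_interval
from .phantom import ExposureSetting

__all__ = [
    "TestResult",
    "shapiro_wilk",
    "holm_sidak",
    "rm_anova_holm_sidak",
    "friedman_statistic",
    "friedman_dunn",
    "summarize_settings",
    "recommend_setting",
    "plot_setting_summary",
]


@dataclass
class TestResult:
    method: str
    statistic: float
    p: float
    posthoc: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or math.isnan(self.p)):
            raise ValueError(f"p-value out of [0, 1]: {self.p}")


def _as_matrix(matrix) -> np.ndarray:
    arr = np.asarray(matrix, dtype=float)
    if isinstance(matrix, pd.DataFrame):
        arr = matrix.to_numpy(dtype=float)
    if arr.ndim != 2:
        raise ValueError("replicate matrix must be 2-D (subjects x conditions)")
    if np.isnan(arr).any():
        raise ValueError("replicate matrix has missing cells")
    return arr


def shapiro_wilk(series) -> TestResult:
    """Shapiro-Wilk normality test (3 <= n <= 50)."""
    x = np.asarray(series, dtype=float)
    if not 3 <= x.size <= 50:
        raise ValueError(f"Shapiro-Wilk supported for 3 <= n <= 50, got n={x.size}")
    if np.ptp(x) == 0:
        raise ValueError("constant series: normality test is degenerate")
    w, p = sps.shapiro(x)
    return TestResult("shapiro-wilk", float(w), float(p))


def holm_sidak(pvalues) -> np.ndarray:
    """Holm-Sidak step-down adjustment.

    Raw p-values sorted ascending get adjusted as 1 - (1 - p_(i))^(m-i+1),
    with running-maximum enforcement so adjusted values are monotone
    non-decreasing in raw-p order; results return in the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def rm_anova_holm_sidak(matrix, condition_names=None) -> TestResult:
    """One-way repeated-measures ANOVA with Holm-Sidak post hoc.

    The omnibus F compares condition means against the subject-by-condition
    interaction; pairwise comparisons are paired t tests whose p-values are
    Holm-Sidak adjusted.  Identical columns give F = 0, p = 1.
    """
    arr = _as_matrix(matrix)
    n, k = arr.shape
    if k < 2:
        raise ValueError("need at least two conditions")
    if condition_names is None:
        condition_names = (
            list(matrix.columns) if isinstance(matrix, pd.DataFrame) else list(range(k))
        )

    grand = arr.mean()
    cond_means = arr.mean(axis=0)
    subj_means = arr.mean(axis=1)
    ss_cond = n * ((cond_means - grand) ** 2).sum()
    ss_subj = k * ((subj_means - grand) ** 2).sum()
    ss_total = ((arr - grand) ** 2).sum()
    ss_err = ss_total - ss_cond - ss_subj
    df_cond, df_err = k - 1, (k - 1) * (n - 1)
    ms_cond = ss_cond / df_cond
    ms_err = ss_err / df_err if df_err > 0 else 0.0
    if ms_err <= 0:
        f_stat, p = (0.0, 1.0) if ms_cond <= 1e-12 else (float("inf"), 0.0)
    else:
        f_stat = ms_cond / ms_err
        p = float(sps.f.sf(f_stat, df_cond, df_err))

    pairs = list(itertools.combinations(range(k), 2))
    raw = []
    for i, j in pairs:
        diff = arr[:, i] - arr[:, j]
        if np.ptp(diff) == 0:
            raw.append(1.0 if abs(diff[0]) < 1e-12 else 0.0)
        else:
            raw.append(float(sps.ttest_rel(arr[:, i], arr[:, j]).pvalue))
    adj = holm_sidak(raw)
    posthoc = pd.DataFrame(
        {
            "a": [condition_names[i] for i, _ in pairs],
            "b": [condition_names[j] for _, j in pairs],
            "p_raw": raw,
            "p_adj": adj,
        }
    )
    return TestResult("rm-anova + holm-sidak", float(f_stat), float(p), posthoc)


def _mid_ranks(arr: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(sps.rankdata, 1, arr)


def friedman_statistic(matrix) -> float:
    """Friedman chi-square with mid-rank ties:
    chi2_F = 12/(n k (k+1)) * sum_j R_j^2 - 3 n (k+1)."""
    arr = _as_matrix(matrix)
    n, k = arr.shape
    ranks = _mid_ranks(arr)
    rj = ranks.sum(axis=0)
    return float(12.0 / (n * k * (k + 1)) * (rj**2).sum() - 3.0 * n * (k + 1))


def friedman_dunn(
    matrix,
    condition_names=None,
    p_method: str = "auto",
    n_resamples: int = 20000,
    seed: int = 0,
    exact_limit: int = 2_000_000,
) -> TestResult:
    """Friedman test with Dunn's pairwise post hoc (Bonferroni correction).

    ``p_method``: 'asymptotic' uses the chi-square tail with k-1 df;
    'exact' uses the permutation distribution over all (k!)^n within-row
    rank arrangements (Monte-Carlo sampled when enumeration exceeds
    ``exact_limit``); 'auto' picks exact for small designs.
    Dunn's z for conditions i, j is (Rbar_i - Rbar_j)/sqrt(k(k+1)/(6n)).
    """
    arr = _as_matrix(matrix)
    n, k = arr.shape
    if k < 3:
        raise ValueError("Friedman test needs at least three conditions")
    if condition_names is None:
        condition_names = (
            list(matrix.columns) if isinstance(matrix, pd.DataFrame) else list(range(k))
        )
    stat = friedman_statistic(arr)

    n_arrangements = math.factorial(k) ** n
    if p_method == "auto":
        p_method = "exact" if n_arrangements <= exact_limit else "asymptotic"
    if p_method == "asymptotic":
        p = float(sps.chi2.sf(stat, k - 1))
    elif p_method == "exact":
        ranks = _mid_ranks(arr)
        if n_arrangements <= exact_limit:
            perms = np.array(list(itertools.permutations(range(k))))  # (k!, k)
            hits = total = 0
            # row-wise independent permutations of each subject's ranks
            for combo in itertools.product(range(len(perms)), repeat=n):
                rj = np.zeros(k)
                for row, pi in enumerate(combo):
                    rj += ranks[row, perms[pi]]
                s = 12.0 / (n * k * (k + 1)) * (rj**2).sum() - 3.0 * n * (k + 1)
                hits += s >= stat - 1e-9
                total += 1
            p = hits / total
        else:
            rng = np.random.default_rng(seed)
            hits = 0
            for _ in range(n_resamples):
                perm = np.array([row[rng.permutation(k)] for row in ranks])
                rj = perm.sum(axis=0)
                s = 12.0 / (n * k * (k + 1)) * (rj**2).sum() - 3.0 * n * (k + 1)
                hits += s >= stat - 1e-9
            p = (hits + 1) / (n_resamples + 1)
    else:
        raise ValueError(f"unknown p_method {p_method!r}")

    ranks = _mid_ranks(arr)
    rbar = ranks.mean(axis=0)
    se = math.sqrt(k * (k + 1) / (6.0 * n))
    pairs = list(itertools.combinations(range(k), 2))
    m = len(pairs)
    rows = []
    for i, j in pairs:
        z = (rbar[i] - rbar[j]) / se
        p_raw = 2.0 * sps.norm.sf(abs(z))
        rows.append(
            (condition_names[i], condition_names[j], z, p_raw, min(1.0, p_raw * m))
        )
    posthoc = pd.DataFrame(rows, columns=["a", "b", "z", "p_raw", "p_adj"])
    return TestResult("friedman + dunn", stat, float(p), posthoc)


def summarize_settings(
    results_frame: pd.DataFrame, calibration: CalibrationSummary
) -> pd.DataFrame:
    """Per (setting, step) record for the coverage-chart summary.

    ``results_frame`` is the tidy quantification output (one row per
    source/setting/step, columns kv, mas, step, percent, flagged).  Returns
    range_low/range_high (calibration means), mean/sd of percent, n, and
    n_artifact_occurrences out of n sources.
    """
    required = {"kv", "mas", "step", "percent", "flagged"}
    if not required <= set(results_frame.columns):
        raise ValueError(f"results frame needs columns {sorted(required)}")
    rows = []
    for (kv, mas), grp in results_frame.groupby(["kv", "mas"], sort=True):
        try:
            ranges = {
                r.step: r for r in calibration.for_setting(kv, mas).mean_ranges()
            }
        except KeyError:
            raise ValueError(
                f"calibration summary lacks the setting {kv:g} kV; {mas:g} mAs"
            ) from None
        for step, cell in grp.groupby("step"):
            rows.append(
                {
                    "kv": kv,
                    "mas": mas,
                    "step": int(step),
                    "range_low": ranges[int(step)].min_hu,
                    "range_high": ranges[int(step)].max_hu,
                    "mean_percent": float(cell["percent"].mean()),
                    "sd_percent": float(cell["percent"].std(ddof=1))
                    if len(cell) > 1
                    else 0.0,
                    "n": int(len(cell)),
                    "n_artifact_occurrences": int(cell["flagged"].sum()),
                }
            )
    return pd.DataFrame(rows)


def recommend_setting(summary: pd.DataFrame) -> tuple[ExposureSetting, bool]:
    """Select the tube setting covering the lowest HU ranges without
    inducing background artifacts.

    Among settings with zero artifact occurrences, the one with the lowest
    coverage low endpoint wins; ties break toward the wider total coverage.
    If every setting shows artifacts, the least-affected one is returned
    with the warning flag set.
    """
    if summary[["kv", "mas"]].drop_duplicates().shape[0] < 2:
        raise ValueError("need at least two settings to recommend one")
    per_setting = []
    for (kv, mas), grp in summary.groupby(["kv", "mas"]):
        low = grp["range_low"].min()
        high = grp["range_high"].max()
        per_setting.append(
            {
                "kv": kv,
                "mas": mas,
                "low": low,
                "width": high - low,
                "artifacts": int(grp["n_artifact_occurrences"].sum()),
            }
        )
    table = pd.DataFrame(per_setting)
    clean = table[table["artifacts"] == 0]
    warning = clean.empty
    pool = table if warning else clean
    key = (
        ["artifacts", "low", "width"] if warning else ["low", "width"]
    )
    ascending = [True, True, False] if warning else [True, False]
    best = pool.sort_values(key, ascending=ascending, kind="stable").iloc[0]
    return ExposureSetting(float(best["kv"]), float(best["mas"])), bool(warning)


def plot_setting_summary(summary: pd.DataFrame, path, colormap=None) -> None:
    """Coverage chart: per setting, the ten step ranges on the HU axis,
    annotated with mean %color pixels and artifact occurrence counts."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if colormap is None:
        from .decomposition import TABLE1_PALETTE as colormap

    settings = summary[["kv", "mas"]].drop_duplicates().to_numpy()
    fig, ax = plt.subplots(figsize=(1.8 * len(settings) + 2, 6))
    for x, (kv, mas) in enumerate(settings):
        grp = summary[(summary["kv"] == kv) & (summary["mas"] == mas)]
        for _, row in grp.iterrows():
            ax.bar(
                x,
                row["range_high"] - row["range_low"],
                bottom=row["range_low"],
                width=0.6,
                color=colormap.color(int(row["step"])),
                edgecolor="black",
                linewidth=0.3,
            )
            label = f"{row['mean_percent']:.0f}%"
            if row["n_artifact_occurrences"]:
                label += f" ({int(row['n_artifact_occurrences'])})"
            ax.text(
                x + 0.33,
                (row["range_low"] + row["range_high"]) / 2,
                label,
                fontsize=5,
                va="center",
            )
    ax.set_xticks(range(len(settings)))
    ax.set_xticklabels([f"{kv:g} kV\n{mas:g} mAs" for kv, mas in settings])
    ax.set_ylabel("relative density (HU)")
    fig.tight_layout()
    fig.savefig(str(path), dpi=150)
    plt.close(fig)
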