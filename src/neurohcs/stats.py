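"""Per-well aggregation and nonparametric group statistics.

The statistical unit is the well: field-level metrics are averaged per
well first, and only well means enter the tests.  Normality is checked
with Shapiro-Wilk; group effects are assessed with a Kruskal-Wallis
rank-sums omnibus test, and post-hoc comparisons are run only when the
omnibus test is significant (gatekeeping at alpha = 0.05):

* Steel test — many-to-one comparisons against a control group, the
  rank analogue of Dunnett's test.  Each treatment is rank-summed
  jointly with the control; the family-wise adjusted p-value accounts
  for the correlation between comparisons (they share the control) via
  the permutation distribution of the maximum standardized statistic
  (default, exact in the limit of permutations) or a multivariate-
  normal approximation.
* Dunn all-pairs test — pairwise z statistics from joint ranks with tie
  correction, Bonferroni-adjusted, the rank analogue of pairwise
  comparisons with Bonferroni.

Ties get mid-ranks throughout; rank-statistic variances are computed
from the realized rank population, which is exact under ties.  No
normalization across biological replicates and no mixed models are
applied — wells are compared as-is.

Significance tiers mirror the two-star convention: * p < 0.05,
** p < 0.005.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats import rankdata

ALPHA_GATE = 0.05
TIERS = ((0.005, "**"), (0.05, "*"))


def significance_tier(p: float) -> str:
    for thr, mark in TIERS:
        if p < thr:
            return mark
    return "ns"


# ---------------------------------------------------------------------------
# per-well aggregation
# ---------------------------------------------------------------------------

def aggregate_per_well(
    field_metrics: pd.DataFrame,
    metric_columns: list[str] | None = None,
    well_column: str = "well",
) -> pd.DataFrame:
    """Arithmetic mean of each metric per well.

    ``field_metrics`` has one row per (well, field).  Undefined (NaN)
    field values are excluded from the mean, and ``n_used_<metric>``
    reports how many fields contributed.  A well where every field is
    undefined stays NaN and is excluded from testing downstream.
    """
    if well_column not in field_metrics.columns:
        raise ValueError(f"missing {well_column!r} column")
    if metric_columns is None:
        metric_columns = [
            c for c in field_metrics.columns
            if c not in (well_column, "field")
            and pd.api.types.is_numeric_dtype(field_metrics[c])
        ]
    rows = []
    for well, grp in field_metrics.groupby(well_column, sort=True):
        row: dict = {well_column: well, "n_fields": len(grp)}
        for m in metric_columns:
            vals = grp[m].dropna()
            row[m] = vals.mean() if len(vals) else float("nan")
            row[f"n_used_{m}"] = int(len(vals))
            if not len(vals):
                warnings.warn(f"well {well}: all fields undefined for {m}")
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# univariate tests
# ---------------------------------------------------------------------------

def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk W and p; NaN for degenerate (constant) samples."""
    x = np.asarray(values, dtype=np.float64)
    if len(x) < 3:
        raise ValueError("Shapiro-Wilk needs n >= 3")
    if len(x) > 5000:
        raise ValueError("Shapiro-Wilk limited to n <= 5000")
    if np.ptp(x) == 0:
        warnings.warn("constant sample: Shapiro-Wilk undefined")
        return float("nan"), float("nan")
    res = sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(groups: list) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and chi-square p (k-1 df)."""
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 1 for g in groups):
        raise ValueError("every group needs n >= 1")
    if sum(len(g) for g in groups) < 3:
        raise ValueError("need total n >= 3")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


# ---------------------------------------------------------------------------
# Steel many-to-one test
# ---------------------------------------------------------------------------

def _steel_z(pooled: np.ndarray, sizes: np.ndarray, control: int) -> np.ndarray:
    """Standardized pairwise rank-sum statistics vs the control group.

    ``pooled`` may be 1D (one dataset) or 2D (rows = permutations).
    Each treatment is ranked jointly with the control (mid-ranks); the
    treatment rank sum is standardized with the exact finite-population
    moments of the realized ranks, which handles ties exactly.
    """
    pooled = np.atleast_2d(pooled)
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    ctrl = pooled[:, offsets[control]:offsets[control + 1]]
    n0 = sizes[control]
    zs = []
    for g in range(len(sizes)):
        if g == control:
            continue
        trt = pooled[:, offsets[g]:offsets[g + 1]]
        ni = sizes[g]
        m = n0 + ni
        sub = np.concatenate([ctrl, trt], axis=1)
        ranks = rankdata(sub, method="average", axis=1)
        w = ranks[:, n0:].sum(axis=1)
        mean_r = ranks.mean(axis=1)                       # = (m+1)/2 always
        var_pop = ranks.var(axis=1)
        var_w = ni * (m - ni) / (m - 1) * var_pop
        var_w = np.maximum(var_w, 1e-300)
        zs.append((w - ni * mean_r) / np.sqrt(var_w))
    return np.stack(zs, axis=1)                            # (n_perm, k-1)


def steel_test(
    groups: list,
    control_index: int = 0,
    n_permutations: int = 10_000,
    seed: int | np.random.Generator | None = None,
    method: str = "permutation",
) -> list[dict]:
    """Steel many-to-one rank test: each treatment vs the control.

    Returns one dict per treatment with the standardized rank-sum
    statistic ``z`` and the family-wise adjusted p-value over the
    correlated comparisons.  ``method="permutation"`` (default) uses the
    permutation null of the maximum |z| across comparisons;
    ``method="normal"`` uses the multivariate-normal approximation with
    the known comparison correlation sqrt(n_i n_j / ((n_i+n0)(n_j+n0))).
    """
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(groups) < 2:
        raise ValueError("need control plus at least one treatment")
    if not 0 <= control_index < len(groups):
        raise ValueError("invalid control index")
    if len(groups[control_index]) == 0:
        raise ValueError("control group is empty")
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    sizes = np.array([len(g) for g in groups])
    pooled = np.concatenate(groups)
    z_obs = _steel_z(pooled, sizes, control_index)[0]

    treatment_ids = [g for g in range(len(groups)) if g != control_index]
    if method == "normal":
        n0 = sizes[control_index]
        ns = sizes[treatment_ids].astype(float)
        corr = np.sqrt(np.outer(ns, ns)
                       / np.outer(ns + n0, ns + n0))
        np.fill_diagonal(corr, 1.0)
        mvn = sps.multivariate_normal(mean=np.zeros(len(ns)), cov=corr,
                                      allow_singular=True)
        p_adj = []
        for z in z_obs:
            a = abs(z)
            inside = mvn.cdf(np.full(len(ns), a),
                             lower_limit=np.full(len(ns), -a))
            p_adj.append(min(1.0, max(0.0, 1.0 - float(inside))))
    elif method == "permutation":
        rng = seed if isinstance(seed, np.random.Generator) \
            else np.random.default_rng(seed)
        keys = rng.random((n_permutations, len(pooled)))
        perm = pooled[np.argsort(keys, axis=1)]
        z_perm = _steel_z(perm, sizes, control_index)
        max_abs = np.abs(z_perm).max(axis=1)
        p_adj = [
            (1 + int(np.sum(max_abs >= abs(z) - 1e-12))) / (n_permutations + 1)
            for z in z_obs
        ]
    else:
        raise ValueError(f"unknown method {method!r}")

    return [
        {"group": g, "control": control_index, "z": float(z),
         "p_adjusted": float(p), "tier": significance_tier(float(p))}
        for g, z, p in zip(treatment_ids, z_obs, p_adj)
    ]


# ---------------------------------------------------------------------------
# Dunn all-pairs test
# ---------------------------------------------------------------------------

def dunn_all_pairs(groups: list) -> list[dict]:
    """Dunn all-pairs test on joint ranks with Bonferroni adjustment.

    All observations are ranked jointly (mid-ranks); for each pair the z
    statistic compares mean ranks with the tie-corrected variance; the
    two-sided normal p is Bonferroni-multiplied by the number of pairs.
    """
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    sizes = np.array([len(g) for g in groups])
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = rankdata(pooled, method="average")
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    mean_ranks = [ranks[offsets[i]:offsets[i + 1]].mean()
                  for i in range(len(groups))]

    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (n - 1)) if n > 1 else 0.0
    base_var = n * (n + 1) / 12.0 - tie_term

    n_pairs = len(groups) * (len(groups) - 1) // 2
    out = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = np.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            p = 2.0 * sps.norm.sf(abs(z))
            p_adj = min(1.0, p * n_pairs)
            out.append({
                "group_a": i, "group_b": j, "z": float(z),
                "p": float(p), "p_adjusted": float(p_adj),
                "tier": significance_tier(float(p_adj)),
            })
    return out


# ---------------------------------------------------------------------------
# full comparison workflow
# ---------------------------------------------------------------------------

@dataclass
class GroupComparisonResult:
    metric: str
    group_names: list[str]
    shapiro: dict[str, tuple[float, float]]
    kruskal_h: float
    kruskal_p: float
    posthoc_method: str | None
    comparisons: list[dict] = field(default_factory=list)
    gate_alpha: float = ALPHA_GATE

    @property
    def gate_passed(self) -> bool:
        return self.kruskal_p <= self.gate_alpha


def compare_groups(
    well_summary: pd.DataFrame,
    metric: str,
    group_column: str = "treatment",
    control: str | None = None,
    posthoc: str = "steel",
    alpha: float = ALPHA_GATE,
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> GroupComparisonResult:
    """Run the full per-metric testing scheme on well means.

    Shapiro-Wilk per group, Kruskal-Wallis omnibus, and — only when the
    omnibus p <= alpha — the post-hoc procedure: Steel vs the designated
    control, or Dunn all pairs.  ND wells (NaN metric) are dropped with
    a notice before testing.
    """
    df = well_summary[[group_column, metric]].copy()
    n_nd = int(df[metric].isna().sum())
    if n_nd:
        warnings.warn(f"{n_nd} ND well(s) excluded from tests for {metric}")
        df = df.dropna(subset=[metric])
    names = sorted(df[group_column].unique().tolist())
    if posthoc == "steel":
        if control is None:
            raise ValueError("Steel test needs a designated control group")
        if control not in names:
            raise ValueError(f"control group {control!r} absent")
        names = [control] + [g for g in names if g != control]
    groups = [df.loc[df[group_column] == g, metric].to_numpy() for g in names]

    shapiro = {}
    for g, vals in zip(names, groups):
        if len(vals) >= 3 and np.ptp(vals) > 0:
            shapiro[g] = shapiro_wilk(vals)
        else:
            shapiro[g] = (float("nan"), float("nan"))

    h, p = kruskal_wallis(groups)
    res = GroupComparisonResult(
        metric=metric, group_names=names, shapiro=shapiro,
        kruskal_h=h, kruskal_p=p, posthoc_method=None, gate_alpha=alpha,
    )
    if p <= alpha:
        res.posthoc_method = posthoc
        if posthoc == "steel":
            comps = steel_test(groups, control_index=0,
                               n_permutations=n_permutations, seed=seed)
        elif posthoc == "dunn":
            comps = dunn_all_pairs(groups)
        else:
            raise ValueError(f"unknown post-hoc {posthoc!r}")
        for c in comps:
            c["group_a_name"] = names[c.get("group_a", c.get("group", 0))]
            if "group_b" in c:
                c["group_b_name"] = names[c["group_b"]]
            else:
                c["control_name"] = names[c["control"]]
        res.comparisons = comps
    return res


def comparisons_table(results: list[GroupComparisonResult]) -> pd.DataFrame:
    """Long-format results table across metrics (one row per comparison)."""
    rows = []
    for r in results:
        if not r.comparisons:
            rows.append({
                "metric": r.metric, "comparison": "(omnibus only)",
                "statistic": r.kruskal_h, "p": r.kruskal_p,
                "p_adjusted": float("nan"),
                "tier": "ns" if not r.gate_passed else "",
                "kruskal_p": r.kruskal_p, "posthoc": "",
            })
        for c in r.comparisons:
            if "group_b_name" in c:
                comp = f"{c['group_a_name']} vs {c['group_b_name']}"
            else:
                comp = f"{c['group_a_name']} vs {c['control_name']} (control)"
            rows.append({
                "metric": r.metric, "comparison": comp,
                "statistic": c["z"], "p": c.get("p", float("nan")),
                "p_adjusted": c["p_adjusted"], "tier": c["tier"],
                "kruskal_p": r.kruskal_p, "posthoc": r.posthoc_method,
            })
    return pd.DataFrame(rows)
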