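"""Taxon-subsampling reliability experiment.

How many taxa does a phylogenetic-signal analysis need before its answer
stabilizes?  The experiment prunes a source tree to a grid of tip counts
(by default 5, 10, 15, 20 and 30, with 20 independent random prunings per
count), recomputes all six signal statistics on every pruned tree, and then
asks — by one-way ANOVA across tip counts, and by an ANCOVA that adds the
retained genome-size range as a covariate — whether the statistics' values
and their boundary p-values depend on taxon number.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .phylo import Phylogeny, random_subtree
from .signal import abouheif_cmean, blomberg_k, fit_pagel, morans_i
from .tables import align_trait

__all__ = [
    "SubsampleDesign",
    "run_design",
    "anova_values",
    "anova_pvalues",
    "ancova_range",
    "child_seed",
    "STATISTIC_COLUMNS",
]


@dataclass(frozen=True)
class SubsampleDesign:
    """Grid of tip counts and replicates for the pruning experiment."""

    taxa_counts: tuple[int, ...] = (5, 10, 15, 20, 30)
    replicates_per_count: int = 20
    master_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.taxa_counts) == 0:
            raise ValueError("taxa_counts must be non-empty")
        if any(c < 4 for c in self.taxa_counts):
            raise ValueError("every taxa count must be >= 4")
        if self.replicates_per_count < 2:
            raise ValueError("need at least 2 replicates per count")


def child_seed(master_seed: int, taxa_count: int, replicate: int) -> int:
    """Deterministic per-replicate seed, decorrelated from neighbours by a
    splitmix64-style avalanche of (master, count, replicate)."""
    x = (
        (master_seed & 0xFFFFFFFFFFFFFFFF) * 0x9E3779B97F4A7C15
        + taxa_count * 0xBF58476D1CE4E5B9
        + replicate * 0x94D049BB133111EB
    ) & 0xFFFFFFFFFFFFFFFF
    x ^= x >> 30
    x = (x * 0xBF58476D1CE4E5B9) & 0xFFFFFFFFFFFFFFFF
    x ^= x >> 27
    x = (x * 0x94D049BB133111EB) & 0xFFFFFFFFFFFFFFFF
    x ^= x >> 31
    return int(x % (2**31))


#: record column holding each statistic's value, and its p-value column(s)
STATISTIC_COLUMNS: dict[str, dict[str, str]] = {
    "lambda": {"estimate": "lambda_est", "p_zero": "lambda_p_zero", "p_one": "lambda_p_one",
               "p_opposite": "lambda_p_opposite"},
    "kappa": {"estimate": "kappa_est", "p_zero": "kappa_p_zero", "p_one": "kappa_p_one",
              "p_opposite": "kappa_p_opposite"},
    "delta": {"estimate": "delta_est", "p_zero": "delta_p_zero", "p_one": "delta_p_one",
              "p_opposite": "delta_p_opposite"},
    "blomberg_k": {"estimate": "k_est", "p": "k_p"},
    "abouheif_cmean": {"estimate": "cmean_est", "p": "cmean_p"},
    "morans_i": {"estimate": "moran_est", "p": "moran_p"},
}


def _opposite_bound_p(estimate: float, p_zero: float, p_one: float) -> float:
    """Boundary p-value at the bound opposite the point estimate: an
    estimate near 1 is tested against 0 and vice versa (the informative
    direction; the test against the bound the estimate sits on is 1 by
    construction)."""
    return p_zero if estimate >= 0.5 else p_one


def run_design(
    tree: Phylogeny,
    y,
    design: SubsampleDesign,
    n_perm: int = 999,
) -> pd.DataFrame:
    """Run the full pruning experiment; one row per (taxa count, replicate).

    Each replicate prunes the tree to its tip count under a deterministic
    child seed, records the genome-size range among retained taxa, and
    computes all six statistics.  A statistic that fails on a replicate is
    recorded as NaN with the reason in the ``error`` column; the run
    continues.
    """
    if max(design.taxa_counts) > tree.n_tips:
        raise ValueError("taxa count exceeds tree size")
    yv = align_trait(tree, y)
    trait = pd.Series(yv, index=list(tree.tip_labels))
    rows = []
    for count in design.taxa_counts:
        for rep in range(1, design.replicates_per_count + 1):
            seed = child_seed(design.master_seed, count, rep)
            sub = random_subtree(tree, count, seed)
            sub_y = trait.loc[list(sub.tip_labels)]
            row: dict = {
                "taxa_count": count,
                "replicate": rep,
                "seed": seed,
                "trait_range": float(sub_y.max() - sub_y.min()),
                "error": "",
            }
            errors = []
            for which in ("lambda", "kappa", "delta"):
                cols = STATISTIC_COLUMNS[which]
                try:
                    est = fit_pagel(sub, sub_y, which)
                    row[cols["estimate"]] = est.estimate
                    row[cols["p_zero"]] = est.p_vs_zero
                    row[cols["p_one"]] = est.p_vs_one
                    row[cols["p_opposite"]] = _opposite_bound_p(
                        est.estimate, est.p_vs_zero, est.p_vs_one
                    )
                except Exception as exc:
                    for c in cols.values():
                        row[c] = np.nan
                    errors.append(f"{which}: {exc}")
            for which, fn in (
                ("blomberg_k", blomberg_k),
                ("abouheif_cmean", abouheif_cmean),
                ("morans_i", morans_i),
            ):
                cols = STATISTIC_COLUMNS[which]
                try:
                    res = fn(sub, sub_y, n_perm=n_perm, seed=seed)
                    row[cols["estimate"]] = res.observed
                    row[cols["p"]] = res.p_value
                except Exception as exc:
                    for c in cols.values():
                        row[c] = np.nan
                    errors.append(f"{which}: {exc}")
            row["error"] = "; ".join(errors)
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ANOVA / ANCOVA over the replicate table
# ---------------------------------------------------------------------------


def _anova_table(rows: list[dict], **attrs) -> pd.DataFrame:
    out = pd.DataFrame(rows, columns=["term", "df", "sum_sq", "mean_sq", "f_value", "p_value"])
    out.attrs.update(attrs)
    return out


def _oneway_anova(values: np.ndarray, groups: np.ndarray) -> pd.DataFrame:
    """One-way fixed-effects ANOVA of values on a grouping factor."""
    levels = np.unique(groups)
    if len(levels) < 2:
        raise ValueError("need at least 2 group levels")
    for lvl in levels:
        if np.sum(groups == lvl) < 2:
            raise ValueError(f"need at least 2 replicates in group {lvl}")
    grand = values.mean()
    ss_total = float(np.sum((values - grand) ** 2))
    ss_between = 0.0
    ss_within = 0.0
    for lvl in levels:
        g = values[groups == lvl]
        ss_between += len(g) * (g.mean() - grand) ** 2
        ss_within += float(np.sum((g - g.mean()) ** 2))
    df_b = len(levels) - 1
    df_w = len(values) - len(levels)
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    if ss_total == 0:
        return _anova_table(
            [
                {"term": "Taxa", "df": df_b, "sum_sq": 0.0, "mean_sq": 0.0,
                 "f_value": np.nan, "p_value": 1.0},
                {"term": "Residuals", "df": df_w, "sum_sq": 0.0, "mean_sq": 0.0,
                 "f_value": np.nan, "p_value": np.nan},
            ],
            degenerate=True,
        )
    if ms_w == 0:
        f, p, degenerate = np.inf, 0.0, True
    else:
        f = ms_b / ms_w
        p = float(stats.f.sf(f, df_b, df_w))
        degenerate = False
    return _anova_table(
        [
            {"term": "Taxa", "df": df_b, "sum_sq": ss_between, "mean_sq": ms_b,
             "f_value": f, "p_value": p},
            {"term": "Residuals", "df": df_w, "sum_sq": ss_within, "mean_sq": ms_w,
             "f_value": np.nan, "p_value": np.nan},
        ],
        degenerate=degenerate,
    )


def _select_column(records: pd.DataFrame, statistic: str, kind: str) -> pd.Series:
    if statistic not in STATISTIC_COLUMNS:
        raise ValueError(f"unknown statistic {statistic!r}")
    cols = STATISTIC_COLUMNS[statistic]
    if kind not in cols:
        raise ValueError(f"statistic {statistic!r} has no {kind!r} column")
    return records[cols[kind]]


def anova_values(records: pd.DataFrame, statistic: str) -> pd.DataFrame:
    """One-way ANOVA of a statistic's point estimates on taxa count
    (treated as a factor)."""
    col = _select_column(records, statistic, "estimate")
    ok = col.notna()
    return _oneway_anova(col[ok].to_numpy(dtype=float), records.loc[ok, "taxa_count"].to_numpy())


def anova_pvalues(records: pd.DataFrame, statistic: str, which_bound: str = "opposite") -> pd.DataFrame:
    """One-way ANOVA of a statistic's boundary/permutation p-values on taxa
    count.  ``which_bound``: "opposite" (default; the bound opposite each
    replicate's estimate), "zero", "one", or "p" for permutation statistics.
    """
    kind = {"opposite": "p_opposite", "zero": "p_zero", "one": "p_one", "p": "p"}.get(which_bound)
    if kind is None:
        raise ValueError(f"unknown bound {which_bound!r}")
    cols = STATISTIC_COLUMNS[statistic]
    if kind not in cols and "p" in cols:
        kind = "p"  # permutation statistics carry a single p-value
    col = _select_column(records, statistic, kind)
    ok = col.notna()
    return _oneway_anova(col[ok].to_numpy(dtype=float), records.loc[ok, "taxa_count"].to_numpy())


def ancova_range(records: pd.DataFrame, response: str = "lambda_p_opposite") -> pd.DataFrame:
    """Sequential (type-I) ANCOVA of a boundary p-value on taxa count and
    genome-size range, both numeric, plus their interaction.

    Terms enter in the order Taxa, Gsrange, Taxa x Gsrange; each row's sum
    of squares is the drop in residual sum of squares when that term is
    added, so the rows plus the residual sum to the total corrected sum of
    squares.  The table attrs carry the full-model R-squared, F and p.
    """
    ok = records[response].notna()
    y = records.loc[ok, response].to_numpy(dtype=float)
    taxa = records.loc[ok, "taxa_count"].to_numpy(dtype=float)
    rng_ = records.loc[ok, "trait_range"].to_numpy(dtype=float)
    n = len(y)
    if len(np.unique(taxa)) < 2:
        raise ValueError("taxa count is constant; ANCOVA needs variation in taxa number")
    terms = [("Taxa", taxa), ("Gsrange", rng_)]
    interaction_dropped = False
    if np.ptp(rng_) == 0:
        import warnings

        warnings.warn("genome-size range is constant; interaction term dropped")
        interaction_dropped = True
    else:
        terms.append(("Taxa:Gsrange", taxa * rng_))

    def rss_of(cols: list[np.ndarray]) -> float:
        M = np.column_stack([np.ones(n)] + cols)
        beta, *_ = np.linalg.lstsq(M, y, rcond=None)
        r = y - M @ beta
        return float(r @ r)

    ss_total = float(np.sum((y - y.mean()) ** 2))
    rows = []
    prev_rss = ss_total
    cols: list[np.ndarray] = []
    for name, col in terms:
        cols.append(col)
        rss = rss_of(cols)
        rows.append({"term": name, "df": 1, "sum_sq": prev_rss - rss})
        prev_rss = rss
    df_resid = n - 1 - len(terms)
    if df_resid < 1:
        raise ValueError(
            f"ANCOVA needs more records: {n} rows leave {df_resid} residual df"
        )
    ms_resid = prev_rss / df_resid
    for row in rows:
        row["mean_sq"] = row["sum_sq"] / row["df"]
        if ms_resid > 0:
            row["f_value"] = row["mean_sq"] / ms_resid
            row["p_value"] = float(stats.f.sf(row["f_value"], row["df"], df_resid))
        else:
            row["f_value"], row["p_value"] = np.inf, 0.0
    rows.append({"term": "Residuals", "df": df_resid, "sum_sq": prev_rss,
                 "mean_sq": ms_resid, "f_value": np.nan, "p_value": np.nan})
    r2 = 1.0 - prev_rss / ss_total if ss_total > 0 else np.nan
    k = len(terms)
    if prev_rss > 0 and ss_total > 0:
        f_model = ((ss_total - prev_rss) / k) / ms_resid
        p_model = float(stats.f.sf(f_model, k, df_resid))
    else:
        f_model, p_model = np.inf, 0.0
    return _anova_table(
        rows,
        r_squared=r2,
        f_statistic=f_model,
        model_p=p_model,
        interaction_dropped=interaction_dropped,
    )
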