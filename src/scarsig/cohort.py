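"""Cohort-level QC, grouping and statistics.

The cohort frame is a plain pandas DataFrame with one row per sample: the
three scar scores, the instability metrics, ACF, and any number of free-form
grouping labels (cancer type, MSI status, p53 status, dichotomized stage /
grade / smoking bins, ...). Functions here implement the analyses run on such
a frame: an ACF quality filter, per-group score quantiles with an average-rank
ordering, Spearman rank correlation, the two-sided Wilcoxon rank-sum test, and
Fisher's exact test with the sample odds ratio.

All p-values are two-sided and unadjusted.
"""

from __future__ import annotations

import itertools
import math
import warnings
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import ValidationError
from .instability import InstabilityMetrics
from .scars import ScarScores

__all__ = [
    "DEFAULT_MIN_ACF",
    "QCResult",
    "build_cohort_table",
    "qc_filter",
    "group_medians",
    "spearman_rho",
    "wilcoxon_ranksum",
    "fisher_odds_ratio",
]

#: Minimum aberrant cell fraction for a sample to enter the analysis.
DEFAULT_MIN_ACF = 0.36

SCORE_COLUMNS = ["ntai", "lst", "hrd_loh"]


def build_cohort_table(
    scores: Sequence[ScarScores],
    metrics: Sequence[InstabilityMetrics] | None = None,
    acf: dict[str, float] | None = None,
    labels: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble per-sample scores (+ optional metrics, ACF, labels) into one frame.

    ``labels`` must carry a ``sample_id`` column; its remaining columns are
    merged as grouping labels. Sample ids must be unique.
    """
    rows = [
        {"sample_id": s.sample_id, "ntai": s.ntai, "lst": s.lst, "hrd_loh": s.hrd_loh}
        for s in scores
    ]
    df = pd.DataFrame(rows)
    if df["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in scores")
    if metrics is not None:
        mdf = pd.DataFrame(
            [
                {
                    "sample_id": m.sample_id,
                    "wgii": m.wgii,
                    "floh": m.floh,
                    "nmut": np.nan if m.nmut is None else m.nmut,
                    "dna_index": m.dna_index,
                    "ploidy_class": str(m.ploidy_class),
                }
                for m in metrics
            ]
        )
        df = df.merge(mdf, on="sample_id", how="left")
    if acf is not None:
        df["acf"] = df["sample_id"].map(acf)
    if labels is not None:
        if "sample_id" not in labels.columns:
            raise ValidationError("labels table must have a sample_id column")
        df = df.merge(labels, on="sample_id", how="left")
    return df


@dataclass(frozen=True)
class QCResult:
    table: pd.DataFrame
    n_removed_low_acf: int
    n_removed_missing_acf: int


def qc_filter(cohort: pd.DataFrame, min_acf: float = DEFAULT_MIN_ACF) -> QCResult:
    """Drop samples with ACF strictly below ``min_acf``.

    A sample at exactly the threshold is retained. Rows with missing ACF are
    excluded too, with a warning — an unknown tumor-cell fraction cannot pass QC.
    """
    if "acf" not in cohort.columns:
        raise ValidationError("cohort table has no 'acf' column")
    acf = pd.to_numeric(cohort["acf"], errors="coerce")
    missing = acf.isna()
    low = acf < min_acf
    if missing.any():
        warnings.warn(
            f"excluding {int(missing.sum())} sample(s) with missing ACF",
            stacklevel=2,
        )
    kept = cohort.loc[~(missing | low)].reset_index(drop=True)
    return QCResult(
        table=kept,
        n_removed_low_acf=int((low & ~missing).sum()),
        n_removed_missing_acf=int(missing.sum()),
    )


def group_medians(
    cohort: pd.DataFrame,
    group_col: str,
    score_cols: Sequence[str] = tuple(SCORE_COLUMNS),
    *,
    ranking: str = "mean_rank",
) -> pd.DataFrame:
    """Quartiles of each score per group, plus an average ranking of groups.

    For every group: the 25th/50th/75th percentiles (linear interpolation) of
    each score column. Groups are then ordered by an "average ranking": with
    ``ranking="mean_rank"`` each score ranks the groups by median (descending,
    average ranks on ties) and groups are ranked by the mean of those ranks;
    ``ranking="mean_score"`` ranks by the mean of the raw medians instead.
    Rows with a missing group label are dropped with a warning.
    """
    if ranking not in {"mean_rank", "mean_score"}:
        raise ValidationError(f"unknown ranking mode: {ranking!r}")
    data = cohort.copy()
    missing = data[group_col].isna()
    if missing.any():
        warnings.warn(
            f"dropping {int(missing.sum())} sample(s) with missing {group_col}",
            stacklevel=2,
        )
        data = data.loc[~missing]
    if data.empty:
        raise ValidationError("no samples with a group label")
    records = []
    for group, sub in data.groupby(group_col, sort=True):
        rec: dict[str, object] = {group_col: group, "n": len(sub)}
        for col in score_cols:
            vals = pd.to_numeric(sub[col], errors="coerce").dropna()
            q25, q50, q75 = (
                (np.nan, np.nan, np.nan)
                if vals.empty
                else np.percentile(vals, [25, 50, 75])
            )
            rec[f"{col}_q25"] = q25
            rec[f"{col}_median"] = q50
            rec[f"{col}_q75"] = q75
        records.append(rec)
    out = pd.DataFrame(records)
    medians = out[[f"{c}_median" for c in score_cols]]
    if ranking == "mean_rank":
        per_score_ranks = medians.rank(ascending=False, method="average")
        key = per_score_ranks.mean(axis=1)
        out["average_ranking"] = key.rank(ascending=True, method="min")
    else:
        key = -medians.mean(axis=1)
        out["average_ranking"] = key.rank(ascending=True, method="min")
    return out.sort_values("average_ranking", kind="mergesort").reset_index(drop=True)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average ranks for ties.

    Pairs with a missing value in either vector are dropped (pairwise-complete).
    Returns NaN when fewer than 3 complete pairs remain or either vector has
    zero rank variance.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValidationError("x and y must have equal length")
    keep = ~(np.isnan(xa) | np.isnan(ya))
    xa, ya = xa[keep], ya[keep]
    if xa.size < 3:
        return float("nan")
    if np.unique(xa).size == 1 or np.unique(ya).size == 1:
        return float("nan")
    rho = stats.spearmanr(xa, ya).statistic
    return float(rho)


def wilcoxon_ranksum(
    a: Sequence[float],
    b: Sequence[float],
    *,
    exact_max_n: int = 12,
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (rank sum of ``a``, p).

    For combined sample sizes up to ``exact_max_n`` the null distribution of
    the rank sum is enumerated exhaustively over all group assignments, which
    remains valid under ties (average ranks); the two-sided p-value uses the
    distribution's symmetry around n_a (N + 1) / 2. Larger samples use the
    tie-corrected normal approximation with continuity correction.
    """
    aa = np.asarray(a, dtype=float)
    bb = np.asarray(b, dtype=float)
    if aa.size == 0 or bb.size == 0:
        raise ValidationError("both groups must be nonempty")
    pooled = np.concatenate([aa, bb])
    ranks = stats.rankdata(pooled)
    n_a, n = aa.size, pooled.size
    w_obs = float(ranks[:n_a].sum())
    if n <= exact_max_n:
        mu = n_a * (n + 1) / 2.0
        dev = abs(w_obs - mu)
        extreme = 0
        total = 0
        for combo in itertools.combinations(range(n), n_a):
            total += 1
            w = sum(ranks[i] for i in combo)
            if abs(w - mu) >= dev - 1e-12:
                extreme += 1
        return w_obs, extreme / total
    res = stats.mannwhitneyu(aa, bb, alternative="two-sided", method="asymptotic")
    return w_obs, float(res.pvalue)


def fisher_odds_ratio(
    table: Sequence[Sequence[float]],
) -> tuple[float, float]:
    """Sample odds ratio and two-sided Fisher exact p for a 2×2 count table.

    The odds ratio is the cross-product (a·d)/(b·c); with a zero off-diagonal
    cell it is ``inf`` (or 0 with a zero diagonal cell), and the p-value —
    the sum of hypergeometric probabilities no larger than the observed
    table's — is still computed.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValidationError("expected a 2x2 table of non-negative counts")
    a, b_, c, d = t.ravel()
    if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
        raise ValidationError("both margins must be nonzero")
    if b_ * c == 0:
        oratio = math.inf if a * d > 0 else math.nan
    else:
        oratio = (a * d) / (b_ * c)
    p = float(stats.fisher_exact(np.round(t).astype(int), alternative="two-sided")[1])
    return oratio, p
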