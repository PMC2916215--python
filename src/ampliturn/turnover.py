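"""Seasonal turnover statistics on an OTU table.

After subsampling every sample to equal depth, each OTU is summarised by
its occupancy N (number of samples where it is detected), total reads n,
and mean abundance when present A = n/N.  OTUs are grouped by occupancy
class; differences in per-sample OTU counts across classes are tested by
one-way ANOVA with Tukey's HSD post hoc.  For OTUs with dataset-wide
abundance > 10, the slope m of their descending-sorted log counts against
rank measures the strength of between-sample abundance shifts, and the
correlation between m and N quantifies whether seasonally restricted OTUs
fluctuate more than persistent ones.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .otu import OtuTable


class UndefinedStatisticError(ValueError):
    """A statistic is undefined on this input (e.g. zero variance)."""


def subsample_equal_depth(table: OtuTable, depth: int, seed: int | None = 0) -> OtuTable:
    """Rarefy every sample to ``depth`` reads without replacement.

    Each column is one multivariate hypergeometric draw (a uniform
    without-replacement sample of reads); columns are drawn left to right
    from a single seeded generator.  OTUs losing all reads are dropped.
    """
    rng = np.random.default_rng(seed)
    columns = {}
    for sample in table.samples:
        col = table.counts[sample].to_numpy()
        total = int(col.sum())
        if depth > total:
            raise ValueError(
                f"depth {depth} exceeds the {total} reads of sample {sample}"
            )
        columns[sample] = rng.multivariate_hypergeometric(col, depth)
    frame = pd.DataFrame(columns, index=table.otu_ids)
    keep = frame.sum(axis=1) > 0
    frame = frame.loc[keep]
    reps = {i: table.representatives[i] for i in frame.index if i in table.representatives}
    return OtuTable(counts=frame, representatives=reps)


def occupancy_stats(table: OtuTable) -> pd.DataFrame:
    """One record per OTU: occupancy N, total reads n, A = n/N."""
    counts = table.counts
    n = counts.sum(axis=1)
    present = counts > 0
    N = present.sum(axis=1)
    records = pd.DataFrame({"N": N, "n": n})
    records = records[records["n"] > 0]
    records["A"] = records["n"] / records["N"]
    records.index.name = "otu_id"
    return records


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p_value: float
    ms_within: float
    group_sizes: dict[int, int]
    tukey: pd.DataFrame  # columns: group1, group2, mean_diff, q, p_adj


def anova_oneway(groups: dict[int, np.ndarray]) -> AnovaResult:
    """One-way ANOVA from standard sums of squares, with Tukey's HSD.

    Tukey q statistics use the Tukey-Kramer standard error
    sqrt(MSW/2 * (1/n_i + 1/n_j)) (= sqrt(MSW/n) for equal sizes) and
    adjusted p-values from the studentized range distribution.
    """
    labels = sorted(groups)
    data = {k: np.asarray(groups[k], dtype=float) for k in labels}
    sizes = {k: len(v) for k, v in data.items()}
    if len(labels) < 2 or any(size < 1 for size in sizes.values()):
        raise UndefinedStatisticError("ANOVA needs >= 2 non-empty groups")
    all_values = np.concatenate([data[k] for k in labels])
    grand = all_values.mean()
    n_total = len(all_values)
    k_groups = len(labels)
    ss_between = sum(sizes[k] * (data[k].mean() - grand) ** 2 for k in labels)
    ss_within = sum(((data[k] - data[k].mean()) ** 2).sum() for k in labels)
    df_between = k_groups - 1
    df_within = n_total - k_groups
    if df_within < 1:
        raise UndefinedStatisticError("no within-group degrees of freedom")
    ms_within = ss_within / df_within
    if ms_within == 0:
        f_stat = 0.0 if ss_between == 0 else math.inf
    else:
        f_stat = (ss_between / df_between) / ms_within
    p_value = float(stats.f.sf(f_stat, df_between, df_within)) if math.isfinite(f_stat) else 0.0

    rows = []
    for a, b in itertools.combinations(labels, 2):
        diff = data[b].mean() - data[a].mean()
        se = math.sqrt(ms_within / 2.0 * (1.0 / sizes[a] + 1.0 / sizes[b]))
        q = abs(diff) / se if se > 0 else (0.0 if diff == 0 else math.inf)
        if math.isfinite(q):
            p_adj = float(stats.studentized_range.sf(q, k_groups, df_within))
        else:
            p_adj = 0.0
        rows.append((a, b, diff, q, p_adj))
    tukey = pd.DataFrame(rows, columns=["group1", "group2", "mean_diff", "q", "p_adj"])
    return AnovaResult(
        F=float(f_stat), df_between=df_between, df_within=df_within,
        p_value=p_value, ms_within=float(ms_within), group_sizes=sizes, tukey=tukey,
    )


def occupancy_class_matrix(table: OtuTable) -> pd.DataFrame:
    """Per-sample OTU counts per occupancy class (samples x classes).

    Entry (s, k): number of OTUs detected in sample s whose dataset-wide
    occupancy is k.  These per-sample counts are the replicates of the
    occupancy-class ANOVA.
    """
    present = table.counts > 0
    occupancy = present.sum(axis=1)
    n_samples = len(table.samples)
    matrix = pd.DataFrame(
        0, index=table.samples, columns=range(1, n_samples + 1), dtype=np.int64
    )
    for k in range(1, n_samples + 1):
        rows = occupancy[occupancy == k].index
        if len(rows):
            matrix[k] = present.loc[rows].sum(axis=0)
    return matrix


def occupancy_class_summary(
    table: OtuTable,
) -> tuple[pd.DataFrame, AnovaResult | None]:
    """Mean/SD of N and A per occupancy class, plus the class ANOVA.

    The summary has one row per occupancy class k = 1..n_samples with the
    number of OTUs in the class and the within-class mean and SD of N and
    A.  The ANOVA compares per-sample OTU counts between occupancy classes
    (replicates = samples); classes with no OTUs are excluded from it.
    """
    records = occupancy_stats(table)
    n_samples = len(table.samples)
    rows = []
    for k in range(1, n_samples + 1):
        klass = records[records["N"] == k]
        rows.append(
            {
                "occupancy_class": k,
                "n_otus": len(klass),
                "mean_N": klass["N"].mean() if len(klass) else np.nan,
                "sd_N": klass["N"].std(ddof=1) if len(klass) > 1 else (0.0 if len(klass) else np.nan),
                "mean_A": klass["A"].mean() if len(klass) else np.nan,
                "sd_A": klass["A"].std(ddof=1) if len(klass) > 1 else (0.0 if len(klass) else np.nan),
            }
        )
    summary = pd.DataFrame(rows).set_index("occupancy_class")

    matrix = occupancy_class_matrix(table)
    groups = {
        k: matrix[k].to_numpy()
        for k in matrix.columns
        if summary.at[k, "n_otus"] > 0
    }
    anova = anova_oneway(groups) if len(groups) >= 2 else None
    return summary, anova


@dataclass
class SlopeRecord:
    otu_id: str
    m: float
    points: int
    N: int


def slope_statistic(
    counts, otu_id: str = "", min_total: int = 10, log_base: float = 10.0
) -> SlopeRecord | None:
    """OLS slope of descending-sorted log counts against rank 1..k.

    Only OTUs with dataset-wide abundance strictly greater than
    ``min_total`` qualify; zero counts are excluded (log undefined), so
    the number of points equals the occupancy.  Returns None when the
    statistic is undefined (too few reads or a single occupied sample).
    """
    c = np.asarray(counts, dtype=np.int64)
    total = int(c.sum())
    nonzero = np.sort(c[c > 0])[::-1]
    if total <= min_total or len(nonzero) < 2:
        return None
    y = np.log(nonzero.astype(float)) / np.log(log_base)
    x = np.arange(1, len(y) + 1, dtype=float)
    slope = float(np.polyfit(x, y, 1)[0])
    return SlopeRecord(otu_id=otu_id, m=slope, points=len(y), N=len(y))


def slope_table(
    table: OtuTable, min_total: int = 10, log_base: float = 10.0
) -> pd.DataFrame:
    """Slope records for every qualifying OTU (columns: m, points, N)."""
    rows = []
    for otu_id, row in table.counts.iterrows():
        record = slope_statistic(
            row.to_numpy(), otu_id=otu_id, min_total=min_total, log_base=log_base
        )
        if record is not None:
            rows.append((record.otu_id, record.m, record.points, record.N))
    return pd.DataFrame(rows, columns=["otu_id", "m", "points", "N"]).set_index("otu_id")


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    n_pairs: int


def slope_occupancy_correlation(
    slopes: pd.DataFrame,
) -> tuple[CorrelationResult, pd.DataFrame]:
    """Pearson correlation between slope m and occupancy N.

    Computed on per-OTU (m, N) pairs with a two-sided p from the t
    transform; also returns per-occupancy-class mean and SD of m for
    plotting.  Raises :class:`UndefinedStatisticError` when either
    variable has zero variance or fewer than 3 pairs are available.
    """
    if len(slopes) < 3 or slopes["N"].nunique() < 2:
        raise UndefinedStatisticError(
            "correlation needs >= 3 slopes spanning >= 2 occupancy values"
        )
    m = slopes["m"].to_numpy(dtype=float)
    N = slopes["N"].to_numpy(dtype=float)
    if np.ptp(m) == 0 or np.ptp(N) == 0:
        raise UndefinedStatisticError("zero variance in slopes or occupancy")
    result = stats.pearsonr(m, N)
    per_class = (
        slopes.groupby("N")["m"]
        .agg(mean_m="mean", sd_m=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0,
             n_otus="size")
    )
    return (
        CorrelationResult(r=float(result.statistic), p_value=float(result.pvalue),
                          n_pairs=len(slopes)),
        per_class,
    )
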