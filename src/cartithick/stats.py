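"""Cohort aggregation, outlier screening and inter-method agreement statistics.

Per-knee mean thickness is summarized globally, per region (LT/MT/LF/MF) and
per subregion.  Outlier knees are those with any (method, subregion) mean
more than five standard deviations from the average pooled over all methods
and knees of that subregion; a flagged knee is removed entirely (single-pass
semantics).  Inter-method comparison per (sub)region uses one-way
repeated-measures ANOVA (knee as subject) with Tukey-Kramer post-hoc tests
on the within-subject error term at a family-wise alpha of 0.01, plus
Bland-Altman bias and 95% limits of agreement and Lin's concordance
correlation coefficient for every method pair.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
from scipy.stats import studentized_range

from .errors import InsufficientDataError, PairingError
from .regions import region_of
from .thickness.base import ThicknessMap

FAMILY_WISE_ALPHA = 0.01
OUTLIER_SD = 5.0


def summarize(maps: Iterable[ThicknessMap], knee_id: str = "") -> pd.DataFrame:
    """Per-knee mean thickness table at global, region and subregion level.

    Means are unweighted arithmetic means of the individual samples.  The
    global mean pools all samples of a method over both bones.  Returns a
    tidy frame with columns (knee_id, method, level, name, mean_mm, n).
    """
    maps = list(maps)
    if not maps:
        raise InsufficientDataError("no thickness maps to summarize")
    frames = [m.to_dataframe() for m in maps]
    df = pd.concat(frames, ignore_index=True)
    df = df[df["subregion"] != ""]
    rows = []
    for method, g in df.groupby("method"):
        rows.append((knee_id, method, "global", "joint", g["thickness_mm"].mean(), len(g)))
        reg = g["subregion"].map(region_of)
        for name, gg in g.groupby(reg):
            rows.append((knee_id, method, "region", name, gg["thickness_mm"].mean(), len(gg)))
        for name, gg in g.groupby("subregion"):
            rows.append((knee_id, method, "subregion", name, gg["thickness_mm"].mean(), len(gg)))
    return pd.DataFrame(rows, columns=["knee_id", "method", "level", "name", "mean_mm", "n"])


def count_measurements(tmap: ThicknessMap) -> dict:
    """Successful sample count plus failure counts of one map."""
    return {
        "method": tmap.method,
        "structure": tmap.structure,
        "n_samples": len(tmap),
        **{f"failed_{k}": v for k, v in tmap.counts.items()},
    }


def detect_outlier_knees(cohort: pd.DataFrame, sd_limit: float = OUTLIER_SD) -> list:
    """Knees with any subregional mean beyond ``sd_limit`` pooled SDs.

    ``cohort`` is a summary table as produced by :func:`summarize` for many
    knees.  For every subregion the pool is all (knee, method) means; a knee
    is flagged when any of its values lies outside pool mean +- limit*SD.
    Subregions with zero pooled SD flag nobody.  Single pass: the statistics
    are computed once on the full cohort.
    """
    sub = cohort[cohort["level"] == "subregion"]
    if sub["knee_id"].nunique() < 2 or sub["method"].nunique() < 2:
        raise InsufficientDataError("outlier screening needs >= 2 knees and >= 2 methods")
    flagged = set()
    for _name, g in sub.groupby("name"):
        v = g["mean_mm"].to_numpy(dtype=float)
        mu, sd = v.mean(), v.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            continue
        out = np.abs(v - mu) > sd_limit * sd
        flagged.update(g.loc[out, "knee_id"].tolist())
    return sorted(flagged)


@dataclass(frozen=True)
class RMAnovaResult:
    f_value: float
    p_value: float
    df_treatment: int
    df_error: int
    ms_error: float
    pairwise: pd.DataFrame  # columns: method_a, method_b, mean_diff, p_adj, significant


def rm_anova_tukey(
    data: pd.DataFrame | np.ndarray,
    methods: Sequence[str] | None = None,
    alpha: float = FAMILY_WISE_ALPHA,
) -> RMAnovaResult:
    """One-way repeated-measures ANOVA with Tukey-Kramer post-hoc tests.

    ``data`` is a complete knees x methods matrix (rows = subjects).  The
    pairwise comparisons use the studentized range distribution with the
    within-subject mean-square error, giving multiplicity-adjusted p-values;
    significance is declared at the family-wise ``alpha`` (default 0.01).
    """
    if isinstance(data, pd.DataFrame):
        methods = list(data.columns) if methods is None else list(methods)
        mat = data.to_numpy(dtype=float)
    else:
        mat = np.asarray(data, dtype=float)
        methods = [f"m{i}" for i in range(mat.shape[1])] if methods is None else list(methods)
    n, k = mat.shape
    if k < 2 or n < 3:
        raise InsufficientDataError(f"need >= 2 methods and >= 3 subjects, got {k} x {n}")
    if not np.isfinite(mat).all():
        raise InsufficientDataError("repeated-measures matrix must be complete")

    grand = mat.mean()
    col_means = mat.mean(axis=0)
    row_means = mat.mean(axis=1)
    ss_treat = n * ((col_means - grand) ** 2).sum()
    ss_subj = k * ((row_means - grand) ** 2).sum()
    ss_total = ((mat - grand) ** 2).sum()
    ss_err = ss_total - ss_treat - ss_subj
    df_t, df_e = k - 1, (n - 1) * (k - 1)
    ms_treat = ss_treat / df_t
    ms_err = max(ss_err / df_e, 0.0)
    if ms_err == 0:
        f_value = 0.0 if ms_treat == 0 else np.inf
        p_value = 1.0 if ms_treat == 0 else 0.0
    else:
        f_value = ms_treat / ms_err
        p_value = float(f_dist.sf(f_value, df_t, df_e))

    rows = []
    se = np.sqrt(ms_err / n)
    for a, b in combinations(range(k), 2):
        diff = col_means[a] - col_means[b]
        if se == 0:
            p_adj = 1.0 if diff == 0 else 0.0
        else:
            q = abs(diff) / se
            p_adj = float(np.clip(studentized_range.sf(q, k, df_e), 0.0, 1.0))
        rows.append((methods[a], methods[b], diff, p_adj, p_adj < alpha))
    pairwise = pd.DataFrame(
        rows, columns=["method_a", "method_b", "mean_diff", "p_adj", "significant"]
    )
    return RMAnovaResult(
        f_value=float(f_value),
        p_value=float(p_value),
        df_treatment=df_t,
        df_error=df_e,
        ms_error=float(ms_err),
        pairwise=pairwise,
    )


@dataclass(frozen=True)
class BlandAltman:
    bias: float
    loa_lower: float
    loa_upper: float
    sd: float


def bland_altman(a: np.ndarray, b: np.ndarray) -> BlandAltman:
    """Bias and 95% limits of agreement of paired differences a - b.

    Limits are bias +- 1.96 * SD of the differences (sample SD, ddof=1).
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise PairingError(f"paired series differ in length: {len(a)} vs {len(b)}")
    if len(a) < 2:
        raise PairingError("need >= 2 pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(bias=bias, loa_lower=bias - 1.96 * sd, loa_upper=bias + 1.96 * sd, sd=sd)


def lin_ccc(a: np.ndarray, b: np.ndarray) -> float:
    """Lin's concordance correlation coefficient.

    CCC = 2 cov(a,b) / (var(a) + var(b) + (mean(a) - mean(b))^2), with
    population (1/n) moments as in Lin's original definition.  Penalizes
    both dispersion and location shift; |CCC| <= |Pearson r|.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise PairingError(f"paired series differ in length: {len(a)} vs {len(b)}")
    if len(a) < 2:
        raise PairingError("need >= 2 pairs")
    va = a.var()
    vb = b.var()
    if va == 0 and vb == 0:
        raise InsufficientDataError("CCC undefined: both series constant")
    cov = ((a - a.mean()) * (b - b.mean())).mean()
    return float(2.0 * cov / (va + vb + (a.mean() - b.mean()) ** 2))


def agreement_report(
    cohort: pd.DataFrame,
    alpha: float = FAMILY_WISE_ALPHA,
    sd_limit: float = OUTLIER_SD,
) -> dict[str, pd.DataFrame]:
    """Full inter-method agreement analysis of a cohort summary table.

    Screens outlier knees (removed entirely), then per (sub)region and
    globally runs the repeated-measures ANOVA + Tukey-Kramer tests and, per
    method pair, Bland-Altman and CCC on per-knee means.  Knees missing a
    value for some (sub)region are excluded from that (sub)region's analysis
    only (complete-case per region).  Returns the tables keyed by
    {"outliers", "anova", "pairwise"}.
    """
    outliers = detect_outlier_knees(cohort, sd_limit=sd_limit)
    clean = cohort[~cohort["knee_id"].isin(outliers)]
    anova_rows, pair_rows = [], []
    for (level, name), g in clean.groupby(["level", "name"]):
        wide = g.pivot_table(index="knee_id", columns="method", values="mean_mm")
        wide = wide.dropna(axis=0)
        if wide.shape[0] < 3 or wide.shape[1] < 2:
            continue
        res = rm_anova_tukey(wide, alpha=alpha)
        anova_rows.append((level, name, wide.shape[0], res.f_value, res.p_value))
        for _, pr in res.pairwise.iterrows():
            a, b = pr["method_a"], pr["method_b"]
            ba = bland_altman(wide[a].to_numpy(), wide[b].to_numpy())
            try:
                ccc = lin_ccc(wide[a].to_numpy(), wide[b].to_numpy())
            except InsufficientDataError:
                ccc = np.nan
            pair_rows.append(
                (
                    level,
                    name,
                    a,
                    b,
                    pr["mean_diff"],
                    pr["p_adj"],
                    pr["significant"],
                    ba.bias,
                    ba.loa_lower,
                    ba.loa_upper,
                    ccc,
                )
            )
    return {
        "outliers": pd.DataFrame({"knee_id": outliers}),
        "anova": pd.DataFrame(
            anova_rows, columns=["level", "name", "n_knees", "F", "p"]
        ),
        "pairwise": pd.DataFrame(
            pair_rows,
            columns=[
                "level",
                "name",
                "method_a",
                "method_b",
                "mean_diff",
                "p_adj",
                "significant",
                "ba_bias",
                "ba_loa_lower",
                "ba_loa_upper",
                "ccc",
            ],
        ),
    }
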