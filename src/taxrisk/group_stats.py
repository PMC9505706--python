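"""Differential-abundance statistics with multiplicity correction.

Clinical case/control comparisons use a variance-ratio (F) test to choose
between the pooled and Welch t-test, reported with raw p-values; rat
multi-group comparisons use Kruskal–Wallis plus pairwise Mann–Whitney U
with Benjamini–Hochberg correction, following common practice for small
non-normal group sizes.  Fold changes are ratios of group mean relative
abundances.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from taxrisk.errors import ConfigError, ValidationError
from taxrisk.taxa_io import SampleMetadata


@dataclass
class DiffAbundanceRow:
    """One taxon's differential-abundance record."""

    taxon: str
    rank: str
    case_mean: float
    control_mean: float
    fold_change: float  # case/control; nan when control mean is 0
    test: str
    p_value: float
    adjusted_p: float | None = None
    significant: bool = False


def var_ratio_test(x, y) -> tuple[float, float]:
    """Two-sided variance-ratio F test; F = s_x^2 / s_y^2."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("each sample needs >= 2 observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 or vy == 0:
        raise ValidationError("zero variance in a sample")
    f = vx / vy
    dfx, dfy = len(x) - 1, len(y) - 1
    cdf = stats.f.cdf(f, dfx, dfy)
    p = 2 * min(cdf, 1 - cdf)
    return float(f), float(min(p, 1.0))


def two_sample_t(x, y, equal_var: bool | None = None,
                 alpha: float = 0.05) -> tuple[float, float, float]:
    """Two-sided t-test; returns (t, df, p).

    When ``equal_var`` is None the choice between the pooled and Welch
    statistic is gated by the variance-ratio test at ``alpha`` (pooled when
    the F test does not reject equality of variances).
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("each sample needs >= 2 observations")
    if equal_var is None:
        try:
            _, p_f = var_ratio_test(x, y)
            equal_var = p_f >= alpha
        except ValidationError:  # zero variance: Welch still defined-ish
            equal_var = True
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    df = float(res.df)
    return float(res.statistic), df, float(res.pvalue)


def chi2_2x2(table, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-squared on a 2x2 table, df=1, no Yates correction by default."""
    tab = np.asarray(table, dtype=float)
    if tab.shape != (2, 2):
        raise ValidationError(f"expected a 2x2 table, got {tab.shape}")
    if np.any(tab < 0) or np.any(tab != np.round(tab)):
        raise ValidationError("table entries must be non-negative integers")
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise ValidationError("zero margin in 2x2 table")
    stat, p, _, _ = stats.chi2_contingency(tab, correction=correction)
    return float(stat), float(p)


def _exact_mwu_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided MWU p by enumerating all label assignments.

    Handles ties via midranks; two-sided p is the tail probability of
    |U - mu_U| >= |U_obs - mu_U| over all C(n+m, n) assignments.
    """
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n, m = len(x), len(y)
    mu = n * m / 2.0
    u_obs = ranks[:n].sum() - n * (n + 1) / 2.0
    dev_obs = abs(u_obs - mu)
    total = math.comb(n + m, n)
    hits = 0
    for idx in itertools.combinations(range(n + m), n):
        u = ranks[list(idx)].sum() - n * (n + 1) / 2.0
        if abs(u - mu) >= dev_obs - 1e-12:
            hits += 1
    return float(u_obs), hits / total


def mann_whitney_u(x, y, exact: bool | None = None) -> tuple[float, float]:
    """Mann–Whitney U (U for x) with a two-sided p-value.

    Exact enumeration of the permutation distribution (midrank tie
    handling) when both sides have <= 8 observations; tie-corrected normal
    approximation otherwise.  ``exact`` overrides the size rule.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("empty sample")
    if exact is None:
        exact = len(x) <= 8 and len(y) <= 8
    if exact:
        return _exact_mwu_p(x, y)
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="asymptotic", use_continuity=False)
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H with chi-squared (k-1 df) p-value.

    All observations identical is a degenerate but valid input: H = 0, p = 1.
    """
    if len(groups) == 1 and isinstance(groups[0], (list, tuple)) and \
            not np.isscalar(groups[0][0]):
        groups = tuple(groups[0])
    if len(groups) < 2:
        raise ValidationError("need >= 2 groups")
    arrays = [np.asarray(g, float) for g in groups]
    if any(len(a) == 0 for a in arrays):
        raise ValidationError("empty group")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return adj


def _collapse_to_rank(values: pd.DataFrame, lineages: dict, rank: str) -> pd.DataFrame:
    if rank == "genus" or not lineages:
        return values
    labels = [lineages[g].label_at(rank) for g in values.columns]
    return values.T.groupby(np.asarray(labels, dtype=object), sort=False).sum().T


def diff_abundance_table(
    profile,
    metadata: SampleMetadata,
    rank: str = "genus",
    design: str = "two_group_t",
    case: str | None = None,
    control: str | None = None,
    alpha: float = 0.05,
) -> list[DiffAbundanceRow]:
    """Per-taxon case-vs-control differential abundance at a taxonomic rank.

    ``design="two_group_t"`` runs the F-test-gated t-test and flags taxa at
    raw p < alpha (the clinical convention here); ``design="kw_mwu_bh"``
    runs Mann–Whitney U with BH correction across taxa and flags at
    adjusted p < alpha.  ``profile`` is a GenusProfile/AccumulatedProfile
    or a samples × taxa DataFrame of relative abundances.
    """
    if design not in ("two_group_t", "kw_mwu_bh"):
        raise ConfigError(f"unknown design {design!r}")
    values = profile.values if hasattr(profile, "values") and isinstance(
        getattr(profile, "values"), pd.DataFrame) else profile
    lineages = getattr(profile, "lineages", {}) or {}
    values = _collapse_to_rank(values, lineages, rank)

    labels = metadata.labels_for(list(values.index))
    levels = [g for g in metadata.levels if g in set(labels)]
    if len(levels) < 2:
        raise ValidationError("need >= 2 groups present in the profile")
    control = control or levels[0]
    case = case or levels[1]
    x = values.loc[labels == case].to_numpy()
    y = values.loc[labels == control].to_numpy()

    rows: list[DiffAbundanceRow] = []
    raw_ps = []
    for j, taxon in enumerate(values.columns):
        xv, yv = x[:, j], y[:, j]
        cm, km = float(xv.mean()), float(yv.mean())
        fc = cm / km if km > 0 else float("nan")
        if design == "two_group_t":
            try:
                _, _, p = two_sample_t(xv, yv)
                test = "t"
            except ValidationError:
                p, test = 1.0, "t(degenerate)"
        else:
            if np.all(np.concatenate([xv, yv]) ==
                      np.concatenate([xv, yv])[0]):
                p, test = 1.0, "mwu(degenerate)"
            else:
                _, p = mann_whitney_u(xv, yv)
                test = "mwu"
        raw_ps.append(p)
        rows.append(DiffAbundanceRow(
            taxon=str(taxon), rank=rank, case_mean=cm, control_mean=km,
            fold_change=fc, test=test, p_value=float(p),
        ))
    if design == "kw_mwu_bh":
        adj = bh_adjust(raw_ps)
        for row, a in zip(rows, adj):
            row.adjusted_p = float(a)
            row.significant = a < alpha
    else:
        for row in rows:
            row.significant = row.p_value < alpha
    return rows


def diff_table_to_frame(rows: list[DiffAbundanceRow]) -> pd.DataFrame:
    """Tabular view of a differential-abundance result."""
    return pd.DataFrame([r.__dict__ for r in rows])
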