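"""Descriptive trait statistics, heritability and group contrasts.

Summaries are computed on per-sample entry means (mean over replicates
within an environment).  SV% is the coefficient of variation,
``100 * SD / mean`` with the sample SD (n-1 denominator), rounded
half-up to 2 decimals for reporting.  Broad-sense heritability uses the
entry-mean basis over k environments: ``H2 = sg2 / (sg2 + se2 / k)``.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats as sps


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def sv_percent(mean: float, sd: float) -> float:
    """Coefficient of variation in percent, 2-decimal half-up rounding.

    NaN marker when the mean is zero (undefined)."""
    if mean == 0:
        return float("nan")
    return _round2(100.0 * sd / mean)


def summarize(phen: pd.DataFrame) -> pd.DataFrame:
    """Per (trait, environment): range, mean, SD and SV% on entry means."""
    rows = []
    for (trait, env), sub in phen.groupby(["trait", "environment"], sort=True):
        vals = sub.groupby("sample_id")["value"].mean()
        if len(vals) < 2:
            raise ValueError(f"trait {trait}/{env}: need >= 2 observations")
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1))
        rows.append(
            dict(trait=trait, environment=env,
                 min=float(vals.min()), max=float(vals.max()),
                 mean=mean, sd=sd, sv_percent=sv_percent(mean, sd))
        )
    return pd.DataFrame(rows)


def heritability(var_g: float, var_e: float, k: int = 2) -> float:
    """Broad-sense heritability, percent, on an entry-mean basis over k
    environments: ``100 * sg2 / (sg2 + se2/k)``.  NaN when both variances
    are zero."""
    if var_g < 0 or var_e < 0:
        raise ValueError("variance components must be non-negative")
    if k < 1:
        raise ValueError("k must be >= 1")
    denom = var_g + var_e / k
    if denom == 0:
        return float("nan")
    return 100.0 * var_g / denom


def variance_components(phen: pd.DataFrame, trait: str) -> tuple[float, float]:
    """Method-of-moments variance components from the genotype x environment
    entry-mean table.

    Environment means are removed (equivalently, a two-way entry-mean
    ANOVA), then the one-way decomposition over genotypes gives
    ``sg2 = (MS_geno - MS_err) / k`` (floored at 0) and ``se2 = MS_err``.
    """
    sub = phen[phen["trait"] == trait]
    if sub.empty:
        raise ValueError(f"no records for trait {trait}")
    table = (
        sub.groupby(["sample_id", "environment"])["value"].mean().unstack("environment")
    )
    k = table.shape[1]
    n_rep = sub.groupby(["sample_id", "environment"])["replicate"].nunique().max()
    if k < 2 and n_rep < 2:
        raise ValueError("single environment with single replicate: components unidentifiable")
    if k < 2:
        # fall back to replicate-level error within the one environment
        wide = sub.pivot_table(index="sample_id", columns="replicate", values="value")
        table = wide
        k = table.shape[1]
    centered = table - table.mean(axis=0)
    grand = centered.to_numpy().mean()
    geno_means = centered.mean(axis=1).to_numpy()
    resid = centered.to_numpy() - geno_means[:, None] - grand
    n_g = table.shape[0]
    ms_geno = k * np.sum((geno_means - grand) ** 2) / (n_g - 1)
    ms_err = np.sum(resid**2) / ((n_g - 1) * (k - 1))
    var_g = max((ms_geno - ms_err) / k, 0.0)
    return float(var_g), float(ms_err)


def trait_h2(phen: pd.DataFrame, trait: str) -> float:
    """Broad-sense heritability (%) of one trait from its phenotype table."""
    sub = phen[phen["trait"] == trait]
    k = sub["environment"].nunique()
    var_g, var_e = variance_components(phen, trait)
    return heritability(var_g, var_e, k)


_STARS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def star_code(p: float) -> str:
    for cut, sym in _STARS:
        if p < cut:
            return sym
    return "ns"


def group_contrast(phen: pd.DataFrame, groups: dict[str, str]) -> pd.DataFrame:
    """Welch two-sample t-test of group A vs group B per (trait, env).

    Star coding: ``***`` p<0.001, ``**`` p<0.01, ``*`` p<0.05, else
    ``ns``.  Groups with fewer than 2 values yield NaN/undefined rows.
    """
    rows = []
    for (trait, env), sub in phen.groupby(["trait", "environment"], sort=True):
        vals = sub.groupby("sample_id")["value"].mean()
        labels = vals.index.map(groups)
        a = vals[labels == "A"].to_numpy()
        b = vals[labels == "B"].to_numpy()
        if a.size == 0 or b.size == 0:
            raise ValueError(f"{trait}/{env}: a group is empty")
        if a.size < 2 or b.size < 2:
            rows.append(dict(trait=trait, environment=env, mean_A=float(np.mean(a)) if a.size else np.nan,
                             mean_B=float(np.mean(b)) if b.size else np.nan,
                             t=np.nan, p_value=np.nan, stars="undefined"))
            continue
        if np.array_equal(np.sort(a), np.sort(b)):
            t, p = 0.0, 1.0  # identical distributions: no evidence by construction
        else:
            t, p = sps.ttest_ind(a, b, equal_var=False)
        rows.append(dict(trait=trait, environment=env, mean_A=float(np.mean(a)),
                         mean_B=float(np.mean(b)), t=float(t), p_value=float(p),
                         stars=star_code(float(p))))
    return pd.DataFrame(rows)


def trait_correlations(phen: pd.DataFrame, environment: str | None = None) -> pd.DataFrame:
    """Pairwise Pearson correlations of trait entry means.

    Entry means are per sample, pooled over environments unless one is
    given.  Zero-variance traits get NaN rows/columns (undefined marker)
    with a unit diagonal preserved for well-defined traits.
    """
    sub = phen if environment is None else phen[phen["environment"] == environment]
    wide = sub.pivot_table(index="sample_id", columns="trait", values="value", aggfunc="mean")
    if wide.shape[0] < 3:
        raise ValueError("need >= 3 paired observations")
    corr = wide.corr(method="pearson", min_periods=3)
    zero_var = wide.std(ddof=1) == 0
    corr.loc[zero_var, :] = np.nan
    corr.loc[:, zero_var] = np.nan
    for t in corr.index[~zero_var]:
        corr.loc[t, t] = 1.0
    return corr
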