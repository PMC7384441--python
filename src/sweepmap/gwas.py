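"""P+K mixed-model association, region building and haplotype grouping.

The association model is ``y = mu + PCs*gamma + x*beta + u + e`` with
``cov(u) = sigma_g^2 K`` (VanRaden genomic relationship).  Variance
components are estimated once per trait/environment by REML on the null
model through a single eigendecomposition of K (the P3D / EMMAX
strategy), then each SNP is tested by generalized least squares with a
per-marker profiled residual variance, which reduces exactly to ordinary
least squares when K is the identity.

Significant SNPs are flanked by 150 kb on each side to form associated
regions; regions for the same trait are merged transitively when their
intervals overlap or when they contain a common gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .io import GeneModel, GenotypeMatrix, entry_means, genes_in_interval
from .structure import pca

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# kinship


def compute_kinship(g: GenotypeMatrix) -> pd.DataFrame:
    """VanRaden genomic relationship matrix.

    ``K = M M' / (2 sum p(1-p))`` with M the dosage matrix centered by
    twice the allele frequency; missing calls are imputed to the site
    mean (zero after centering).
    """
    if g.n_samples < 2:
        raise ValueError("kinship needs at least 2 samples")
    x = g.dosage.copy()
    mu = np.nanmean(x, axis=0)
    idx = np.where(np.isnan(x))
    x[idx] = mu[idx[1]]
    p = mu / 2.0
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("zero-variance denominator: all sites monomorphic")
    m = x - 2.0 * p
    k = m @ m.T / denom
    return pd.DataFrame(k, index=g.samples, columns=g.samples)


def stabilize_kinship(k: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Shift the spectrum up if the smallest eigenvalue is below eps."""
    w = np.linalg.eigvalsh(k)
    if w[0] < eps:
        logger.info("kinship not PSD (min eig %.3g); applying diagonal shift", w[0])
        k = k + (eps - w[0]) * np.eye(k.shape[0])
    return k


# ---------------------------------------------------------------------------
# REML / P3D scan


def _reml_delta(y_r: np.ndarray, x_r: np.ndarray, lam: np.ndarray) -> float:
    """Maximize the null-model REML likelihood over delta = sig_e^2/sig_g^2.

    Inputs are already rotated by the eigenvectors of K; ``lam`` holds the
    eigenvalues.  A coarse log-grid is refined by bounded Brent search.
    """
    n, p = x_r.shape

    def neg_reml(log_delta: float) -> float:
        d = lam + np.exp(log_delta)
        w = 1.0 / d
        xtwx = x_r.T @ (x_r * w[:, None])
        beta = np.linalg.solve(xtwx, x_r.T @ (y_r * w))
        r = y_r - x_r @ beta
        sigma2 = float(r @ (r * w)) / (n - p)
        _, logdet_xtwx = np.linalg.slogdet(xtwx)
        ll = -0.5 * (
            (n - p) * (np.log(2 * np.pi * sigma2) + 1.0)
            + np.sum(np.log(d))
            + logdet_xtwx
        )
        return -ll

    grid = np.linspace(-8.0, 8.0, 33)
    vals = [neg_reml(g_) for g_ in grid]
    j = int(np.argmin(vals))
    lo = grid[max(j - 1, 0)]
    hi = grid[min(j + 1, grid.size - 1)]
    res = optimize.minimize_scalar(neg_reml, bounds=(lo, hi), method="bounded")
    return float(np.exp(res.x))


@dataclass
class MixedModel:
    """Rotated null-model pieces reused across all SNP tests."""

    u: np.ndarray          # eigenvectors of K
    lam: np.ndarray        # eigenvalues of K
    delta: float           # sig_e^2 / sig_g^2 from null REML
    x0_r: np.ndarray       # rotated covariates (intercept + PCs)
    y_r: np.ndarray        # rotated phenotype


def mixed_model_scan(
    g: GenotypeMatrix,
    y: pd.Series,
    kinship: pd.DataFrame,
    n_pcs: int = 3,
) -> pd.DataFrame:
    """Per-SNP GLS association under the P+K model (P3D).

    Parameters
    ----------
    y
        Per-sample phenotype (entry means for one trait/environment),
        indexed by sample id.  Samples absent from the genotype matrix
        are dropped with a warning.
    kinship
        Relatedness matrix covering all phenotyped samples.
    n_pcs
        Number of genotype principal components as fixed covariates.

    Returns a DataFrame (snp_id, chrom, pos, beta, se, p_value, n_used);
    monomorphic SNPs are absent from the output.
    """
    missing = [s for s in y.index if s not in g.samples]
    if missing:
        logger.warning("dropping %d phenotyped samples absent from genotypes", len(missing))
        y = y.drop(index=missing)
    order = [s for s in g.samples if s in y.index]
    sub = g.take_samples(np.array([g.samples.index(s) for s in order]))
    yv = y.loc[order].to_numpy(dtype=float)
    n = yv.size

    k = stabilize_kinship(kinship.loc[order, order].to_numpy())
    lam, u = np.linalg.eigh(k)

    covs = [np.ones((n, 1))]
    if n_pcs > 0:
        scores, _ = pca(sub, n_components=n_pcs)
        covs.append(scores)
    x0 = np.hstack(covs)

    y_r = u.T @ yv
    x0_r = u.T @ x0
    delta = _reml_delta(y_r, x0_r, lam)
    w = 1.0 / (lam + delta)

    dose = sub.dosage.copy()
    mu = np.nanmean(dose, axis=0)
    idx = np.where(np.isnan(dose))
    dose[idx] = mu[idx[1]]
    poly = np.nanstd(dose, axis=0) > 0
    dose_r = u.T @ dose

    p_cov = x0.shape[1]
    rows = []
    df = n - p_cov - 1
    for j in np.flatnonzero(poly):
        xj = np.hstack([x0_r, dose_r[:, j][:, None]])
        xtwx = xj.T @ (xj * w[:, None])
        try:
            xtwx_inv = np.linalg.inv(xtwx)
        except np.linalg.LinAlgError:
            continue
        beta = xtwx_inv @ (xj.T @ (y_r * w))
        resid = y_r - xj @ beta
        sigma2 = float(resid @ (resid * w)) / df
        se = float(np.sqrt(sigma2 * xtwx_inv[-1, -1]))
        b = float(beta[-1])
        t = b / se if se > 0 else 0.0
        p = float(2.0 * sps.t.sf(abs(t), df))
        rows.append(
            dict(snp_id=f"{sub.chrom[j]}_{sub.pos[j]}", chrom=int(sub.chrom[j]),
                 pos=int(sub.pos[j]), beta=b, se=se, p_value=max(p, 5e-324), n_used=n)
        )
    return pd.DataFrame(rows)


def fit_mlm(
    g: GenotypeMatrix,
    phen: pd.DataFrame,
    kinship: pd.DataFrame,
    trait: str,
    environment: str,
    n_pcs: int = 3,
) -> pd.DataFrame:
    """P+K scan for one trait/environment using per-sample entry means."""
    y = entry_means(phen, trait, environment)
    res = mixed_model_scan(g, y, kinship, n_pcs=n_pcs)
    res["trait"] = trait
    res["environment"] = environment
    return res


def significant_snps(res: pd.DataFrame, alpha: float = 1e-3) -> pd.DataFrame:
    """Keep records with p <= alpha (inclusive); no multiplicity correction,
    matching the flat genome-wide threshold the scan is used with."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    return res[res["p_value"] <= alpha].reset_index(drop=True)


# ---------------------------------------------------------------------------
# associated regions


def build_regions(
    snps: pd.DataFrame,
    genes: list[GeneModel],
    flank: int = 150_000,
) -> pd.DataFrame:
    """Flank significant SNPs and merge regions sharing genes or overlapping.

    Each SNP contributes ``[pos - flank, pos + flank]`` (floored at 1).
    Regions for the same trait are merged transitively whenever their
    intervals overlap on the same chromosome OR their resident gene sets
    intersect; the merged region carries the union span, member SNPs and
    union gene list.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    out = []
    for trait, grp in snps.groupby("trait", sort=True):
        items = []
        for rec in grp.itertuples(index=False):
            start = max(1, rec.pos - flank)
            end = rec.pos + flank
            gset = frozenset(genes_in_interval(genes, rec.chrom, start, end))
            items.append(dict(chrom=rec.chrom, start=start, end=end, genes=gset,
                              snps=[rec.snp_id],
                              envs={getattr(rec, "environment", "")},
                              min_p=rec.p_value))
        parent = list(range(len(items)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        def union(i: int, j: int) -> None:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[rj] = ri

        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                a, b = items[i], items[j]
                if a["chrom"] != b["chrom"]:
                    continue
                overlap = a["start"] <= b["end"] and b["start"] <= a["end"]
                share = bool(a["genes"] & b["genes"])
                if overlap or share:
                    union(i, j)

        merged: dict[int, dict] = {}
        for i, item in enumerate(items):
            r = find(i)
            if r not in merged:
                merged[r] = dict(chrom=item["chrom"], start=item["start"], end=item["end"],
                                 genes=set(item["genes"]), snps=list(item["snps"]),
                                 envs=set(item["envs"]), min_p=item["min_p"])
            else:
                m = merged[r]
                m["start"] = min(m["start"], item["start"])
                m["end"] = max(m["end"], item["end"])
                m["genes"] |= item["genes"]
                m["snps"] += item["snps"]
                m["envs"] |= item["envs"]
                m["min_p"] = min(m["min_p"], item["min_p"])
        for m in merged.values():
            out.append(dict(chrom=m["chrom"], start=m["start"], end=m["end"], trait=trait,
                            environments=",".join(sorted(e for e in m["envs"] if e)),
                            member_snps=",".join(sorted(m["snps"])),
                            genes=",".join(sorted(m["genes"])), min_p=m["min_p"]))
    return (
        pd.DataFrame(out, columns=["chrom", "start", "end", "trait", "environments",
                                   "member_snps", "genes", "min_p"])
        .sort_values(["trait", "chrom", "start"])
        .reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# haplotype grouping


def haplotype_groups(
    g: GenotypeMatrix,
    snp_ids: list[str],
    phen: pd.DataFrame | None = None,
    traits: list[str] | None = None,
) -> pd.DataFrame:
    """Group samples by their allele string across a set of SNPs.

    Homozygous calls render as the single base (ref or alt); samples with
    a heterozygous or missing call at any member SNP are excluded (inbred
    context).  Returns one row per (haplotype, group) with carrier count,
    the percentage of that group's included samples, and per-trait means
    when a phenotype table is supplied.
    """
    if not snp_ids:
        raise ValueError("need at least one SNP")
    ids = list(g.snp_ids)
    cols = []
    for s in snp_ids:
        if s not in ids:
            raise KeyError(f"unknown SNP id {s}")
        cols.append(ids.index(s))
    dose = g.dosage[:, cols]
    complete = np.all((dose == 0.0) | (dose == 2.0), axis=1)
    if not complete.any():
        raise ValueError("all samples excluded (het or missing calls at member SNPs)")

    strings = []
    for i in np.flatnonzero(complete):
        chars = [
            str(g.ref[c]) if dose[i, k] == 0.0 else str(g.alt[c])
            for k, c in enumerate(cols)
        ]
        strings.append("".join(chars))
    carriers = pd.DataFrame(
        {"sample_id": [g.samples[i] for i in np.flatnonzero(complete)],
         "group": g.group[complete],
         "haplotype": strings}
    )
    group_sizes = carriers.groupby("group")["sample_id"].count()

    rows = []
    for (hap, grp), sub in carriers.groupby(["haplotype", "group"]):
        row = dict(
            haplotype=hap, group=grp, n=len(sub),
            pct=haplotype_percentage(len(sub), int(group_sizes[grp])),
        )
        if phen is not None:
            for t in traits or sorted(phen["trait"].unique()):
                vals = entry_means(phen, t)
                row[f"mean_{t}"] = float(vals.reindex(sub["sample_id"]).mean())
        rows.append(row)
    return pd.DataFrame(rows).sort_values(["haplotype", "group"]).reset_index(drop=True)


def haplotype_percentage(count: int, group_total: int) -> float:
    """Carrier percentage of a group, rounded to 2 decimals."""
    return round(100.0 * count / group_total, 2)
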