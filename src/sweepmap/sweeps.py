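"""Windowed diversity statistics and empirical-tail sweep calling.

Statistics per non-overlapping window (default 100 kb):

* nucleotide diversity pi per group: per site ``(n/(n-1)) * 2 p (1-p)``
  with ``n`` the non-missing allele count and ``p`` the alternate-allele
  frequency within the group; window pi is the per-site sum divided by
  the window length in bp;
* the pi ratio (group A over group B), the sweep scan's diversity signal;
* Weir & Cockerham (1984) Fst with ratio-of-sums window averaging
  (sum of the a components over sum of a+b+c, the VCFtools convention);
* Tajima's D per group from windowed pi, segregating sites and the
  standard constants, treating each inbred diploid as two sequences.

A window is called swept in group A when its pi ratio falls in the
bottom ``tail`` of the empirical distribution AND its Fst in the top
``tail``; swept in group B with the top pi-ratio tail instead.  Tajima's
D is reported alongside but is not part of the calling rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GeneModel, GenotypeMatrix, genes_in_interval


# ---------------------------------------------------------------------------
# windows


def tile_windows(g: GenotypeMatrix, size: int = 100_000) -> pd.DataFrame:
    """Non-overlapping windows [start, start+size-1] tiling each chromosome
    out to the last observed SNP."""
    rows = []
    for c in np.unique(g.chrom):
        last = g.pos[g.chrom == c].max()
        for s in range(1, int(last) + 1, size):
            rows.append((int(c), s, s + size - 1))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _site_pi(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (pi, n_alleles) for a dosage block (samples x sites)."""
    n = 2.0 * np.sum(~np.isnan(d), axis=0)
    alt = np.nansum(d, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
        pi = np.where(n > 1, n / (n - 1.0) * 2.0 * p * (1.0 - p), np.nan)
    return pi, n


def _wc_components(da: np.ndarray, db: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir & Cockerham (1984) per-site variance components a, b, c
    for two populations of diploid genotypes (sites along axis 1)."""
    r = 2.0
    comps = []
    for d in (da, db):
        n_i = np.sum(~np.isnan(d), axis=0).astype(float)      # individuals
        p_i = np.nansum(d, axis=0) / np.maximum(2.0 * n_i, 1.0)
        h_i = np.sum(d == 1.0, axis=0) / np.maximum(n_i, 1.0)  # het frequency
        comps.append((n_i, p_i, h_i))
    (n1, p1, h1), (n2, p2, h2) = comps
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
        )
        c = hbar / 2.0
    ok = (n1 >= 2) & (n2 >= 2) & np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    a = np.where(ok, a, np.nan)
    b = np.where(ok, b, np.nan)
    c = np.where(ok, c, np.nan)
    return a, b, c


def _tajima_constants(n: float) -> dict[str, float]:
    """Tajima (1989) normalizing constants for n sequences."""
    i = np.arange(1, int(round(n)))
    a1 = np.sum(1.0 / i)
    a2 = np.sum(1.0 / i**2)
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def tajima_d(pi_sum: float, s: int, n_seq: float) -> float:
    """Tajima's D from the windowed pairwise-diversity sum, the number of
    segregating sites and the sequence count; NaN when S = 0 or n < 4."""
    if s == 0 or n_seq < 4:
        return float("nan")
    k = _tajima_constants(n_seq)
    var = k["e1"] * s + k["e2"] * s * (s - 1.0)
    if var <= 0:
        return float("nan")
    return float((pi_sum - s / k["a1"]) / np.sqrt(var))


# ---------------------------------------------------------------------------
# windowed statistics


@dataclass
class ScanConfig:
    window_size: int = 100_000
    min_snps: int = 3      # windows below this in either group leave quantile pools
    tail: float = 0.10


def window_stats(g: GenotypeMatrix, windows: pd.DataFrame | None = None,
                 size: int = 100_000) -> pd.DataFrame:
    """Per-window pi (both groups), pi ratio, W&C Fst and Tajima's D.

    Returns a DataFrame with one row per window: chrom, start, end,
    n_snps_A, n_snps_B, pi_A, pi_B, pi_ratio, fst, tajd_A, tajd_B.
    Undefined quantities (no SNPs, zero denominator) are NaN markers.
    """
    if windows is None:
        windows = tile_windows(g, size)
    mask_a = g.group_mask("A")
    mask_b = g.group_mask("B")
    pi_a_site, n_a_site = _site_pi(g.dosage[mask_a])
    pi_b_site, n_b_site = _site_pi(g.dosage[mask_b])
    a_c, b_c, c_c = _wc_components(g.dosage[mask_a], g.dosage[mask_b])

    rows = []
    for chrom, start, end in windows[["chrom", "start", "end"]].itertuples(index=False):
        length = end - start + 1
        sel = (g.chrom == chrom) & (g.pos >= start) & (g.pos <= end)
        idx = np.flatnonzero(sel)
        pa, pb = pi_a_site[idx], pi_b_site[idx]
        na, nb = n_a_site[idx], n_b_site[idx]
        n_snps_a = int(np.sum(na > 0))
        n_snps_b = int(np.sum(nb > 0))
        pi_a = float(np.nansum(pa)) / length
        pi_b = float(np.nansum(pb)) / length
        pi_ratio = pi_a / pi_b if pi_b > 0 else np.nan
        num = np.nansum(a_c[idx])
        den = np.nansum(a_c[idx] + b_c[idx] + c_c[idx])
        fst = float(num / den) if np.isfinite(den) and den != 0 and np.any(np.isfinite(a_c[idx])) else np.nan
        s_a = int(np.nansum((pa > 0)))
        s_b = int(np.nansum((pb > 0)))
        med_na = float(np.median(na[na > 0])) if n_snps_a else 0.0
        med_nb = float(np.median(nb[nb > 0])) if n_snps_b else 0.0
        rows.append(
            dict(
                chrom=int(chrom), start=int(start), end=int(end),
                n_snps_A=n_snps_a, n_snps_B=n_snps_b,
                pi_A=pi_a, pi_B=pi_b, pi_ratio=pi_ratio, fst=fst,
                tajd_A=tajima_d(float(np.nansum(pa)), s_a, med_na),
                tajd_B=tajima_d(float(np.nansum(pb)), s_b, med_nb),
            )
        )
    return pd.DataFrame(rows)


def window_pi(g: GenotypeMatrix, group: str, windows: pd.DataFrame | None = None,
              size: int = 100_000) -> pd.Series:
    """Per-window nucleotide diversity per bp for one group."""
    stats = window_stats(g, windows, size)
    return stats[f"pi_{group}"]


def window_fst(g: GenotypeMatrix, windows: pd.DataFrame | None = None,
               size: int = 100_000) -> pd.Series:
    """Per-window Weir-Cockerham Fst (ratio of sums)."""
    return window_stats(g, windows, size)["fst"]


def window_tajd(g: GenotypeMatrix, group: str, windows: pd.DataFrame | None = None,
                size: int = 100_000) -> pd.Series:
    return window_stats(g, windows, size)[f"tajd_{group}"]


# ---------------------------------------------------------------------------
# sweep calling


def call_sweeps(
    stats: pd.DataFrame,
    tail: float = 0.10,
    min_snps: int = 3,
    genes: list[GeneModel] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Empirical-tail sweep calling on windowed statistics.

    A-selected windows: pi_ratio in the bottom ``tail`` quantile AND Fst
    in the top ``tail``.  B-selected: pi_ratio top tail AND Fst top tail.
    Quantiles are empirical (type 7); ties at the threshold are included.
    Windows with undefined pi_ratio/Fst or with fewer than ``min_snps``
    SNPs in either group are excluded from the quantile pools.

    Returns
    -------
    flagged : DataFrame
        The per-window table with boolean ``swept_A`` / ``swept_B``
        columns (the per-window bookkeeping tally).
    regions : DataFrame
        Adjacent qualifying windows of the same group merged, with
        resident genes when ``genes`` is given.
    """
    if not 0.0 < tail <= 0.5:
        raise ValueError("tail must be in (0, 0.5]")
    stats = stats.copy()
    eligible = (
        stats["pi_ratio"].notna()
        & stats["fst"].notna()
        & (stats["n_snps_A"] >= min_snps)
        & (stats["n_snps_B"] >= min_snps)
    )
    pool = stats[eligible]
    if len(pool) < int(np.ceil(1.0 / tail)):
        raise ValueError(
            f"only {len(pool)} eligible windows; tail quantiles at {tail} are meaningless"
        )
    ratio_lo = np.quantile(pool["pi_ratio"], tail)
    ratio_hi = np.quantile(pool["pi_ratio"], 1.0 - tail)
    fst_hi = np.quantile(pool["fst"], 1.0 - tail)
    fst_top = eligible & (stats["fst"] >= fst_hi)
    stats["swept_A"] = fst_top & (stats["pi_ratio"] <= ratio_lo)
    stats["swept_B"] = fst_top & (stats["pi_ratio"] >= ratio_hi)
    if ratio_lo == ratio_hi:
        # degenerate pool (e.g. all ratios identical): nothing is extreme
        stats["swept_A"] = False
        stats["swept_B"] = False

    regions = _merge_regions(stats, genes)
    return stats, regions


def _merge_regions(stats: pd.DataFrame, genes: list[GeneModel] | None) -> pd.DataFrame:
    rows = []
    for grp in ("A", "B"):
        flag = stats[stats[f"swept_{grp}"]].sort_values(["chrom", "start"])
        cur = None
        for rec in flag.itertuples(index=False):
            if (
                cur is not None
                and rec.chrom == cur["chrom"]
                and rec.start == cur["end"] + 1
            ):
                cur["end"] = rec.end
                cur["n_windows"] += 1
                cur["fst"] = max(cur["fst"], rec.fst)
                cur["pi_ratio"] = (
                    min(cur["pi_ratio"], rec.pi_ratio) if grp == "A"
                    else max(cur["pi_ratio"], rec.pi_ratio)
                )
            else:
                if cur is not None:
                    rows.append(cur)
                cur = dict(chrom=rec.chrom, start=rec.start, end=rec.end, group=grp,
                           n_windows=1, fst=rec.fst, pi_ratio=rec.pi_ratio)
        if cur is not None:
            rows.append(cur)
    regions = pd.DataFrame(rows, columns=["chrom", "start", "end", "group",
                                          "n_windows", "fst", "pi_ratio"])
    if genes is not None and not regions.empty:
        regions["genes"] = [
            ",".join(genes_in_interval(genes, r.chrom, r.start, r.end))
            for r in regions.itertuples(index=False)
        ]
    elif genes is not None:
        regions["genes"] = pd.Series(dtype=object)
    return regions.sort_values(["chrom", "start"]).reset_index(drop=True)
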