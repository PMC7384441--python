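"""Population characterization: PCA, IBS/UPGMA tree, LD decay.

Distances for the tree are 1 - IBS allele-sharing proportion computed on
dosages (a p-distance on SNP calls); pairs use only sites non-missing in
both samples.  PCA mean-imputes missing calls per site and uses the plain
(unscaled) sample covariance.  LD is genotype r-squared: lines are
near-homozygous inbreds, so dosage correlation approximates haplotype
correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import squareform

from .io import GenotypeMatrix


# ---------------------------------------------------------------------------
# PCA


def pca(g: GenotypeMatrix, n_components: int = 3, *, scale: bool = False):
    """Principal components of the sample x site dosage matrix.

    Missing calls are imputed to the site mean; sites are mean-centered
    (and optionally scaled by sqrt(2p(1-p)) when ``scale`` is set).

    Returns
    -------
    scores : np.ndarray, shape (n_samples, n_components)
    var_frac : np.ndarray
        Fraction of total variance per returned component (non-increasing).
    """
    x = g.dosage.copy()
    mu = np.nanmean(x, axis=0)
    if np.isnan(mu).any():
        raise ValueError("site with all calls missing; filter first")
    idx = np.where(np.isnan(x))
    x[idx] = mu[idx[1]]
    x -= mu
    if scale:
        p = mu / 2.0
        sd = np.sqrt(2.0 * p * (1.0 - p))
        keep = sd > 0
        x = x[:, keep] / sd[keep]
    if not (x.std(axis=0) > 0).any():
        raise ValueError("all sites monomorphic")
    cov = x @ x.T / max(g.n_sites - 1, 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    vals = np.clip(vals, 0.0, None)
    var_frac = vals / vals.sum()
    scores = vecs * np.sqrt(np.maximum(vals, 0.0))
    return scores[:, :n_components], var_frac[:n_components]


# ---------------------------------------------------------------------------
# IBS distance + UPGMA


def ibs_distance(g: GenotypeMatrix) -> pd.DataFrame:
    """Pairwise 1 - IBS proportion; only sites non-missing in both samples.

    IBS per site for dosages a, b is ``1 - |a - b| / 2`` (identical call 1,
    het vs hom 0.5, opposite homozygotes 0).
    """
    return pd.DataFrame(_ibs_from_dosage(g.dosage), index=g.samples, columns=g.samples)


def _ibs_from_dosage(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    out = np.zeros((n, n))
    mask = ~np.isnan(d)
    filled = np.nan_to_num(d)
    for i in range(n):
        both = mask[i] & mask
        diff = np.abs(filled[i] - filled) / 2.0
        diff[~both] = 0.0
        cnt = both.sum(axis=1)
        if (cnt == 0).any():
            bad = np.flatnonzero(cnt == 0)
            bad = bad[bad != i]
            if bad.size:
                raise ValueError(f"samples {i} and {bad[0]} share no genotyped sites")
        out[i] = diff.sum(axis=1) / np.maximum(cnt, 1)
    np.fill_diagonal(out, 0.0)
    return out


@dataclass
class UpgmaTree:
    """Average-linkage tree: scipy linkage matrix + leaf names + supports.

    ``linkage`` follows scipy conventions; node heights are half the merge
    distance so the tree is ultrametric.  ``support`` maps an internal
    node's leaf set (frozenset of leaf names) to bootstrap support in
    [0, 100]; empty when the tree was built without bootstraps.
    """

    linkage: np.ndarray
    leaves: list[str]
    support: dict[frozenset, float]

    def bipartitions(self) -> list[frozenset]:
        return _bipartitions(self.linkage, self.leaves)

    def leaf_heights(self) -> np.ndarray:
        """Root-to-leaf path lengths (equal for an ultrametric tree)."""
        n = len(self.leaves)
        root_h = self.linkage[-1, 2] / 2.0
        return np.full(n, root_h)

    def newick(self) -> str:
        """Newick string with node heights and bootstrap supports."""
        n = len(self.leaves)
        heights = {i: 0.0 for i in range(n)}
        clades = {i: frozenset([self.leaves[i]]) for i in range(n)}
        text = {i: self.leaves[i] for i in range(n)}
        for k, (a, b, dist, _cnt) in enumerate(self.linkage):
            a, b = int(a), int(b)
            h = dist / 2.0
            node = n + k
            clades[node] = clades[a] | clades[b]
            sup = self.support.get(clades[node])
            label = "" if sup is None else f"{sup:.0f}"
            text[node] = (
                f"({text[a]}:{h - heights[a]:.6g},{text[b]}:{h - heights[b]:.6g}){label}"
            )
            heights[node] = h
        return text[n + len(self.linkage) - 1] + ";"


def _bipartitions(z: np.ndarray, leaves: list[str]) -> list[frozenset]:
    n = len(leaves)
    clades: dict[int, frozenset] = {i: frozenset([leaves[i]]) for i in range(n)}
    out = []
    for k, (a, b, *_rest) in enumerate(z):
        c = clades[int(a)] | clades[int(b)]
        clades[n + k] = c
        if 1 < len(c) < n:
            out.append(c)
    return out


def upgma(d: pd.DataFrame, g: GenotypeMatrix | None = None,
          bootstraps: int = 0, seed: int = 0) -> UpgmaTree:
    """Classic average-linkage (UPGMA) tree from a distance matrix.

    With ``bootstraps > 0`` (requires ``g``, the genotype matrix the
    distances came from), sites are resampled with replacement, the
    distance matrix and tree rebuilt, and each internal node's support is
    the percentage of replicate trees containing its bipartition.
    """
    if d.shape[0] < 2:
        raise ValueError("UPGMA needs at least 2 samples")
    leaves = list(d.index)
    z = average(squareform(d.to_numpy(), checks=False))
    support: dict[frozenset, float] = {}
    if bootstraps > 0:
        if g is None:
            raise ValueError("bootstraps require the genotype matrix")
        rng = np.random.default_rng(seed)
        counts = {c: 0 for c in _bipartitions(z, leaves)}
        for _ in range(bootstraps):
            idx = rng.integers(0, g.n_sites, size=g.n_sites)
            rep = _ibs_from_dosage(g.dosage[:, idx])
            rep_z = average(squareform(rep, checks=False))
            for c in _bipartitions(rep_z, leaves):
                if c in counts:
                    counts[c] += 1
        support = {c: 100.0 * v / bootstraps for c, v in counts.items()}
    return UpgmaTree(linkage=z, leaves=leaves, support=support)


# ---------------------------------------------------------------------------
# LD


def ld_r2(g: GenotypeMatrix, max_dist: int = 500_000, *, min_shared: int = 3):
    """Pairwise genotype r-squared for intra-chromosome pairs within range.

    Yields a DataFrame with columns (chrom, pos1, pos2, dist, r2); r2 is
    the squared Pearson correlation of dosages over samples non-missing at
    both sites.  Pairs sharing fewer than ``min_shared`` samples are
    skipped and counted in the ``skipped`` attribute of the result.
    """
    rows = []
    skipped = 0
    d = g.dosage
    mask = ~np.isnan(d)
    complete = mask.all()
    if complete:
        mu = d.mean(axis=0)
        sd = d.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (d - mu) / sd  # NaN columns where sd == 0
    for c in np.unique(g.chrom):
        sites = np.flatnonzero(g.chrom == c)
        pos = g.pos[sites]
        for ii, j0 in enumerate(sites):
            hi = np.searchsorted(pos, pos[ii] + max_dist, side="right")
            if hi <= ii + 1:
                continue
            block = sites[ii + 1 : hi]
            if complete:
                if sd[j0] == 0:
                    skipped += block.size
                    continue
                r = z[:, j0] @ z[:, block] / d.shape[0]
                flat = sd[block] == 0
                skipped += int(flat.sum())
                for jj, rj, is_flat in zip(range(ii + 1, hi), r, flat):
                    if is_flat:
                        continue
                    rows.append((int(c), int(pos[ii]), int(pos[jj]),
                                 int(pos[jj] - pos[ii]), float(rj * rj)))
                continue
            for jj in range(ii + 1, hi):
                j1 = sites[jj]
                both = mask[:, j0] & mask[:, j1]
                if both.sum() < min_shared:
                    skipped += 1
                    continue
                a, b = d[both, j0], d[both, j1]
                if a.std() == 0 or b.std() == 0:
                    skipped += 1
                    continue
                r = np.corrcoef(a, b)[0, 1]
                rows.append((int(c), int(pos[ii]), int(pos[jj]), int(pos[jj] - pos[ii]), r * r))
    out = pd.DataFrame(rows, columns=["chrom", "pos1", "pos2", "dist", "r2"])
    out.attrs["skipped"] = skipped
    return out


@dataclass
class LdDecayCurve:
    """Binned mean r2 by distance, plus the r2 = 0.2 crossing point."""

    bins: pd.DataFrame  # bin_start, bin_end, mean_r2, n_pairs
    decay_distance: float | None  # bp, or None if r2 stays above 0.2

    def to_tsv(self, path: str) -> None:
        self.bins.to_csv(path, sep="\t", index=False)


def _decay_point(centers: np.ndarray, means: np.ndarray, threshold: float = 0.2) -> float | None:
    ok = ~np.isnan(means)
    centers, means = centers[ok], means[ok]
    if means.size == 0 or means[0] <= threshold:
        return float(centers[0]) if means.size and means[0] <= threshold else None
    below = np.flatnonzero(means <= threshold)
    if below.size == 0:
        return None  # never reaches the threshold within range
    j = below[0]
    x0, x1 = centers[j - 1], centers[j]
    y0, y1 = means[j - 1], means[j]
    if y0 == y1:
        return float(x1)
    return float(x0 + (y0 - threshold) * (x1 - x0) / (y0 - y1))


def ld_decay(g: GenotypeMatrix, bin_width: int = 1000, max_dist: int = 500_000) -> LdDecayCurve:
    """Bin-averaged LD decay curve and the distance where mean r2 hits 0.2.

    The crossing is linearly interpolated between the flanking bin
    centers; empty bins are carried as missing and excluded from the
    interpolation.  ``decay_distance`` is None when the curve stays above
    0.2 out to ``max_dist``.
    """
    pairs = ld_r2(g, max_dist=max_dist)
    if pairs.empty:
        raise ValueError("no eligible site pairs for LD decay")
    edges = np.arange(0, max_dist + bin_width, bin_width)
    which = np.clip(np.searchsorted(edges, pairs["dist"], side="right") - 1, 0, edges.size - 2)
    mean_r2 = np.full(edges.size - 1, np.nan)
    n_pairs = np.zeros(edges.size - 1, dtype=int)
    for b in np.unique(which):
        sel = which == b
        mean_r2[b] = pairs.loc[sel, "r2"].mean()
        n_pairs[b] = int(sel.sum())
    bins = pd.DataFrame(
        {"bin_start": edges[:-1], "bin_end": edges[1:], "mean_r2": mean_r2, "n_pairs": n_pairs}
    )
    centers = (edges[:-1] + edges[1:]) / 2.0
    return LdDecayCurve(bins=bins, decay_distance=_decay_point(centers, mean_r2))


def resampled_ld_decay(
    g: GenotypeMatrix,
    group: str,
    k: int,
    reps: int = 100,
    seed: int = 0,
    bin_width: int = 1000,
    max_dist: int = 500_000,
) -> tuple[LdDecayCurve, list[float | None]]:
    """LD decay for a group, averaged over random subsamples of size ``k``.

    Controls for sample-size effects when comparing groups of unequal
    size (the smaller group is matched by subsampling the larger one
    ``reps`` times without replacement).  Returns the binwise-averaged
    curve and the per-replicate decay distances.
    """
    members = np.flatnonzero(g.group_mask(group))
    if k > members.size:
        raise ValueError(f"k={k} exceeds group {group} size {members.size}")
    if k == members.size:
        import logging

        logging.getLogger(__name__).warning(
            "resampled_ld_decay: k equals group size; resampling is vacuous"
        )
        curve = ld_decay(g.take_samples(members), bin_width, max_dist)
        return curve, [curve.decay_distance]
    rng = np.random.default_rng(seed)
    curves, dists = [], []
    for _ in range(reps):
        sub = np.sort(rng.choice(members, size=k, replace=False))
        c = ld_decay(g.take_samples(sub), bin_width, max_dist)
        curves.append(c.bins["mean_r2"].to_numpy())
        dists.append(c.decay_distance)
    stack = np.vstack(curves)
    with np.errstate(invalid="ignore"):
        mean_curve = np.nanmean(stack, axis=0)
    edges = np.arange(0, max_dist + bin_width, bin_width)
    out_bins = pd.DataFrame(
        {"bin_start": edges[:-1], "bin_end": edges[1:], "mean_r2": mean_curve,
         "n_pairs": np.sum(~np.isnan(stack), axis=0)}
    )
    centers = (edges[:-1] + edges[1:]) / 2.0
    return LdDecayCurve(bins=out_bins, decay_distance=_decay_point(centers, mean_curve)), dists
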