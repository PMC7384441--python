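"""Weighted gene co-expression network: adjacency, TOM, modules, neighbors.

The network is unsigned: adjacency ``a_ij = |cor(i,j)|^beta`` with the
soft-threshold power ``beta`` (default 6, chosen for scale-free
topology).  Edge weights are topological overlap (TOM), which credits
shared weighted neighbors:

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)

with ``k_i = sum_{u != i} a_iu`` the weighted connectivity.  Modules are
found by average-linkage clustering of ``1 - TOM`` with a static cut
(deterministic alternative to dynamic tree cutting); clusters below
``min_size`` stay unassigned (label 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)


def normalize_expression(raw: pd.DataFrame, *, literal: bool = True) -> pd.DataFrame:
    """Zero-replacement followed by log2 transform.

    ``literal=True`` (default): zeros are first replaced with 0.01, then
    every value is transformed as ``log2(x + 0.01)`` — so an input zero
    maps to ``log2(0.02)``.  ``literal=False`` applies the single-step
    floor variant ``log2(x + 0.01)`` without the prior replacement.
    Negative input raises.
    """
    x = raw.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("expression values must be non-negative")
    x = x.copy()
    if literal:
        x[x == 0.0] = 0.01
    return pd.DataFrame(np.log2(x + 0.01), index=raw.index, columns=raw.columns)


def adjacency(expr: pd.DataFrame, beta: float = 6.0) -> pd.DataFrame:
    """Unsigned soft-threshold adjacency ``|pearson|^beta`` (unit diagonal).

    Zero-variance genes get zero off-diagonal adjacency (logged).
    """
    if beta < 1:
        raise ValueError("beta must be >= 1")
    if expr.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    x = expr.to_numpy(dtype=float)
    sd = x.std(axis=1)
    flat = sd == 0
    if flat.any():
        logger.info("adjacency: %d zero-variance genes set to 0 correlation", flat.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    r[np.isnan(r)] = 0.0
    a = np.abs(r) ** beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=expr.index, columns=expr.index)


def tom(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix of a non-negative adjacency (unit diagonal)."""
    a = adj.to_numpy(dtype=float)
    k = a.sum(axis=1) - np.diag(a)
    shared = a @ a  # includes u=i and u=j terms: a_ij*(a_ii + a_jj) = 2 a_ij
    numer = shared - 2.0 * a + a
    kmin = np.minimum.outer(k, k)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = numer / (kmin + 1.0 - a)
    np.fill_diagonal(t, 1.0)
    return pd.DataFrame(t, index=adj.index, columns=adj.columns)


def detect_modules(tom_m: pd.DataFrame, min_size: int = 30, cut_height: float = 0.8) -> pd.Series:
    """Average-linkage clustering of 1 - TOM with a static height cut.

    Clusters smaller than ``min_size`` are pooled into label 0
    (unassigned); surviving modules are relabeled 1..m by decreasing
    size.  Deterministic given the input.
    """
    n = tom_m.shape[0]
    if n < min_size:
        raise ValueError(f"need >= min_size ({min_size}) genes, got {n}")
    d = 1.0 - tom_m.to_numpy(dtype=float)
    np.fill_diagonal(d, 0.0)
    z = average(squareform(np.clip(d, 0.0, None), checks=False))
    raw = fcluster(z, t=cut_height, criterion="distance")
    sizes = pd.Series(raw).value_counts()
    keep = sizes[sizes >= min_size].index
    order = sorted(keep, key=lambda c: (-sizes[c], c))
    relabel = {c: i + 1 for i, c in enumerate(order)}
    labels = np.array([relabel.get(c, 0) for c in raw])
    return pd.Series(labels, index=tom_m.index, name="module")


def connectivity_degree(adj: pd.DataFrame) -> pd.Series:
    """Weighted connectivity per gene: sum of off-diagonal adjacency."""
    a = adj.to_numpy(dtype=float)
    return pd.Series(a.sum(axis=1) - np.diag(a), index=adj.index, name="degree")


@dataclass
class CoexprNetwork:
    """Bundled co-expression network.

    Edge ``weight`` means TOM throughout (the export convention);
    adjacency is retained for degree and for weight_kind="adjacency".
    """

    gene_ids: list[str]
    beta: float
    adjacency: pd.DataFrame
    tom: pd.DataFrame
    module_of: pd.Series
    degree: pd.Series

    @classmethod
    def build(cls, expr: pd.DataFrame, beta: float = 6.0, min_size: int = 30,
              cut_height: float = 0.8) -> "CoexprNetwork":
        adj = adjacency(expr, beta)
        t = tom(adj)
        return cls(
            gene_ids=list(expr.index), beta=beta, adjacency=adj, tom=t,
            module_of=detect_modules(t, min_size=min_size, cut_height=cut_height),
            degree=connectivity_degree(adj),
        )


def neighbors(
    net: CoexprNetwork,
    seed_genes: list[str],
    weight_cutoff: float,
    *,
    weight_kind: str = "tom",
) -> pd.DataFrame:
    """Edges from seed genes to partners with weight strictly above cutoff.

    Returns a DataFrame (seed, gene, weight) sorted by descending weight;
    the number of distinct partner genes interacting with any seed is in
    ``result.attrs['n_interacting']``.  Unknown seed genes raise.
    """
    if not 0.0 < weight_cutoff < 1.0 and weight_cutoff != 1.0:
        raise ValueError("weight cutoff must be in (0, 1]")
    w = net.tom if weight_kind == "tom" else net.adjacency
    for s in seed_genes:
        if s not in w.index:
            raise KeyError(f"unknown seed gene {s}")
    rows = []
    seeds = set(seed_genes)
    for s in seed_genes:
        vals = w.loc[s]
        hits = vals[(vals > weight_cutoff) & (vals.index != s)]
        for gene, weight in hits.items():
            rows.append(dict(seed=s, gene=gene, weight=float(weight)))
    out = pd.DataFrame(rows, columns=["seed", "gene", "weight"])
    if not out.empty:
        out = out.sort_values("weight", ascending=False).reset_index(drop=True)
    out.attrs["n_interacting"] = int(out.loc[~out["gene"].isin(seeds), "gene"].nunique()) if not out.empty else 0
    return out


def scale_free_fit(degree: pd.Series, n_bins: int = 10) -> float:
    """R^2 of the log-log regression of the binned degree distribution.

    The scale-free topology index used to choose the soft-threshold
    power: higher means the degree distribution is closer to a power law.
    """
    k = degree.to_numpy(dtype=float)
    k = k[k > 0]
    if k.size < n_bins:
        raise ValueError("too few genes with positive degree")
    edges = np.linspace(k.min(), k.max() + 1e-9, n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        sel = which == b
        if sel.sum() == 0:
            continue
        xs.append(np.log10(k[sel].mean()))
        ys.append(np.log10(sel.mean()))
    xs, ys = np.array(xs), np.array(ys)
    if xs.size < 3:
        return 0.0
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)
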