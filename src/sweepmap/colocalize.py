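"""Intersect sweep regions with GWAS associated regions.

A candidate region is an associated region that overlaps at least one
swept window by >= 1 bp.  The candidate keeps the ASSOCIATED region's
span (not the sweep window's), so genes near but outside the narrow
sweep window are not lost.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import GeneModel, genes_in_interval


def overlap_regions(sweeps: pd.DataFrame, assoc: pd.DataFrame) -> pd.DataFrame:
    """Candidate regions: associated regions overlapping >= 1 sweep window.

    Parameters
    ----------
    sweeps
        Sweep regions/windows with columns chrom, start, end, group and
        (optionally) fst, pi_ratio.
    assoc
        Associated regions with columns chrom, start, end, trait,
        environments, min_p (as built by :func:`sweepmap.gwas.build_regions`).

    Returns one row per (associated region x overlapping sweep window):
    the candidate span is the associated region's span; every overlapped
    window is listed, so a region hitting two adjacent windows yields two
    rows sharing the same candidate span.
    """
    rows = []
    for a in assoc.itertuples(index=False):
        hits = sweeps[
            (sweeps["chrom"] == a.chrom)
            & (sweeps["start"] <= a.end)
            & (sweeps["end"] >= a.start)
        ]
        for s in hits.itertuples(index=False):
            rows.append(
                dict(
                    chrom=int(a.chrom),
                    sweep_start=int(s.start), sweep_end=int(s.end),
                    sweep_group=s.group,
                    fst=getattr(s, "fst", np.nan),
                    pi_ratio=getattr(s, "pi_ratio", np.nan),
                    assoc_start=int(a.start), assoc_end=int(a.end),
                    trait=a.trait,
                    environments=getattr(a, "environments", ""),
                    min_p=getattr(a, "min_p", np.nan),
                )
            )
    return pd.DataFrame(
        rows,
        columns=["chrom", "sweep_start", "sweep_end", "sweep_group", "fst", "pi_ratio",
                 "assoc_start", "assoc_end", "trait", "environments", "min_p"],
    ).sort_values(["chrom", "assoc_start", "sweep_start"]).reset_index(drop=True)


def candidate_gene_table(cands: pd.DataFrame, genes: list[GeneModel]) -> pd.DataFrame:
    """Report rows for candidate regions, one per candidate span.

    Collapses the per-window rows of :func:`overlap_regions` to unique
    (chrom, assoc span, trait) candidates, attaches resident gene ids
    (empty list retained as an empty string — gene-free regions are
    reported, not dropped) and the windowed statistics of the overlapped
    sweep windows, including log10 of the pi ratio as reported in sweep
    summaries.
    """
    if cands.empty:
        return pd.DataFrame(
            columns=["chrom", "assoc_start", "assoc_end", "trait", "environments",
                     "sweep_windows", "log10_pi_ratio", "fst", "min_p", "genes", "n_genes"]
        )
    rows = []
    keys = ["chrom", "assoc_start", "assoc_end", "trait"]
    for (chrom, a_start, a_end, trait), sub in cands.groupby(keys, sort=True):
        gids = genes_in_interval(genes, int(chrom), int(a_start), int(a_end))
        with np.errstate(divide="ignore", invalid="ignore"):
            log_ratio = ",".join(
                f"{np.log10(v):.3f}" if v > 0 else "NA" for v in sub["pi_ratio"]
            )
        rows.append(
            dict(
                chrom=int(chrom), assoc_start=int(a_start), assoc_end=int(a_end),
                trait=trait,
                environments=";".join(sorted(set(sub["environments"]))),
                sweep_windows=";".join(
                    f"{s}-{e}({g})" for s, e, g in
                    zip(sub["sweep_start"], sub["sweep_end"], sub["sweep_group"])
                ),
                log10_pi_ratio=log_ratio,
                fst=",".join(f"{v:.3f}" for v in sub["fst"]),
                min_p=float(sub["min_p"].min()),
                genes=",".join(gids),
                n_genes=len(gids),
            )
        )
    return pd.DataFrame(rows).sort_values(["chrom", "assoc_start"]).reset_index(drop=True)
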