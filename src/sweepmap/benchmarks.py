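"""Parameter-recovery experiments on synthetic data.

These runners generate data with the synthetic module, execute the
pipeline stage under study and measure recovery of the planted signal.
They back both the acceptance test suite and the reproduction script, so
the measured quantities come from one implementation.

Problem sizes follow the package's synthetic test scale (30 + 60 lines,
2,000 SNPs on 10 chromosomes; GWAS population of 120 lines), chosen so
each experiment completes in minutes on one CPU while keeping the
statistical structure of the study design (two diverged inbred groups,
heritabilities near 0.7, a 78-sample expression panel).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import coexpression as cx
from .gwas import compute_kinship, mixed_model_scan
from .io import entry_means
from .pheno import trait_h2
from .simulate import SimConfig, simulate_expression, simulate_phenotypes, simulate_populations
from .sweeps import call_sweeps, window_stats


def _default_sweep_config(seed: int) -> SimConfig:
    """Two-group scenario with 5 planted sweeps per group on 200 windows."""
    sweeps = [(c, 1_000_000, "A") for c in (1, 3, 5, 7, 9)] + [
        (c, 1_000_000, "B") for c in (2, 4, 6, 8, 10)
    ]
    return SimConfig(
        n_a=30, n_b=60, n_snps=2000, n_chrom=10, chrom_len=2_000_000,
        swept_loci=sweeps, seed=seed,
    )


def sweep_recovery(n_seeds: int = 20, base_seed: int = 0, *,
                   window: int = 100_000, tail: float = 0.10,
                   flank_windows: int = 2) -> dict[str, float]:
    """Recovery of planted sweeps by the empirical-tail scan.

    A planted locus counts as recovered when a called window of the
    right group lies within ``flank_windows`` windows of it (hitch-hiking
    legitimately spreads the signal to neighbors).  Called windows
    farther than that from any same-group planted locus are false
    positives.  Returns mean per-seed recalls and the false-positive
    fraction of called windows.
    """
    recalls_a, recalls_b, fp_fracs = [], [], []
    for s in range(n_seeds):
        cfg = _default_sweep_config(base_seed + s)
        g = simulate_populations(cfg)
        stats = window_stats(g, size=window)
        flagged, _regions = call_sweeps(stats, tail=tail)
        planted = {"A": [], "B": []}
        for c, p, grp in cfg.swept_loci:
            planted[grp].append((c, (p - 1) // window))
        n_called = 0
        n_fp = 0
        rec = {"A": 0, "B": 0}
        for grp in ("A", "B"):
            called = flagged[flagged[f"swept_{grp}"]]
            idx = [(r.chrom, (r.start - 1) // window) for r in called.itertuples(index=False)]
            n_called += len(idx)
            for c, wi in planted[grp]:
                if any(cc == c and abs(ww - wi) <= flank_windows for cc, ww in idx):
                    rec[grp] += 1
            for cc, ww in idx:
                if not any(cc == c and abs(ww - wi) <= flank_windows for c, wi in planted[grp]):
                    n_fp += 1
        recalls_a.append(rec["A"] / len(planted["A"]))
        recalls_b.append(rec["B"] / len(planted["B"]))
        fp_fracs.append(n_fp / n_called if n_called else 0.0)
    return dict(
        recall_A=float(np.mean(recalls_a)),
        recall_B=float(np.mean(recalls_b)),
        fp_fraction=float(np.mean(fp_fracs)),
        n_seeds=n_seeds,
    )


def _gwas_population(seed: int, *, n_a: int = 40, n_b: int = 80,
                     n_snps: int = 1500,
                     qtl: list[tuple[int, int, float, str]] | None = None,
                     h2: float = 0.70) -> tuple:
    # the GWAS panel is assembled from a broad program; a 5x census keeps
    # realistic relatedness without the sweep panel's very low drift
    cfg = SimConfig(
        n_a=n_a, n_b=n_b, n_snps=n_snps, n_chrom=10, chrom_len=2_000_000,
        census_factor=5, qtl=qtl or [], h2_target=h2, seed=seed,
    )
    g = simulate_populations(cfg)
    return cfg, g


def qtl_power(n_seeds: int = 50, base_seed: int = 0, *, alpha: float = 1e-3,
              share: float = 0.15) -> dict[str, float]:
    """Detection power for a planted QTL at n = 120 lines.

    The QTL's single-environment entry-mean variance share is set to
    ``share`` by choosing the heritability target accordingly (with k=2
    environments, H2 = 2 s/(1+s)); detection means p <= alpha at the
    planted SNP in the P+K scan.
    """
    # per-env share s relates to entry-mean H2 over k envs by
    # s = sg2/(sg2+se2), se2 = k sg2 (1-H2)/H2  =>  H2 = k s/(1+(k-1)s)
    k = 2
    h2 = k * share / (1.0 + (k - 1) * share)
    hits = 0
    shares = []
    for s in range(n_seeds):
        qtl = [(1, 1_000_000, 1.0, "EL")]
        cfg, g = _gwas_population(base_seed + 1000 + s, qtl=qtl, h2=h2)
        phen = simulate_phenotypes(g, cfg)
        y = entry_means(phen, "EL", "E1")
        j = int(np.flatnonzero((g.chrom == 1) & (g.pos == 1_000_000))[0])
        gv = g.dosage[:, j]
        shares.append(float(np.var(gv * 1.0) / np.var(y.loc[g.samples].to_numpy())))
        kin = compute_kinship(g)
        res = mixed_model_scan(g, y, kin, n_pcs=3)
        row = res[(res.chrom == 1) & (res.pos == 1_000_000)]
        if not row.empty and float(row["p_value"].iloc[0]) <= alpha:
            hits += 1
    return dict(power=hits / n_seeds, mean_variance_share=float(np.mean(shares)),
                n_seeds=n_seeds)


def h2_recovery(n_seeds: int = 50, base_seed: int = 0, *, target: float = 0.70) -> dict[str, float]:
    """Mean recovered broad-sense heritability vs the simulation target."""
    cfg0, g = _gwas_population(base_seed + 2000, n_a=70, n_b=130,
                               qtl=[(c, 1_000_000, 0.7, "EL") for c in range(1, 9)],
                               h2=target)
    ests = []
    for s in range(n_seeds):
        cfg = SimConfig(**{**cfg0.__dict__, "seed": base_seed + 3000 + s})
        phen = simulate_phenotypes(g, cfg)
        ests.append(trait_h2(phen, "EL") / 100.0)
    return dict(mean_h2=float(np.mean(ests)), target=target, n_seeds=n_seeds)


def type_i_error(n_seeds: int = 5, base_seed: int = 0, *, alpha: float = 0.05) -> dict[str, float]:
    """Null rejection rate of the P+K scan on structured populations.

    Phenotypes carry group structure through a polygenic term (so naive
    regression would be inflated) but no single-SNP effect; the rate of
    p <= alpha across all SNPs and seeds estimates the type-I error.
    """
    rates = []
    for s in range(n_seeds):
        cfg, g = _gwas_population(base_seed + 4000 + s)
        rng = np.random.default_rng(base_seed + 5000 + s)
        kin = compute_kinship(g)
        kv = kin.to_numpy()
        kv = kv + (1e-6 - min(np.linalg.eigvalsh(kv).min(), 0.0)) * np.eye(kv.shape[0])
        u = rng.multivariate_normal(np.zeros(kv.shape[0]), kv, method="cholesky")
        y = pd.Series(u + rng.normal(0, 1, size=kv.shape[0]), index=g.samples)
        res = mixed_model_scan(g, y, kin, n_pcs=3)
        rates.append(float((res["p_value"] <= alpha).mean()))
    return dict(rejection_rate=float(np.mean(rates)), alpha=alpha, n_seeds=n_seeds)


def module_recovery(seed: int = 0, *, n_genes: int = 300, n_samples: int = 78,
                    module_sizes: tuple[int, ...] = (50, 50, 50),
                    within_cor: float = 0.8) -> dict[str, float]:
    """Adjusted-Rand agreement between planted and detected modules."""
    from sklearn.metrics import adjusted_rand_score

    expr = simulate_expression(
        n_genes, n_samples, [(m, within_cor) for m in module_sizes], seed=seed
    )
    norm = cx.normalize_expression(expr)
    net = cx.CoexprNetwork.build(norm, beta=6.0, min_size=min(module_sizes) // 2)
    truth = []
    row = 0
    for i, m in enumerate(module_sizes, start=1):
        truth += [i] * m
        row += m
    truth += [0] * (n_genes - row)
    planted_mask = np.array(truth) > 0
    ari = adjusted_rand_score(
        np.array(truth)[planted_mask], net.module_of.to_numpy()[planted_mask]
    )
    return dict(ari=float(ari), n_genes=n_genes, n_samples=n_samples)
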