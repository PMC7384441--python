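"""Forward simulation of a two-group inbred breeding scenario.

The generator emulates the study design the pipeline targets: two
subpopulations of near-homozygous inbred lines drawn from one ancestral
pool, diverged by drift and directional selection at planted loci, with
quantitative traits controlled by planted QTLs and a gene-expression
matrix carrying planted co-expression modules.

Model
-----
Founder haplotypes (default 60) are block mosaics of a few deep
prototype haplotypes, giving the pool ancestral LD; individuals start as
random founder copies and evolve by discrete Wright-Fisher generations
with Poisson recombination and partial selfing.  Planted sweeps use truncation selection in the target group
only: each generation the lines richest in favored alleles (top
``truncation_fraction``) are the parent pool.  Linked founder segments
hitch-hike, producing the windowed high-Fst / low-diversity signal the
sweep scan looks for.  A final burst of enforced selfing generations
drives lines to near-homozygosity.

All generators are deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenotypeMatrix


@dataclass
class SimConfig:
    """Parameters of the breeding-scenario simulation.

    Defaults are the test-scale conditions: 30 + 60 lines, 2,000 SNPs on
    10 chromosomes of 10 Mb.  The study scale (54 + 154 lines, ~32 k SNPs)
    is reached by overriding ``n_a``, ``n_b`` and ``n_snps``.
    """

    n_a: int = 30
    n_b: int = 60
    census_factor: int = 15  # breeding census = factor x genotyped sample size
    n_snps: int = 2000
    n_chrom: int = 10
    chrom_len: int = 10_000_000
    n_generations: int = 10
    n_founders: int = 60
    selfing_rate: float = 0.2
    self_generations: int = 3
    recomb_rate: float = 5e-7  # crossovers per bp per gamete per generation
    truncation_fraction: float = 0.3  # fraction of lines kept as parents each generation
    swept_loci: list[tuple[int, int, str]] = field(default_factory=list)  # (chrom, pos, group)
    qtl: list[tuple[int, int, float, str]] = field(default_factory=list)  # (chrom, pos, effect, trait)
    h2_target: float = 0.70
    trait_baseline: float = 12.0  # intercept so traits sit on a realistic positive scale
    n_environments: int = 2
    n_replicates: int = 2
    n_proto: int = 5  # deep ancestral haplotypes behind the founder pool
    proto_block: int = 200_000  # bp scale of ancestral LD blocks in founders
    sweep_init_freq: float = 0.02  # single founder carrier -> hard, diversity-collapsing sweep
    introgression_span: int = 250_000  # bp of donor segment around each swept locus
    qtl_init_freq: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_a <= 1 or self.n_b <= 1:
            raise ValueError("subpopulation sizes must exceed 1")
        if not 0.0 <= self.h2_target < 1.0:
            raise ValueError("h2_target must be in [0, 1)")


def _site_positions(cfg: SimConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Random sorted unique positions, swept/QTL positions forced in."""
    per_chrom = np.full(cfg.n_chrom, cfg.n_snps // cfg.n_chrom)
    per_chrom[: cfg.n_snps % cfg.n_chrom] += 1
    forced: dict[int, set[int]] = {}
    for c, p, *_ in list(cfg.swept_loci) + list(cfg.qtl):
        forced.setdefault(int(c), set()).add(int(p))
    chroms, poss = [], []
    for c in range(1, cfg.n_chrom + 1):
        want = forced.get(c, set())
        n_free = int(per_chrom[c - 1]) - len(want)
        if n_free < 0:
            raise ValueError(f"more forced loci than SNPs on chromosome {c}")
        sites = set(want)
        while len(sites) < per_chrom[c - 1]:
            extra = rng.integers(1, cfg.chrom_len + 1, size=per_chrom[c - 1] - len(sites))
            sites.update(int(x) for x in extra)
        pos = np.sort(np.fromiter(sites, dtype=np.int64))
        chroms.append(np.full(pos.size, c, dtype=np.int64))
        poss.append(pos)
    return np.concatenate(chroms), np.concatenate(poss)


def _recombine(h0: np.ndarray, h1: np.ndarray, chrom: np.ndarray, pos: np.ndarray,
               rate: float, rng: np.random.Generator) -> np.ndarray:
    """One gamete from a haplotype pair with Poisson crossovers per chromosome."""
    use_h1 = np.empty(pos.size, dtype=bool)
    for c in np.unique(chrom):
        idx = chrom == c
        p = pos[idx]
        span = int(p[-1] - p[0] + 1) if p.size else 1
        n_cross = rng.poisson(rate * span)
        phase = rng.integers(0, 2)
        if n_cross == 0:
            use_h1[idx] = bool(phase)
            continue
        breaks = np.sort(rng.integers(p[0], p[-1] + 1, size=n_cross))
        seg = np.searchsorted(breaks, p, side="right")
        use_h1[idx] = ((seg + phase) % 2).astype(bool)
    return np.where(use_h1, h1, h0)


def simulate_populations(cfg: SimConfig) -> GenotypeMatrix:
    """Simulate the two-group inbred panel; see module docstring for the model.

    Raises
    ------
    ValueError
        If a planted sweep locus is monomorphic among the founders
        (nothing to sweep).
    """
    rng = np.random.default_rng(cfg.seed)
    chrom, pos = _site_positions(cfg, rng)
    m = pos.size

    # founder haplotypes are block mosaics of a few deep prototype
    # haplotypes, so the founder pool carries ancestral LD that decays on
    # the proto_block scale (real germplasm is not site-independent)
    p_anc = rng.uniform(0.1, 0.9, size=m)
    site_index = {(int(c), int(p)): j for j, (c, p) in enumerate(zip(chrom, pos))}
    protos = (rng.random((cfg.n_proto, m)) < p_anc).astype(np.int8)
    founders = np.empty((cfg.n_founders, m), dtype=np.int8)
    for f in range(cfg.n_founders):
        for c in range(1, cfg.n_chrom + 1):
            idx = np.flatnonzero(chrom == c)
            p = pos[idx]
            span = int(p[-1] - p[0] + 1) if idx.size else 1
            n_switch = rng.poisson(span / cfg.proto_block)
            breaks = np.sort(rng.integers(p[0], p[-1] + 1, size=n_switch)) if n_switch else np.array([])
            seg = np.searchsorted(breaks, p, side="right")
            choice = rng.integers(0, cfg.n_proto, size=n_switch + 1)
            founders[f, idx] = protos[choice[seg], idx]
    # a sprinkle of founder-private variation keeps sites polymorphic beyond
    # the prototypes
    flip = rng.random((cfg.n_founders, m)) < 0.02
    founders = np.where(flip, 1 - founders, founders).astype(np.int8)
    # planted loci get an exact founder carrier count so sweeps start from a
    # controlled number of haplotypes and QTLs segregate at moderate frequency
    for loci, freq in ((cfg.swept_loci, cfg.sweep_init_freq), (cfg.qtl, cfg.qtl_init_freq)):
        for c, p, *_ in loci:
            j = site_index[(int(c), int(p))]
            n_carriers = max(1, int(round(freq * cfg.n_founders)))
            founders[:, j] = 0
            founders[rng.choice(cfg.n_founders, size=n_carriers, replace=False), j] = 1

    swept_idx: dict[str, list[int]] = {"A": [], "B": []}
    donor_of: dict[str, list[int]] = {"A": [], "B": []}
    for c, p, grp in cfg.swept_loci:
        j = site_index[(int(c), int(p))]
        carriers = np.flatnonzero(founders[:, j] == 1)
        if carriers.size == 0 or carriers.size == cfg.n_founders:
            raise ValueError(f"swept locus {c}:{p} is monomorphic among founders")
        swept_idx[grp].append(j)
        donor_of[grp].append(int(carriers[0]))

    def start_pop(n: int) -> np.ndarray:
        picks = rng.integers(0, cfg.n_founders, size=(n, 2))
        return founders[picks]  # (n, 2, m)

    # the breeding program is larger than the genotyped panel: evolve the
    # census population, then genotype a random subsample of lines
    pops = {"A": start_pop(cfg.n_a * cfg.census_factor),
            "B": start_pop(cfg.n_b * cfg.census_factor)}
    # each target group starts with its donor segment introgressed: one line
    # carries the favored allele on a local donor segment (as after
    # backcrossing a donor cross), guaranteeing the sweep can start without
    # genome-wide linkage drag
    for grp, donors in donor_of.items():
        for i, (f, j) in enumerate(zip(donors, swept_idx[grp])):
            seg = (chrom == chrom[j]) & (np.abs(pos - pos[j]) <= cfg.introgression_span // 2)
            tgt = i % pops[grp].shape[0]
            pops[grp][tgt, 0, seg] = founders[f, seg]

    def next_generation(haps: np.ndarray, sel_sites: list[int], selfing: float) -> np.ndarray:
        # truncation selection: only the top fraction of lines by favored-allele
        # count reproduce, sampled uniformly (bounds reproductive skew, as in
        # breeding programs; avoids the Ne collapse of multiplicative fitness)
        n = haps.shape[0]
        if sel_sites:
            score = haps[:, :, sel_sites].sum(axis=(1, 2)).astype(float)
            order = np.lexsort((rng.random(n), -score))  # rank desc, random ties
            parents = order[: max(1, int(np.ceil(cfg.truncation_fraction * n)))]
            w = np.zeros(n)
            w[parents] = 1.0 / parents.size
        else:
            w = np.full(n, 1.0 / n)
        out = np.empty_like(haps)
        for i in range(n):
            p1 = rng.choice(n, p=w)
            p2 = p1 if rng.random() < selfing else rng.choice(n, p=w)
            out[i, 0] = _recombine(haps[p1, 0], haps[p1, 1], chrom, pos, cfg.recomb_rate, rng)
            out[i, 1] = _recombine(haps[p2, 0], haps[p2, 1], chrom, pos, cfg.recomb_rate, rng)
        return out

    for grp in ("A", "B"):
        for _ in range(cfg.n_generations):
            pops[grp] = next_generation(pops[grp], swept_idx[grp], cfg.selfing_rate)
        for _ in range(cfg.self_generations):
            pops[grp] = next_generation(pops[grp], [], 1.0)

    pick_a = rng.choice(pops["A"].shape[0], size=cfg.n_a, replace=False)
    pick_b = rng.choice(pops["B"].shape[0], size=cfg.n_b, replace=False)
    dosage = np.concatenate(
        [pops["A"][pick_a].sum(axis=1), pops["B"][pick_b].sum(axis=1)], axis=0
    ).astype(float)
    samples = [f"A{i + 1:03d}" for i in range(cfg.n_a)] + [f"B{i + 1:03d}" for i in range(cfg.n_b)]
    group = np.array(["A"] * cfg.n_a + ["B"] * cfg.n_b, dtype=object)
    bases = np.array(["A", "C", "G", "T"], dtype=object)
    ref = bases[rng.integers(0, 4, size=m)]
    alt_shift = rng.integers(1, 4, size=m)
    alt = bases[(np.searchsorted(bases, ref) + alt_shift) % 4]
    return GenotypeMatrix(samples, group, chrom, pos, ref, alt, dosage)


def simulate_phenotypes(g: GenotypeMatrix, cfg: SimConfig) -> pd.DataFrame:
    """Quantitative traits from planted QTLs at a target entry-mean heritability.

    Additive genetic value per line is the dosage-weighted sum of QTL
    effects.  Environment and residual noise are scaled so the realized
    broad-sense heritability on an entry-mean basis over
    ``cfg.n_environments`` environments matches ``cfg.h2_target``:
    sigma_e^2 = k * sigma_g^2 * (1 - H2) / H2.  Two replicates per
    environment are emitted; replicate-level and environment-level noise
    split the error variance so the per-environment entry mean carries
    sigma_e^2 in total.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    traits = sorted({t for *_x, t in cfg.qtl}) or ["T1"]
    site_index = {(int(c), int(p)): j for j, (c, p) in enumerate(zip(g.chrom, g.pos))}
    n = g.n_samples
    k = cfg.n_environments
    r = cfg.n_replicates

    records: list[dict] = []
    for trait in traits:
        gv = np.zeros(n)
        for c, p, eff, t in cfg.qtl:
            if t != trait:
                continue
            if (int(c), int(p)) not in site_index:
                raise ValueError(f"QTL position {c}:{p} absent from genotype matrix")
            d = g.dosage[:, site_index[(int(c), int(p))]]
            gv += eff * np.where(np.isnan(d), np.nanmean(d), d)
        var_g = float(np.var(gv))
        if cfg.h2_target == 0.0 and var_g > 0:
            raise ValueError("h2_target=0 is inconsistent with nonzero QTL effects")
        if var_g > 0 and cfg.h2_target > 0:
            var_e = k * var_g * (1.0 - cfg.h2_target) / cfg.h2_target
        else:
            var_e = 1.0  # no genetic signal: unit noise
        # split error: half at environment level, half at replicate level,
        # so the per-env entry mean variance is var_e in total
        sd_env = np.sqrt(var_e / 2.0)
        sd_rep = np.sqrt(var_e * r / 2.0)
        env_shift = rng.normal(0.0, 1.0, size=k) * np.sqrt(max(var_g, 1.0))
        for j in range(k):
            e_env = rng.normal(0.0, sd_env, size=n)
            for rep in range(1, r + 1):
                e_rep = rng.normal(0.0, sd_rep, size=n)
                y = cfg.trait_baseline + gv + env_shift[j] + e_env + e_rep
                for i, s in enumerate(g.samples):
                    records.append(
                        dict(sample_id=s, environment=f"E{j + 1}", trait=trait,
                             replicate=rep, value=y[i])
                    )
    return pd.DataFrame.from_records(records)


def simulate_expression(
    n_genes: int,
    n_samples: int,
    modules: list[tuple[int, float]],
    seed: int = 0,
    *,
    gene_ids: list[str] | None = None,
    mean: float = 5.0,
    scale: float = 2.0,
) -> pd.DataFrame:
    """Gene x sample expression with planted co-expression modules.

    Each planted module of ``(size, within_cor)`` shares one latent sample
    factor so member genes have pairwise Pearson correlation
    ``within_cor``; remaining genes are independent noise.  Values are
    shifted/scaled Gaussians clipped at zero, so the matrix is
    non-negative and contains exact zeros (exercising the downstream
    zero-replacement rule).
    """
    rng = np.random.default_rng(seed)
    total = sum(size for size, _ in modules)
    if total > n_genes:
        raise ValueError(f"module sizes sum to {total} > n_genes={n_genes}")
    for _, rho in modules:
        if not 0.0 <= rho <= 1.0:
            raise ValueError("within-module correlation must be in [0, 1]")

    z = np.empty((n_genes, n_samples))
    row = 0
    for size, rho in modules:
        factor = rng.normal(size=n_samples)
        noise = rng.normal(size=(size, n_samples))
        z[row : row + size] = np.sqrt(rho) * factor + np.sqrt(1.0 - rho) * noise
        row += size
    z[row:] = rng.normal(size=(n_genes - row, n_samples))

    x = np.clip(mean + scale * z, 0.0, None)
    ids = gene_ids or [f"gene{i + 1:05d}" for i in range(n_genes)]
    cols = [f"S{j + 1:03d}" for j in range(n_samples)]
    return pd.DataFrame(x, index=pd.Index(ids, name="gene_id"), columns=cols)


def simulate_genes(
    g: GenotypeMatrix,
    n_genes: int,
    seed: int = 0,
    *,
    length: int = 4000,
    chrom_len: int | None = None,
) -> list:
    """Random non-overlapping gene models on the chromosomes of ``g``."""
    from .io import GeneModel

    rng = np.random.default_rng(seed)
    chroms = np.unique(g.chrom)
    span = chrom_len or int(g.pos.max())
    genes = []
    per_chrom = np.full(chroms.size, n_genes // chroms.size)
    per_chrom[: n_genes % chroms.size] += 1
    gid = 0
    for c, cnt in zip(chroms, per_chrom):
        starts = np.sort(rng.choice(np.arange(1, max(span - length, 2), length * 2),
                                    size=min(cnt, max((span - length) // (length * 2), 1)),
                                    replace=False))
        for s in starts:
            gid += 1
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(f"gene{gid:05d}", int(c), int(s), int(s + length - 1), strand))
    return genes
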