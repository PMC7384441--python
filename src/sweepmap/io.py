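"""Genotype, annotation, phenotype and expression I/O.

Defines the in-memory containers shared by the whole pipeline and the
coordinate conventions: all genomic coordinates are 1-based inclusive
(VCF/GFF3 convention); analysis windows are ``[start, start + size - 1]``.

Genotypes are stored as alternate-allele dosages (0, 1, 2) with missing
calls kept as NaN.  Heterozygous calls in inbred lines are retained as
dosage 1 — residual heterozygosity is informative and no filter is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PHENOTYPE_COLUMNS = ["sample_id", "environment", "trait", "replicate", "value"]


# ---------------------------------------------------------------------------
# containers


@dataclass
class GenotypeMatrix:
    """Samples x biallelic sites dosage matrix with site metadata.

    Attributes
    ----------
    samples : list of str
        Line identifiers, one per row of ``dosage``.
    group : np.ndarray of str
        Per-sample subpopulation label (e.g. ``"A"`` / ``"B"``).
    chrom : np.ndarray of int
        Per-site chromosome id.
    pos : np.ndarray of int
        Per-site 1-based physical position (bp), sorted within chromosome.
    ref, alt : np.ndarray of str
        Per-site allele pair.
    dosage : np.ndarray of float, shape (n_samples, n_sites)
        Alternate-allele count per sample per site; NaN marks a missing call.
    """

    samples: list[str]
    group: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.group = np.asarray(self.group, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=np.int64)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.samples), self.pos.size):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {self.pos.size} sites"
            )
        if self.group.size != len(self.samples):
            raise ValueError("every sample needs a group label")
        ok = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = np.unique(self.dosage[~ok])
            raise ValueError(f"dosage values outside {{0,1,2,missing}}: {bad}")
        self._check_sorted()

    def _check_sorted(self) -> None:
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if p.size > 1 and not (np.diff(p) > 0).all():
                raise ValueError(f"positions not strictly increasing on chromosome {c}")

    # -- basic accessors ----------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return int(self.pos.size)

    @property
    def snp_ids(self) -> np.ndarray:
        """Per-site identifiers of the form ``{chrom}_{pos}``."""
        return np.array([f"{c}_{p}" for c, p in zip(self.chrom, self.pos)], dtype=object)

    def group_mask(self, label: str) -> np.ndarray:
        return self.group == label

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            samples=list(self.samples),
            group=self.group.copy(),
            chrom=self.chrom[index],
            pos=self.pos[index],
            ref=self.ref[index],
            alt=self.alt[index],
            dosage=self.dosage[:, index],
        )

    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in index],
            group=self.group[index],
            chrom=self.chrom.copy(),
            pos=self.pos.copy(),
            ref=self.ref.copy(),
            alt=self.alt.copy(),
            dosage=self.dosage[index, :],
        )

    def alt_freq(self, sample_mask: np.ndarray | None = None) -> np.ndarray:
        """Alternate-allele frequency per site from non-missing calls only."""
        d = self.dosage if sample_mask is None else self.dosage[sample_mask]
        with np.errstate(invalid="ignore"):
            n_alleles = 2.0 * np.sum(~np.isnan(d), axis=0)
            alt = np.nansum(d, axis=0)
            return np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)


@dataclass(frozen=True)
class GeneModel:
    """One gene feature: 1-based inclusive span on a chromosome."""

    gene_id: str
    chrom: int
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path: str, groups: dict[str, str], *, skip_multiallelic: bool = True) -> GenotypeMatrix:
    """Read a biallelic-SNP VCF into a :class:`GenotypeMatrix`.

    Parameters
    ----------
    path
        VCF 4.x file (uncompressed or bgzipped).
    groups
        Sample id -> group label; every sample in the VCF must be present.
    skip_multiallelic
        Skip records with more than one ALT allele (default) instead of
        raising.
    """
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    missing = [s for s in samples if s not in groups]
    if missing:
        raise KeyError(f"samples without a group label: {missing}")

    chroms: list[int] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    rows: list[np.ndarray] = []
    last: tuple[int, int] | None = None
    for rec in vcf:
        if len(rec.ALT) != 1:
            if skip_multiallelic:
                logger.info("skipping multiallelic record %s:%s", rec.CHROM, rec.POS)
                continue
            raise ValueError(f"multiallelic record at {rec.CHROM}:{rec.POS}")
        chrom = int(str(rec.CHROM).removeprefix("chr"))
        key = (chrom, rec.POS)
        if last is not None and key <= last and chrom == last[0]:
            raise ValueError(f"unsorted VCF record at {rec.CHROM}:{rec.POS}")
        last = key
        # gts012: 0/1/2 = alt dosage, 3 = missing
        gt = rec.gt_types.astype(float)
        gt[gt == 3] = np.nan
        chroms.append(chrom)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        rows.append(gt)

    dosage = np.array(rows, dtype=float).T if rows else np.empty((len(samples), 0))
    return GenotypeMatrix(
        samples=samples,
        group=np.array([groups[s] for s in samples], dtype=object),
        chrom=np.array(chroms, dtype=np.int64),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        dosage=dosage,
    )


def write_vcf(g: GenotypeMatrix, path: str) -> None:
    """Write a minimal VCF 4.2 with GT fields matching the dosage matrix."""
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in sorted(set(int(x) for x in np.unique(g.chrom))):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(g.samples) + "\n")
        for j in range(g.n_sites):
            calls = [
                "./." if np.isnan(d) else gt_map[float(d)] for d in g.dosage[:, j]
            ]
            fh.write(
                f"{g.chrom[j]}\t{g.pos[j]}\t{g.chrom[j]}_{g.pos[j]}\t"
                f"{g.ref[j]}\t{g.alt[j]}\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n"
            )


# ---------------------------------------------------------------------------
# filtering


def filter_maf(g: GenotypeMatrix, cutoff: float = 0.05) -> GenotypeMatrix:
    """Retain sites with minor allele frequency >= ``cutoff`` (inclusive).

    Frequency is computed from non-missing alleles only.  Sites with all
    calls missing are dropped and counted in the log.
    """
    if not 0.0 <= cutoff <= 0.5:
        raise ValueError(f"MAF cutoff must be in [0, 0.5], got {cutoff}")
    p = g.alt_freq()
    all_missing = np.isnan(p)
    if all_missing.any():
        logger.info("filter_maf: dropping %d sites with all calls missing", all_missing.sum())
    maf = np.minimum(p, 1.0 - p)
    keep = ~all_missing & (maf >= cutoff)
    logger.info("filter_maf: kept %d of %d sites at cutoff %g", keep.sum(), g.n_sites, cutoff)
    return g.take_sites(np.flatnonzero(keep))


# ---------------------------------------------------------------------------
# GFF3


def read_gff(path: str) -> list[GeneModel]:
    """Read gene features from a GFF3 file, keeping 1-based inclusive spans."""
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 tab-separated fields, got {len(parts)}")
            seqid, _source, ftype, start, end, _score, strand, _phase, attrs = parts
            if ftype != "gene":
                continue
            gene_id = None
            for item in attrs.split(";"):
                key, _, val = item.partition("=")
                if key.strip() == "ID":
                    gene_id = val.strip()
            if gene_id is None:
                raise ValueError(f"{path}:{lineno}: gene feature without ID attribute")
            if gene_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicated gene id {gene_id}")
            seen.add(gene_id)
            try:
                genes.append(
                    GeneModel(
                        gene_id=gene_id,
                        chrom=int(seqid.removeprefix("chr")),
                        start=int(start),
                        end=int(end),
                        strand=strand,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return genes


def write_gff(genes: list[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gm in genes:
            fh.write(
                f"{gm.chrom}\tsweepmap\tgene\t{gm.start}\t{gm.end}\t.\t{gm.strand}\t.\tID={gm.gene_id}\n"
            )


def genes_in_interval(genes: list[GeneModel], chrom: int, start: int, end: int) -> list[str]:
    """Gene ids whose span overlaps ``[start, end]`` by >= 1 bp on ``chrom``.

    Overlap, not containment: a gene partially inside the interval counts.
    Strand is ignored (regions are unstranded).
    """
    if start > end:
        raise ValueError(f"start {start} > end {end}")
    if not genes:
        return []
    chroms = np.array([gm.chrom for gm in genes])
    starts = np.array([gm.start for gm in genes])
    ends = np.array([gm.end for gm in genes])
    hit = (chroms == chrom) & (starts <= end) & (ends >= start)
    return [genes[i].gene_id for i in np.flatnonzero(hit)]


# ---------------------------------------------------------------------------
# phenotypes & expression


def validate_phenotypes(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format phenotype table.

    Required columns: sample_id, environment, trait, replicate, value.
    Setting-rate (SR) values must lie in [0, 1]; duplicate
    (sample, environment, trait, replicate) keys are rejected.
    """
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns: {missing}")
    key = ["sample_id", "environment", "trait", "replicate"]
    if df.duplicated(subset=key).any():
        dup = df[df.duplicated(subset=key, keep=False)].head()
        raise ValueError(f"duplicated phenotype keys, e.g.\n{dup}")
    sr = df.loc[df["trait"] == "SR", "value"]
    if ((sr < 0) | (sr > 1)).any():
        raise ValueError("SR values outside [0, 1]")
    return df


def read_phenotypes(path: str) -> pd.DataFrame:
    return validate_phenotypes(pd.read_csv(path))


def write_phenotypes(df: pd.DataFrame, path: str) -> None:
    validate_phenotypes(df).to_csv(path, index=False)


def entry_means(phen: pd.DataFrame, trait: str, environment: str | None = None) -> pd.Series:
    """Per-sample mean over replicates (and environments if env is None)."""
    sub = phen[phen["trait"] == trait]
    if environment is not None:
        sub = sub[sub["environment"] == environment]
    if sub.empty:
        raise ValueError(f"no phenotype records for trait={trait!r} env={environment!r}")
    return sub.groupby("sample_id")["value"].mean()


def read_expression(path: str) -> pd.DataFrame:
    """Gene x sample expression TSV with gene ids in the first column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")
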