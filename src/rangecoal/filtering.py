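"""RAD-SNP retention cascade.

Two nested datasets are produced from a multi-sample biallelic SNP matrix:

* the *complete* dataset — per locus with at most ``max_snps_per_locus``
  SNPs, one random SNP with missingness <= 50%, observed heterozygosity
  <= 50% and a minor allele carried by at least two individuals;
* the *reduced* dataset — additionally masking genotypes below a read
  coverage of 6, requiring every sampling site to retain at least two
  genotyped individuals per SNP, and dropping SNPs whose overall
  alternate-allele frequency is exactly 0.5 (their minor allele is
  undefined).

All boundary thresholds are inclusive. Each rejected SNP is attributed
to exactly one rule in a rejection log.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "FilterThresholds",
    "select_random_snp_per_locus",
    "filter_complete",
    "filter_reduced",
    "read_vcf",
    "read_popmap",
    "write_vcf",
]

# genotype codes
HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1


@dataclass
class GenotypeMatrix:
    """Diploid genotype calls with per-genotype coverage and sample labels.

    genotypes is (n_samples, n_snps) int8 with codes 0 = hom-ref,
    1 = het, 2 = hom-alt, -1 = missing; coverage is the matching read
    depth (only meaningful where the genotype is called).
    """

    samples: list[str]
    sites: np.ndarray  # (n_samples,) sampling-site label per sample
    demes: np.ndarray  # (n_samples,) deme label per sample
    loci: np.ndarray  # (n_snps,) RAD-locus ID per SNP
    snp_ids: np.ndarray  # (n_snps,) SNP identifier (e.g. chrom:pos)
    genotypes: np.ndarray  # (n_samples, n_snps) int8
    coverage: np.ndarray  # (n_samples, n_snps) int32
    positions: np.ndarray | None = None  # (n_snps,) 1-based position
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n, m = len(self.samples), len(self.loci)
        if self.genotypes.shape != (n, m):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} != ({n}, {m})"
            )
        if self.coverage.shape != (n, m):
            raise ValueError("coverage shape does not match genotypes")
        if len(self.sites) != n or len(self.demes) != n:
            raise ValueError("every sample needs exactly one site and one deme label")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.loci)

    def take_snps(self, idx: np.ndarray) -> "GenotypeMatrix":
        """Subset to the given SNP indices, preserving sample order."""
        return replace(
            self,
            loci=self.loci[idx],
            snp_ids=self.snp_ids[idx],
            genotypes=self.genotypes[:, idx],
            coverage=self.coverage[:, idx],
            positions=None if self.positions is None else self.positions[idx],
            meta=dict(self.meta),
        )

    def sites_by_deme(self) -> dict[str, list[str]]:
        """Ordered map deme -> its sampling sites (first-seen order)."""
        out: dict[str, list[str]] = {}
        for site, deme in zip(self.sites, self.demes):
            out.setdefault(deme, [])
            if site not in out[deme]:
                out[deme].append(site)
        return out


@dataclass(frozen=True)
class FilterThresholds:
    max_snps_per_locus: int = 10
    max_missing_fraction: float = 0.50
    max_obs_het: float = 0.50
    min_coverage: int = 6
    min_individuals_per_site: int = 2

    def __post_init__(self) -> None:
        for p in (self.max_missing_fraction, self.max_obs_het):
            if not 0.0 <= p <= 1.0:
                raise ValueError("proportions must lie in [0, 1]")
        for k in (self.max_snps_per_locus, self.min_coverage, self.min_individuals_per_site):
            if k < 1:
                raise ValueError("integer thresholds must be >= 1")


def _allele_stats(genotypes: np.ndarray):
    """Per-SNP call counts, het fraction, allele copy counts, carrier counts."""
    called = genotypes != MISSING
    n_called = called.sum(axis=0)
    het = genotypes == HET
    with np.errstate(invalid="ignore", divide="ignore"):
        hobs = np.where(n_called > 0, het.sum(axis=0) / np.maximum(n_called, 1), 1.0)
    alt_copies = het.sum(axis=0) + 2 * (genotypes == HOM_ALT).sum(axis=0)
    ref_copies = 2 * n_called - alt_copies
    carriers_alt = ((genotypes == HET) | (genotypes == HOM_ALT)).sum(axis=0)
    carriers_ref = ((genotypes == HET) | (genotypes == HOM_REF)).sum(axis=0)
    return n_called, hobs, alt_copies, ref_copies, carriers_alt, carriers_ref


def _per_snp_complete_flags(gm: GenotypeMatrix, th: FilterThresholds):
    """Qualifying flags for the complete dataset plus per-SNP failure rule."""
    n = gm.n_samples
    n_called, hobs, alt, ref, c_alt, c_ref = _allele_stats(gm.genotypes)
    miss_frac = 1.0 - n_called / n

    # minor-allele carriers; on an exact copy-count tie both alleles must
    # be carried by >= 2 individuals for the SNP to count as non-singleton
    minor_carriers = np.where(
        alt < ref, c_alt, np.where(ref < alt, c_ref, np.minimum(c_alt, c_ref))
    )
    rule = np.full(gm.n_snps, "", dtype=object)
    ok_miss = miss_frac <= th.max_missing_fraction
    ok_het = hobs <= th.max_obs_het
    ok_sing = minor_carriers >= 2
    rule[~ok_sing] = "singleton"
    rule[~ok_het] = "heterozygosity"
    rule[~ok_miss] = "missingness"
    return ok_miss & ok_het & ok_sing, rule


def select_random_snp_per_locus(
    gm: GenotypeMatrix,
    max_snps: int = 10,
    seed: int = 0,
    th: FilterThresholds = FilterThresholds(),
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Retain one random qualifying SNP per locus.

    Loci carrying more than ``max_snps`` SNPs are dropped entirely; among
    the remaining locus's SNPs that individually pass the complete-dataset
    per-SNP criteria, exactly one is drawn uniformly. Returns the reduced
    matrix and a per-SNP rejection log (columns snp, locus, rule).
    """
    loci = np.asarray(gm.loci)
    for j, loc in enumerate(loci):
        if loc is None or (isinstance(loc, str) and loc == ""):
            raise ValueError(f"SNP {gm.snp_ids[j]} has no locus annotation")

    rng = np.random.default_rng(seed)
    qual, rule = _per_snp_complete_flags(gm, th)

    order = {}
    for j, loc in enumerate(loci):
        order.setdefault(loc, []).append(j)

    keep: list[int] = []
    log: list[tuple[str, str, str]] = []
    for loc, idx in order.items():
        if len(idx) > max_snps:
            for j in idx:
                log.append((gm.snp_ids[j], str(loc), "locus_too_many_snps"))
            continue
        q = [j for j in idx if qual[j]]
        for j in idx:
            if not qual[j]:
                log.append((gm.snp_ids[j], str(loc), rule[j]))
        if not q:
            continue
        chosen = q[rng.integers(len(q))] if len(q) > 1 else q[0]
        keep.append(chosen)
        for j in q:
            if j != chosen:
                log.append((gm.snp_ids[j], str(loc), "not_selected"))

    keep_idx = np.array(sorted(keep), dtype=np.int64)
    out = gm.take_snps(keep_idx)
    out.meta["filter_seed"] = seed
    return out, pd.DataFrame(log, columns=["snp", "locus", "rule"])


def filter_complete(
    gm: GenotypeMatrix,
    th: FilterThresholds = FilterThresholds(),
    seed: int = 0,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Build the complete dataset: per-SNP quality rules + one SNP per locus."""
    out, log = select_random_snp_per_locus(gm, th.max_snps_per_locus, seed, th)
    if out.n_snps == 0:
        warnings.warn("complete-dataset filter retained zero SNPs", stacklevel=2)
    return out, log


def filter_reduced(
    gm: GenotypeMatrix,
    th: FilterThresholds = FilterThresholds(),
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Build the reduced dataset from a complete-filtered matrix.

    Genotypes below ``min_coverage`` are set missing, then every sampling
    site must retain >= ``min_individuals_per_site`` called individuals at
    each SNP, and SNPs with an overall alternate-allele frequency of
    exactly 0.5 (minor allele undefined) are removed.
    """
    sites = np.asarray(gm.sites)
    site_labels, site_counts = np.unique(sites, return_counts=True)
    too_small = site_labels[site_counts < th.min_individuals_per_site]
    if too_small.size:
        raise ValueError(
            f"sampling site(s) {list(too_small)} have fewer than "
            f"{th.min_individuals_per_site} samples and can never pass the presence rule"
        )

    genotypes = gm.genotypes.copy()
    low = (genotypes != MISSING) & (gm.coverage < th.min_coverage)
    genotypes[low] = MISSING

    called = genotypes != MISSING
    presence_ok = np.ones(gm.n_snps, dtype=bool)
    for lab in site_labels:
        presence_ok &= called[sites == lab].sum(axis=0) >= th.min_individuals_per_site

    # MAF-exactly-0.5 on integer copy counts (2*alt == total), never on floats
    _, _, alt, ref, _, _ = _allele_stats(genotypes)
    total = alt + ref
    maf_half = (total > 0) & (2 * alt == total)

    keep = presence_ok & ~maf_half
    log: list[tuple[str, str, str]] = []
    for j in np.flatnonzero(~keep):
        rule = "site_presence" if not presence_ok[j] else "maf_half"
        log.append((gm.snp_ids[j], str(gm.loci[j]), rule))

    out = replace(gm, genotypes=genotypes, meta=dict(gm.meta))
    out = out.take_snps(np.flatnonzero(keep))
    if out.n_snps == 0:
        warnings.warn("reduced-dataset filter retained zero SNPs", stacklevel=2)
    return out, pd.DataFrame(log, columns=["snp", "locus", "rule"])


# ---------------------------------------------------------------------------
# I/O


def read_popmap(path) -> pd.DataFrame:
    """Read a 3-column TSV ``sample<TAB>site<TAB>deme``."""
    pm = pd.read_csv(path, sep="\t", header=None, names=["sample", "site", "deme"], dtype=str)
    if pm.isna().any().any():
        raise ValueError(f"popmap {path} must have 3 tab-separated columns")
    return pm


def read_vcf(vcf_path, popmap, locus_regex: str | None = None) -> GenotypeMatrix:
    """Load biallelic SNPs from a VCF plus a population map.

    The RAD-locus ID defaults to CHROM; if ``locus_regex`` is given it is
    applied to the ID column and the first capture group used instead.
    """
    from cyvcf2 import VCF

    pm = popmap if isinstance(popmap, pd.DataFrame) else read_popmap(popmap)
    vcf = VCF(str(vcf_path))
    vcf_samples = list(vcf.samples)
    pm = pm.set_index("sample")
    missing = [s for s in vcf_samples if s not in pm.index]
    if missing:
        raise ValueError(f"samples in VCF absent from popmap: {missing}")
    sites = pm.loc[vcf_samples, "site"].to_numpy()
    demes = pm.loc[vcf_samples, "deme"].to_numpy()

    pattern = re.compile(locus_regex) if locus_regex else None
    gts, covs, loci, snp_ids, pos = [], [], [], [], []
    # cyvcf2 gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
    code = np.array([HOM_REF, HET, MISSING, HOM_ALT], dtype=np.int8)
    for v in vcf:
        if len(v.ALT) != 1:
            warnings.warn(f"skipping non-biallelic record at {v.CHROM}:{v.POS}", stacklevel=2)
            continue
        gts.append(code[v.gt_types])
        dp = v.format("DP")
        if dp is None:
            covs.append(np.zeros(len(vcf_samples), dtype=np.int32))
        else:
            dp = dp.reshape(-1).astype(np.int64)
            covs.append(np.where(dp < 0, 0, dp))
        if pattern is not None:
            m = pattern.search(v.ID or "")
            if not m:
                raise ValueError(f"locus regex failed on ID {v.ID!r} at {v.CHROM}:{v.POS}")
            loci.append(m.group(1))
        else:
            loci.append(v.CHROM)
        snp_ids.append(f"{v.CHROM}:{v.POS}")
        pos.append(v.POS)
    vcf.close()

    n_snps = len(loci)
    genotypes = (
        np.stack(gts, axis=1).astype(np.int8)
        if n_snps
        else np.zeros((len(vcf_samples), 0), np.int8)
    )
    coverage = (
        np.stack(covs, axis=1).astype(np.int32)
        if n_snps
        else np.zeros((len(vcf_samples), 0), np.int32)
    )
    return GenotypeMatrix(
        samples=vcf_samples,
        sites=sites,
        demes=demes,
        loci=np.array(loci, dtype=object),
        snp_ids=np.array(snp_ids, dtype=object),
        genotypes=genotypes,
        coverage=coverage,
        positions=np.array(pos, dtype=np.int64),
    )


_GT_STR = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a minimal VCFv4.2 with GT:DP fields (one record per SNP)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        seed = gm.meta.get("filter_seed")
        if seed is not None:
            fh.write(f"##rangecoal_filter_seed={seed}\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read Depth">\n')
        for loc in dict.fromkeys(gm.loci):
            fh.write(f"##contig=<ID={loc}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        for j in range(gm.n_snps):
            p = int(gm.positions[j]) if gm.positions is not None else j + 1
            cells = [
                f"{_GT_STR[int(gm.genotypes[i, j])]}:{int(gm.coverage[i, j])}"
                for i in range(gm.n_samples)
            ]
            fh.write(
                f"{gm.loci[j]}\t{p}\t{gm.snp_ids[j]}\tA\tT\t.\tPASS\t.\tGT:DP\t"
                + "\t".join(cells)
                + "\n"
            )
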