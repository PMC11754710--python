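"""Synthetic RAD-like genotype datasets with known generating truth.

Emulates the statistical structure of the reduced RAD dataset the
analysis expects: 4 demes sampled at 15 sites (Pgal 3, Pnig 4, PspE 6,
PspW 2) with 3-4 diploids each, ~12,486 biallelic SNPs (one per locus),
per-genotype missingness and overdispersed per-genotype read coverage.
Haplotypes are simulated under an explicit demographic model, so every
downstream stage (filtering, SFS construction, fitting) can be tested
against a known truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .demography import DemographicModel
from .engine import expected_pair_sfs, sample_snp_patterns
from .filtering import GenotypeMatrix
from .sfs import Folded2DSFS

__all__ = ["SyntheticConfig", "generate_dataset", "pseudoreplicate_sfs", "write_popmap"]

DEFAULT_SITES_PER_DEME = {"Pgal": 3, "Pnig": 4, "PspE": 6, "PspW": 2}


@dataclass
class SyntheticConfig:
    """Study-design and noise parameters of a synthetic dataset.

    ``model``/``true_params`` define the generating demography. The deme
    sample layout defaults to the reduced-dataset design; per-genotype
    missingness is independent Bernoulli (site_dropout switches to
    whole-site locus dropout to stress the presence filter) and coverage
    follows a negative binomial with the given mean and fixed dispersion,
    so the coverage >= 6 rule is actually exercised.
    """

    model: DemographicModel
    true_params: dict
    n_snps: int = 12_486
    sites_per_deme: dict = field(default_factory=lambda: dict(DEFAULT_SITES_PER_DEME))
    diploids_per_site: int = 4
    missing_rate: float = 0.10
    coverage_mean: float = 20.0
    coverage_dispersion: float = 5.0  # negative-binomial size parameter
    site_dropout: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps <= 0:
            raise ValueError("n_snps must be positive")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must lie in [0, 1]")
        if not 3 <= self.diploids_per_site <= 4:
            raise ValueError("diploids_per_site must be 3 or 4")


def generate_dataset(cfg: SyntheticConfig) -> tuple[GenotypeMatrix, dict]:
    """Simulate a genotype matrix plus a truth record.

    Each SNP comes from its own genealogy (one SNP per RAD locus);
    haplotypes are paired into diploids site by site. The model's haploid
    sample sizes must equal 2 * diploids_per_site * sites_per_deme for
    each deme so that every sampled haplotype maps to a chromosome.
    Deterministic under ``cfg.seed``.
    """
    model = cfg.model
    demes = model.deme_names
    hap_per_site = 2 * cfg.diploids_per_site
    expect_ns = {d: hap_per_site * cfg.sites_per_deme[d] for d in demes}
    actual_ns = model.sample_sizes
    for d in demes:
        if actual_ns[d] != expect_ns[d]:
            raise ValueError(
                f"model samples {actual_ns[d]} haploids in {d}, but the study design "
                f"needs {expect_ns[d]} (= {hap_per_site} x {cfg.sites_per_deme[d]} sites)"
            )

    patterns = sample_snp_patterns(
        model, cfg.true_params, cfg.n_snps, seed=cfg.seed, per_haplotype=True
    )  # (n_snps, total haplotypes) 0/1
    hap = patterns.T  # (n_hap, n_snps)

    rng = np.random.default_rng(cfg.seed + 1)
    samples, sites, deme_labels = [], [], []
    for d in demes:
        for s in range(cfg.sites_per_deme[d]):
            for i in range(cfg.diploids_per_site):
                samples.append(f"{d}_s{s + 1}_i{i + 1}")
                sites.append(f"{d}-{s + 1}")
                deme_labels.append(d)
    n_ind = len(samples)

    # haplotypes are already grouped by deme in model order; pair consecutively
    genotypes = (hap[0::2] + hap[1::2]).astype(np.int8)  # 0/1/2 alt copies

    cover = rng.negative_binomial(
        cfg.coverage_dispersion,
        cfg.coverage_dispersion / (cfg.coverage_dispersion + cfg.coverage_mean),
        size=genotypes.shape,
    ).astype(np.int32)

    if cfg.site_dropout:
        # whole sampling site loses a locus at once
        site_arr = np.array(sites)
        miss = np.zeros(genotypes.shape, dtype=bool)
        for lab in dict.fromkeys(sites):
            drop = rng.random(cfg.n_snps) < cfg.missing_rate
            miss[site_arr == lab] |= drop[None, :]
    else:
        miss = rng.random(genotypes.shape) < cfg.missing_rate
    genotypes = np.where(miss, np.int8(-1), genotypes)
    cover = np.where(miss, 0, cover)

    loci = np.array([f"locus_{j + 1}" for j in range(cfg.n_snps)], dtype=object)
    gm = GenotypeMatrix(
        samples=samples,
        sites=np.array(sites, dtype=object),
        demes=np.array(deme_labels, dtype=object),
        loci=loci,
        snp_ids=np.array([f"locus_{j + 1}:10" for j in range(cfg.n_snps)], dtype=object),
        genotypes=genotypes,
        coverage=cover,
        positions=np.full(cfg.n_snps, 10, dtype=np.int64),
        meta={"synthetic_seed": cfg.seed},
    )
    truth = {
        "model": model.name,
        "submodel": model.submodel,
        "params": {k: float(v) for k, v in model.bind(cfg.true_params).items()},
        "n_snps": cfg.n_snps,
        "seed": cfg.seed,
        "n_individuals": n_ind,
    }
    return gm, truth


def pseudoreplicate_sfs(
    model: DemographicModel,
    params,
    n_snps,
    seed: int = 0,
    n_sims: int = 100_000,
    direct: bool = False,
) -> list[Folded2DSFS]:
    """Simulate one pseudoreplicate set of observed pairwise spectra.

    By default draws multinomial counts per pair from the model's masked
    expected SFS (``n_snps`` may be an int applied to all pairs or a
    per-pair sequence); with ``direct=True`` each SNP is simulated
    individually instead. Deterministic under ``seed``.
    """
    exp = expected_pair_sfs(model, params, n_sims=n_sims, seed=seed)
    rng = np.random.default_rng(seed)
    if np.isscalar(n_snps):
        n_snps = [int(n_snps)] * len(exp)
    if direct:
        from .engine import pair_sfs_counts

        ns = [d.sample_n for d in model.demes]
        out = []
        for e, n in zip(exp, n_snps):
            patterns = sample_snp_patterns(model, params, int(n), seed=seed)
            mats, pairs = pair_sfs_counts(patterns, ns)
            names = model.deme_names
            k = pairs.index((names.index(e.deme_a), names.index(e.deme_b)))
            out.append(
                Folded2DSFS(
                    deme_a=e.deme_a, deme_b=e.deme_b, n_a=e.n_a, n_b=e.n_b,
                    counts=mats[k], mask=e.mask, seed=seed,
                    meta={"kind": "pseudoreplicate", "mode": "direct"},
                )
            )
        return out
    out = []
    for e, n in zip(exp, n_snps):
        p = e.counts[~e.mask]
        counts = np.zeros_like(e.counts)
        counts[~e.mask] = rng.multinomial(n, p / p.sum())
        out.append(
            Folded2DSFS(
                deme_a=e.deme_a, deme_b=e.deme_b, n_a=e.n_a, n_b=e.n_b,
                counts=counts, mask=e.mask, seed=seed,
                meta={"kind": "pseudoreplicate"},
            )
        )
    return out


def write_popmap(gm: GenotypeMatrix, path) -> None:
    """Write the 3-column popmap TSV matching a genotype matrix."""
    with open(path, "w") as fh:
        for s, site, d in zip(gm.samples, gm.sites, gm.demes):
            fh.write(f"{s}\t{site}\t{d}\n")


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1)
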