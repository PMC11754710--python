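"""Folded joint (2D) site frequency spectra from genotype matrices.

Missing data are removed by downsampling: at every SNP, each sampling
site contributes exactly four haploid alleles drawn uniformly without
replacement from that site's present alleles. A site whose present-allele
pool is smaller than four makes the SNP unusable for any deme containing
that site. Haploid sample sizes are therefore always 4 x (number of
sampling sites in the deme).

Each deme pair gets its own spectrum, folded on that pair's pooled minor
allele. Cells that are ignored during likelihood computation (the
monomorphic corner and the singleton diagonal, plus the structurally
unreachable major-allele region) carry a boolean mask.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np

from .filtering import MISSING, GenotypeMatrix

__all__ = [
    "Folded2DSFS",
    "fold_pattern",
    "fold_counts_vec",
    "folded_mask",
    "downsample_site",
    "site_allele_pools",
    "draw_site_blocks",
    "build_folded_2d_sfs",
    "all_pair_sfs",
    "write_obs",
    "read_obs",
]


def fold_pattern(c_a: int, c_b: int, n_a: int, n_b: int) -> tuple[int, int]:
    """Fold a joint derived-count pattern onto the pair's minor allele.

    Patterns with pooled count above half the pooled sample size are
    complemented; exact ties are stored at the lexicographically smaller
    of the two images (deterministic tie-break).
    """
    s2 = 2 * (c_a + c_b)
    S = n_a + n_b
    if s2 > S:
        return (n_a - c_a, n_b - c_b)
    if s2 == S:
        return min((c_a, c_b), (n_a - c_a, n_b - c_b))
    return (c_a, c_b)


def fold_counts_vec(c_a: np.ndarray, c_b: np.ndarray, n_a: int, n_b: int):
    """Vectorised :func:`fold_pattern` over arrays of joint counts."""
    c_a = np.asarray(c_a)
    c_b = np.asarray(c_b)
    S = n_a + n_b
    s2 = 2 * (c_a + c_b)
    comp_a, comp_b = n_a - c_a, n_b - c_b
    flip = s2 > S
    tie_flip = (s2 == S) & ((comp_a < c_a) | ((comp_a == c_a) & (comp_b < c_b)))
    flip = flip | tie_flip
    return np.where(flip, comp_a, c_a), np.where(flip, comp_b, c_b)


def folded_mask(n_a: int, n_b: int) -> np.ndarray:
    """Boolean (n_a+1, n_b+1) matrix of ignored cells (True = masked).

    Masked: the monomorphic corner (0,0) (which is also the fold-image of
    the all-derived corner), all singleton cells i+j = 1, and every cell
    outside the folded minor-allele region (structurally zero).
    """
    i = np.arange(n_a + 1)[:, None]
    j = np.arange(n_b + 1)[None, :]
    s = i + j
    S = n_a + n_b
    mask = (s <= 1) | (2 * s > S)
    # on the tie diagonal only the lexicographically smaller image is kept
    tie = 2 * s == S
    larger = (i > n_a - i) | ((i == n_a - i) & (j > n_b - j))
    mask |= tie & larger
    return mask


@dataclass
class Folded2DSFS:
    """Pairwise folded SFS: SNP counts indexed by (minor count in a, in b)."""

    deme_a: str
    deme_b: str
    n_a: int
    n_b: int
    counts: np.ndarray  # (n_a+1, n_b+1) float64
    mask: np.ndarray = None  # True = ignored cell
    n_skipped: int = 0
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.counts.shape != (self.n_a + 1, self.n_b + 1):
            raise ValueError(
                f"counts shape {self.counts.shape} != ({self.n_a + 1}, {self.n_b + 1})"
            )
        if self.mask is None:
            self.mask = folded_mask(self.n_a, self.n_b)
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.deme_a, self.deme_b)

    def total(self) -> float:
        """Total SNP count over all cells (masked included)."""
        return float(self.counts.sum())

    def unmasked_total(self) -> float:
        return float(self.counts[~self.mask].sum())


def downsample_site(calls: np.ndarray, k: int = 4, rng=None) -> np.ndarray | None:
    """Draw ``k`` haploid alleles without replacement from one site's calls.

    ``calls`` are the site's diploid genotype codes at one SNP; each
    non-missing call contributes two alleles to the pool. Returns an
    allele array of length k, or None when fewer than k present alleles
    exist (the SNP is then unusable for any pair involving this site).
    """
    if k <= 0:
        raise ValueError("k must be positive")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    calls = np.asarray(calls)
    pool: list[int] = []
    for g in calls:
        if g == MISSING:
            continue
        pool.extend((0, 0) if g == 0 else (0, 1) if g == 1 else (1, 1))
    if len(pool) < k:
        return None
    idx = rng.choice(len(pool), size=k, replace=False)
    return np.asarray(pool, dtype=np.int8)[idx]


def site_allele_pools(gm: GenotypeMatrix, site: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP (alt copies, pool size) for one sampling site."""
    sel = np.asarray(gm.sites) == site
    if not sel.any():
        raise ValueError(f"unknown sampling site {site!r}")
    g = gm.genotypes[sel]
    called = g != MISSING
    alt = (g == 1).sum(axis=0) + 2 * (g == 2).sum(axis=0)
    return alt.astype(np.int64), (2 * called.sum(axis=0)).astype(np.int64)


def draw_site_blocks(gm: GenotypeMatrix, k: int = 4, seed: int = 0) -> dict[str, np.ndarray]:
    """One downsampling realisation: per site, per SNP, the alt-allele count
    in a k-allele block (or -1 where the pool is too small).

    Drawing k alleles without replacement from a pool of ``m`` alleles of
    which ``a`` are alternate yields a hypergeometric alt count; block
    composition is all the spectrum needs, so blocks are stored as counts.
    """
    rng = np.random.default_rng(seed)
    blocks: dict[str, np.ndarray] = {}
    for site in dict.fromkeys(gm.sites):
        alt, m = site_allele_pools(gm, site)
        ok = m >= k
        out = np.full(gm.n_snps, -1, dtype=np.int64)
        if ok.any():
            out[ok] = rng.hypergeometric(alt[ok], m[ok] - alt[ok], k)
        blocks[site] = out
    return blocks


def _pair_sfs_from_blocks(
    gm: GenotypeMatrix,
    deme_a: str,
    deme_b: str,
    blocks: dict[str, np.ndarray],
    k: int,
    seed: int | None,
) -> Folded2DSFS:
    by_deme = gm.sites_by_deme()
    for d in (deme_a, deme_b):
        if d not in by_deme or not by_deme[d]:
            raise ValueError(f"deme {d!r} has zero sampling sites")
    sites_a, sites_b = by_deme[deme_a], by_deme[deme_b]
    n_a, n_b = k * len(sites_a), k * len(sites_b)

    stack_a = np.stack([blocks[s] for s in sites_a])
    stack_b = np.stack([blocks[s] for s in sites_b])
    usable = (stack_a >= 0).all(axis=0) & (stack_b >= 0).all(axis=0)
    c_a = stack_a.sum(axis=0)[usable]
    c_b = stack_b.sum(axis=0)[usable]

    i, j = fold_counts_vec(c_a, c_b, n_a, n_b)

    counts = np.zeros((n_a + 1, n_b + 1))
    np.add.at(counts, (i, j), 1.0)
    return Folded2DSFS(
        deme_a=deme_a,
        deme_b=deme_b,
        n_a=n_a,
        n_b=n_b,
        counts=counts,
        n_skipped=int(gm.n_snps - usable.sum()),
        seed=seed,
    )


def build_folded_2d_sfs(
    gm: GenotypeMatrix, deme_a: str, deme_b: str, seed: int = 0, k: int = 4, n_draws: int = 1
) -> Folded2DSFS:
    """Folded joint SFS for one deme pair from one (default) or the average
    of several downsampling realisations."""
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    out = None
    for d in range(n_draws):
        blocks = draw_site_blocks(gm, k=k, seed=seed + d)
        s = _pair_sfs_from_blocks(gm, deme_a, deme_b, blocks, k, seed)
        if out is None:
            out = s
        else:
            out.counts += s.counts
            out.n_skipped += s.n_skipped
    if n_draws > 1:
        out.counts /= n_draws
        out.n_skipped = out.n_skipped // n_draws
    return out


def all_pair_sfs(
    gm: GenotypeMatrix, demes: list[str] | None = None, seed: int = 0, k: int = 4
) -> list[Folded2DSFS]:
    """All C(D,2) pairwise spectra sharing a single downsampling draw.

    The same per-site block at each SNP feeds every pair, so the spectra
    are mutually consistent realisations of the same downsampled dataset.
    """
    if demes is None:
        demes = list(dict.fromkeys(gm.demes))
    if len(demes) < 2:
        raise ValueError("need at least 2 demes for pairwise spectra")
    blocks = draw_site_blocks(gm, k=k, seed=seed)
    return [
        _pair_sfs_from_blocks(gm, a, b, blocks, k, seed)
        for a, b in itertools.combinations(demes, 2)
    ]


# ---------------------------------------------------------------------------
# fastsimcoal-dialect observed-SFS text files


def write_obs(sfs: Folded2DSFS, path, sidecar: bool = True) -> None:
    """Write a pairwise observed SFS in the joint-minor-allele text dialect.

    Rows are indexed by the second deme (d1), columns by the first (d0),
    matching the ``*_jointMAFpop1_0.obs`` layout. A JSON sidecar records
    sample sizes, the ignore-mask and the downsampling seed.
    """
    path = str(path)
    with open(path, "w") as fh:
        fh.write("1 observations\n")
        fh.write("\t" + "\t".join(f"d0_{i}" for i in range(sfs.n_a + 1)) + "\n")
        for j in range(sfs.n_b + 1):
            row = "\t".join(f"{sfs.counts[i, j]:g}" for i in range(sfs.n_a + 1))
            fh.write(f"d1_{j}\t{row}\n")
    if sidecar:
        meta = {
            "deme_a": sfs.deme_a,
            "deme_b": sfs.deme_b,
            "n_a": sfs.n_a,
            "n_b": sfs.n_b,
            "seed": sfs.seed,
            "n_skipped": sfs.n_skipped,
            "mask": sfs.mask.astype(int).tolist(),
        }
        with open(path + ".json", "w") as fh:
            json.dump(meta, fh, indent=1)


def read_obs(path, deme_a: str = "pop0", deme_b: str = "pop1") -> Folded2DSFS:
    """Read a pairwise observed SFS written by :func:`write_obs`."""
    import os

    path = str(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    rows = [ln.split("\t")[1:] for ln in lines[2:]]
    counts = np.array(rows, dtype=float).T  # back to (a, b) indexing
    n_a, n_b = counts.shape[0] - 1, counts.shape[1] - 1
    kw: dict = {}
    if os.path.exists(path + ".json"):
        with open(path + ".json") as fh:
            meta = json.load(fh)
        deme_a, deme_b = meta["deme_a"], meta["deme_b"]
        kw = {
            "seed": meta.get("seed"),
            "n_skipped": meta.get("n_skipped", 0),
            "mask": np.array(meta["mask"], dtype=bool),
        }
    return Folded2DSFS(deme_a=deme_a, deme_b=deme_b, n_a=n_a, n_b=n_b, counts=counts, **kw)
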