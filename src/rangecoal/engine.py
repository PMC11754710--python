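"""Structured-coalescent simulation of unlinked biallelic SNPs.

Each SNP is generated from its own genealogy (unlinked-sites assumption,
matching the one-SNP-per-locus data): a continuous-time structured
coalescent runs backwards through the model's event schedule, then a
single mutation is placed uniformly on total branch length, so every
simulated site is segregating by construction. In the low-mutation-rate
limit a segregating site's genealogy is size-biased by total branch
length, so the expected SFS accumulates every branch of every genealogy
weighted by its length (which also has lower Monte Carlo variance than
one pattern per genealogy), and SNP-pattern sampling draws genealogies
with probability proportional to their total length.

Within deme d of diploid size N_d each lineage pair coalesces at rate
1/(2 N_d) per generation; lineages migrate i -> j at the backward rate
m[i][j]; a merge moves all source lineages to the destination deme; an
admixture founding sends each hybrid lineage to parent_a with
probability alpha, else parent_b. Migration to and from a deme is shut
off once that deme becomes extinct (backwards in time).

The batch path is compiled with numba; :func:`simulate_genealogy`
provides an explicit per-genealogy object for inspection and tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .demography import (
    AdmixtureEvent,
    DemographicModel,
    MergeEvent,
    SizeChangeEvent,
    eval_expr,
    validate_event_order,
)
from .sfs import Folded2DSFS, fold_counts_vec, folded_mask

__all__ = [
    "Genealogy",
    "CompiledModel",
    "compile_model",
    "simulate_genealogy",
    "simulate_site_patterns",
    "sample_snp_patterns",
    "drop_snp",
    "expected_pair_sfs",
    "expected_folded_sfs_1d",
    "pair_sfs_counts",
]

MAX_TIME = 1e9  # absorbing-state safeguard (generations)
EV_MERGE, EV_ADMIX, EV_SIZE = 0, 1, 2


# ---------------------------------------------------------------------------
# model compilation


@dataclass
class CompiledModel:
    """Array form of a bound demographic model, ready for the kernel."""

    deme_names: list[str]
    ns: np.ndarray  # haploid sample size per deme
    N0: np.ndarray  # present diploid size per deme
    mig0: np.ndarray  # base backward migration matrix
    ev_t: np.ndarray
    ev_type: np.ndarray
    ev_a: np.ndarray
    ev_b: np.ndarray
    ev_p: np.ndarray
    env: dict = field(default_factory=dict)


def compile_model(model: DemographicModel, params) -> CompiledModel:
    """Bind a parameter vector and lower the model to plain arrays.

    Raises on event-order violations so the kernel only ever sees valid
    schedules.
    """
    violations = validate_event_order(model, params)
    if violations:
        raise ValueError("invalid parameter vector:\n" + "\n".join(violations))
    env = model.bind(params)
    names = model.deme_names
    idx = {n: i for i, n in enumerate(names)}
    D = len(names)

    ns = np.array([d.sample_n for d in model.demes], dtype=np.int64)
    N0 = np.array([eval_expr(d.N, env) for d in model.demes], dtype=np.float64)
    mig0 = model.migration_matrix(env)

    events = model.concrete_events(env)
    E = len(events)
    ev_t = np.zeros(E)
    ev_type = np.zeros(E, dtype=np.int64)
    ev_a = np.zeros(E, dtype=np.int64)
    ev_b = np.zeros(E, dtype=np.int64)
    ev_p = np.zeros(E)
    for i, ev in enumerate(events):
        ev_t[i] = ev.t
        if isinstance(ev, MergeEvent):
            ev_type[i] = EV_MERGE
            ev_a[i], ev_b[i] = idx[ev.source], idx[ev.dest]
        elif isinstance(ev, AdmixtureEvent):
            ev_type[i] = EV_ADMIX
            # hybrid in the low byte, parent_b in the high byte of ev_a
            ev_a[i] = idx[ev.hybrid] + (idx[ev.parent_b] << 8)
            ev_b[i] = idx[ev.parent_a]
            ev_p[i] = ev.alpha
        else:
            ev_type[i] = EV_SIZE
            ev_a[i] = idx[ev.deme]
            ev_p[i] = ev.new_N
    return CompiledModel(names, ns, N0, mig0, ev_t, ev_type, ev_a, ev_b, ev_p, env)


# ---------------------------------------------------------------------------
# numba kernel


@njit(cache=True)
def _sim_patterns_kernel(
    ns, group, G, N0, mig0, ev_t, ev_type, ev_a, ev_b, ev_p, n_sims, seed,
    out_pat, out_tmrca, out_tbl,
):
    np.random.seed(seed)
    D = ns.shape[0]
    ntot = 0
    for d in range(D):
        ntot += ns[d]
    E = ev_t.shape[0]

    lin_deme = np.empty(ntot, np.int64)
    lin_birth = np.empty(ntot, np.float64)
    lin_cnt = np.empty((ntot, G), np.int64)
    br_len = np.empty(2 * ntot, np.float64)
    br_cnt = np.empty((2 * ntot, G), np.int64)
    k = np.empty(D, np.int64)
    N = np.empty(D, np.float64)
    mig = np.empty((D, D), np.float64)
    rowsum = np.empty(D, np.float64)

    for s in range(n_sims):
        # reset state
        li = 0
        for d in range(D):
            k[d] = ns[d]
            N[d] = N0[d]
            for _ in range(ns[d]):
                lin_deme[li] = d
                lin_birth[li] = 0.0
                for g in range(G):
                    lin_cnt[li, g] = 0
                lin_cnt[li, group[li]] = 1
                li += 1
        for i in range(D):
            rs = 0.0
            for j in range(D):
                mig[i, j] = mig0[i, j]
                rs += mig0[i, j]
            rowsum[i] = rs

        n_active = ntot
        nbr = 0
        t = 0.0
        ei = 0

        while n_active > 1:
            coal_tot = 0.0
            mig_tot = 0.0
            for d in range(D):
                coal_tot += k[d] * (k[d] - 1) / (4.0 * N[d])
                mig_tot += k[d] * rowsum[d]
            R = coal_tot + mig_tot

            if R > 0.0:
                dt = -np.log(np.random.random()) / R
            else:
                dt = np.inf

            if ei < E and t + dt >= ev_t[ei]:
                # jump to the event; waiting times are memoryless
                t = ev_t[ei]
                typ = ev_type[ei]
                if typ == 0:  # merge a -> b
                    a = ev_a[ei]
                    b = ev_b[ei]
                    for l in range(n_active):
                        if lin_deme[l] == a:
                            lin_deme[l] = b
                    k[b] += k[a]
                    k[a] = 0
                    for j in range(D):
                        mig[a, j] = 0.0
                        mig[j, a] = 0.0
                elif typ == 1:  # admixture founding of the hybrid deme
                    h = ev_a[ei] & 0xFF
                    pb = ev_a[ei] >> 8
                    pa = ev_b[ei]
                    alpha = ev_p[ei]
                    for l in range(n_active):
                        if lin_deme[l] == h:
                            if np.random.random() < alpha:
                                lin_deme[l] = pa
                                k[pa] += 1
                            else:
                                lin_deme[l] = pb
                                k[pb] += 1
                            k[h] -= 1
                    for j in range(D):
                        mig[h, j] = 0.0
                        mig[j, h] = 0.0
                else:  # size change
                    N[ev_a[ei]] = ev_p[ei]
                for i in range(D):
                    rs = 0.0
                    for j in range(D):
                        rs += mig[i, j]
                    rowsum[i] = rs
                ei += 1
                continue

            if R <= 0.0:
                return -1  # absorbing state: no rates and no events left

            t += dt
            if t > MAX_TIME:
                return -2  # non-convergence safeguard

            u = np.random.random() * R
            if u < coal_tot:
                # coalescence in deme d
                acc = 0.0
                d = 0
                for dd in range(D):
                    acc += k[dd] * (k[dd] - 1) / (4.0 * N[dd])
                    if u < acc:
                        d = dd
                        break
                # pick two distinct lineages uniformly within deme d
                r1 = np.random.randint(0, k[d])
                r2 = np.random.randint(0, k[d] - 1)
                if r2 >= r1:
                    r2 += 1
                i1 = -1
                i2 = -1
                c = 0
                for l in range(n_active):
                    if lin_deme[l] == d:
                        if c == r1:
                            i1 = l
                        if c == r2:
                            i2 = l
                        c += 1
                # record both child branches
                br_len[nbr] = t - lin_birth[i1]
                for g in range(G):
                    br_cnt[nbr, g] = lin_cnt[i1, g]
                nbr += 1
                br_len[nbr] = t - lin_birth[i2]
                for g in range(G):
                    br_cnt[nbr, g] = lin_cnt[i2, g]
                nbr += 1
                # parent occupies slot i1; drop i2 by swapping in the tail
                lin_birth[i1] = t
                for g in range(G):
                    lin_cnt[i1, g] += lin_cnt[i2, g]
                last = n_active - 1
                lin_deme[i2] = lin_deme[last]
                lin_birth[i2] = lin_birth[last]
                for g in range(G):
                    lin_cnt[i2, g] = lin_cnt[last, g]
                n_active -= 1
                k[d] -= 1
            else:
                # migration
                u -= coal_tot
                acc = 0.0
                d = 0
                for dd in range(D):
                    acc += k[dd] * rowsum[dd]
                    if u < acc:
                        d = dd
                        break
                r = np.random.randint(0, k[d])
                li = -1
                c = 0
                for l in range(n_active):
                    if lin_deme[l] == d:
                        if c == r:
                            li = l
                            break
                        c += 1
                v = np.random.random() * rowsum[d]
                acc = 0.0
                dest = -1
                for j in range(D):
                    acc += mig[d, j]
                    if v < acc:
                        dest = j
                        break
                if dest >= 0:
                    lin_deme[li] = dest
                    k[d] -= 1
                    k[dest] += 1

        # one uniform mutation on total branch length
        total = 0.0
        for b in range(nbr):
            total += br_len[b]
        u = np.random.random() * total
        acc = 0.0
        hit = nbr - 1
        for b in range(nbr):
            acc += br_len[b]
            if u < acc:
                hit = b
                break
        for g in range(G):
            out_pat[s, g] = br_cnt[hit, g]
        out_tmrca[s] = t
        out_tbl[s] = total
    return 0


def simulate_site_patterns(
    model: DemographicModel,
    params,
    n_sims: int,
    seed: int = 0,
    per_haplotype: bool = False,
):
    """Simulate ``n_sims`` independent segregating sites.

    Returns ``(patterns, tmrca, total_length)`` where ``patterns`` holds
    derived-allele counts per deme (or a 0/1 indicator per sampled
    haplotype when ``per_haplotype``), and the other two arrays the TMRCA
    and total branch length (generations) of each genealogy.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    cm = compile_model(model, params)
    ntot = int(cm.ns.sum())
    if per_haplotype:
        group = np.arange(ntot, dtype=np.int64)
        G = ntot
    else:
        group = np.repeat(np.arange(len(cm.ns), dtype=np.int64), cm.ns)
        G = len(cm.ns)
    out_pat = np.zeros((n_sims, G), dtype=np.int64)
    out_tmrca = np.zeros(n_sims)
    out_tbl = np.zeros(n_sims)
    rc = _sim_patterns_kernel(
        cm.ns, group, G, cm.N0, cm.mig0,
        cm.ev_t, cm.ev_type, cm.ev_a, cm.ev_b, cm.ev_p,
        n_sims, seed & 0x7FFFFFFF, out_pat, out_tmrca, out_tbl,
    )
    if rc == -1:
        raise RuntimeError(
            "coalescent reached an absorbing state (disconnected demes with no "
            "remaining events) — model schedule is inconsistent"
        )
    if rc == -2:
        raise RuntimeError(f"no MRCA after {MAX_TIME:g} generations — absorbing-state bug")
    return out_pat, out_tmrca, out_tbl


@njit(cache=True)
def _sim_expected_kernel(
    ns, N0, mig0, ev_t, ev_type, ev_a, ev_b, ev_p, n_sims, seed, pa, pb, mats
):
    """Branch-length-weighted accumulation of folded pair patterns.

    Every branch of every genealogy adds its length to the folded cell of
    each deme pair; mats[p] then sums to total branch length, whose value
    is returned (negative = error code).
    """
    np.random.seed(seed)
    D = ns.shape[0]
    P = pa.shape[0]
    ntot = 0
    for d in range(D):
        ntot += ns[d]
    E = ev_t.shape[0]

    lin_deme = np.empty(ntot, np.int64)
    lin_birth = np.empty(ntot, np.float64)
    lin_cnt = np.empty((ntot, D), np.int64)
    k = np.empty(D, np.int64)
    N = np.empty(D, np.float64)
    mig = np.empty((D, D), np.float64)
    rowsum = np.empty(D, np.float64)
    pair_ids = np.empty(2, np.int64)
    grand_total = 0.0

    for s in range(n_sims):
        li = 0
        for d in range(D):
            k[d] = ns[d]
            N[d] = N0[d]
            for _ in range(ns[d]):
                lin_deme[li] = d
                lin_birth[li] = 0.0
                for g in range(D):
                    lin_cnt[li, g] = 0
                lin_cnt[li, d] = 1
                li += 1
        for i in range(D):
            rs = 0.0
            for j in range(D):
                mig[i, j] = mig0[i, j]
                rs += mig0[i, j]
            rowsum[i] = rs

        n_active = ntot
        t = 0.0
        ei = 0

        while n_active > 1:
            coal_tot = 0.0
            mig_tot = 0.0
            for d in range(D):
                coal_tot += k[d] * (k[d] - 1) / (4.0 * N[d])
                mig_tot += k[d] * rowsum[d]
            R = coal_tot + mig_tot

            if R > 0.0:
                dt = -np.log(np.random.random()) / R
            else:
                dt = np.inf

            if ei < E and t + dt >= ev_t[ei]:
                t = ev_t[ei]
                typ = ev_type[ei]
                if typ == 0:
                    a = ev_a[ei]
                    b = ev_b[ei]
                    for l in range(n_active):
                        if lin_deme[l] == a:
                            lin_deme[l] = b
                    k[b] += k[a]
                    k[a] = 0
                    for j in range(D):
                        mig[a, j] = 0.0
                        mig[j, a] = 0.0
                elif typ == 1:
                    h = ev_a[ei] & 0xFF
                    pb_ = ev_a[ei] >> 8
                    pa_ = ev_b[ei]
                    alpha = ev_p[ei]
                    for l in range(n_active):
                        if lin_deme[l] == h:
                            if np.random.random() < alpha:
                                lin_deme[l] = pa_
                                k[pa_] += 1
                            else:
                                lin_deme[l] = pb_
                                k[pb_] += 1
                            k[h] -= 1
                    for j in range(D):
                        mig[h, j] = 0.0
                        mig[j, h] = 0.0
                else:
                    N[ev_a[ei]] = ev_p[ei]
                for i in range(D):
                    rs = 0.0
                    for j in range(D):
                        rs += mig[i, j]
                    rowsum[i] = rs
                ei += 1
                continue

            if R <= 0.0:
                return -1.0
            t += dt
            if t > MAX_TIME:
                return -2.0

            u = np.random.random() * R
            if u < coal_tot:
                acc = 0.0
                d = 0
                for dd in range(D):
                    acc += k[dd] * (k[dd] - 1) / (4.0 * N[dd])
                    if u < acc:
                        d = dd
                        break
                r1 = np.random.randint(0, k[d])
                r2 = np.random.randint(0, k[d] - 1)
                if r2 >= r1:
                    r2 += 1
                i1 = -1
                i2 = -1
                c = 0
                for l in range(n_active):
                    if lin_deme[l] == d:
                        if c == r1:
                            i1 = l
                        if c == r2:
                            i2 = l
                        c += 1
                # fold and accumulate both child branches
                pair_ids[0] = i1
                pair_ids[1] = i2
                for w in range(2):
                    ch = pair_ids[w]
                    ln = t - lin_birth[ch]
                    grand_total += ln
                    for p in range(P):
                        a = pa[p]
                        b = pb[p]
                        ca = lin_cnt[ch, a]
                        if a == b:  # one-deme (1D) spectrum
                            na = ns[a]
                            if 2 * ca > na or (2 * ca == na and na - ca < ca):
                                ca = na - ca
                            mats[p, ca, 0] += ln
                        else:
                            cb = lin_cnt[ch, b]
                            na = ns[a]
                            nb = ns[b]
                            s2 = 2 * (ca + cb)
                            S = na + nb
                            if s2 > S or (
                                s2 == S
                                and (na - ca < ca or (na - ca == ca and nb - cb < cb))
                            ):
                                ca = na - ca
                                cb = nb - cb
                            mats[p, ca, cb] += ln
                lin_birth[i1] = t
                for g in range(D):
                    lin_cnt[i1, g] += lin_cnt[i2, g]
                last = n_active - 1
                lin_deme[i2] = lin_deme[last]
                lin_birth[i2] = lin_birth[last]
                for g in range(D):
                    lin_cnt[i2, g] = lin_cnt[last, g]
                n_active -= 1
                k[d] -= 1
            else:
                u -= coal_tot
                acc = 0.0
                d = 0
                for dd in range(D):
                    acc += k[dd] * rowsum[dd]
                    if u < acc:
                        d = dd
                        break
                r = np.random.randint(0, k[d])
                li = -1
                c = 0
                for l in range(n_active):
                    if lin_deme[l] == d:
                        if c == r:
                            li = l
                            break
                        c += 1
                v = np.random.random() * rowsum[d]
                acc = 0.0
                dest = -1
                for j in range(D):
                    acc += mig[d, j]
                    if v < acc:
                        dest = j
                        break
                if dest >= 0:
                    lin_deme[li] = dest
                    k[d] -= 1
                    k[dest] += 1
    return grand_total


def _run_expected_kernel(cm: CompiledModel, pairs, n_sims: int, seed: int):
    D = len(cm.ns)
    pa = np.array([p[0] for p in pairs], dtype=np.int64)
    pb = np.array([p[1] for p in pairs], dtype=np.int64)
    mx = int(cm.ns.max())
    mats = np.zeros((len(pairs), mx + 1, mx + 1))
    total = _sim_expected_kernel(
        cm.ns, cm.N0, cm.mig0, cm.ev_t, cm.ev_type, cm.ev_a, cm.ev_b, cm.ev_p,
        n_sims, seed & 0x7FFFFFFF, pa, pb, mats,
    )
    if total == -1.0:
        raise RuntimeError(
            "coalescent reached an absorbing state (disconnected demes with no "
            "remaining events) — model schedule is inconsistent"
        )
    if total == -2.0:
        raise RuntimeError(f"no MRCA after {MAX_TIME:g} generations — absorbing-state bug")
    return mats, total


def sample_snp_patterns(
    model: DemographicModel,
    params,
    n_snps: int,
    seed: int = 0,
    per_haplotype: bool = False,
    oversample: int = 2,
) -> np.ndarray:
    """Draw ``n_snps`` SNP site patterns from the model's stationary SNP law.

    Simulates ``oversample * n_snps`` genealogies, selects genealogies
    with probability proportional to their total branch length (the
    size-biasing implied by conditioning on a segregating site), and
    returns the uniformly placed mutation's pattern of each selection.
    """
    n_sims = int(oversample) * int(n_snps)
    patterns, _, tbl = simulate_site_patterns(
        model, params, n_sims, seed, per_haplotype=per_haplotype
    )
    rng = np.random.default_rng(seed)
    idx = rng.choice(n_sims, size=n_snps, replace=True, p=tbl / tbl.sum())
    return patterns[idx]


def expected_folded_sfs_1d(
    model: DemographicModel, params, n_sims: int = 100_000, seed: int = 0
) -> np.ndarray:
    """Expected folded 1D SFS of a single-deme model (no masking).

    Returns proportions indexed by the minor-allele count 0..n//2 (the
    0 cell is structurally empty: every simulated site segregates).
    """
    if model.n_demes != 1:
        raise ValueError("expected_folded_sfs_1d requires a single-deme model")
    cm = compile_model(model, params)
    mats, total = _run_expected_kernel(cm, [(0, 0)], n_sims, seed)
    n = int(cm.ns[0])
    return mats[0, : n // 2 + 1, 0] / total


# ---------------------------------------------------------------------------
# expected SFS


def pair_sfs_counts(patterns: np.ndarray, ns, pairs=None):
    """Fold site patterns into per-pair 2D count matrices.

    ``patterns`` is (n_sims, D) per-deme derived counts; ``ns`` the
    haploid sample sizes in deme order. Sites monomorphic within a pair
    fall into masked corner cells, exactly as in the observed spectra.
    """
    ns = np.asarray(ns)
    D = len(ns)
    if pairs is None:
        pairs = list(itertools.combinations(range(D), 2))
    out = []
    for a, b in pairs:
        n_a, n_b = int(ns[a]), int(ns[b])
        i, j = fold_counts_vec(patterns[:, a], patterns[:, b], n_a, n_b)
        counts = np.zeros((n_a + 1, n_b + 1))
        np.add.at(counts, (i, j), 1.0)
        out.append(counts)
    return out, pairs


def expected_pair_sfs(
    model: DemographicModel,
    params,
    n_sims: int = 100_000,
    seed: int = 0,
    floor_factor: float = 10.0,
) -> list[Folded2DSFS]:
    """Monte Carlo estimate of the expected folded 2D SFS for every deme pair.

    Branch-length-weighted over ``n_sims`` genealogies (the exact SNP
    pattern law in the low-mutation-rate limit). Cell probabilities are
    renormalised over unmasked cells after every unmasked cell receives a
    floor of 1/(floor_factor * n_sims), which keeps composite
    log-likelihoods finite for cells unseen at finite simulation effort.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    cm = compile_model(model, params)
    D = len(cm.ns)
    if D < 2:
        raise ValueError("expected_pair_sfs needs >= 2 demes; see expected_folded_sfs_1d")
    ns = [int(x) for x in cm.ns]
    names = model.deme_names
    pairs = list(itertools.combinations(range(D), 2))
    mats, total = _run_expected_kernel(cm, pairs, n_sims, seed)
    floor = 1.0 / (floor_factor * n_sims)
    out = []
    for (a, b), mat in zip(pairs, mats):
        n_a, n_b = ns[a], ns[b]
        mask = folded_mask(n_a, n_b)
        probs = mat[: n_a + 1, : n_b + 1] / total
        raw = probs.copy()
        probs[~mask] = np.maximum(probs[~mask], floor)
        probs[mask] = 0.0
        probs[~mask] /= probs[~mask].sum()
        sfs = Folded2DSFS(
            deme_a=names[a], deme_b=names[b], n_a=n_a, n_b=n_b,
            counts=probs, mask=mask, seed=seed,
            meta={"kind": "expected", "n_sims": n_sims, "raw_probs": raw},
        )
        out.append(sfs)
    return out


# ---------------------------------------------------------------------------
# explicit single genealogies


@dataclass
class Genealogy:
    """An explicit coalescent tree: leaves at time 0, one root.

    ``times[v]`` is the node age in generations, ``parents[v]`` the parent
    node (-1 at the root), ``leaf_demes`` the deme label of each leaf
    (leaves are nodes 0..n-1).
    """

    times: np.ndarray
    parents: np.ndarray
    leaf_demes: list[str]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.parents = np.asarray(self.parents, dtype=int)
        if (self.parents == -1).sum() != 1:
            raise ValueError("genealogy must have exactly one root")
        if self.total_length <= 0:
            raise ValueError("total branch length must be positive")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_demes)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parents == -1)[0])

    @property
    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each node (0 at the root)."""
        out = np.zeros_like(self.times)
        has_parent = self.parents >= 0
        out[has_parent] = self.times[self.parents[has_parent]] - self.times[has_parent]
        return out

    @property
    def total_length(self) -> float:
        return float(self.branch_lengths.sum())

    @property
    def tmrca(self) -> float:
        return float(self.times[self.root])

    def leaves_under(self, v: int) -> list[int]:
        children: dict[int, list[int]] = {}
        for u, p in enumerate(self.parents):
            if p >= 0:
                children.setdefault(p, []).append(u)
        stack, found = [v], []
        while stack:
            u = stack.pop()
            if u < self.n_leaves:
                found.append(u)
            stack.extend(children.get(u, []))
        return sorted(found)


def simulate_genealogy(model: DemographicModel, params, rng=None) -> Genealogy:
    """Simulate one explicit genealogy under the model (pure-python path)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    cm = compile_model(model, params)
    D = len(cm.ns)
    ntot = int(cm.ns.sum())

    leaf_demes = [cm.deme_names[d] for d in range(D) for _ in range(cm.ns[d])]
    times = list(np.zeros(ntot))
    parents = [-1] * ntot
    active = list(range(ntot))  # node ids
    node_deme = list(np.repeat(np.arange(D), cm.ns))
    N = cm.N0.copy()
    mig = cm.mig0.copy()

    t, ei, E = 0.0, 0, len(cm.ev_t)
    while len(active) > 1:
        k = np.bincount([node_deme[v] for v in active], minlength=D)
        coal = k * (k - 1) / (4.0 * N)
        migr = k * mig.sum(axis=1)
        R = coal.sum() + migr.sum()
        dt = rng.exponential(1.0 / R) if R > 0 else np.inf

        if ei < E and t + dt >= cm.ev_t[ei]:
            t = cm.ev_t[ei]
            typ = cm.ev_type[ei]
            if typ == EV_MERGE:
                a, b = cm.ev_a[ei], cm.ev_b[ei]
                for v in active:
                    if node_deme[v] == a:
                        node_deme[v] = b
                mig[a, :] = 0.0
                mig[:, a] = 0.0
            elif typ == EV_ADMIX:
                h, pb = cm.ev_a[ei] & 0xFF, cm.ev_a[ei] >> 8
                pa, alpha = cm.ev_b[ei], cm.ev_p[ei]
                for v in active:
                    if node_deme[v] == h:
                        node_deme[v] = pa if rng.random() < alpha else pb
                mig[h, :] = 0.0
                mig[:, h] = 0.0
            else:
                N[cm.ev_a[ei]] = cm.ev_p[ei]
            ei += 1
            continue
        if R <= 0:
            raise RuntimeError("absorbing state: disconnected demes with no events left")
        t += dt
        if t > MAX_TIME:
            raise RuntimeError("no MRCA before the time safeguard — absorbing-state bug")

        u = rng.random() * R
        if u < coal.sum():
            d = int(np.searchsorted(np.cumsum(coal), u, side="right"))
            members = [v for v in active if node_deme[v] == d]
            i1, i2 = rng.choice(len(members), size=2, replace=False)
            v1, v2 = members[i1], members[i2]
            w = len(times)
            times.append(t)
            parents.append(-1)
            parents[v1] = parents[v2] = w
            node_deme.append(d)
            active.remove(v1)
            active.remove(v2)
            active.append(w)
        else:
            u -= coal.sum()
            d = int(np.searchsorted(np.cumsum(migr), u, side="right"))
            members = [v for v in active if node_deme[v] == d]
            v = members[rng.integers(len(members))]
            dest = int(np.searchsorted(np.cumsum(mig[d]), rng.random() * mig[d].sum(), side="right"))
            node_deme[v] = dest

    return Genealogy(np.array(times), np.array(parents), leaf_demes)


def drop_snp(gen: Genealogy, rng=None) -> dict[str, int]:
    """Place one mutation uniformly on total branch length.

    Returns derived-allele counts per deme; the root has no parent branch,
    so the resulting pattern is always segregating.
    """
    if gen.n_leaves < 2:
        raise ValueError("genealogy needs at least 2 leaves")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    bl = gen.branch_lengths
    u = rng.random() * bl.sum()
    node = int(np.searchsorted(np.cumsum(bl), u, side="right"))
    counts: dict[str, int] = {d: 0 for d in dict.fromkeys(gen.leaf_demes)}
    for leaf in gen.leaves_under(node):
        counts[gen.leaf_demes[leaf]] += 1
    return counts
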