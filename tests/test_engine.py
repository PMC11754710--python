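import numpy as np
import pytest
from scipy import stats

from conftest import one_deme_model
from rangecoal.demography import (
    AdmixtureEvent,
    DemeSpec,
    DemographicModel,
    MergeEvent,
    SizeChangeEvent,
    build_model,
)
from rangecoal.engine import (
    Genealogy,
    drop_snp,
    expected_folded_sfs_1d,
    expected_pair_sfs,
    sample_snp_patterns,
    simulate_genealogy,
    simulate_site_patterns,
)


def split_model(T=4000.0, N=10_000.0, N_anc=10_000.0, n_a=4, n_b=4, mig=0.0):
    """Two demes A and B splitting from a common ancestor T generations ago."""
    migration = {("A", "B"): mig, ("B", "A"): mig} if mig > 0 else {}
    return DemographicModel(
        name="toy-split",
        demes=[DemeSpec("A", N, n_a), DemeSpec("B", N, n_b)],
        events=[
            MergeEvent(t=T, source="A", dest="B"),
            SizeChangeEvent(t=T, deme="B", new_N=N_anc, role="ancestral"),
        ],
        migration=migration,
        params=[],
    )


# ---------------------------------------------------------------------------
# coalescence times


def test_pairwise_tmrca_is_exponential_with_mean_2n():
    m = one_deme_model(N=1000.0, n=2)
    _, tmrca, _ = simulate_site_patterns(m, {}, 50_000, seed=1)
    assert abs(tmrca.mean() / 2000.0 - 1.0) < 0.02
    ks = stats.kstest(tmrca, "expon", args=(0, 2000.0))
    assert ks.pvalue > 0.01


def test_no_common_ancestor_before_the_split():
    # cross-deme lineages cannot coalesce until the merge at T
    m = split_model(T=5000.0, n_a=2, n_b=2)
    _, tmrca, _ = simulate_site_patterns(m, {}, 5_000, seed=2)
    assert tmrca.min() >= 5000.0


def test_two_lineages_always_give_singleton_patterns():
    m = one_deme_model(N=500.0, n=2)
    patterns, _, _ = simulate_site_patterns(m, {}, 2_000, seed=3)
    assert np.all(patterns == 1)


def test_patterns_always_segregating():
    m = split_model(n_a=4, n_b=4)
    patterns, _, _ = simulate_site_patterns(m, {}, 5_000, seed=4)
    tot = patterns.sum(axis=1)
    assert tot.min() >= 1 and tot.max() <= 7


def test_per_haplotype_patterns_aggregate_to_deme_patterns():
    m = split_model(n_a=4, n_b=6, mig=1e-4)
    per_deme, t1, _ = simulate_site_patterns(m, {}, 3_000, seed=5)
    per_hap, t2, _ = simulate_site_patterns(m, {}, 3_000, seed=5, per_haplotype=True)
    assert np.array_equal(t1, t2)  # identical genealogy stream
    agg = np.stack([per_hap[:, :4].sum(axis=1), per_hap[:, 4:].sum(axis=1)], axis=1)
    assert np.array_equal(agg, per_deme)


def test_simulation_deterministic_under_seed():
    m = split_model(mig=1e-4)
    a = simulate_site_patterns(m, {}, 500, seed=9)
    b = simulate_site_patterns(m, {}, 500, seed=9)
    c = simulate_site_patterns(m, {}, 500, seed=10)
    assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
    assert not np.array_equal(a[1], c[1])


def test_disconnected_demes_raise_absorbing_state_error():
    m = DemographicModel(
        name="toy-disconnected",
        demes=[DemeSpec("A", 1000.0, 4), DemeSpec("B", 1000.0, 4)],
        events=[],
        migration={},
        params=[],
    )
    with pytest.raises(RuntimeError, match="absorbing"):
        simulate_site_patterns(m, {}, 10, seed=0)


def test_invalid_event_order_rejected_before_simulation():
    m = build_model("3-dicho")
    params = dict(
        N_Pgal=2e4, N_Pnig=3e4, N_Pspi=5e4, N_ANC=4e4, N_ANC_GN=3e4,
        TDIV_GAL=70_000.0, TDIV_ANC=60_000.0,
        MIG_Pnig_Pspi=1e-5, MIG_Pspi_Pnig=1e-5,
    )
    with pytest.raises(ValueError, match="TDIV_GAL"):
        simulate_site_patterns(m, params, 10, seed=0)


# ---------------------------------------------------------------------------
# expected spectra


def test_expected_pair_sfs_is_a_probability_distribution():
    m = split_model(mig=1e-5)
    (sfs,) = expected_pair_sfs(m, {}, n_sims=20_000, seed=6)
    keep = ~sfs.mask
    assert sfs.counts[keep].sum() == pytest.approx(1.0)
    assert np.all(sfs.counts[keep] > 0)  # probability floor
    assert np.all(sfs.counts[sfs.mask] == 0)


def test_expected_folded_sfs_matches_constant_size_theory():
    # folded neutral SFS for n=4: proportions 8/11 and 3/11
    m = one_deme_model(N=5000.0, n=4)
    props = expected_folded_sfs_1d(m, {}, n_sims=50_000, seed=7)
    assert props[0] == 0.0
    assert props[1] == pytest.approx(8 / 11, abs=0.01)
    assert props[2] == pytest.approx(3 / 11, abs=0.01)


def test_island_model_expected_sfs_is_exchangeable():
    m = DemographicModel(
        name="toy-island",
        demes=[DemeSpec("A", 10_000.0, 4), DemeSpec("B", 10_000.0, 4)],
        events=[],
        migration={("A", "B"): 1e-4, ("B", "A"): 1e-4},
        params=[],
    )
    (sfs,) = expected_pair_sfs(m, {}, n_sims=50_000, seed=8)
    keep = ~sfs.mask & ~sfs.mask.T
    diff = np.abs(sfs.counts - sfs.counts.T)[keep]
    assert diff.max() < 0.015


def test_shared_polymorphism_decreases_with_divergence_time():
    shared = []
    for T in (500.0, 4_000.0, 16_000.0, 64_000.0):
        m = split_model(T=T)
        (sfs,) = expected_pair_sfs(m, {}, n_sims=30_000, seed=11)
        keep = ~sfs.mask
        both = (np.arange(5)[:, None] >= 1) & (np.arange(5)[None, :] >= 1)
        shared.append(sfs.counts[keep & both].sum())
    assert all(a > b for a, b in zip(shared, shared[1:]))


def test_full_admixture_equals_merge():
    # alpha = 1: every hybrid lineage goes to parent_a, exactly like a merge
    demes = [DemeSpec("A", 5000.0, 4), DemeSpec("B", 5000.0, 4), DemeSpec("C", 5000.0, 4)]
    tail = [
        MergeEvent(t=4000.0, source="C", dest="B"),
        SizeChangeEvent(t=4000.0, deme="B", new_N=5000.0),
    ]
    m_adm = DemographicModel(
        name="toy-adm",
        demes=demes,
        events=[AdmixtureEvent(t=500.0, hybrid="A", parent_a="B", parent_b="C", alpha=1.0)]
        + tail,
        migration={},
        params=[],
    )
    m_merge = DemographicModel(
        name="toy-merge",
        demes=demes,
        events=[MergeEvent(t=500.0, source="A", dest="B")] + tail,
        migration={},
        params=[],
    )
    sfs_a = expected_pair_sfs(m_adm, {}, n_sims=50_000, seed=12)
    sfs_m = expected_pair_sfs(m_merge, {}, n_sims=50_000, seed=13)
    for a, b in zip(sfs_a, sfs_m):
        tv = 0.5 * np.abs(a.counts - b.counts).sum()
        assert tv < 0.02, (a.pair, tv)


def test_admixture_proportion_shifts_ancestry():
    # with alpha near 0, hybrid lineages trace to C: A-C sharing >> A-B sharing
    def model(alpha):
        return DemographicModel(
            name="toy-alpha",
            demes=[DemeSpec("A", 5000.0, 8), DemeSpec("B", 5000.0, 8), DemeSpec("C", 5000.0, 8)],
            events=[
                AdmixtureEvent(t=200.0, hybrid="A", parent_a="B", parent_b="C", alpha=alpha),
                MergeEvent(t=50_000.0, source="C", dest="B"),
            ],
            migration={},
            params=[],
        )

    def shared_mass(sfs):
        i = np.arange(sfs.n_a + 1)[:, None] >= 1
        j = np.arange(sfs.n_b + 1)[None, :] >= 1
        return sfs.counts[~sfs.mask & (i & j)].sum()

    ab, ac, bc = expected_pair_sfs(model(0.05), {}, n_sims=30_000, seed=14)
    assert shared_mass(ac) > shared_mass(ab) + 0.05
    ab2, ac2, bc2 = expected_pair_sfs(model(0.95), {}, n_sims=30_000, seed=15)
    assert shared_mass(ab2) > shared_mass(ac2) + 0.05


# ---------------------------------------------------------------------------
# SNP-pattern sampling


def test_sample_snp_patterns_shape_and_determinism():
    m = split_model()
    p1 = sample_snp_patterns(m, {}, 400, seed=16)
    p2 = sample_snp_patterns(m, {}, 400, seed=16)
    assert p1.shape == (400, 2)
    assert np.array_equal(p1, p2)
    hap = sample_snp_patterns(m, {}, 400, seed=16, per_haplotype=True)
    assert hap.shape == (400, 8)
    assert set(np.unique(hap)) <= {0, 1}


def test_sampled_snp_frequencies_match_expected_sfs():
    # the size-biased SNP draws must reproduce the branch-weighted law
    # a large oversample keeps the finite genealogy pool from inflating the
    # chi-square beyond its multinomial reference distribution
    m = split_model(T=2000.0)
    (exp,) = expected_pair_sfs(m, {}, n_sims=200_000, seed=17)
    pats = sample_snp_patterns(m, {}, 5_000, seed=18, oversample=40)
    from rangecoal.engine import pair_sfs_counts

    (counts,), _ = pair_sfs_counts(pats, [4, 4])
    keep = ~exp.mask & (counts + exp.counts > 0)
    obs = counts[keep]
    p = exp.counts[keep] / exp.counts[keep].sum()
    chi = stats.chisquare(obs, p * obs.sum())
    assert chi.pvalue > 0.01


# ---------------------------------------------------------------------------
# explicit genealogies


def test_genealogy_invariants():
    m = one_deme_model(N=2000.0, n=6)
    gen = simulate_genealogy(m, {}, rng=21)
    assert gen.n_leaves == 6
    assert len(gen.times) == 11  # 6 leaves + 5 internal nodes
    assert np.all(gen.times[:6] == 0.0)
    assert gen.tmrca == gen.times.max()
    assert gen.total_length > 0
    assert gen.leaves_under(gen.root) == list(range(6))


def test_genealogy_requires_single_root():
    with pytest.raises(ValueError, match="root"):
        Genealogy(times=[0.0, 0.0, 1.0, 2.0], parents=[2, 2, -1, -1], leaf_demes=["a", "b"])


def test_mutation_lands_on_branches_proportionally_to_length():
    # fixed tree: leaves a,b coalesce at 0.5, join leaf c at 10
    gen = Genealogy(
        times=np.array([0.0, 0.0, 0.0, 0.5, 10.0]),
        parents=np.array([3, 3, 4, 4, -1]),
        leaf_demes=["a", "b", "c"],
    )
    lens = {"a_only": 0.5, "b_only": 0.5, "c_only": 10.0, "ab": 9.5}
    rng = np.random.default_rng(22)
    n = 20_000
    hits = dict.fromkeys(lens, 0)
    for _ in range(n):
        cnt = drop_snp(gen, rng)
        if cnt == {"a": 1, "b": 0, "c": 0}:
            hits["a_only"] += 1
        elif cnt == {"a": 0, "b": 1, "c": 0}:
            hits["b_only"] += 1
        elif cnt == {"a": 0, "b": 0, "c": 1}:
            hits["c_only"] += 1
        elif cnt == {"a": 1, "b": 1, "c": 0}:
            hits["ab"] += 1
        else:
            raise AssertionError(f"impossible pattern {cnt}")
    total = sum(lens.values())
    expected = np.array([lens[k] / total for k in lens]) * n
    chi = stats.chisquare(np.array([hits[k] for k in lens]), expected)
    assert chi.pvalue > 0.01
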