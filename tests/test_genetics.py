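"""Tests for cluster dynamics, HWE genotype probabilities and the likelihood."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from empdisp import Behavior, Theta
from empdisp.errors import NoLociSurviveError
from empdisp.genetics import (
    LikelihoodEngine,
    estimate_cluster_frequencies,
    filter_snps,
    genotype_log_prob,
    init_cluster_state,
    initial_mu,
    log_likelihood,
    mixture_log_prob,
    project_clusters,
)
from empdisp.types import ClusterAlleleFreqs, GenotypeDataset, MISSING

from conftest import make_circular_map, make_forcing, make_theta


def make_dataset(codes, colonies=None, years=None, locus_ids=None):
    codes = np.asarray(codes, dtype=np.int8)
    n, L = codes.shape
    return GenotypeDataset(
        individual_ids=[f"i{k}" for k in range(n)],
        colony_ids=np.array(colonies if colonies is not None else ["c0"] * n, dtype=object),
        years=np.array(years if years is not None else [2013] * n),
        locus_ids=locus_ids or [f"L{j}" for j in range(L)],
        codes=codes,
    )


# -------------------------------------------------------------------- filters


def test_locus_missing_in_one_colony_is_dropped():
    codes = np.array(
        [
            [1, MISSING],
            [2, MISSING],
            [0, 1],
            [1, 2],
        ]
    )
    data = make_dataset(codes, colonies=["a", "a", "b", "b"])
    kept = filter_snps(data, min_presence=0.5)
    assert kept.locus_ids == ["L0"]


def test_presence_threshold_enforced_per_colony():
    # locus 1 genotyped in 7 of 10 individuals of colony a: 70% < 80%
    codes = np.ones((10, 2), dtype=np.int8)
    codes[:3, 1] = MISSING
    codes[0, 0] = 0  # keep locus 0 polymorphic
    data = make_dataset(codes, colonies=["a"] * 10)
    kept = filter_snps(data)
    assert kept.locus_ids == ["L0"]


def test_monomorphic_locus_dropped():
    codes = np.array([[2, 1], [2, 0], [2, 2]])
    data = make_dataset(codes)
    kept = filter_snps(data)
    assert kept.locus_ids == ["L1"]


def test_all_loci_removed_raises():
    data = make_dataset(np.full((4, 2), 2, dtype=np.int8))
    with pytest.raises(NoLociSurviveError):
        filter_snps(data)


# -------------------------------------------------------- frequency estimation


def test_allele_counting():
    data = make_dataset(np.array([[0], [1], [2]]))
    freqs = estimate_cluster_frequencies(data, {"c0": "C1"})
    assert freqs.p[0, 0] == pytest.approx(0.5)  # 3 ref copies / 6


def test_fixed_reference_gives_frequency_one():
    data = make_dataset(np.full((4, 1), 2, dtype=np.int8))
    freqs = estimate_cluster_frequencies(data, {"c0": "C1"})
    assert freqs.p[0, 0] == 1.0


def test_private_allele_zero_preserved_exactly():
    codes = np.array([[2, 2], [2, 1]])
    data = make_dataset(codes, colonies=["a", "b"])
    freqs = estimate_cluster_frequencies(data, {"a": "C1", "b": "C2"}, ["C1", "C2"])
    assert freqs.p[0, 1] == 1.0  # alternate allele absent from C1: exact zero freq
    assert freqs.p[1, 1] == pytest.approx(0.5)


def test_missing_excluded_from_both_sides():
    codes = np.array([[2], [MISSING], [0]])
    data = make_dataset(codes)
    freqs = estimate_cluster_frequencies(data, {"c0": "C1"})
    assert freqs.p[0, 0] == pytest.approx(0.5)  # 2 of 4 observed copies


def test_cluster_without_observations_flagged_nan():
    codes = np.array([[2], [MISSING]])
    data = make_dataset(codes, colonies=["a", "b"])
    freqs = estimate_cluster_frequencies(data, {"a": "C1", "b": "C2"}, ["C1", "C2"])
    assert np.isnan(freqs.p[1, 0])


# ---------------------------------------------------------- initial condition


def test_characterized_region_gets_indicator_mu():
    cmap = make_circular_map(n=4, regions=["A", "A", "B", "B"])
    theta = make_theta(n_regions=2)
    mu0 = initial_mu(cmap, theta, {"A": "C1", "B": "C2"}, ["C1", "C2"])
    np.testing.assert_array_equal(mu0, [[1, 0], [1, 0], [0, 1], [0, 1]])


def test_uncharacterized_region_proportional_split():
    cmap = make_circular_map(n=2, regions=["A", "U"], n0=[1000.0, 1000.0])
    theta = Theta(
        d=400.0,
        pm=[0.1, 0.1],
        behavior=Behavior.SEMI_INFORMED,
        mu_unknown={"U": np.full(4, 0.25)},
    )
    nr0 = init_cluster_state(cmap, theta, {"A": "C1"}, ["C1", "C2", "C3", "C4"])
    np.testing.assert_allclose(nr0[1], [250.0, 250.0, 250.0, 250.0])
    np.testing.assert_allclose(nr0.sum(axis=1), cmap.n0)


def test_unmapped_region_rejected():
    cmap = make_circular_map(n=2, regions=["A", "U"])
    theta = make_theta(n_regions=2)
    with pytest.raises(KeyError, match="U"):
        initial_mu(cmap, theta, {"A": "C1"}, ["C1", "C2"])


# ---------------------------------------------------------- cluster dynamics


def test_single_cluster_trajectory_equals_total():
    cmap = make_circular_map(n=3, regions=["A"] * 3)
    forcing = make_forcing(np.random.default_rng(0).normal(0, 0.2, (3, 10)), rc_star=-1.0)
    theta = make_theta()
    traj, ctraj = project_clusters(cmap, forcing, theta, 2000, 2010, {"A": "C1"}, ["C1"])
    np.testing.assert_allclose(ctraj.nr[:, 0, :], traj.n)


def test_mu_constant_without_movement():
    cmap = make_circular_map(n=4, regions=["A", "A", "B", "B"])
    forcing = make_forcing(
        np.random.default_rng(1).normal(-0.1, 0.1, (4, 8)), rc_star=-1.0
    )
    theta = make_theta(behavior=Behavior.RANDOM, pm=0.0, n_regions=2)
    _, ctraj = project_clusters(
        cmap, forcing, theta, 2000, 2008, {"A": "C1", "B": "C2"}, ["C1", "C2"]
    )
    mu = ctraj.mu()
    for t in range(9):
        np.testing.assert_allclose(mu[:, :, t], mu[:, :, 0], atol=1e-12)


def test_full_swap_exchanges_cluster_composition():
    # two colonies, both emigrate fully and each settles at the other:
    # their mu rows exchange after one year
    cmap = make_circular_map(
        n=2, circumference=200.0, regions=["A", "B"], K=[1e6, 1e6], n0=[100.0, 200.0]
    )
    forcing = make_forcing([[-0.5], [-0.5]], rc_star=-0.5)
    theta = Theta(d=400.0, pm=[1.0, 1.0], behavior=Behavior.SEMI_INFORMED)
    _, ctraj = project_clusters(
        cmap, forcing, theta, 2000, 2001, {"A": "C1", "B": "C2"}, ["C1", "C2"]
    )
    mu = ctraj.mu()
    np.testing.assert_allclose(mu[0, :, 0], [1, 0])
    np.testing.assert_allclose(mu[1, :, 0], [0, 1])
    np.testing.assert_allclose(mu[0, :, 1], [0, 1], atol=1e-12)
    np.testing.assert_allclose(mu[1, :, 1], [1, 0], atol=1e-12)


def test_linking_identity_through_time(benchmark):
    _, cmap, forcing, freqs, traj, ctraj, data = benchmark
    tot = ctraj.nr.sum(axis=1)
    np.testing.assert_allclose(tot, traj.n, rtol=1e-10)


# --------------------------------------------------- genotype log-probability


def test_heterozygote_probability():
    assert genotype_log_prob(np.array([1]), np.array([0.5])) == pytest.approx(
        math.log(0.5)
    )


def test_certain_genotype_has_probability_one():
    lp = genotype_log_prob(np.full(5, 2, dtype=np.int8), np.ones(5))
    assert lp == 0.0


def test_private_allele_mismatch_is_impossible():
    # individual carries the alternate allele; cluster has alt frequency 0
    assert genotype_log_prob(np.array([1]), np.array([1.0])) == -np.inf
    assert genotype_log_prob(np.array([0]), np.array([1.0])) == -np.inf


def test_three_heterozygous_loci_product():
    lp = genotype_log_prob(np.array([1, 1, 1]), np.full(3, 0.5))
    assert lp == pytest.approx(math.log(0.125))


def test_missing_loci_contribute_nothing():
    lp = genotype_log_prob(np.array([1, MISSING]), np.array([0.5, 0.9]))
    assert lp == pytest.approx(math.log(0.5))


def test_invalid_code_rejected():
    with pytest.raises(ValueError):
        genotype_log_prob(np.array([3]), np.array([0.5]))


@given(p=st.floats(0.0, 1.0))
@settings(max_examples=200, derandomize=True)
def test_single_locus_genotype_probabilities_normalize(p):
    probs = [
        math.exp(genotype_log_prob(np.array([c]), np.array([p]))) for c in (0, 1, 2)
    ]
    assert sum(probs) == pytest.approx(1.0, abs=1e-12)


# --------------------------------------------------------------- mixture


def freqs_2x1(p1, p2):
    return ClusterAlleleFreqs(clusters=["C1", "C2"], locus_ids=["L0"], p=np.array([[p1], [p2]]))


def test_identity_mixture_reduces_to_cluster_probability():
    fr = freqs_2x1(0.3, 0.8)
    g = np.array([1])
    lp = mixture_log_prob(g, fr, np.array([1.0, 0.0]))
    assert lp == pytest.approx(genotype_log_prob(g, fr.p[0]))


def test_arithmetic_mixture():
    # construct per-cluster genotype probabilities 0.2 and 0.4 for code 1:
    # 2p(1-p) = 0.2 -> p ~ 0.1127; 2p(1-p) = 0.4 -> p ~ 0.2764
    p1 = (1 - math.sqrt(1 - 2 * 0.2)) / 2
    p2 = (1 - math.sqrt(1 - 2 * 0.4)) / 2
    fr = freqs_2x1(p1, p2)
    lp = mixture_log_prob(np.array([1]), fr, np.array([0.5, 0.5]))
    assert lp == pytest.approx(math.log(0.3))


def test_impossible_in_every_admissible_cluster():
    fr = freqs_2x1(1.0, 0.5)
    lp = mixture_log_prob(np.array([0]), fr, np.array([1.0, 0.0]))
    assert lp == -np.inf


def test_mixture_monotone_in_component_weight():
    rng = np.random.default_rng(5)
    for _ in range(30):
        fr = freqs_2x1(rng.uniform(0.05, 0.95), rng.uniform(0.05, 0.95))
        g = np.array([rng.integers(0, 3)])
        lps = []
        for w in (0.1, 0.5, 0.9):
            mu = np.array([w, 1 - w])
            lps.append(mixture_log_prob(g, fr, mu))
        lp1 = genotype_log_prob(g, fr.p[0])
        lp2 = genotype_log_prob(g, fr.p[1])
        if lp1 > lp2:  # raising the weight of the better cluster helps
            assert lps[0] <= lps[1] <= lps[2]
        elif lp1 < lp2:
            assert lps[0] >= lps[1] >= lps[2]


# ------------------------------------------------------------- log-likelihood


def brute_force_likelihood(theta, data, freqs, cmap, forcing, r2c, t0, t1):
    """Naive direct-product oracle: raw probabilities, nested loops."""
    _, ctraj = project_clusters(
        cmap, forcing, theta, t0, t1, r2c, freqs.clusters
    )
    mu = ctraj.mu()
    total = 1.0
    for i in range(data.n_individuals):
        ci = cmap.index(data.colony_ids[i])
        ti = data.years[i] - t0
        p_g = 0.0
        for r in range(freqs.n_clusters):
            prob_r = 1.0
            for lam in range(data.n_loci):
                c = data.codes[i, lam]
                if c == MISSING:
                    continue
                p = freqs.p[r, lam]
                prob_r *= [(1 - p) ** 2, 2 * p * (1 - p), p**2][c]
            p_g += mu[ci, r, ti] * prob_r
        total *= p_g
    return math.log(total) if total > 0 else -math.inf


def random_tiny_instance(seed):
    rng = np.random.default_rng(seed)
    cmap = make_circular_map(
        n=3,
        circumference=float(rng.uniform(600, 3000)),
        regions=["A", "A", "B"],
        K=rng.uniform(500, 5000, 3),
        n0=rng.uniform(100, 3000, 3),
    )
    forcing = make_forcing(rng.normal(0, 0.2, (3, 6)), t0=2000, rc_star=-0.8)
    theta = Theta(
        d=float(rng.uniform(250, 2000)),
        pm=rng.uniform(0, 1, 2),
        behavior=[Behavior.RANDOM, Behavior.SEMI_INFORMED, Behavior.INFORMED][seed % 3],
    )
    p = rng.uniform(0.05, 0.95, (2, 3))
    freqs = ClusterAlleleFreqs(clusters=["C1", "C2"], locus_ids=["a", "b", "c"], p=p)
    codes = rng.integers(0, 3, size=(5, 3)).astype(np.int8)
    codes[rng.random((5, 3)) < 0.1] = MISSING
    data = GenotypeDataset(
        individual_ids=[f"i{k}" for k in range(5)],
        colony_ids=np.array(rng.choice(cmap.ids, 5), dtype=object),
        years=rng.integers(2001, 2006, 5),
        locus_ids=["a", "b", "c"],
        codes=codes,
    )
    return cmap, forcing, theta, freqs, data


@pytest.mark.parametrize("seed", range(5))
def test_log_likelihood_matches_brute_force_oracle(seed):
    cmap, forcing, theta, freqs, data = random_tiny_instance(seed)
    r2c = {"A": "C1", "B": "C2"}
    got = log_likelihood(theta, data, freqs, cmap, forcing, r2c, t0=2000, t1=2005)
    want = brute_force_likelihood(theta, data, freqs, cmap, forcing, r2c, 2000, 2005)
    assert got == pytest.approx(want, rel=1e-12, abs=1e-12)


def test_likelihood_is_sum_of_independent_individuals():
    cmap, forcing, theta, freqs, data = random_tiny_instance(7)
    r2c = {"A": "C1", "B": "C2"}

    def single(i):
        sub = GenotypeDataset(
            individual_ids=[data.individual_ids[i]],
            colony_ids=data.colony_ids[i : i + 1],
            years=data.years[i : i + 1],
            locus_ids=data.locus_ids,
            codes=data.codes[i : i + 1],
        )
        return log_likelihood(theta, sub, freqs, cmap, forcing, r2c, t0=2000, t1=2005)

    total = log_likelihood(theta, data, freqs, cmap, forcing, r2c, t0=2000, t1=2005)
    assert total == pytest.approx(sum(single(i) for i in range(5)), rel=1e-12)


def test_single_cluster_likelihood_ignores_dispersal_parameters():
    rng = np.random.default_rng(2)
    cmap = make_circular_map(n=3, regions=["A"] * 3)
    forcing = make_forcing(rng.normal(0, 0.2, (3, 5)), rc_star=-0.9)
    freqs = ClusterAlleleFreqs(
        clusters=["C1"], locus_ids=["a", "b"], p=rng.uniform(0.2, 0.8, (1, 2))
    )
    codes = rng.integers(0, 3, (4, 2)).astype(np.int8)
    data = GenotypeDataset(
        individual_ids=list("wxyz"),
        colony_ids=np.array(["c0", "c1", "c2", "c0"], dtype=object),
        years=np.array([2004] * 4),
        locus_ids=["a", "b"],
        codes=codes,
    )
    lls = {
        log_likelihood(
            make_theta(d=d, pm=pm), data, freqs, cmap, forcing, {"A": "C1"}, t0=2000, t1=2004
        )
        for d, pm in [(300, 0.1), (2000, 0.9), (6000, 0.5)]
    }
    assert len({round(v, 9) for v in lls}) == 1


def test_extinct_sampled_colony_gives_zero_likelihood():
    cmap = make_circular_map(n=3, regions=["A"] * 3, n0=[0.0, 500.0, 500.0])
    forcing = make_forcing(np.full((3, 3), -0.1), rc_star=-0.5)
    freqs = ClusterAlleleFreqs(clusters=["C1"], locus_ids=["a"], p=np.array([[0.5]]))
    data = GenotypeDataset(
        individual_ids=["i0"],
        colony_ids=np.array(["c0"], dtype=object),
        years=np.array([2002]),
        locus_ids=["a"],
        codes=np.array([[1]], dtype=np.int8),
    )
    theta = make_theta(behavior=Behavior.RANDOM, pm=0.0)  # nothing immigrates
    ll = log_likelihood(theta, data, freqs, cmap, forcing, {"A": "C1"}, t0=2000, t1=2002)
    assert ll == -np.inf
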