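import itertools
import math

import numpy as np
import pytest

from mtpopgen import (
    DistanceMatrix,
    GroupingScheme,
    PopulationMap,
    amova,
    bh_fdr,
    fixation_indices_from_components,
    pairwise_phi_st,
    permutation_test,
)
from mtpopgen.structure import DesignError, _partition


def dist_from_values(values, prefix="i"):
    labels = tuple(f"{prefix}{k}" for k in range(len(values)))
    return DistanceMatrix(labels, np.asarray(values, dtype=float))


def pm_from_sizes(sizes, prefix="i"):
    entries = {}
    k = 0
    for p, n in enumerate(sizes):
        for _ in range(n):
            entries[f"{prefix}{k}"] = {"locality": f"P{p+1}"}
            k += 1
    return PopulationMap(entries)


def scalar_design(values_by_pop):
    """Scalar observations embedded as squared-Euclidean distances, so AMOVA
    sums of squares can be checked against classical nested ANOVA."""
    flat = [v for pop in values_by_pop for v in pop]
    n = len(flat)
    d2 = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            d2[i, j] = (flat[i] - flat[j]) ** 2
    return dist_from_values(d2), pm_from_sizes([len(p) for p in values_by_pop])


def test_fixation_index_identity_on_published_style_components():
    idx = fixation_indices_from_components(0.747, 0.119, 1.158)
    assert (1 - idx["phi_st"]) == pytest.approx(
        (1 - idx["phi_ct"]) * (1 - idx["phi_sc"])
    )


def test_two_population_fixed_difference_phi_st_is_one(make_aln, make_pm):
    # within-population identical haplotypes, fixed difference between
    d2 = np.zeros((4, 4))
    for i, j in itertools.product(range(4), repeat=2):
        d2[i, j] = 0 if (i < 2) == (j < 2) else 4.0
    res = amova(dist_from_values(d2), pm_from_sizes([2, 2]), n_perm=0)
    assert res.phi_st == pytest.approx(1.0)


def test_amova_sums_of_squares_match_scalar_anova():
    """1-D data: AMOVA SSDs must equal classical nested-ANOVA sums of squares."""
    rng = np.random.default_rng(4)
    pops = [list(rng.normal(m, 1.0, n)) for m, n in [(0, 5), (0.5, 7), (3, 4), (3.5, 6)]]
    dist, pm = scalar_design(pops)
    grouping = GroupingScheme("g", {"P1": "A", "P2": "A", "P3": "B", "P4": "B"})
    res = amova(dist, pm, grouping, n_perm=0)
    flat = np.concatenate(pops)
    grand = flat.mean()
    pop_means = [np.mean(p) for p in pops]
    group_vals = [np.concatenate(pops[:2]), np.concatenate(pops[2:])]
    group_means = [g.mean() for g in group_vals]
    ss_total = np.sum((flat - grand) ** 2)
    ss_wp = sum(np.sum((np.asarray(p) - m) ** 2) for p, m in zip(pops, pop_means))
    ss_wg = sum(np.sum((g - m) ** 2) for g, m in zip(group_vals, group_means))
    ssd = res.rows["SSD"].to_numpy()
    assert ssd[2] == pytest.approx(ss_wp)
    assert ssd[1] == pytest.approx(ss_wg - ss_wp)
    assert ssd[0] == pytest.approx(ss_total - ss_wg)
    assert ssd.sum() == pytest.approx(ss_total, abs=1e-9)
    # df bookkeeping: sums to N-1
    assert res.rows["d.f."].sum() == len(flat) - 1
    # percent variation sums to 100
    assert res.rows["% var"].sum() == pytest.approx(100.0, abs=0.1)


def test_amova_index_identity_holds_every_run():
    rng = np.random.default_rng(8)
    pops = [list(rng.normal(m, 1.0, n)) for m, n in [(0, 4), (1, 6), (4, 5), (6, 3)]]
    dist, pm = scalar_design(pops)
    grouping = GroupingScheme("g", {"P1": "A", "P2": "A", "P3": "B", "P4": "B"})
    res = amova(dist, pm, grouping, n_perm=0)
    assert (1 - res.phi_st) == pytest.approx(
        (1 - res.phi_ct) * (1 - res.phi_sc), abs=1e-9
    )


def test_two_population_amova_equals_pairwise_entry():
    rng = np.random.default_rng(3)
    pops = [list(rng.normal(0, 1, 6)), list(rng.normal(2, 1, 5))]
    dist, pm = scalar_design(pops)
    res = amova(dist, pm, n_perm=0)
    phi = pairwise_phi_st(dist, pm, n_perm=0)
    assert phi.values[0, 1] == pytest.approx(res.phi_st, abs=1e-12)


def test_permutation_p_matches_exhaustive_enumeration():
    """3 populations x 2 individuals: compare against all index partitions."""
    rng = np.random.default_rng(5)
    vals = [list(rng.normal(m, 0.5, 2)) for m in (0, 1, 5)]
    dist, pm = pm_and_dist = scalar_design(vals)
    d2 = dist.values
    sizes = [2, 2, 2]

    def phi_of(partition):
        pops = [np.array(p) for p in partition]
        part = _partition(d2, pops, None)
        sa, sc = part["sigma"]
        return sa / (sa + sc)

    observed = phi_of([[0, 1], [2, 3], [4, 5]])
    # exhaustive: all ways to split 6 individuals into ordered pops of size 2
    count_ge = 0
    total = 0
    for perm in itertools.permutations(range(6)):
        partition = [sorted(perm[0:2]), sorted(perm[2:4]), sorted(perm[4:6])]
        stat = phi_of(partition)
        total += 1
        if stat >= observed - 1e-12:
            count_ge += 1
    exact_p = count_ge / total
    # estimator p uses (b+1)/(B+1); with large B it converges to exact_p
    p = permutation_test(dist, pm, None, "phi_st", n_perm=4000, seed=1)
    assert p == pytest.approx(exact_p, abs=0.03)


def test_permutation_p_bound_cases():
    # two well-separated pops: observed phi above every permuted value
    rng = np.random.default_rng(6)
    vals = [list(rng.normal(0, 0.01, 5)), list(rng.normal(10, 0.01, 5))]
    dist, pm = scalar_design(vals)
    p = permutation_test(dist, pm, None, "phi_st", n_perm=99, seed=0)
    # only permutations recreating the observed split tie the statistic, so
    # p sits at (1 + #ties)/(B + 1), bounded below by the +1 convention
    assert 1 / 100 <= p <= 5 / 100

    # anti-structured design: observed statistic below almost every permuted
    lo, hi = list(rng.normal(0, 0.01, 3)), list(rng.normal(10, 0.01, 3))
    mixed = [[lo[0], hi[0], lo[1]], [hi[1], lo[2], hi[2]]]
    dist, pm = scalar_design(mixed)
    p = permutation_test(dist, pm, None, "phi_st", n_perm=99, seed=0)
    assert p > 0.5


def test_phi_ct_requires_grouping():
    rng = np.random.default_rng(7)
    vals = [list(rng.normal(0, 1, 3)), list(rng.normal(0, 1, 3))]
    dist, pm = scalar_design(vals)
    with pytest.raises(DesignError):
        permutation_test(dist, pm, None, "phi_ct", n_perm=10)


def test_null_phi_ct_near_zero_and_p_not_extreme():
    """Groups assembled by splitting one panmictic deme: Phi_CT ~ 0."""
    from mtpopgen import (
        SimConfig,
        SubstitutionModelConfig,
        pairwise_distance_matrix,
        simulate_coalescent,
    )

    phis, ps = [], []
    for i in range(10):
        ds = simulate_coalescent(
            SimConfig(demes=1, sample_sizes=24, theta=5, sequence_length=500, seed=100 + i)
        )
        # arbitrary split into 4 pseudo-populations of 6, grouped 2+2
        entries = {
            ind: {"locality": f"P{k // 6 + 1}"}
            for k, ind in enumerate(ds.alignment.ids)
        }
        pm = PopulationMap(entries)
        dm = pairwise_distance_matrix(
            ds.alignment, SubstitutionModelConfig(model="p-distance")
        )
        grouping = GroupingScheme("null", {"P1": "A", "P2": "A", "P3": "B", "P4": "B"})
        res = amova(dm, pm, grouping, n_perm=100, seed=i)
        phis.append(res.phi_ct)
        ps.append(res.p_phi_ct)
    assert abs(np.mean(phis)) < 0.05
    assert 0.05 < np.mean(ps) < 0.95  # p roughly uniform under the null


def test_bh_fdr_hand_case_and_brute_force():
    adj, rej = bh_fdr([0.01, 0.02, 0.04], q=0.05)
    assert rej.all()  # largest k with p_(k) <= k*q/m is k = 3

    def brute_force(pvals, q):
        m = len(pvals)
        order = np.argsort(pvals)
        k_star = 0
        for k in range(1, m + 1):
            if pvals[order[k - 1]] <= k * q / m:
                k_star = k
        reject = np.zeros(m, dtype=bool)
        reject[order[:k_star]] = True
        return reject

    rng = np.random.default_rng(11)
    for trial in range(50):
        m = int(rng.integers(1, 11))
        pv = np.round(rng.random(m), 3)
        adj, rej = bh_fdr(pv, q=0.05)
        assert np.array_equal(rej, brute_force(pv, 0.05))
        # adjusted p monotone in rank
        order = np.argsort(pv)
        assert np.all(np.diff(adj[order]) >= -1e-12)


def test_bh_fdr_empty_and_single():
    adj, rej = bh_fdr([])
    assert adj.size == 0
    adj, rej = bh_fdr([0.2])
    assert adj[0] == pytest.approx(0.2)


def test_pairwise_phi_st_identical_and_fixed(make_aln):
    # identical demes -> ~0; fixed different haplotypes -> 1
    d2 = np.zeros((6, 6))
    res = pairwise_phi_st(dist_from_values(d2 + 0.0), pm_from_sizes([3, 3]), n_perm=0)
    assert math.isnan(res.values[0, 1])  # all-zero distances: undefined

    for i, j in itertools.product(range(6), repeat=2):
        d2[i, j] = 0 if (i < 3) == (j < 3) else 2.0
    res = pairwise_phi_st(dist_from_values(d2), pm_from_sizes([3, 3]), n_perm=0)
    assert res.values[0, 1] == pytest.approx(1.0)


def test_grouping_presets_cover_study_localities():
    from mtpopgen import GROUPING_PRESETS

    a = GROUPING_PRESETS["coi_A"]
    assert len(a.assignment) == 27
    assert a.assignment["VEN"] == "G1"
    b = GROUPING_PRESETS["coi_B"]
    assert b.assignment["VEN"] == "G3"
    assert GROUPING_PRESETS["concat_A"].assignment["EP"] == "G2"
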