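import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from scipy.stats import poisson

from mtpopgen import (
    DatingConfig,
    SimConfig,
    fit_sudden_expansion,
    fus_fs,
    mismatch_expected,
    mismatch_observed,
    simulate_coalescent,
    ssd_pvalue,
    tajimas_d,
    time_since_expansion,
)
from mtpopgen.demography import _ssd, ewens_k_tail_probability
from mtpopgen.diversity import InsufficientDataError


# ---------------------------------------------------------------------------
# observed mismatch histogram
# ---------------------------------------------------------------------------

def test_mismatch_observed_identical_and_hand_case(make_aln):
    h = mismatch_observed(make_aln(["AAAA"] * 3))
    assert h.tolist() == [3]
    aln = make_aln(["AAAA", "AAAT", "ATCT"])  # pairwise diffs {1, 2, 3}
    assert mismatch_observed(aln).tolist() == [0, 1, 1, 1]


def test_mismatch_observed_matches_double_loop(random_alignment):
    aln = random_alignment(10, 40, p=0.1, seed=6)
    h = mismatch_observed(aln)
    diffs = [
        sum(a != b for a, b in zip(x, y))
        for x, y in itertools.combinations(aln.sequences, 2)
    ]
    assert h.sum() == aln.n * (aln.n - 1) / 2
    expected = np.bincount(diffs)
    assert h.tolist() == expected.tolist()


# ---------------------------------------------------------------------------
# model curve
# ---------------------------------------------------------------------------

def test_expected_equilibrium_limit_at_tau_zero():
    th = 2.0
    e = mismatch_expected(0.0, th, 50.0, 20, tail="none")
    ref = np.array([th**i / (1 + th) ** (i + 1) for i in range(21)])
    assert np.abs(e - ref).max() < 1e-9


def test_expected_poisson_limit():
    e = mismatch_expected(3.0, 0.0, 1e9, 40, tail="none")
    assert np.abs(e - poisson.pmf(np.arange(41), 3.0)).max() < 1e-3


def test_expected_matches_transcription_oracle():
    """Direct (slow) transcription of the sudden-expansion closed form."""

    def oracle(i, tau, th0, th1):
        def feq(j, th):
            return th**j / (1 + th) ** (j + 1)

        total = feq(i, th1)
        decay = math.exp(-tau * (th1 + 1) / th1)
        for j in range(i + 1):
            total += decay * tau**j / math.factorial(j) * (feq(i - j, th0) - feq(i - j, th1))
        return total

    for tau, th0, th1 in [(1.5, 0.5, 8.0), (4.0, 1.0, 30.0), (0.3, 2.0, 2.5)]:
        e = mismatch_expected(tau, th0, th1, 25, tail="none")
        ref = [oracle(i, tau, th0, th1) for i in range(26)]
        assert np.abs(e - np.asarray(ref)).max() < 1e-10


def test_expected_sums_to_one_on_wide_support():
    tau, th0, th1 = 5.0, 1.0, 20.0
    e = mismatch_expected(tau, th0, th1, int(10 * (tau + th1)), tail="none")
    assert e.sum() == pytest.approx(1.0, abs=1e-6)
    folded = mismatch_expected(tau, th0, th1, 15, tail="fold")
    assert folded.sum() == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# fitting and SSD
# ---------------------------------------------------------------------------

def test_ssd_invariant_to_zero_padding():
    counts = np.array([0, 5, 9, 4, 1], dtype=float)
    padded = np.concatenate([counts, np.zeros(10)])
    assert _ssd(counts, 2.0, 0.5, 10.0) == pytest.approx(
        _ssd(padded, 2.0, 0.5, 10.0)
    )


def test_fit_recovers_generating_parameters_from_exact_curve():
    probs = mismatch_expected(4.0, 1.0, 30.0, 30, tail="none")
    fit = fit_sudden_expansion(probs * 1e6, n=50, n_restarts=10, seed=1)
    assert fit.ssd < 1e-10
    assert fit.tau == pytest.approx(4.0, abs=0.01)
    assert fit.theta0 == pytest.approx(1.0, abs=0.01)


def test_fit_on_equilibrium_data_low_tau_or_good_fit():
    # equilibrium histogram: the no-growth geometric curve
    th = 3.0
    probs = np.array([th**i / (1 + th) ** (i + 1) for i in range(30)])
    fit = fit_sudden_expansion(probs * 1e5, n=40, n_restarts=10, seed=2)
    # either tau collapses toward 0 or the model nests equilibrium well
    assert fit.ssd < 1e-6


def test_pin_theta1_mode():
    probs = mismatch_expected(3.0, 0.5, 25.0, 25, tail="none")
    fit = fit_sudden_expansion(probs * 1e6, n=50, pin_theta1=25.0, n_restarts=8, seed=3)
    assert fit.theta1 == 25.0
    assert fit.tau == pytest.approx(3.0, abs=0.05)


def test_ssd_pvalue_is_one_when_observed_ssd_zero():
    probs = mismatch_expected(2.0, 0.5, 15.0, 20, tail="none")
    fit = fit_sudden_expansion(probs * 1e6, n=30, analysed_length=300, n_restarts=6, seed=4)
    assert fit.ssd < 1e-10
    p = ssd_pvalue(fit, B=19, seed=5)
    assert p == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

def tajima_oracle(n, S, d):
    """Independent textbook transcription of the D statistic."""
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    return (d - S / a1) / math.sqrt(c1 / a1 * S + c2 / (a1**2 + a2) * S * (S - 1))


def test_tajimas_d_undefined_without_variation(make_aln):
    assert math.isnan(tajimas_d(make_aln(["AAAA"] * 5)))


def test_tajimas_d_matches_formula_oracle(random_alignment):
    from mtpopgen import mean_pairwise_differences, segregating_sites

    checked = 0
    for seed in range(40):
        aln = random_alignment(10, 60, p=0.05, seed=seed)
        S = segregating_sites(aln)
        if S == 0:
            continue
        ref = tajima_oracle(aln.n, S, mean_pairwise_differences(aln))
        assert tajimas_d(aln) == pytest.approx(ref, abs=1e-10)
        checked += 1
    assert checked >= 30


def test_tajimas_d_agrees_with_independent_library(random_alignment):
    dendropy = pytest.importorskip("dendropy")
    from dendropy.calculate import popgenstat

    aln = random_alignment(12, 80, p=0.06, seed=5)
    mat = dendropy.DnaCharacterMatrix.from_dict(dict(aln.records))
    assert tajimas_d(aln) == pytest.approx(popgenstat.tajimas_d(mat), abs=1e-10)


# ---------------------------------------------------------------------------
# Fu's Fs
# ---------------------------------------------------------------------------

def exact_ewens_tail(n, k, theta):
    th = Fraction(theta).limit_denominator(10**9)
    s = [[Fraction(0)] * (n + 1) for _ in range(n + 1)]
    s[0][0] = Fraction(1)
    for m in range(1, n + 1):
        for kk in range(1, m + 1):
            s[m][kk] = s[m - 1][kk] * (m - 1) + s[m - 1][kk - 1]
    rising = Fraction(1)
    for i in range(n):
        rising *= th + i
    return float(sum(s[n][kk] * th**kk for kk in range(k, n + 1)) / rising)


def test_ewens_tail_matches_exact_arithmetic_for_small_n():
    for n in range(2, 9):
        for k in range(1, n + 1):
            for theta in (0.3, 1.0, 2.5, 7.0):
                assert ewens_k_tail_probability(n, k, theta) == pytest.approx(
                    exact_ewens_tail(n, k, theta), abs=1e-12
                )


def test_fus_fs_undefined_for_identical_pair(make_aln):
    assert math.isnan(fus_fs(make_aln(["ACGT", "ACGT"])))


def test_fus_fs_sign_reflects_haplotype_excess(make_aln):
    # many distinct haplotypes at low divergence -> strongly negative Fs
    seqs = ["AAAAAAAAAA"]
    for j in range(7):
        s = list("AAAAAAAAAA")
        s[j] = "T"
        seqs.append("".join(s))
    fs_excess = fus_fs(make_aln(seqs))
    assert fs_excess < 0
    # two deeply divergent clusters, few haplotypes -> positive Fs
    seqs2 = ["AAAAAAAAAA"] * 4 + ["TTTTTTTTTT"] * 4
    aln2 = make_aln(seqs2)
    assert fus_fs(aln2) > 0


def test_fus_fs_large_sample_is_finite(random_alignment):
    aln = random_alignment(320, 60, p=0.03, seed=12)
    fs = fus_fs(aln)
    assert math.isfinite(fs)


# ---------------------------------------------------------------------------
# expansion signatures on simulated data
# ---------------------------------------------------------------------------

def test_growth_simulations_give_negative_d_and_fs():
    """Strong recent growth (theta 100x) leaves negative D and Fs."""
    neg_d = neg_f = 0
    reps = 30
    for i in range(reps):
        ds = simulate_coalescent(
            SimConfig(
                demes=1,
                sample_sizes=30,
                theta=10.0,
                expansion=(3.0, 0.1, 10.0),
                sequence_length=500,
                seed=500 + i,
            )
        )
        d = tajimas_d(ds.alignment)
        f = fus_fs(ds.alignment)
        if not math.isnan(d) and d < 0:
            neg_d += 1
        if not math.isnan(f) and f < 0:
            neg_f += 1
    assert neg_d >= 0.9 * reps
    assert neg_f >= 0.9 * reps


def test_bimodal_mixture_rejected_by_ssd_test():
    """Two deep lineages produce a bimodal histogram the sudden-expansion
    model cannot reproduce: SSD p-value should be small."""
    rng = np.random.default_rng(77)
    from mtpopgen import AlignedSequenceSet

    base = rng.choice(list("ACGT"), 300)
    other = base.copy()
    for j in rng.choice(300, 25, replace=False):
        other[j] = rng.choice([b for b in "ACGT" if b != other[j]])
    recs = []
    for i in range(15):
        s = base.copy()
        for j in rng.choice(300, rng.integers(0, 3), replace=False):
            s[j] = rng.choice([b for b in "ACGT" if b != s[j]])
        recs.append((f"a{i}", "".join(s)))
    for i in range(15):
        s = other.copy()
        for j in rng.choice(300, rng.integers(0, 3), replace=False):
            s[j] = rng.choice([b for b in "ACGT" if b != s[j]])
        recs.append((f"b{i}", "".join(s)))
    aln = AlignedSequenceSet(tuple(recs), 300)
    counts = mismatch_observed(aln)
    fit = fit_sudden_expansion(counts, aln.n, analysed_length=300, n_restarts=10, seed=9)
    p = ssd_pvalue(fit, B=99, seed=10)
    assert p < 0.05


# ---------------------------------------------------------------------------
# dating
# ---------------------------------------------------------------------------

def test_dating_zero_tau():
    out = time_since_expansion(0.0, DatingConfig(sequence_length=338))
    assert out.t_years == 0.0


def test_dating_printed_constants_arithmetic():
    """tau=5, s=338, 0.52%/Myr unhalved, 2-year generations."""
    out = time_since_expansion(5.0, DatingConfig(sequence_length=338))
    assert out.mu == pytest.approx(1.04e-8)
    assert out.u == pytest.approx(3.5152e-6)
    assert out.t_generations == pytest.approx(711_197.9, rel=1e-4)
    assert out.t_years == pytest.approx(1.422e6, rel=1e-3)


def test_dating_algebra_scaling():
    base = time_since_expansion(5.0, DatingConfig(sequence_length=338))
    double_s = time_since_expansion(5.0, DatingConfig(sequence_length=676))
    assert double_s.t_years == pytest.approx(base.t_years / 2)
    halved = time_since_expansion(
        5.0, DatingConfig(sequence_length=338, halve_rate=True)
    )
    assert halved.t_years == pytest.approx(2 * base.t_years)


def test_dating_transforms_ci_endpoints():
    out = time_since_expansion(
        5.0, DatingConfig(sequence_length=338), tau_ci=(2.5, 10.0)
    )
    assert out.ci_years[0] == pytest.approx(out.t_years / 2)
    assert out.ci_years[1] == pytest.approx(out.t_years * 2)
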