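"""Mismatch-distribution demographic inference, neutrality tests, and
expansion dating.

The sudden-expansion model: a population at mutation-drift equilibrium with
scaled size theta0 grew instantaneously to theta1 at a time tau (in units
of 1/(2u) generations, u the locus mutation rate) before sampling. The
probability of observing i pairwise differences is

    F_i = Feq(i, theta1)
        + exp(-tau * (theta1 + 1) / theta1)
          * sum_{j=0..i} tau^j / j! * [Feq(i-j, theta0) - Feq(i-j, theta1)]

with the equilibrium geometric form Feq(i, th) = th^i / (1 + th)^(i+1).
At tau = 0 this collapses to Feq(i, theta0); for theta0 = 0 and
theta1 -> inf it tends to Poisson(tau).

Model fit minimises the sum of squared deviations (SSD) between observed
relative frequencies and model probabilities; significance and the tau CI
come from a parametric bootstrap that re-simulates coalescent samples
under the fitted model and refits each.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, gammaln, logit

from .diversity import (
    InsufficientDataError,
    _encoded,
    mean_pairwise_differences,
    segregating_sites,
)
from .seqio import AlignedSequenceSet


# ---------------------------------------------------------------------------
# mismatch distribution
# ---------------------------------------------------------------------------

def mismatch_observed(aln: AlignedSequenceSet) -> np.ndarray:
    """Histogram of pairwise difference counts; sums to n(n-1)/2."""
    if aln.n < 2:
        raise InsufficientDataError("need >= 2 sequences")
    m = _encoded(aln)
    n = aln.n
    diffs = []
    for i in range(n):
        d = np.sum(m[i + 1 :] != m[i], axis=1)
        diffs.append(d)
    diffs = np.concatenate(diffs)
    return np.bincount(diffs)


def _f_eq(i: np.ndarray, theta: float) -> np.ndarray:
    """Equilibrium geometric distribution of pairwise differences."""
    i = np.asarray(i)
    if theta <= 0:
        return (i == 0).astype(float)
    # th^i/(1+th)^(i+1) in log space to survive large i
    return np.exp(i * math.log(theta) - (i + 1) * math.log1p(theta))


def mismatch_expected(
    tau: float,
    theta0: float,
    theta1: float,
    support_max: int,
    tail: str = "fold",
) -> np.ndarray:
    """Model probabilities of 0..support_max differences.

    ``tail="fold"`` folds the truncated upper tail mass into the last bin so
    the vector sums to 1; ``tail="none"`` returns raw probabilities.
    """
    if min(tau, theta0, theta1) < 0:
        raise ValueError("parameters must be >= 0")
    i = np.arange(support_max + 1)
    if tau == 0:
        probs = _f_eq(i, theta0)
    elif theta1 <= 0:
        probs = _f_eq(i, 0.0)
    else:
        feq1 = _f_eq(i, theta1)
        feq0 = _f_eq(i, theta0)
        # Poisson-like factors tau^j/j! times the decay exp(-tau(1+th1)/th1)
        logw = i * math.log(tau) - gammaln(i + 1) if tau > 0 else np.where(i == 0, 0.0, -np.inf)
        w = np.exp(logw - tau * (theta1 + 1.0) / theta1)
        probs = feq1 + np.convolve(w, feq0 - feq1)[: support_max + 1]
        probs = np.clip(probs, 0.0, None)
    if tail == "fold":
        probs = probs.copy()
        probs[-1] += max(1.0 - probs.sum(), 0.0)
    elif tail != "none":
        raise ValueError(f"unknown tail mode {tail!r}")
    return probs


@dataclass
class MismatchFit:
    observed: np.ndarray
    n: int
    analysed_length: int
    tau: float
    theta0: float
    theta1: float
    ssd: float
    ssd_p: Optional[float] = None
    tau_ci: Optional[tuple[float, float]] = None
    converged: bool = True

    @property
    def support(self) -> int:
        """Last index with a non-zero observed count (SSD truncation point)."""
        nz = np.nonzero(self.observed)[0]
        return int(nz[-1]) if nz.size else 0

    def expected(self, tail: str = "none") -> np.ndarray:
        return mismatch_expected(self.tau, self.theta0, self.theta1, self.support, tail)


def _ssd(counts: np.ndarray, tau, theta0, theta1) -> float:
    nz = np.nonzero(counts)[0]
    k = int(nz[-1]) if nz.size else 0
    f = counts[: k + 1] / counts.sum()
    e = mismatch_expected(tau, theta0, theta1, k, tail="none")
    return float(np.sum((f - e) ** 2))


def fit_sudden_expansion(
    observed: np.ndarray,
    n: int,
    analysed_length: int = 0,
    n_restarts: int = 20,
    seed: int = 0,
    pin_theta1: Optional[float] = None,
    extra_starts: Sequence[tuple[float, float, float]] = (),
) -> MismatchFit:
    """Least-squares (tau, theta0, theta1) for an observed mismatch histogram.

    Bounded multi-start Nelder-Mead on a sigmoid-transformed parameter
    space; bounds tau in [0, 4*max_diff], theta in [0, 10*mean_diff].
    ``pin_theta1`` fixes theta1 (the reduced two-parameter variant).
    """
    counts = np.asarray(observed, dtype=float)
    if counts.sum() <= 0:
        raise ValueError("empty histogram")
    nz = np.nonzero(counts)[0]
    kmax = int(nz[-1]) if nz.size else 0
    freqs = counts / counts.sum()
    d_hat = float(np.sum(np.arange(len(freqs)) * freqs))
    hi_tau = max(4.0 * kmax, 1.0)
    hi_th = max(10.0 * d_hat, 1.0)
    lo = np.array([0.0, 0.0, 0.0])
    hi = np.array([hi_tau, hi_th, hi_th])

    def unpack(z):
        p = lo + (hi - lo) * expit(z)
        if pin_theta1 is not None:
            p[2] = pin_theta1
        return p

    # fast inline SSD: precompute support arrays once per fit
    i_arr = np.arange(kmax + 1, dtype=float)
    lgam = gammaln(i_arr + 1.0)
    f_obs = freqs[: kmax + 1]

    def _expected_fast(tau, th0, th1):
        if th0 <= 0:
            feq0 = np.zeros(kmax + 1)
            feq0[0] = 1.0
        else:
            feq0 = np.exp(i_arr * math.log(th0) - (i_arr + 1) * math.log1p(th0))
        if tau == 0:
            return feq0
        if th1 <= 0:
            out = np.zeros(kmax + 1)
            out[0] = 1.0
            return out
        feq1 = np.exp(i_arr * math.log(th1) - (i_arr + 1) * math.log1p(th1))
        w = np.exp(i_arr * math.log(tau) - lgam - tau * (th1 + 1.0) / th1)
        e = feq1 + np.convolve(w, feq0 - feq1)[: kmax + 1]
        return np.clip(e, 0.0, None)

    def objective(z):
        tau, th0, th1 = unpack(z)
        e = _expected_fast(tau, th0, th1)
        r = f_obs - e
        return float(r @ r)

    def squash(p):
        frac = np.clip((p - lo) / (hi - lo), 1e-6, 1.0 - 1e-6)
        return logit(frac)

    rng = np.random.default_rng(seed)
    # warm starts (supplied, then method-of-moments) come first so a small
    # n_restarts still uses them; random scatter fills the rest
    starts = [np.asarray(s, dtype=float) for s in extra_starts]
    starts += [
        np.array([max(d_hat, 0.5), 0.1 * max(d_hat, 0.5), 0.9 * hi_th]),
        np.array([0.5 * max(d_hat, 0.5), 0.01, 0.5 * hi_th]),
    ]
    n_starts = max(n_restarts, len(extra_starts) or 1)
    while len(starts) < n_starts:
        starts.append(lo + (hi - lo) * rng.random(3))
    best = None
    ok = False
    for p0 in starts[:n_starts]:
        res = minimize(
            objective,
            squash(np.clip(p0, lo + 1e-9, hi - 1e-9)),
            method="Nelder-Mead",
            options={"xatol": 1e-5, "fatol": 1e-12, "maxiter": 300},
        )
        if best is None or res.fun < best.fun:
            best = res
            ok = bool(res.success)
    tau, th0, th1 = unpack(best.x)
    return MismatchFit(
        observed=counts,
        n=n,
        analysed_length=analysed_length,
        tau=float(tau),
        theta0=float(th0),
        theta1=float(th1),
        ssd=float(best.fun),
        converged=ok,
    )


def parametric_bootstrap(
    fit: MismatchFit,
    B: int = 10_000,
    seed: int = 0,
    n_restarts: int = 2,
) -> np.ndarray:
    """Re-simulate B coalescent samples under the fitted expansion model and
    refit each; returns an array of shape (B, 2) with columns (tau, SSD)."""
    from .simdata import SimConfig, simulate_coalescent  # local import: avoid cycle

    if B < 1:
        raise ValueError("B must be >= 1")
    L = fit.analysed_length or max(10 * fit.support, 100)
    rng = np.random.default_rng(seed)
    out = np.empty((B, 2))
    for b in range(B):
        cfg = SimConfig(
            demes=1,
            sample_sizes=fit.n,
            theta=fit.theta1,
            expansion=(fit.tau, fit.theta0, fit.theta1),
            sequence_length=L,
            seed=int(rng.integers(1, 2**31 - 1)),
        )
        ds = simulate_coalescent(cfg)
        counts = mismatch_observed(ds.alignment)
        refit = fit_sudden_expansion(
            counts,
            fit.n,
            analysed_length=L,
            n_restarts=n_restarts,
            seed=int(rng.integers(1, 2**31 - 1)),
            extra_starts=[(fit.tau, fit.theta0, fit.theta1)],
        )
        out[b] = (refit.tau, refit.ssd)
    return out


def ssd_pvalue(
    fit: MismatchFit,
    B: int = 10_000,
    seed: int = 0,
    boot: Optional[np.ndarray] = None,
) -> float:
    """P(simulated SSD >= observed SSD) under the fitted model, (b+1)/(B+1)."""
    if boot is None:
        boot = parametric_bootstrap(fit, B=B, seed=seed)
    b = int(np.sum(boot[:, 1] >= fit.ssd - 1e-15))
    return (b + 1) / (len(boot) + 1)


def tau_confidence_interval(
    fit: MismatchFit,
    B: int = 10_000,
    level: float = 0.95,
    seed: int = 0,
    boot: Optional[np.ndarray] = None,
) -> tuple[float, float]:
    """Percentile bootstrap CI for tau."""
    if boot is None:
        boot = parametric_bootstrap(fit, B=B, seed=seed)
    a = (1.0 - level) / 2.0
    lo, hi = np.quantile(boot[:, 0], [a, 1.0 - a])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# neutrality tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NeutralityResult:
    n: int
    S: int
    tajima_d: Optional[float]
    fu_fs: Optional[float]
    p_tajima: Optional[float] = None
    p_fu: Optional[float] = None


def tajimas_d(aln: AlignedSequenceSet) -> float:
    """Tajima's D = (d - S/a1) / sqrt(e1*S + e2*S*(S-1))."""
    n = aln.n
    if n < 2:
        raise InsufficientDataError("need >= 2 sequences")
    S = segregating_sites(aln)
    if S == 0:
        return math.nan
    d = mean_pairwise_differences(aln)
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (d - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1.0))


def _log_stirling_first(n: int) -> np.ndarray:
    """log of unsigned Stirling numbers |s(n, k)| for k = 0..n."""
    log_s = np.full(n + 1, -np.inf)
    log_s[1] = 0.0  # |s(1,1)| = 1
    for m in range(1, n):
        nxt = np.full(n + 1, -np.inf)
        # |s(m+1,k)| = m*|s(m,k)| + |s(m,k-1)|
        nxt[1:] = np.logaddexp(math.log(m) + log_s[1:], log_s[:-1])
        nxt[0] = -np.inf
        log_s = nxt
    return log_s


def ewens_k_tail_probability(n: int, k_obs: int, theta: float) -> float:
    """S' = P(K >= k_obs | theta, n) under the Ewens sampling distribution."""
    if theta <= 0:
        return 1.0 if k_obs <= 1 else 0.0
    log_s = _log_stirling_first(n)
    k = np.arange(n + 1)
    log_terms = log_s + k * math.log(theta)
    log_rising = sum(math.log(theta + i) for i in range(n))
    log_p = log_terms - log_rising
    tail = np.exp(log_p[k_obs:]).sum()
    return float(min(max(tail, 0.0), 1.0))


def fus_fs(aln: AlignedSequenceSet) -> float:
    """Fu's Fs = ln(S'/(1-S')) with S' = P(K >= k_obs | theta = d)."""
    n = aln.n
    if n < 2:
        raise InsufficientDataError("need >= 2 sequences")
    k_obs = len(set(aln.sequences))
    d = mean_pairwise_differences(aln)
    if d <= 0:
        return math.nan  # undefined without variation
    sp = ewens_k_tail_probability(n, k_obs, d)
    if sp <= 0.0:
        return math.inf
    if sp >= 1.0:
        return -math.inf
    return math.log(sp / (1.0 - sp))


def neutrality_tests(
    aln: AlignedSequenceSet,
    n_sims: int = 1000,
    seed: int = 0,
) -> NeutralityResult:
    """D and Fs with one-tailed (lower) p-values from a neutral
    constant-size coalescent null simulated at theta = observed d."""
    from .simdata import SimConfig, simulate_coalescent

    S = segregating_sites(aln)
    if S == 0:
        return NeutralityResult(aln.n, 0, None, None)
    D = tajimas_d(aln)
    Fs = fus_fs(aln)
    p_d = p_f = None
    if n_sims > 0:
        theta = mean_pairwise_differences(aln)
        rng = np.random.default_rng(seed)
        bd = bf = 0
        for _ in range(n_sims):
            ds = simulate_coalescent(
                SimConfig(
                    demes=1,
                    sample_sizes=aln.n,
                    theta=theta,
                    sequence_length=aln.length,
                    seed=int(rng.integers(1, 2**31 - 1)),
                )
            )
            try:
                d_sim = tajimas_d(ds.alignment)
                f_sim = fus_fs(ds.alignment)
            except InsufficientDataError:
                continue
            if not math.isnan(d_sim) and d_sim <= D:
                bd += 1
            if not math.isnan(f_sim) and f_sim <= Fs:
                bf += 1
        p_d = (bd + 1) / (n_sims + 1)
        p_f = (bf + 1) / (n_sims + 1)
    return NeutralityResult(aln.n, S, D, Fs, p_d, p_f)


# ---------------------------------------------------------------------------
# expansion dating
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DatingConfig:
    sequence_length: int
    generation_time_years: float = 2.0
    divergence_rate_pct_per_myr: float = 0.52
    halve_rate: bool = False  # treat the divergence rate as twice the per-lineage rate


@dataclass(frozen=True)
class ExpansionDating:
    tau: float
    u: float  # mutation rate per fragment per generation
    mu: float  # per-nucleotide per-generation rate
    t_generations: float
    t_years: float
    ci_years: Optional[tuple[float, float]]
    config: DatingConfig


def time_since_expansion(
    tau: float,
    cfg: DatingConfig,
    tau_ci: Optional[tuple[float, float]] = None,
) -> ExpansionDating:
    """t = tau / (2u) with u = mu * s; years via the generation time.

    mu is the divergence rate per site per year times the generation time,
    halved first when ``halve_rate`` is set (per-lineage convention).
    """
    if tau < 0 or cfg.sequence_length <= 0 or cfg.divergence_rate_pct_per_myr <= 0:
        raise ValueError("tau >= 0, s > 0 and rate > 0 required")
    rate_per_site_per_year = cfg.divergence_rate_pct_per_myr / 100.0 / 1e6
    if cfg.halve_rate:
        rate_per_site_per_year /= 2.0
    mu = rate_per_site_per_year * cfg.generation_time_years
    u = mu * cfg.sequence_length
    t_gen = tau / (2.0 * u) if tau > 0 else 0.0
    t_years = t_gen * cfg.generation_time_years
    ci = None
    if tau_ci is not None:
        ci = tuple(
            x / (2.0 * u) * cfg.generation_time_years if x > 0 else 0.0
            for x in tau_ci
        )
    return ExpansionDating(tau, u, mu, t_gen, t_years, ci, cfg)
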