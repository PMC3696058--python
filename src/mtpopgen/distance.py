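"""Pairwise sequence distances: p-distance and Tamura-Nei (1993), with
optional gamma rate-heterogeneity correction.

The TN93 distance separates the two transition classes (A<->G within
purines, C<->T within pyrimidines) from transversions and corrects each
multiple-hit term with the empirical base composition. With a gamma shape
``alpha`` each logarithmic term ``-ln(x)`` is replaced by its
gamma-integrated counterpart ``alpha * (x**(-1/alpha) - 1)`` (term
substitution, the convention used by distance-based population software).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .seqio import AlignedSequenceSet, HaplotypeTable


class SaturationError(ValueError):
    """A correction term's argument was non-positive (distance saturated)."""

    def __init__(self, pairs):
        self.pairs = pairs
        super().__init__(f"saturated distance for pairs: {pairs}")


@dataclass(frozen=True)
class SubstitutionModelConfig:
    model: str = "TN93"  # {"p-distance", "TN93"}
    gamma_shape: Optional[float] = 0.5
    empirical_base_freqs: Optional[dict] = None

    def __post_init__(self):
        if self.model not in {"p-distance", "TN93"}:
            raise ValueError(f"unknown model {self.model!r}")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be > 0")
        if self.empirical_base_freqs is not None:
            s = sum(self.empirical_base_freqs.values())
            if abs(s - 1.0) > 1e-9:
                raise ValueError("base frequencies must sum to 1")


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        v = self.values
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be zero")

    def to_phylip(self) -> str:
        lines = [f" {len(self.labels)}"]
        for lab, row in zip(self.labels, self.values):
            lines.append(
                f"{lab:<10s} " + " ".join(f"{x:.6f}" for x in row)
            )
        return "\n".join(lines) + "\n"


_PUR = {"A", "G"}
_PYR = {"C", "T"}


def estimate_base_freqs(sequences: Sequence[str]) -> dict:
    """Empirical A/C/G/T frequencies pooled over all sequences (gaps/N ignored)."""
    counts = {b: 0 for b in "ACGT"}
    for seq in sequences:
        for b in "ACGT":
            counts[b] += seq.count(b)
    tot = sum(counts.values())
    if tot == 0:
        raise ValueError("no unambiguous bases to estimate frequencies from")
    return {b: counts[b] / tot for b in "ACGT"}


def _pair_counts(x: str, y: str):
    """(comparable sites, transitions AG, transitions CT, transversions)."""
    n = p1 = p2 = q = 0
    for a, b in zip(x, y):
        if a in "-N" or b in "-N":
            continue
        n += 1
        if a == b:
            continue
        pair = {a, b}
        if pair == _PUR:
            p1 += 1
        elif pair == _PYR:
            p2 += 1
        else:
            q += 1
    return n, p1, p2, q


def _corr(x: float, alpha: Optional[float]) -> float:
    """-ln(x), or its gamma-rate counterpart alpha*(x^(-1/alpha) - 1)."""
    if x <= 0:
        raise ValueError("saturation")
    if alpha is None:
        return -math.log(x)
    return alpha * (x ** (-1.0 / alpha) - 1.0)


def _p_distance_matrix(seqs: Sequence[str]) -> np.ndarray:
    """Vectorised all-pairs p-distance (gap/N sites excluded per pair)."""
    n, L = len(seqs), len(seqs[0])
    m = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8).reshape(n, L)
    valid = (m != ord("-")) & (m != ord("N"))
    out = np.zeros((n, n))
    for i in range(n):
        both = valid[i] & valid[i + 1 :]
        comp = both.sum(axis=1)
        diff = ((m[i] != m[i + 1 :]) & both).sum(axis=1)
        with np.errstate(invalid="ignore"):
            out[i, i + 1 :] = diff / comp
    out = out + out.T
    if np.any(np.isnan(out)):
        raise ValueError("a sequence pair has no comparable sites")
    return out


def p_distance(x: str, y: str) -> float:
    n, p1, p2, q = _pair_counts(x, y)
    if n == 0:
        raise ValueError("no comparable sites")
    return (p1 + p2 + q) / n


def tn93_distance(x: str, y: str, cfg: SubstitutionModelConfig) -> float:
    """TN93 (or p-) distance between two aligned sequences.

    Raises :class:`SaturationError` when a correction argument is
    non-positive; callers decide whether to flag or fall back.
    """
    if len(x) != len(y):
        raise ValueError("sequences differ in length")
    if cfg.model == "p-distance":
        return p_distance(x, y)
    n, p1c, p2c, qc = _pair_counts(x, y)
    if n == 0:
        raise ValueError("no comparable sites")
    P1, P2, Q = p1c / n, p2c / n, qc / n
    f = cfg.empirical_base_freqs or estimate_base_freqs([x, y])
    gA, gC, gG, gT = f["A"], f["C"], f["G"], f["T"]
    gR, gY = gA + gG, gC + gT
    k1 = 2.0 * gA * gG / gR
    k2 = 2.0 * gC * gT / gY
    k3 = 2.0 * (gR * gY - gA * gG * gY / gR - gC * gT * gR / gY)
    x1 = 1.0 - P1 / k1 - Q / (2.0 * gR) if k1 > 0 else 1.0
    x2 = 1.0 - P2 / k2 - Q / (2.0 * gY) if k2 > 0 else 1.0
    x3 = 1.0 - Q / (2.0 * gR * gY)
    try:
        d = 0.0
        if k1 > 0:
            d += k1 * _corr(x1, cfg.gamma_shape)
        if k2 > 0:
            d += k2 * _corr(x2, cfg.gamma_shape)
        d += k3 * _corr(x3, cfg.gamma_shape)
    except ValueError:
        raise SaturationError([(x[:10], y[:10])])
    return d


def pairwise_distance_matrix(
    data: AlignedSequenceSet | HaplotypeTable,
    cfg: Optional[SubstitutionModelConfig] = None,
    on_saturation: str = "error",  # {"error", "p-distance"}
) -> DistanceMatrix:
    """Symmetric distance matrix over individuals (or haplotypes).

    Base frequencies are estimated from the pooled input unless supplied in
    ``cfg``. Saturated pairs raise an error listing them, or fall back to
    the p-distance when ``on_saturation="p-distance"``.
    """
    cfg = cfg or SubstitutionModelConfig()
    if isinstance(data, HaplotypeTable):
        labels = tuple(h["haplotype_id"] for h in data.haplotypes)
        seqs = data.sequences
    else:
        labels = data.ids
        seqs = data.sequences
    if len(seqs) < 2:
        raise ValueError("need >= 2 entries for a distance matrix")
    if cfg.model == "TN93" and cfg.empirical_base_freqs is None:
        cfg = SubstitutionModelConfig(
            model=cfg.model,
            gamma_shape=cfg.gamma_shape,
            empirical_base_freqs=estimate_base_freqs(seqs),
        )
    k = len(seqs)
    if cfg.model == "p-distance":
        return DistanceMatrix(labels, _p_distance_matrix(seqs))
    vals = np.zeros((k, k))
    saturated = []
    for i in range(k):
        for j in range(i + 1, k):
            try:
                d = tn93_distance(seqs[i], seqs[j], cfg)
            except SaturationError:
                if on_saturation == "p-distance":
                    d = p_distance(seqs[i], seqs[j])
                else:
                    saturated.append((labels[i], labels[j]))
                    d = np.inf
            vals[i, j] = vals[j, i] = d
    if saturated:
        raise SaturationError(saturated)
    return DistanceMatrix(labels, vals)
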