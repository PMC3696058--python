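"""Molecular-diversity statistics: S, H, h, pi, d.

All statistics assume gap/N columns have already been removed so that every
pair of sequences is compared on the same analysed length L. ``pi`` is per
site and ``d`` is in sites, so d = pi * L exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .seqio import AlignedSequenceSet, PopulationMap, collapse_haplotypes


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class DiversitySummary:
    locality: str
    n: int
    S: Optional[int]
    H: Optional[int]
    h: Optional[float]
    pi: Optional[float]
    d: Optional[float]
    defined: bool = True


def _encoded(aln: AlignedSequenceSet) -> np.ndarray:
    """(n, L) uint8 matrix of the alignment."""
    return np.frombuffer(
        "".join(aln.sequences).encode("ascii"), dtype=np.uint8
    ).reshape(aln.n, aln.length)


def segregating_sites(aln: AlignedSequenceSet) -> int:
    """Number of polymorphic columns (>= 2 distinct observed nucleotides)."""
    if aln.n < 2:
        raise InsufficientDataError("need >= 2 sequences for S")
    m = _encoded(aln)
    return int(np.sum(np.any(m != m[0], axis=0)))


def haplotype_diversity(counts: Iterable[int]) -> float:
    """Nei's unbiased haplotype diversity h = n/(n-1) * (1 - sum p_i^2)."""
    c = np.asarray(list(counts), dtype=float)
    n = c.sum()
    if n < 2:
        raise InsufficientDataError("need >= 2 sequences for h")
    return float(n / (n - 1.0) * (1.0 - np.sum((c / n) ** 2)))


def mean_pairwise_differences(aln: AlignedSequenceSet) -> float:
    """Mean number of differing sites over all unordered sequence pairs."""
    if aln.n < 2:
        raise InsufficientDataError("need >= 2 sequences for d")
    m = _encoded(aln)
    n = aln.n
    # sum of pairwise Hamming distances via per-column allele counts:
    # sum_{i<j} diff_ij = sum_cols [C(n,2) - sum_alleles C(n_a,2)]
    total = 0.0
    pairs = n * (n - 1) / 2.0
    for col in m.T:
        _, cnt = np.unique(col, return_counts=True)
        total += pairs - np.sum(cnt * (cnt - 1) / 2.0)
    return float(total / pairs)


def nucleotide_diversity(aln: AlignedSequenceSet) -> float:
    """Mean per-site proportion of differing columns over all pairs (pi)."""
    return mean_pairwise_differences(aln) / aln.length


def diversity_summary(
    aln: AlignedSequenceSet,
    pm: PopulationMap,
    per_locality: bool = True,
    pooled_label: str = "total",
    pooled: str = "sample",
) -> pd.DataFrame:
    """One row per locality plus a pooled row, columns (locality, N, S, H, h, pi, d).

    Localities with n < 2 are emitted with statistics flagged undefined
    (NaN) rather than as zeros. The pooled row is a pooled-sample statistic
    by default; ``pooled="mean"`` averages the defined per-locality values
    instead (S and H are left blank in that mode, as they do not average
    meaningfully).
    """
    if pooled not in {"sample", "mean"}:
        raise ValueError(f"unknown pooled mode {pooled!r}")
    rows: list[DiversitySummary] = []
    if per_locality:
        for loc, inds in pm.individuals_by_locality().items():
            inds = [i for i in inds if i in set(aln.ids)]
            if not inds:
                continue
            if len(inds) < 2:
                rows.append(
                    DiversitySummary(loc, len(inds), None, None, None, None, None, False)
                )
                continue
            sub = aln.subset(inds)
            rows.append(_summary_row(loc, sub, pm))
    if pooled == "mean" and per_locality:
        defined = [r for r in rows if r.defined]
        rows.append(
            DiversitySummary(
                pooled_label,
                aln.n,
                np.nan,
                np.nan,
                float(np.mean([r.h for r in defined])) if defined else None,
                float(np.mean([r.pi for r in defined])) if defined else None,
                float(np.mean([r.d for r in defined])) if defined else None,
                bool(defined),
            )
        )
    else:
        rows.append(_summary_row(pooled_label, aln, pm))
    return pd.DataFrame(
        [
            {
                "locality": r.locality,
                "N": r.n,
                "S": r.S if r.defined else np.nan,
                "H": r.H if r.defined else np.nan,
                "h": r.h if r.defined else np.nan,
                "pi": r.pi if r.defined else np.nan,
                "d": r.d if r.defined else np.nan,
            }
            for r in rows
        ]
    )


def _summary_row(label: str, aln: AlignedSequenceSet, pm: PopulationMap) -> DiversitySummary:
    ht = collapse_haplotypes(aln, pm)
    return DiversitySummary(
        locality=label,
        n=aln.n,
        S=segregating_sites(aln),
        H=ht.n_haplotypes,
        h=haplotype_diversity(ht.counts),
        pi=nucleotide_diversity(aln),
        d=mean_pairwise_differences(aln),
    )
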