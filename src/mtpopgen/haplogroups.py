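"""Model-based clustering of haplotypes into haplogroups, and per-locality
haplogroup frequency tables.

The cluster model scores a partition of haplotypes by the marginal
likelihood of an independent-polymorphic-sites Dirichlet-multinomial:
within each cluster, every polymorphic column's nucleotide counts
(weighted by haplotype frequency) follow a multinomial with a symmetric
Dirichlet(alpha) prior over A/C/G/T. The best partition over all K up to
``k_max`` is found by randomised greedy reassignment with restarts. This
is a deliberately simple surrogate for linkage-aware Bayesian clustering:
it recovers well-separated haplotype groups but makes no claim of
reproducing any particular published cluster membership.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .seqio import AlignedSequenceSet, HaplotypeTable, PopulationMap, collapse_haplotypes

_BASE_IDX = {b: i for i, b in enumerate("ACGT")}


@dataclass(frozen=True)
class ClusterModel:
    K: int
    assignment: dict  # haplotype_id -> contiguous int label, 0..K-1
    log_marginal_likelihood: float
    runs: int
    replicates: int
    seed: int
    alpha: float


def _site_counts(ht: HaplotypeTable, weighted: bool):
    """(H, n_polymorphic_sites) base-index matrix + per-haplotype weights."""
    seqs = ht.sequences
    L = len(seqs[0])
    poly = [
        j for j in range(L) if len({s[j] for s in seqs}) > 1
    ]
    mat = np.array(
        [[_BASE_IDX.get(s[j], -1) for j in poly] for s in seqs], dtype=int
    )
    wts = np.array(
        [h["total_count"] if weighted else 1 for h in ht.haplotypes], dtype=float
    )
    return mat, wts, poly


def _score(counts: np.ndarray, alpha: float) -> float:
    """Log Dirichlet-multinomial marginal for one cluster.

    ``counts``: (n_sites, 4) weighted nucleotide counts.
    """
    n = counts.sum(axis=1)
    return float(
        np.sum(
            gammaln(4 * alpha)
            - gammaln(4 * alpha + n)
            + np.sum(gammaln(alpha + counts) - gammaln(alpha), axis=1)
        )
    )


def partition_log_marginal(
    ht: HaplotypeTable, labels: np.ndarray, alpha: float = 0.25, weighted: bool = True
) -> float:
    """Score an arbitrary partition (labels per haplotype, in table order)."""
    mat, wts, _ = _site_counts(ht, weighted)
    return _score_all(mat, wts, labels, alpha)


def _cluster_counts(mat, wts, idx) -> np.ndarray:
    n_sites = mat.shape[1]
    counts = np.zeros((n_sites, 4))
    for i in idx:
        row = mat[i]
        valid = row >= 0
        counts[np.arange(n_sites)[valid], row[valid]] += wts[i]
    return counts


def _score_all(mat, wts, labels, alpha) -> float:
    total = 0.0
    for lab in np.unique(labels):
        idx = np.nonzero(labels == lab)[0]
        total += _score(_cluster_counts(mat, wts, idx), alpha)
    return total


def cluster_haplotypes(
    data: HaplotypeTable | AlignedSequenceSet,
    k_max: int = 22,
    runs: int = 10,
    replicates: int = 6,
    seed: int = 0,
    alpha: float = 0.25,
    pm: Optional[PopulationMap] = None,
) -> ClusterModel:
    """Best Dirichlet-multinomial partition over K = 1..k_max.

    ``runs * replicates`` randomised greedy restarts; deterministic given
    ``seed``. Monomorphic input returns the single-cluster model.
    """
    if isinstance(data, AlignedSequenceSet):
        if pm is None:
            pm = PopulationMap({i: {"locality": "all"} for i in data.ids})
        ht = collapse_haplotypes(data, pm)
    else:
        ht = data
    H = ht.n_haplotypes
    if H < 1:
        raise ValueError("empty haplotype table")
    mat, wts, poly = _site_counts(ht, weighted=True)
    ids = [h["haplotype_id"] for h in ht.haplotypes]
    if not poly or H == 1 or k_max == 1:
        labels = np.zeros(H, dtype=int)
        return ClusterModel(
            1,
            dict(zip(ids, labels.tolist())),
            _score_all(mat, wts, labels, alpha) if poly else 0.0,
            runs,
            replicates,
            seed,
            alpha,
        )
    rng = np.random.default_rng(seed)
    best_labels, best_score = None, -np.inf
    k_cap = min(k_max, H)
    n_sites = mat.shape[1]
    # per-haplotype weighted one-hot count contribution, (H, sites, 4)
    contrib = np.zeros((H, n_sites, 4))
    site_ax = np.arange(n_sites)
    for i in range(H):
        valid = mat[i] >= 0
        contrib[i, site_ax[valid], mat[i, valid]] = wts[i]
    for _ in range(runs * replicates):
        k0 = int(rng.integers(1, k_cap + 1))
        labels = rng.integers(0, k0, size=H)
        cl_counts = {
            int(lab): contrib[labels == lab].sum(axis=0) for lab in np.unique(labels)
        }
        cl_score = {lab: _score(c, alpha) for lab, c in cl_counts.items()}
        score = sum(cl_score.values())
        improved = True
        while improved:
            improved = False
            for i in rng.permutation(H):
                a = int(labels[i])
                counts_a_minus = cl_counts[a] - contrib[i]
                score_a_minus = _score(counts_a_minus, alpha)
                base_delta = score_a_minus - cl_score[a]
                options = list(cl_counts)
                if len(cl_counts) < k_cap:
                    options.append(max(cl_counts) + 1)  # open a fresh cluster
                best_move, best_delta = a, 0.0
                for lab in options:
                    if lab == a:
                        continue
                    tgt = cl_counts.get(lab)
                    if tgt is None:
                        gain = _score(contrib[i], alpha)
                    else:
                        gain = _score(tgt + contrib[i], alpha) - cl_score[lab]
                    delta = base_delta + gain
                    if delta > best_delta + 1e-10:
                        best_move, best_delta = lab, delta
                if best_move != a:
                    labels[i] = best_move
                    if np.any(counts_a_minus > 0):
                        cl_counts[a] = counts_a_minus
                        cl_score[a] = score_a_minus
                    else:
                        del cl_counts[a], cl_score[a]
                    if best_move in cl_counts:
                        cl_counts[best_move] = cl_counts[best_move] + contrib[i]
                    else:
                        cl_counts[best_move] = contrib[i].copy()
                    cl_score[best_move] = _score(cl_counts[best_move], alpha)
                    score += best_delta
                    improved = True
        if score > best_score:
            best_score, best_labels = score, labels.copy()
    # contiguous labels, ordered by first appearance
    remap: dict[int, int] = {}
    out = np.empty(H, dtype=int)
    for i, lab in enumerate(best_labels):
        if lab not in remap:
            remap[lab] = len(remap)
        out[i] = remap[lab]
    return ClusterModel(
        int(out.max()) + 1,
        dict(zip(ids, out.tolist())),
        float(best_score),
        runs,
        replicates,
        seed,
        alpha,
    )


def assign_haplogroups(model: ClusterModel, ht: HaplotypeTable) -> pd.DataFrame:
    """Per-haplotype cluster labels; every individual inherits its
    haplotype's label. Unseen haplotypes are an error."""
    rows = []
    for h in ht.haplotypes:
        hid = h["haplotype_id"]
        if hid not in model.assignment:
            raise KeyError(f"haplotype {hid!r} not covered by the cluster model")
        rows.append(
            {
                "haplotype_id": hid,
                "cluster": model.assignment[hid],
                "total_count": h["total_count"],
            }
        )
    return pd.DataFrame(rows)


def haplogroup_frequencies(
    model: ClusterModel,
    ht: HaplotypeTable,
    pooled_label: str = "total",
) -> pd.DataFrame:
    """Tidy per-locality haplogroup counts and relative frequencies, plus a
    pooled row; per-locality frequencies sum to 1."""
    counts: dict[str, dict[int, int]] = {}
    for h in ht.haplotypes:
        lab = model.assignment[h["haplotype_id"]]
        for loc, c in h["counts_by_locality"].items():
            counts.setdefault(loc, {})[lab] = counts.get(loc, {}).get(lab, 0) + c
    pooled: dict[int, int] = {}
    for loc_counts in counts.values():
        for lab, c in loc_counts.items():
            pooled[lab] = pooled.get(lab, 0) + c
    counts[pooled_label] = pooled
    rows = []
    for loc, loc_counts in counts.items():
        tot = sum(loc_counts.values())
        for lab in range(model.K):
            c = loc_counts.get(lab, 0)
            rows.append(
                {
                    "locality": loc,
                    "cluster": lab,
                    "count": c,
                    "frequency": c / tot if tot else np.nan,
                }
            )
    return pd.DataFrame(rows)
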