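"""AMOVA, pairwise Phi_ST, permutation significance, and FDR correction.

Hierarchical analysis of molecular variance partitions the sum of squared
inter-individual molecular distances into among-group, among-population-
within-group, and within-population components (Excoffier's sum-of-squares
formulation with unbalanced-design coefficients). Fixation indices:

    Phi_CT = sigma_a / sigma_T
    Phi_SC = sigma_b / (sigma_b + sigma_c)
    Phi_ST = (sigma_a + sigma_b) / sigma_T

Molecular distances enter the sums of squares directly as the squared
Euclidean metric (for sequences the number of pairwise differences IS the
squared distance in the per-site 0/1 embedding); callers supplying plain
Euclidean distances can request squaring.

Significance comes from permutation nulls: whole populations permuted
among groups for Phi_CT, individuals among populations within groups for
Phi_SC, individuals among populations for Phi_ST; the p-value convention
is (b+1)/(B+1). Negative variance components are reported as computed,
flagged, and used in denominators as-is.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .distance import DistanceMatrix
from .seqio import PopulationMap


class DesignError(ValueError):
    pass


@dataclass(frozen=True)
class GroupingScheme:
    name: str
    assignment: dict  # locality_code -> group_label

    def groups(self) -> dict:
        out: dict[str, list[str]] = {}
        for loc, g in self.assignment.items():
            out.setdefault(g, []).append(loc)
        return out


@dataclass
class AmovaResult:
    rows: pd.DataFrame  # source, df, SSD, variance component, % variation
    phi_st: float
    phi_sc: Optional[float]
    phi_ct: Optional[float]
    p_phi_st: Optional[float] = None
    p_phi_sc: Optional[float] = None
    p_phi_ct: Optional[float] = None
    negative_components: bool = False
    grouping: Optional[str] = None

    def to_frame(self) -> pd.DataFrame:
        """Table-layout frame: Source of variation, d.f., SSD, Var. comp., % var, Fixation indices, P-value."""
        df = self.rows.copy()
        fix, pv = [], []
        if self.phi_ct is not None:
            fix = [self.phi_ct, self.phi_sc, self.phi_st]
            pv = [self.p_phi_ct, self.p_phi_sc, self.p_phi_st]
        else:
            fix = [self.phi_st, None]
            pv = [self.p_phi_st, None]
        df["Fixation indices"] = fix
        df["P-value"] = pv
        return df


@dataclass
class PhiStMatrix:
    labels: tuple[str, ...]
    values: np.ndarray
    p_raw: np.ndarray
    p_adjusted: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def fixation_indices_from_components(
    sigma_a: float, sigma_b: float, sigma_c: float
) -> dict:
    """Phi indices from the three variance components (three-level design)."""
    tot = sigma_a + sigma_b + sigma_c
    return {
        "phi_ct": sigma_a / tot,
        "phi_sc": sigma_b / (sigma_b + sigma_c),
        "phi_st": (sigma_a + sigma_b) / tot,
    }


# ---------------------------------------------------------------------------
# core sums of squares
# ---------------------------------------------------------------------------

def _ss(d2: np.ndarray, idx: np.ndarray) -> float:
    """SS for a set of individuals: (1/n) * sum_{i<j} d^2_ij."""
    sub = d2[np.ix_(idx, idx)]
    return float(sub.sum() / (2.0 * len(idx)))


def _partition(
    d2: np.ndarray,
    pops: list[np.ndarray],
    groups: Optional[list[list[int]]],
):
    """Return (stats dict) for a 2- or 3-level AMOVA from squared distances.

    ``pops`` maps population -> individual indices; ``groups`` maps group ->
    population indices (or None for the 2-level design).
    """
    N = sum(len(p) for p in pops)
    P = len(pops)
    all_idx = np.concatenate(pops)
    ss_total = _ss(d2, all_idx)
    ss_wp = sum(_ss(d2, p) for p in pops)
    n_p = np.array([len(p) for p in pops], dtype=float)

    if groups is None:
        df_ap, df_wp = P - 1, N - P
        ssd_ap = ss_total - ss_wp
        if df_wp == 0:
            raise DesignError("no within-population degrees of freedom")
        ms_ap, ms_wp = ssd_ap / df_ap, ss_wp / df_wp
        n_c = (N - np.sum(n_p**2) / N) / (P - 1)
        sigma_c = ms_wp
        sigma_a = (ms_ap - ms_wp) / n_c
        return {
            "levels": 2,
            "df": [df_ap, df_wp],
            "ssd": [ssd_ap, ss_wp],
            "sigma": [sigma_a, sigma_c],
        }

    G = len(groups)
    if G < 2:
        raise DesignError("Phi_CT requires >= 2 groups")
    ss_wg = []
    N_g, A = [], 0.0
    for g in groups:
        gidx = np.concatenate([pops[p] for p in g])
        ss_wg.append(_ss(d2, gidx))
        Ng = float(len(gidx))
        N_g.append(Ng)
        A += sum(n_p[p] ** 2 for p in g) / Ng
    B = float(np.sum(n_p**2) / N)
    C = float(np.sum(np.array(N_g) ** 2) / N)
    ssd_ag = ss_total - sum(ss_wg)
    ssd_apwg = sum(ss_wg) - ss_wp
    df_ag, df_apwg, df_wp = G - 1, P - G, N - P
    ms_ag = ssd_ag / df_ag
    ms_apwg = ssd_apwg / df_apwg if df_apwg > 0 else 0.0
    ms_wp = ss_wp / df_wp
    n = (N - A) / (P - G) if P > G else 0.0
    n_prime = (A - B) / (G - 1)
    n_dprime = (N - C) / (G - 1)
    sigma_c = ms_wp
    sigma_b = (ms_apwg - sigma_c) / n if n > 0 else 0.0
    sigma_a = (ms_ag - sigma_c - n_prime * sigma_b) / n_dprime
    return {
        "levels": 3,
        "df": [df_ag, df_apwg, df_wp],
        "ssd": [ssd_ag, ssd_apwg, ss_wp],
        "sigma": [sigma_a, sigma_b, sigma_c],
    }


def _indices(part: dict) -> dict:
    if part["levels"] == 2:
        sa, sc = part["sigma"]
        tot = sa + sc
        return {"phi_st": sa / tot if tot != 0 else np.nan, "phi_sc": None, "phi_ct": None}
    sa, sb, sc = part["sigma"]
    tot = sa + sb + sc
    if tot == 0:
        return {"phi_st": np.nan, "phi_sc": np.nan, "phi_ct": np.nan}
    return {
        "phi_st": (sa + sb) / tot,
        "phi_sc": sb / (sb + sc) if (sb + sc) != 0 else np.nan,
        "phi_ct": sa / tot,
    }


def _layout(
    dist: DistanceMatrix, pm: PopulationMap, grouping: Optional[GroupingScheme]
):
    """Index layout: populations as index arrays, groups as population lists."""
    label_pos = {lab: i for i, lab in enumerate(dist.labels)}
    by_loc = pm.individuals_by_locality()
    locs = [loc for loc in by_loc if any(i in label_pos for i in by_loc[loc])]
    pops = [
        np.array([label_pos[i] for i in by_loc[loc] if i in label_pos])
        for loc in locs
    ]
    groups = None
    if grouping is not None:
        glabels: dict[str, list[int]] = {}
        for k, loc in enumerate(locs):
            if loc not in grouping.assignment:
                raise DesignError(f"locality {loc!r} not assigned to a group")
            glabels.setdefault(grouping.assignment[loc], []).append(k)
        groups = list(glabels.values())
    return locs, pops, groups


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def amova(
    dist: DistanceMatrix,
    pm: PopulationMap,
    grouping: Optional[GroupingScheme] = None,
    n_perm: int = 10_000,
    seed: int = 0,
    square_distances: bool = False,
) -> AmovaResult:
    """Two- or three-level AMOVA with permutation p-values.

    The distance entries are used as the squared-distance metric unless
    ``square_distances`` is set (for plain Euclidean input). With
    ``n_perm=0`` no p-values are computed.
    """
    locs, pops, groups = _layout(dist, pm, grouping)
    if len(pops) < 2:
        raise DesignError("need >= 2 populations")
    d2 = dist.values**2 if square_distances else dist.values
    if np.all(d2 == 0):
        raise DesignError("all distances are zero; fixation indices undefined")
    part = _partition(d2, pops, groups)
    idx = _indices(part)
    rng = np.random.default_rng(seed)
    p_st = p_sc = p_ct = None
    if n_perm > 0:
        p_st = _perm_pvalue(d2, pops, groups, "phi_st", idx["phi_st"], n_perm, rng)
        if groups is not None:
            p_sc = _perm_pvalue(d2, pops, groups, "phi_sc", idx["phi_sc"], n_perm, rng)
            p_ct = _perm_pvalue(d2, pops, groups, "phi_ct", idx["phi_ct"], n_perm, rng)
    if part["levels"] == 2:
        sources = ["Among populations", "Within populations"]
    else:
        sources = [
            "Among groups",
            "Among populations within groups",
            "Within populations",
        ]
    sigma = part["sigma"]
    tot = sum(sigma)
    rows = pd.DataFrame(
        {
            "Source of variation": sources,
            "d.f.": part["df"],
            "SSD": part["ssd"],
            "Var. comp.": sigma,
            "% var": [100.0 * s / tot for s in sigma],
        }
    )
    return AmovaResult(
        rows=rows,
        phi_st=idx["phi_st"],
        phi_sc=idx["phi_sc"],
        phi_ct=idx["phi_ct"],
        p_phi_st=p_st,
        p_phi_sc=p_sc,
        p_phi_ct=p_ct,
        negative_components=bool(any(s < 0 for s in sigma)),
        grouping=grouping.name if grouping else None,
    )


def _stat(d2, pops, groups, which) -> float:
    part = _partition(d2, pops, groups if which != "phi_st_2" else None)
    return _indices(part)[which if which != "phi_st_2" else "phi_st"]


def _perm_pvalue(d2, pops, groups, which, observed, n_perm, rng) -> float:
    """Permutation p for one index under its matching permutation scheme."""
    if np.isnan(observed):
        return np.nan
    b = 0
    sizes = [len(p) for p in pops]
    all_idx = np.concatenate(pops)
    for _ in range(n_perm):
        if which == "phi_ct":
            # permute whole populations among groups, keeping group pop-counts
            pop_order = rng.permutation(len(pops))
            new_groups, k = [], 0
            for g in groups:
                new_groups.append([int(pop_order[k + j]) for j in range(len(g))])
                k += len(g)
            stat = _stat(d2, pops, new_groups, "phi_ct")
        elif which == "phi_sc":
            # permute individuals among populations within their group
            new_pops = [None] * len(pops)
            for g in groups:
                gidx = rng.permutation(np.concatenate([pops[p] for p in g]))
                k = 0
                for p in g:
                    new_pops[p] = gidx[k : k + sizes[p]]
                    k += sizes[p]
            stat = _stat(d2, new_pops, groups, "phi_sc")
        else:  # phi_st: individuals among populations, ignoring groups
            shuffled = rng.permutation(all_idx)
            new_pops, k = [], 0
            for s in sizes:
                new_pops.append(shuffled[k : k + s])
                k += s
            if groups is not None:
                stat = _stat(d2, new_pops, groups, "phi_st")
            else:
                stat = _stat(d2, new_pops, None, "phi_st_2")
        if stat >= observed - 1e-12:
            b += 1
    return (b + 1) / (n_perm + 1)


def permutation_test(
    dist: DistanceMatrix,
    pm: PopulationMap,
    grouping: Optional[GroupingScheme],
    index: str,
    n_perm: int = 10_000,
    seed: int = 0,
) -> float:
    """Standalone permutation p-value for one fixation index.

    Scheme mapping: ``phi_ct`` permutes populations among groups; ``phi_sc``
    permutes individuals among populations within groups; ``phi_st``
    permutes individuals among populations (no groups needed).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if index in {"phi_ct", "phi_sc"} and grouping is None:
        raise DesignError(f"{index} requires a grouping scheme")
    locs, pops, groups = _layout(dist, pm, grouping)
    d2 = dist.values
    part = _partition(d2, pops, groups)
    observed = _indices(part)[index]
    rng = np.random.default_rng(seed)
    return _perm_pvalue(d2, pops, groups, index, observed, n_perm, rng)


def pairwise_phi_st(
    dist: DistanceMatrix,
    pm: PopulationMap,
    n_perm: int = 10_000,
    seed: int = 0,
    fdr_q: float = 0.05,
) -> PhiStMatrix:
    """Two-population AMOVA Phi_ST for every locality pair, with permutation
    p-values and BH-FDR adjustment across pairs."""
    locs, pops, _ = _layout(dist, pm, None)
    if len(locs) < 2:
        raise DesignError("need >= 2 localities")
    k = len(locs)
    vals = np.zeros((k, k))
    p_raw = np.full((k, k), np.nan)
    rng = np.random.default_rng(seed)
    pvals, pairs = [], []
    d2 = dist.values
    for i in range(k):
        for j in range(i + 1, k):
            pp = [pops[i], pops[j]]
            part = _partition(d2, pp, None)
            phi = _indices(part)["phi_st"]
            vals[i, j] = vals[j, i] = phi
            if n_perm > 0:
                p = _perm_pvalue(d2, pp, None, "phi_st_2", phi, n_perm, rng)
                p_raw[i, j] = p_raw[j, i] = p
                pvals.append(p)
                pairs.append((i, j))
    p_adj = np.full((k, k), np.nan)
    if pvals:
        adj, _ = bh_fdr(pvals, q=fdr_q)
        for (i, j), a in zip(pairs, adj):
            p_adj[i, j] = p_adj[j, i] = a
    return PhiStMatrix(tuple(locs), vals, p_raw, p_adj)


def bh_fdr(pvalues: Sequence[float], q: float = 0.05):
    """Benjamini-Hochberg step-up: (adjusted p-values, rejection flags)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


# ---------------------------------------------------------------------------
# the study's grouping presets (Tables 2-3 layouts, A-D per dataset)
# ---------------------------------------------------------------------------

_W16 = ["BPC", "OSM", "MOL", "CCE", "SAL", "OTT", "ORI", "MAR",
        "CPA", "MAD", "IPI", "CPC", "ELB", "SVC", "MON", "MLZ"]
_AEG = ["EP", "AG", "XI"]
_TUN = ["M", "N", "S", "B", "K"]


def _scheme(name, groups):
    assignment = {}
    for glab, locs in groups.items():
        for loc in locs:
            assignment[loc] = glab
    return GroupingScheme(name, assignment)


GROUPING_PRESETS = {
    "coi_A": _scheme("coi_A", {
        "G1": _W16 + ["PAC", "OGN", "VEN"], "G2": _AEG + _TUN}),
    "coi_B": _scheme("coi_B", {
        "G1": _W16 + ["PAC", "OGN"], "G2": _AEG + _TUN, "G3": ["VEN"]}),
    "coi_C": _scheme("coi_C", {
        "G1": _W16, "G2": ["PAC", "OGN", "VEN"] + _AEG + _TUN}),
    "coi_D": _scheme("coi_D", {
        "G1": _W16, "G2": ["PAC", "OGN"] + _AEG + _TUN, "G3": ["VEN"]}),
    "concat_A": _scheme("concat_A", {
        "G1": _W16 + ["PAC", "OGN", "VEN"], "G2": _AEG}),
    "concat_B": _scheme("concat_B", {
        "G1": _W16 + ["PAC", "OGN"], "G2": _AEG, "G3": ["VEN"]}),
    "concat_C": _scheme("concat_C", {
        "G1": _W16, "G2": ["PAC", "OGN", "VEN"] + _AEG}),
    "concat_D": _scheme("concat_D", {
        "G1": _W16, "G2": ["PAC", "OGN"] + _AEG, "G3": ["VEN"]}),
}
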