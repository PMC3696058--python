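"""Structured-coalescent synthetic data with known truth.

Generates haploid, non-recombining sequence samples from an island model of
``demes`` populations, with optional sudden demographic expansion, finite-
sites mutation (JC69 or HKY), and a population map — everything the
analysis stages consume, with the generating parameters recorded.

Unit conventions
----------------
* ``theta`` is the scaled mutation rate per locus, theta = 2*N*u for a
  haploid population of size N with locus mutation rate u per generation.
  E[mean pairwise differences] = theta in a single equilibrium deme.
* ``migration`` is the effective scaled island-model rate M, defined so the
  classic equilibrium expectation F_ST = 1/(1+M) holds for any deme count
  d: the per-lineage emigration rate is m = M*(d-1)/(2*N*d).
* ``expansion=(tau, theta0, theta1)`` is in mutational units: the
  population switched from theta0 to theta1 (both per locus) at time
  tau/(2u) generations ago, matching the sudden-expansion mismatch model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import msprime
import numpy as np

from .seqio import (
    AlignedSequenceSet,
    PopulationMap,
    write_fasta_alignment,
    write_population_map,
)

_BASES = np.array(list("ACGT"))
_REF_N = 10_000.0  # arbitrary reference deme size; only scaled rates matter


@dataclass(frozen=True)
class SimConfig:
    demes: int = 1
    sample_sizes: Sequence[int] | int = 20
    theta: float = 5.0
    migration: float = 1.0
    expansion: Optional[tuple[float, float, float]] = None  # (tau, theta0, theta1)
    sequence_length: int = 500
    model: str = "JC"  # {"JC", "HKY"}
    kappa: float = 4.0  # transition/transversion rate ratio for HKY
    merge_time: Optional[float] = None  # generations; required if migration == 0, demes > 1
    seed: int = 1

    def __post_init__(self):
        if self.demes < 1 or self.sequence_length < 1:
            raise ValueError("demes and sequence_length must be positive")
        if self.theta < 0 or self.migration < 0:
            raise ValueError("rates must be >= 0")
        sizes = self.per_deme_sizes()
        if any(s < 1 for s in sizes):
            raise ValueError("sample sizes must be >= 1")
        if self.demes > 1 and self.migration == 0 and self.merge_time is None:
            raise ValueError(
                "migration=0 with >1 deme has no common ancestor; set merge_time"
            )
        if self.model not in {"JC", "HKY"}:
            raise ValueError(f"unknown substitution model {self.model!r}")

    def per_deme_sizes(self) -> list[int]:
        if isinstance(self.sample_sizes, int):
            return [self.sample_sizes] * self.demes
        sizes = list(self.sample_sizes)
        if len(sizes) != self.demes:
            raise ValueError("sample_sizes length must equal demes")
        return sizes


@dataclass(frozen=True)
class SyntheticDataset:
    alignment: AlignedSequenceSet
    popmap: PopulationMap
    truth: dict


def _demography(cfg: SimConfig, u_locus: float) -> msprime.Demography:
    dem = msprime.Demography()
    n_present = (
        cfg.expansion[2] / (2.0 * u_locus) if cfg.expansion else _REF_N
    )
    for i in range(cfg.demes):
        dem.add_population(name=f"D{i + 1}", initial_size=n_present)
    if cfg.demes > 1 and cfg.migration > 0:
        # per-pair backward rate M/(2*N*d): total emigration M(d-1)/(2Nd)
        rate = cfg.migration / (2.0 * n_present * cfg.demes)
        dem.set_symmetric_migration_rate([f"D{i+1}" for i in range(cfg.demes)], rate)
    if cfg.expansion:
        tau, theta0, _ = cfg.expansion
        t_gen = tau / (2.0 * u_locus)
        n_anc = max(theta0 / (2.0 * u_locus), 1e-3)
        for i in range(cfg.demes):
            dem.add_population_parameters_change(
                time=t_gen, population=f"D{i+1}", initial_size=n_anc
            )
    if cfg.merge_time is not None and cfg.demes > 1:
        for i in range(1, cfg.demes):
            dem.add_mass_migration(
                time=cfg.merge_time, source=f"D{i+1}", dest="D1", proportion=1.0
            )
    dem.sort_events()
    return dem


def simulate_coalescent(cfg: SimConfig) -> SyntheticDataset:
    """Simulate one haploid structured-coalescent sample and its sequences."""
    rng = np.random.default_rng(cfg.seed)
    L = cfg.sequence_length
    # fix the present-day size, derive the per-site rate from theta
    if cfg.expansion:
        u_locus = cfg.expansion[2] / (2.0 * _REF_N)
    else:
        u_locus = cfg.theta / (2.0 * _REF_N) if cfg.theta > 0 else 1e-12
    mu_site = u_locus / L
    sizes = cfg.per_deme_sizes()
    samples = {f"D{i + 1}": n for i, n in enumerate(sizes)}
    ts = msprime.sim_ancestry(
        samples=samples,
        demography=_demography(cfg, u_locus),
        ploidy=1,
        sequence_length=L,
        discrete_genome=True,
        random_seed=int(rng.integers(1, 2**31 - 1)),
    )
    if cfg.theta > 0 or cfg.expansion:
        model = (
            msprime.JC69()
            if cfg.model == "JC"
            else msprime.HKY(kappa=cfg.kappa)
        )
        ts = msprime.sim_mutations(
            ts,
            rate=mu_site,
            model=model,
            random_seed=int(rng.integers(1, 2**31 - 1)),
        )
    n_tot = sum(sizes)
    root = rng.choice(_BASES, size=L)
    mat = np.tile(root, (n_tot, 1))
    for var in ts.variants():
        col = np.array([var.alleles[g] for g in var.genotypes])
        mat[:, int(var.site.position)] = col
    ids, locs = [], []
    k = 0
    for i, n in enumerate(sizes):
        for j in range(n):
            ids.append(f"D{i + 1}_{j + 1:03d}")
            locs.append(f"D{i + 1}")
            k += 1
    records = tuple(
        (ind, "".join(mat[i])) for i, ind in enumerate(ids)
    )
    aln = AlignedSequenceSet(records, L, locus_label="sim")
    pm = PopulationMap({ind: {"locality": loc} for ind, loc in zip(ids, locs)})
    truth = {
        "tree_height_generations": float(max(t.time(t.root) for t in ts.trees())),
        "deme_labels": {ind: loc for ind, loc in zip(ids, locs)},
        "theta": cfg.theta,
        "migration": cfg.migration,
        "expansion": list(cfg.expansion) if cfg.expansion else None,
        "sequence_length": L,
        "model": cfg.model,
        "seed": cfg.seed,
    }
    return SyntheticDataset(aln, pm, truth)


def write_synthetic_dataset(ds: SyntheticDataset, out_dir: str | Path) -> dict:
    """Write FASTA + popmap TSV + truth JSON; re-readable by seqio exactly."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "alignment.fasta",
        "popmap": out / "popmap.tsv",
        "truth": out / "truth.json",
    }
    write_fasta_alignment(ds.alignment, paths["fasta"])
    write_population_map(ds.popmap, paths["popmap"])
    with open(paths["truth"], "w") as fh:
        json.dump(ds.truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {k: str(v) for k, v in paths.items()}
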