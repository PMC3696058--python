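"""End-to-end orchestration: load -> filter -> diversity -> distances ->
Phi_ST/AMOVA -> network -> clustering -> demography -> dating, from a
single config, with per-stage seeds and a run manifest.

Every stage writes plain-text tables into the output directory; the
manifest records the config, package version, derived stage seeds, and any
individuals or localities dropped by the filtering rules, so a rerun from
the same manifest reproduces every output byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .demography import (
    DatingConfig,
    fit_sudden_expansion,
    mismatch_observed,
    neutrality_tests,
    parametric_bootstrap,
    ssd_pvalue,
    tau_confidence_interval,
    time_since_expansion,
)
from .distance import SubstitutionModelConfig, pairwise_distance_matrix
from .diversity import diversity_summary
from .haplogroups import assign_haplogroups, cluster_haplotypes, haplogroup_frequencies
from .network import build_network_with_reweighting
from .seqio import (
    collapse_haplotypes,
    concatenate_loci,
    drop_gap_sites,
    filter_min_sample_size,
    join_check,
    read_fasta_alignment,
    read_population_map,
)
from .structure import GROUPING_PRESETS, GroupingScheme, amova, pairwise_phi_st

log = logging.getLogger("mtpopgen")

_ALL_STAGES = (
    "diversity",
    "structure",
    "network",
    "cluster",
    "demography",
)


@dataclass
class RunConfig:
    fasta: str
    popmap: str
    output_dir: str
    fasta2: Optional[str] = None  # second locus, concatenated if given
    min_n: int = 5
    n_perm: int = 10_000
    bootstrap_B: int = 10_000
    neutrality_sims: int = 1000
    model: str = "TN93"
    gamma_shape: Optional[float] = 0.5
    epsilon: float = 0.0
    base_weight: float = 90.0
    reweight_passes: int = 2
    k_max: int = 22
    cluster_runs: int = 10
    cluster_replicates: int = 6
    generation_time_years: float = 2.0
    divergence_rate_pct_per_myr: float = 0.52
    halve_rate: bool = False
    groupings: list = field(default_factory=list)  # preset names or {name: {loc: group}}
    demography_groups: dict = field(default_factory=dict)  # label -> [localities]
    stages: list = field(default_factory=lambda: list(_ALL_STAGES))
    continue_on_error: bool = True
    seed: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage child seed from the global seed (below 2**31)."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def _resolve_groupings(cfg: RunConfig) -> list[GroupingScheme]:
    out = []
    for item in cfg.groupings:
        if isinstance(item, str):
            out.append(GROUPING_PRESETS[item])
        else:
            (name, assignment), = item.items()
            out.append(GroupingScheme(name, dict(assignment)))
    return out


def run_full_analysis(cfg: RunConfig) -> dict:
    """Run every enabled stage; returns the manifest (also written to disk)."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config": asdict(cfg),
        "stage_seeds": {s: stage_seed(cfg.seed, s) for s in _ALL_STAGES},
        "stages_run": [],
        "errors": {},
        "outputs": {},
    }

    aln = read_fasta_alignment(cfg.fasta)
    if cfg.fasta2:
        aln2 = read_fasta_alignment(cfg.fasta2)
        aln, dropped = concatenate_loci(aln, aln2)
        manifest["concatenation_dropped"] = dropped
        log.info("concatenated loci; dropped %d individuals", len(dropped))
    pm = read_population_map(cfg.popmap)
    join_check(aln, pm)
    pm = pm.subset(aln.ids)
    aln, kept_sites = drop_gap_sites(aln)
    manifest["analysed_length"] = aln.length
    manifest["n_individuals"] = aln.n

    def _run(stage, fn):
        if stage not in cfg.stages:
            return
        try:
            fn(stage_seed(cfg.seed, stage))
            manifest["stages_run"].append(stage)
        except Exception as exc:  # noqa: BLE001 - stage isolation is the contract
            log.exception("stage %s failed", stage)
            manifest["errors"][stage] = f"{type(exc).__name__}: {exc}"
            if not cfg.continue_on_error:
                raise

    ht = collapse_haplotypes(aln, pm)
    ht.to_frame().to_csv(out / "haplotypes.csv", index=False)
    manifest["outputs"]["haplotypes"] = "haplotypes.csv"

    def _diversity(seed):
        df = diversity_summary(aln, pm)
        df.to_csv(out / "diversity.csv", index=False)
        manifest["outputs"]["diversity"] = "diversity.csv"

    def _structure(seed):
        pm_f, aln_f, removed = filter_min_sample_size(pm, aln, cfg.min_n)
        manifest["min_n_removed"] = removed
        dm = pairwise_distance_matrix(
            aln_f,
            SubstitutionModelConfig(model=cfg.model, gamma_shape=cfg.gamma_shape),
            on_saturation="p-distance",
        )
        phi = pairwise_phi_st(dm, pm_f, n_perm=cfg.n_perm, seed=seed)
        phi.to_frame().to_csv(out / "pairwise_phi_st.csv")
        pd.DataFrame(phi.p_raw, index=phi.labels, columns=phi.labels).to_csv(
            out / "pairwise_phi_st_p.csv"
        )
        pd.DataFrame(phi.p_adjusted, index=phi.labels, columns=phi.labels).to_csv(
            out / "pairwise_phi_st_p_fdr.csv"
        )
        manifest["outputs"]["pairwise_phi_st"] = "pairwise_phi_st.csv"
        for scheme in _resolve_groupings(cfg):
            res = amova(dm, pm_f, scheme, n_perm=cfg.n_perm, seed=seed)
            res.to_frame().to_csv(out / f"amova_{scheme.name}.csv", index=False)
            manifest["outputs"][f"amova_{scheme.name}"] = f"amova_{scheme.name}.csv"
        res = amova(dm, pm_f, None, n_perm=cfg.n_perm, seed=seed)
        res.to_frame().to_csv(out / "amova_no_groups.csv", index=False)
        manifest["outputs"]["amova_no_groups"] = "amova_no_groups.csv"

    def _network(seed):
        net, _, weights = build_network_with_reweighting(
            ht, cfg.epsilon, cfg.base_weight, cfg.reweight_passes
        )
        net.to_graphml(out / "network.graphml")
        rows = [
            {"node1": u, "node2": v, "n_mutations": n, "sites": ";".join(map(str, s))}
            for u, v, n, s in net.edge_list()
        ]
        pd.DataFrame(rows).to_csv(out / "network_edges.csv", index=False)
        net.node_table().to_csv(out / "network_nodes.csv", index=False)
        pd.DataFrame(
            sorted(weights.weights.items()),
            columns=["site", "weight"],
        ).to_csv(out / "site_weights.csv", index=False)
        manifest["outputs"]["network"] = "network.graphml"

    def _cluster(seed):
        model = cluster_haplotypes(
            ht,
            k_max=cfg.k_max,
            runs=cfg.cluster_runs,
            replicates=cfg.cluster_replicates,
            seed=seed,
        )
        assign_haplogroups(model, ht).to_csv(out / "haplogroups.csv", index=False)
        haplogroup_frequencies(model, ht).to_csv(
            out / "haplogroup_frequencies.csv", index=False
        )
        manifest["outputs"]["haplogroups"] = "haplogroups.csv"
        manifest["cluster_K"] = model.K

    def _demography_one(sub_aln, label, seed):
        counts = mismatch_observed(sub_aln)
        fit = fit_sudden_expansion(
            counts, sub_aln.n, analysed_length=sub_aln.length, seed=seed
        )
        boot = parametric_bootstrap(fit, B=cfg.bootstrap_B, seed=seed)
        fit.ssd_p = ssd_pvalue(fit, boot=boot)
        fit.tau_ci = tau_confidence_interval(fit, boot=boot)
        neut = neutrality_tests(sub_aln, n_sims=cfg.neutrality_sims, seed=seed)
        dating = time_since_expansion(
            fit.tau,
            DatingConfig(
                sequence_length=sub_aln.length,
                generation_time_years=cfg.generation_time_years,
                divergence_rate_pct_per_myr=cfg.divergence_rate_pct_per_myr,
                halve_rate=cfg.halve_rate,
            ),
            tau_ci=fit.tau_ci,
        )
        suffix = "" if label == "all" else f"_{label}"
        pd.DataFrame(
            {
                "i": np.arange(len(counts)),
                "observed_count": counts,
                "observed_freq": counts / counts.sum(),
                "expected_freq": mismatch_expected_padded(fit, len(counts)),
            }
        ).to_csv(out / f"mismatch{suffix}.csv", index=False)
        return {
            "N": sub_aln.n,
            "tau": fit.tau,
            "theta0": fit.theta0,
            "theta1": fit.theta1,
            "SSD": fit.ssd,
            "ssd_p": fit.ssd_p,
            "tau_ci": list(fit.tau_ci),
            "tajima_d": neut.tajima_d,
            "fu_fs": neut.fu_fs,
            "p_tajima": neut.p_tajima,
            "p_fu": neut.p_fu,
            "t_generations": dating.t_generations,
            "t_years": dating.t_years,
            "ci_years": list(dating.ci_years) if dating.ci_years else None,
            "u_per_fragment_per_generation": dating.u,
        }

    def _demography(seed):
        result = _demography_one(aln, "all", seed)
        by_loc = pm.individuals_by_locality()
        groups = {}
        for label, locs in cfg.demography_groups.items():
            ids = [i for loc in locs for i in by_loc.get(loc, [])]
            if len(ids) < 2:
                groups[label] = {"error": "fewer than 2 sequences"}
                continue
            groups[label] = _demography_one(aln.subset(ids), label, seed)
        if groups:
            result["groups"] = groups
        with open(out / "demography.json", "w") as fh:
            json.dump(result, fh, indent=2, sort_keys=True)
            fh.write("\n")
        manifest["outputs"]["demography"] = "demography.json"

    _run("diversity", _diversity)
    _run("structure", _structure)
    _run("network", _network)
    _run("cluster", _cluster)
    _run("demography", _demography)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def mismatch_expected_padded(fit, length: int) -> np.ndarray:
    from .demography import mismatch_expected

    e = mismatch_expected(fit.tau, fit.theta0, fit.theta1, length - 1, tail="none")
    return e
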