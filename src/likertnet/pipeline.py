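"""End-to-end orchestration: ratings in, comparison report out.

The pipeline runs, per condition: cosine similarity -> TMFG filter ->
binarization -> macro metrics and the node bootstrap; then across
conditions: bootstrap ANOVAs and t-tests, pairwise spectral
Jensen-Shannon distances, consensus community partitions with pairwise
Rand indices, community rating profiles against the reference
condition's partition, and core-periphery assignments with core
overlaps.  Every stochastic stage draws its seed deterministically from
the master seed, and the run manifest records configuration and seeds so
a rerun reproduces all outputs bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io
from .association import cosine_similarity_matrix
from .community import (adjusted_rand_index, community_profile,
                        consensus_partition, rand_index)
from .core_periphery import core_overlap, fit_core_periphery
from .metrics import bootstrap_partial_metrics, compare_conditions, macro_metrics
from .spectral import distance_table
from .synthetic import SyntheticConfig, generate_ratings
from .tmfg import binarize_network, tmfg_filter

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything needed to run (and re-run) the full analysis."""

    input_csv: str | None = None
    synthetic: SyntheticConfig | None = None
    association_mode: str = "raw"
    binarize_threshold: int = 4
    bootstrap_n_nodes: int = 37
    bootstrap_n_real: int = 1000
    bootstrap_partial_mode: str = "tmfg"
    louvain_n_iter: int = 1000
    louvain_gamma: float = 1.0
    consensus_tau: float = 0.5
    core_n_restarts: int = 100
    seed: int = 0
    reference_condition: str | None = None
    output_dir: str | None = None

    def __post_init__(self):
        if (self.input_csv is None) == (self.synthetic is None):
            raise ValueError("provide exactly one of input_csv or synthetic")
        for name in ("bootstrap_n_real", "louvain_n_iter", "core_n_restarts"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.bootstrap_n_nodes < 4:
            raise ValueError("bootstrap_n_nodes must be >= 4 (TMFG needs 4 nodes)")
        if not 0 <= self.consensus_tau < 1:
            raise ValueError("consensus_tau must lie in [0, 1)")


@dataclass
class ReportBundle:
    """All pipeline outputs, keyed by condition where applicable."""

    conditions: list
    ratings: dict
    similarities: dict
    networks: dict            # binarized TMFG per condition
    macro: dict               # MacroMetrics per condition
    bootstrap: dict           # condition -> {measure -> BootstrapDistribution}
    bootstrap_stats: dict     # measure -> comparison report
    jsd: pd.DataFrame
    partitions: dict          # consensus Partition per condition
    rand: dict                # (a, b) -> unadjusted Rand
    adjusted_rand: dict
    profile: pd.DataFrame
    profile_anova: dict
    cores: dict               # CoreAssignment per condition
    core_summary: dict
    planted_partition: object = None
    manifest: dict = field(default_factory=dict)


def _stage_seeds(master: int, conditions: list[str]) -> dict:
    """Named substreams: stable as long as the condition list is stable."""
    root = np.random.SeedSequence(master)
    names = ([f"bootstrap:{c}" for c in conditions]
             + [f"consensus:{c}" for c in conditions]
             + [f"core:{c}" for c in conditions]
             + [f"macro_q:{c}" for c in conditions])
    children = root.spawn(len(names))
    return {n: int(ch.generate_state(1)[0] % (2 ** 31)) for n, ch in zip(names, children)}


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute all stages in order; any stage error aborts with context."""
    stage = "load"
    try:
        planted = None
        if config.synthetic is not None:
            ratings, planted = generate_ratings(config.synthetic)
        else:
            ratings = _io.read_ratings(config.input_csv)
        conditions = list(ratings)
        if len(conditions) < 2:
            raise ValueError("pipeline needs at least 2 conditions to compare")
        seeds = _stage_seeds(config.seed, conditions)

        stage = "association"
        sims = {c: cosine_similarity_matrix(ratings[c], mode=config.association_mode,
                                            threshold=config.binarize_threshold)
                for c in conditions}

        stage = "tmfg"
        nets = {c: binarize_network(tmfg_filter(sims[c], condition=c)) for c in conditions}

        stage = "macro"
        macro = {c: macro_metrics(nets[c], gamma=config.louvain_gamma,
                                  seed=seeds[f"macro_q:{c}"]) for c in conditions}

        stage = "bootstrap"
        boot = {c: bootstrap_partial_metrics(
            sims[c], n_nodes=config.bootstrap_n_nodes, n_real=config.bootstrap_n_real,
            partial_mode=config.bootstrap_partial_mode, seed=seeds[f"bootstrap:{c}"],
            gamma=config.louvain_gamma, condition=c) for c in conditions}
        boot_stats = {m: compare_conditions({c: boot[c][m] for c in conditions})
                      for m in ("CC", "ASPL", "Q")}

        stage = "spectral"
        jsd = distance_table(nets)

        stage = "community"
        parts = {c: consensus_partition(nets[c], n_iter=config.louvain_n_iter,
                                        tau=config.consensus_tau, gamma=config.louvain_gamma,
                                        seed=seeds[f"consensus:{c}"]) for c in conditions}
        rand = {}
        arand = {}
        for i, a in enumerate(conditions):
            for b in conditions[i + 1:]:
                rand[(a, b)] = rand_index(parts[a], parts[b])
                arand[(a, b)] = adjusted_rand_index(parts[a], parts[b])
        ref = config.reference_condition or conditions[0]
        profile, profile_anova = community_profile(ratings, parts[ref])

        stage = "core_periphery"
        cores = {c: fit_core_periphery(nets[c], n_restarts=config.core_n_restarts,
                                       seed=seeds[f"core:{c}"]) for c in conditions}
        summary = core_overlap(cores)

        stage = "manifest"
        cfg_dict = asdict(config)
        if cfg_dict.get("synthetic") is not None:
            syn = cfg_dict["synthetic"]
            syn["planted_partition"] = config.synthetic.planted_partition.labels
            syn["condition_mean_profiles"] = np.asarray(
                config.synthetic.condition_mean_profiles).tolist()
        cfg_json = json.dumps(cfg_dict, sort_keys=True, default=str)
        manifest = {
            "config": cfg_dict,
            "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
            "stage_seeds": seeds,
            "conditions": conditions,
            "reference_condition": ref,
            "n_participants": {c: ratings[c].n_participants for c in conditions},
        }
        return ReportBundle(conditions, ratings, sims, nets, macro, boot, boot_stats,
                            jsd, parts, rand, arand, profile, profile_anova, cores,
                            summary, planted, manifest)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc


def write_bundle(bundle: ReportBundle, outdir) -> None:
    """Serialize a ReportBundle to CSV/JSON/GraphML files under outdir."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    _io.write_ratings(bundle.ratings, out / "ratings.csv")
    for c in bundle.conditions:
        bundle.similarities[c].to_csv(out / f"similarity_{c}.csv")
        _io.write_network(bundle.networks[c], out / f"network_{c}.csv")
        _io.write_network(bundle.networks[c], out / f"network_{c}.graphml")
        _io.write_partition(bundle.partitions[c], out / f"partition_{c}.csv")
    pd.DataFrame([bundle.macro[c].to_dict() for c in bundle.conditions]).to_csv(
        out / "macro_metrics.csv", index=False)
    rows = []
    for c in bundle.conditions:
        for m, d in bundle.bootstrap[c].items():
            rows.append(d.summary())
    pd.DataFrame(rows).to_csv(out / "bootstrap_summary.csv", index=False)
    bundle.jsd.to_csv(out / "jsd.csv")
    core_rows = [{"item": n, "condition": c, "role": lab}
                 for c in bundle.conditions
                 for n, lab in bundle.cores[c].labels.items()]
    pd.DataFrame(core_rows).to_csv(out / "core_membership.csv", index=False)
    bundle.profile.to_csv(out / "community_profile.csv", index=False)

    def _jsonable(o):
        if isinstance(o, (set, frozenset)):
            return sorted(o, key=str)
        if isinstance(o, np.generic):
            return o.item()
        if hasattr(o, "to_dict"):
            return o.to_dict()
        return str(o)

    report = {
        "rand_index": {f"{a}|{b}": v for (a, b), v in bundle.rand.items()},
        "adjusted_rand_index": {f"{a}|{b}": v for (a, b), v in bundle.adjusted_rand.items()},
        "jsd": {f"{a}|{b}": float(bundle.jsd.loc[a, b])
                for i, a in enumerate(bundle.conditions) for b in bundle.conditions[i + 1:]},
        "community_counts": {c: bundle.partitions[c].n_communities for c in bundle.conditions},
        "core_summary": {
            "core_sizes": bundle.core_summary["core_sizes"],
            "shared_core": sorted(bundle.core_summary["shared_core"], key=str),
            "unique_core": {k: sorted(v, key=str)
                            for k, v in bundle.core_summary["unique_core"].items()},
        },
        "bootstrap_stats": {
            m: {"anova": rep["anova"].to_dict(),
                "pairwise": {f"{a}|{b}": t.to_dict()
                             for (a, b), t in rep["pairwise"].items()}}
            for m, rep in bundle.bootstrap_stats.items()},
        "profile_anova": {k: v.to_dict() for k, v in bundle.profile_anova.items()},
        "manifest": bundle.manifest,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, default=_jsonable))
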