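"""Configuration-driven orchestration of the full synthetic analysis.

``run_all`` executes the stages in dependency order — simulate → balance →
compartments → tads → expression → ctads → interactome → networks — and
returns a JSON-serialisable ``RunReport`` with per-stage parameter echoes,
summary tables and planted-truth recovery metrics. All randomness flows from
one root seed through per-stage derived seeds, so repeated runs with the
same configuration are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import compartments as comp_mod
from . import ctad as ctad_mod
from . import domains as dom_mod
from . import interactome as int_mod
from . import networks as net_mod
from .expression import ExpressionMatrix, classify_circadian
from .genome import FeatureSet, GenomicInterval
from .matrix import balance, oe_transform
from .simulate import (ArchitectureTruth, SimConfig, simulate_activity_track,
                       simulate_expression, simulate_hic, simulate_pchic,
                       simulate_truth)

__all__ = ["PipelineConfig", "RunReport", "run_all", "ALL_STAGES"]

ALL_STAGES = ("compartments", "tads", "expression", "ctads",
              "interactome", "networks")

_DEPS = {
    "ctads": ("tads", "expression", "compartments"),
    "interactome": ("expression",),
    "networks": ("expression",),
}


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    # stage parameters
    occ_alpha: float = 0.05
    tad_window_bp: int = 200_000
    tad_threshold: float | None = None   # None: chromosome mean insulation
    tad_min_size_bp: int = 150_000
    tad_max_size_bp: int = 1_500_000
    q_threshold: float = 0.01
    fdr: float = 0.05
    min_lfc: float = 1.0
    distance_cut: float = 150_000
    score_threshold: float = 5.0
    n_iter_enrichment: int = 100
    n_iter_resample: int = 200
    # optional ingestion paths (override the matching simulated input)
    expression_path: str | None = None
    interactions_path: str | None = None
    output_dir: str | None = None

    def __post_init__(self):
        self.sim = SimConfig(**{**self.sim.to_dict(), "seed": self.seed}) \
            if isinstance(self.sim, SimConfig) else SimConfig(seed=self.seed, **self.sim)
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise PipelineError(f"unknown stages: {sorted(unknown)}")
        for stage in self.stages:
            for dep in _DEPS.get(stage, ()):
                if dep not in self.stages:
                    raise PipelineError(f"stage {stage!r} requires {dep!r}")

    def validate_paths(self):
        for name in ("expression_path", "interactions_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise PipelineError(f"stage input missing: {name} -> {p}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("sim", {})
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(sim=sim, **raw)


@dataclass
class RunReport:
    sections: dict

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.sections, indent=indent, sort_keys=True,
                          default=_jsonable)

    def write(self, path) -> None:
        Path(path).write_text(self.to_json())


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not serialisable: {type(x)}")


def _f(x) -> float | None:
    x = float(x)
    return None if np.isnan(x) else x


def run_all(config: PipelineConfig) -> RunReport:
    """Execute the configured stages on seeded synthetic data."""
    config.validate_paths()
    sim = config.sim
    truth = simulate_truth(sim)
    report: dict = {"params": {"seed": config.seed, "sim": sim.to_dict(),
                               "stages": list(config.stages)}}
    ctx: dict = {}

    if "compartments" in config.stages:
        report["compartments"] = _stage_compartments(config, truth, ctx)
    if "tads" in config.stages:
        report["tads"] = _stage_tads(config, truth, ctx)
    if "expression" in config.stages:
        report["expression"] = _stage_expression(config, truth, ctx)
    if "ctads" in config.stages:
        report["ctads"] = _stage_ctads(config, truth, ctx)
    if "interactome" in config.stages:
        report["interactome"] = _stage_interactome(config, truth, ctx)
    if "networks" in config.stages:
        report["networks"] = _stage_networks(config, truth, ctx)

    rep = RunReport(report)
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        rep.write(out / "run_report.json")
    return rep


def _stage_compartments(config, truth: ArchitectureTruth, ctx) -> dict:
    sim = truth.config
    tps = sim.timepoints
    all_regions = []
    tp, fp, true_pos_total = 0, 0, 0
    category_counts: dict[str, int] = {}
    occ_span = 0
    for chrom in truth.genome.names:
        activity = simulate_activity_track(truth, chrom)
        track = comp_mod.EigenTrack(chrom, sim.bin_size_compartment)
        for t in tps:
            reps = [simulate_hic(truth, t, r, chrom=chrom)
                    for r in range(1, sim.hic_replicates + 1)]
            for r, m in enumerate(reps, 1):
                track.replicates[(t, r)] = comp_mod.compute_pc1(balance(m), activity)
            merged = reps[0].merged_with(*reps[1:])
            track.merged[t] = comp_mod.compute_pc1(balance(merged), activity)
        regions, per_bin = comp_mod.detect_occ(
            track, alpha=config.occ_alpha,
            chrom_length=truth.genome.length(chrom))
        all_regions.extend(regions)
        called = per_bin["oscillatory"]
        true_occ = truth.occ_bins[chrom]
        tp += int((called & true_occ).sum())
        fp += int((called & ~true_occ).sum())
        true_pos_total += int(true_occ.sum())
        for reg in regions:
            category_counts[reg.category] = category_counts.get(reg.category, 0) \
                + reg.n_bins
            occ_span += reg.interval.length
        ctx.setdefault("eigen_tracks", {})[chrom] = track
    ctx["occ_regions"] = all_regions
    called_total = tp + fp
    genome_bp = sum(l for _, l in truth.genome.chromosomes)
    return {
        "n_occ_regions": len(all_regions),
        "occ_span_bp": occ_span,
        "occ_genome_fraction": occ_span / genome_bp,
        "category_bin_counts": category_counts,
        "recovery": {
            "sensitivity": tp / true_pos_total if true_pos_total else None,
            "fdr": fp / called_total if called_total else 0.0,
        },
        "alpha": config.occ_alpha,
    }


def _stage_tads(config, truth: ArchitectureTruth, ctx) -> dict:
    sim = truth.config
    tads_by_t: dict[int, list] = {t: [] for t in sim.timepoints}
    recovered = planted = 0
    for chrom in truth.genome.names:
        true_bounds = truth.tad_boundaries(chrom)
        for t in sim.timepoints:
            merged = simulate_hic(truth, t, 0, depth=sim.hic_depth * sim.hic_replicates,
                                  chrom=chrom, bin_size=sim.bin_size_tad)
            track = dom_mod.insulation_score(merged, config.tad_window_bp)
            threshold = (config.tad_threshold
                         if config.tad_threshold is not None
                         else float(np.nanmean(track.score)))
            tads = dom_mod.call_tads(track, threshold,
                                     config.tad_min_size_bp,
                                     config.tad_max_size_bp, timepoint=t)
            tads_by_t[t].extend(tads)
            if t == sim.timepoints[0]:
                called = np.array(dom_mod.find_boundaries(track, threshold)) \
                    * sim.bin_size_tad
                planted += len(true_bounds)
                for b in true_bounds:
                    if len(called) and np.min(np.abs(called - b)) <= sim.bin_size_tad:
                        recovered += 1
    t0, t2 = sim.timepoints[0], sim.timepoints[2]
    shared = dom_mod.shared_tads(tads_by_t[t0], tads_by_t[t2])
    sizes = [t.length for t in tads_by_t[t0]]
    ctx["tads"] = tads_by_t
    return {
        "n_tads": {f"ZT{t}": len(v) for t, v in tads_by_t.items()},
        "median_size_bp": float(np.median(sizes)) if sizes else None,
        "shared_fraction_ZT0_ZT12":
            shared.n_shared / len(tads_by_t[t0]) if tads_by_t[t0] else None,
        "boundary_recovery": recovered / planted if planted else None,
        "window_bp": config.tad_window_bp,
    }


def _stage_expression(config, truth: ArchitectureTruth, ctx) -> dict:
    if config.expression_path:
        expr = ExpressionMatrix.read_tsv(config.expression_path)
    else:
        expr = simulate_expression(truth)
    calls = classify_circadian(expr, q_threshold=config.q_threshold)
    ctx["expr"], ctx["calls"] = expr, calls

    truth_circ = set(truth.circadian_gene_ids)
    called = set(calls.circadian_genes)
    power = len(called & truth_circ) / len(truth_circ) if truth_circ else None
    fdr = len(called - truth_circ) / len(called) if called else 0.0
    correct_phase = sum(
        1 for g in (called & truth_circ)
        if calls.phase_of(g) == int(truth.genes.set_index("gene_id").loc[g, "phase"])
    )
    hist = calls.df.loc[calls.df["circadian"], "phase"].value_counts().to_dict()
    return {
        "n_genes": len(calls.df),
        "n_circadian": len(called),
        "phase_histogram": {f"ZT{int(t)}": int(c) for t, c in sorted(hist.items())},
        "recovery": {"power": power, "fdr": fdr,
                     "phase_accuracy": correct_phase / max(len(called & truth_circ), 1)},
        "q_threshold": config.q_threshold,
    }


def _stage_ctads(config, truth: ArchitectureTruth, ctx) -> dict:
    calls = ctx["calls"]
    t0 = truth.config.timepoints[0]
    tads = ctx["tads"][t0]
    genes = truth.genes[["gene_id", "chrom", "tss"]].merge(
        calls.df[["gene_id", "circadian", "phase"]], on="gene_id")
    assignments, unassigned = ctad_mod.assign_genes_to_tads(genes, tads)
    ctads, non_ctads = ctad_mod.make_ctads(assignments)
    n_genes_per_tad = [a.n_genes for a in assignments]

    freqs = calls.phase_frequencies()
    sharing = ctad_mod.phase_sharing(ctads, freqs) if ctads else []
    occ = ctx.get("occ_regions", [])
    seed = (config.seed * 7919 + 11) % (2**31)
    overlap = None
    if ctads and len(non_ctads) >= len(ctads) and occ:
        res = ctad_mod.occ_overlap_test(ctads, non_ctads, occ,
                                        n_iter=config.n_iter_resample, seed=seed)
        overlap = {"observed": res.observed, "z": _f(res.z),
                   "empirical_p": res.empirical_p,
                   "null_mean": _f(res.null_draws.mean())}
    return {
        "n_ctads": len(ctads),
        "n_tads_with_genes": sum(1 for a in assignments if a.n_genes),
        "mean_genes_per_tad": float(np.mean(n_genes_per_tad)) if n_genes_per_tad else None,
        "n_unassigned_genes": len(unassigned),
        "phase_sharing": [
            {"k": r.k, "n_tads": r.n_tads, "observed_prop": r.observed_prop,
             "expected_prop": r.expected_prop, "chi2": _f(r.chi2), "p": _f(r.p),
             "low_count": r.low_count}
            for r in sharing
        ],
        "occ_overlap": overlap,
    }


def _stage_interactome(config, truth: ArchitectureTruth, ctx) -> dict:
    from .io import read_interactions

    sim = truth.config
    calls = ctx["calls"]
    if config.interactions_path:
        table = read_interactions(config.interactions_path, "ibed", truth.fragmap,
                                  baits=truth.bait_universe)
    else:
        table = simulate_pchic(truth)
    ctx["pchic"] = table
    gene_baits = dict(zip(truth.genes["gene_id"], truth.genes["bait_frag"]))
    circ_baits = {gene_baits[g] for g in calls.circadian_genes if g in gene_baits}

    dyn = int_mod.classify_dynamic(table, distance_cut=config.distance_cut,
                                   fdr=config.fdr, min_lfc=config.min_lfc,
                                   bait_filter=circ_baits)
    ctx["dynamic_calls"] = dyn
    # planted-truth scoring over the tested subset
    key = list(zip(dyn.df["bait_frag"], dyn.df["other_frag"]))
    planted = truth.interactions.set_index(["bait_frag", "other_frag"])["klass"]
    truth_class = np.array([planted.get(k, "stable") for k in key])
    called_dyn = (dyn.df["klass"] == "dynamic").to_numpy()
    is_dyn = truth_class == "dynamic"
    power = float((called_dyn & is_dyn).sum() / is_dyn.sum()) if is_dyn.any() else None
    fdr_obs = float((called_dyn & ~is_dyn).sum() / called_dyn.sum()) \
        if called_dyn.any() else 0.0

    cpt = int_mod.contacts_per_timepoint(table, calls, gene_baits,
                                         config.score_threshold)
    seed = (config.seed * 7919 + 23) % (2**31)
    enr = int_mod.matched_null_enrichment(table, truth.planted_features,
                                          truth.bait_universe, truth.fragmap,
                                          n_iter=config.n_iter_enrichment,
                                          seed=seed)
    enh = truth.enhancers
    osc = FeatureSet("osc_eRNA", [
        GenomicInterval(r["chrom"], int(r["start"]), int(r["end"]),
                        phase_hr=float(r["phase_hr"]))
        for _, r in enh[enh["oscillatory"]].iterrows()])
    nonosc = FeatureSet("nonosc_eRNA", [
        GenomicInterval(r["chrom"], int(r["start"]), int(r["end"]))
        for _, r in enh[~enh["oscillatory"]].iterrows()])
    erna = int_mod.erna_contact_enrichment(table, osc, nonosc, circ_baits,
                                           truth.fragmap,
                                           n_iter=config.n_iter_enrichment,
                                           seed=seed + 1)
    target_phases = {int(r["frag"]): float(r["phase_hr"])
                     for _, r in enh[enh["oscillatory"]].iterrows()}
    coherence = int_mod.phase_coherence(table, calls, gene_baits, target_phases,
                                        target_binning="hr8x3",
                                        score_threshold=config.score_threshold)
    core = None
    try:
        cc = int_mod.coreclock_comparison(table, calls, gene_baits, dyn,
                                          n_iter=100, seed=seed + 2,
                                          score_threshold=config.score_threshold)
        core = {
            "core_mean_contacts": _f(cc.core_contacts.mean()),
            "null_mean_contacts": _f(cc.null_contacts.mean()),
            "core_mean_dynamic_frac": _f(cc.core_dynamic_frac.mean()),
            "null_mean_dynamic_frac": _f(cc.null_dynamic_frac.mean()),
            "p_contacts": _f(cc.p_contacts), "p_dynamic": _f(cc.p_dynamic),
        }
    except ValueError:
        pass

    offsets = cpt.offset_counts()
    total_offsets = sum(offsets.values())
    return {
        "n_tested": len(dyn.df),
        "n_dynamic": dyn.n_dynamic,
        "n_stable": dyn.n_stable,
        "recovery": {"power": power, "fdr": fdr_obs},
        "contacts_peak": {
            "chi2": _f(cpt.chi2), "p": _f(cpt.p),
            "offset0_fraction": offsets.get(0, 0) / total_offsets
            if total_offsets else None,
        },
        "feature_enrichment": {"ratio": _f(enr.ratio), "t_p": _f(enr.t_p),
                               "observed": enr.observed,
                               "expected_mean": _f(enr.expected_mean)},
        "erna_enrichment": {"ratio": _f(erna.ratio), "t_p": _f(erna.t_p),
                            "observed": erna.observed},
        "phase_coherence": {
            "wilcoxon_p": _f(coherence.wilcoxon_p),
            "distributions": {k: v.tolist()
                              for k, v in coherence.distributions.items()},
        },
        "core_clock": core,
    }


def _stage_networks(config, truth: ArchitectureTruth, ctx) -> dict:
    calls = ctx["calls"]
    table = ctx.get("pchic")
    if table is None:
        table = simulate_pchic(truth)
    gene_baits = dict(zip(truth.genes["gene_id"], truth.genes["bait_frag"]))
    circ_nodes = {gene_baits[g] for g in calls.circadian_genes if g in gene_baits}
    graph = net_mod.build_graph(table, timepoint=None,
                                score_threshold=config.score_threshold)
    filtered = net_mod.filter_small_components(graph, min_nodes=4)
    seed = (config.seed * 7919 + 37) % (2**31)
    out = {"n_nodes": graph.number_of_nodes(),
           "n_edges": graph.number_of_edges(),
           "n_nodes_filtered": filtered.number_of_nodes()}
    circ_here = circ_nodes & set(graph.nodes)
    non = set(graph.nodes) - circ_here
    if circ_here and len(non) >= len(circ_here):
        zres = net_mod.circadian_edge_zscore(graph, circ_here,
                                             n_iter=config.n_iter_resample,
                                             seed=seed)
        sup = net_mod.edge_support_comparison(graph, circ_here,
                                              n_iter=min(config.n_iter_resample, 100),
                                              seed=seed + 1)
        out["circadian_edges"] = {"observed": zres.observed, "z": _f(zres.z),
                                  "empirical_p": zres.empirical_p,
                                  "null_mean": _f(zres.null_mean)}
        out["edge_support"] = {"mannwhitney_p": _f(sup.mannwhitney_p),
                               "degenerate": sup.degenerate}
    return out
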