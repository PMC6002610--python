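"""End-to-end orchestration: simulate or load -> filter -> DE -> signature
randomisation -> correlation networks, with a reproducibility manifest.

The three standard comparisons (1h EE vs 1h B; 4h EE vs 4h B; all EE vs
all B) share one expression filter applied once to the whole dataset, so
every comparison works on the same gene universe. One master seed spawns a
deterministic per-stage seed from the stage name, so any stage can be rerun
in isolation and two runs with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import pandas as pd
import yaml

from . import __version__
from .de import DEConfig, DifferentialExpression, DEResults
from .io import (ExpressionMatrix, GeneSignature, SampleTable,
                 filter_low_expression, read_matrix, read_samples,
                 read_signatures)
from .network import correlation_graph, export_graph, mcl_cluster
from .randomization import RandomizationResult, randomization_test, results_table
from .simulate import SimConfig, SimOutput, simulate_experiment

log = logging.getLogger(__name__)


def stage_seed(master: int, stage: str) -> int:
    """Deterministic sub-seed for a named stage (below 2**31)."""
    h = hashlib.blake2b(f"{master}:{stage}".encode(), digest_size=8)
    return int.from_bytes(h.digest(), "big") % (2 ** 31)


@dataclass
class Comparison:
    name: str
    treatment_a: str = "EE"
    treatment_b: str = "B"
    timepoint: str | None = None  # None = pool both timepoints


DEFAULT_COMPARISONS = (
    Comparison("1h_EE_vs_B", timepoint="1h"),
    Comparison("4h_EE_vs_B", timepoint="4h"),
    Comparison("all_EE_vs_B", timepoint=None),
)


@dataclass
class NetworkSettings:
    sample_threshold_all: float = 0.99
    sample_threshold_de: float = 0.93
    gene_threshold: float = 0.90
    inflation: float = 2.2

    def __post_init__(self) -> None:
        for t in (self.sample_threshold_all, self.sample_threshold_de,
                  self.gene_threshold):
            if not 0 < t <= 1:
                raise ValueError("correlation thresholds must lie in (0, 1]")


@dataclass
class PipelineConfig:
    """Inputs, thresholds and seeds for one full analysis run.

    Either ``sim`` (synthetic experiment) or the four input paths must be
    given. ``signature_directions`` maps signature name -> up/down for GMT
    files whose description field does not carry the direction.
    """

    sim: SimConfig | None = None
    counts_path: str | None = None
    tpm_path: str | None = None
    samples_path: str | None = None
    signatures_path: str | None = None
    signature_directions: dict[str, str] | None = None
    de: DEConfig = field(default_factory=DEConfig)
    comparisons: Sequence[Comparison] = DEFAULT_COMPARISONS
    filter_threshold: float = 2.0
    s: int = 10_000
    networks: NetworkSettings = field(default_factory=NetworkSettings)
    seed: int = 0
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict[str, Any] = {}
        if "sim" in raw and raw["sim"] is not None:
            sim = raw["sim"]
            for key in ("baseline_log_mean_range", "library_size_range",
                        "gene_length_range"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            kwargs["sim"] = SimConfig(**sim)
        if "de" in raw:
            kwargs["de"] = DEConfig(**raw["de"])
        if "networks" in raw:
            kwargs["networks"] = NetworkSettings(**raw["networks"])
        if "comparisons" in raw:
            kwargs["comparisons"] = [Comparison(**c) for c in raw["comparisons"]]
        for key in ("counts_path", "tpm_path", "samples_path",
                    "signatures_path", "signature_directions",
                    "filter_threshold", "s", "seed", "outdir"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(_as_jsonable(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _as_jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    return obj


@dataclass
class PipelineReport:
    """In-memory bundle of everything one run produced."""

    config: PipelineConfig
    universe: list[str]
    de_results: dict[str, DEResults]
    randomization: dict[str, list[RandomizationResult]]
    networks: dict[str, Any]
    clusterings: dict[str, Any]
    manifest: dict
    sim_output: SimOutput | None = None


def _load_inputs(config: PipelineConfig):
    if config.sim is not None:
        sim_cfg = dataclasses.replace(
            config.sim, seed=stage_seed(config.seed, "simulate")
            if config.sim.seed is None else config.sim.seed)
        out = simulate_experiment(sim_cfg)
        sigs = out.signatures
        if config.signatures_path:
            sigs = read_signatures(config.signatures_path,
                                   config.signature_directions)
        return out.counts, out.tpm, out.samples, sigs, out
    needed = (config.counts_path, config.tpm_path, config.samples_path)
    if any(p is None for p in needed):
        raise ValueError("need either a sim config or counts/tpm/samples paths")
    counts = read_matrix(config.counts_path, "counts")
    tpm = read_matrix(config.tpm_path, "TPM")
    samples = read_samples(config.samples_path)
    sigs = (read_signatures(config.signatures_path, config.signature_directions)
            if config.signatures_path else [])
    return counts, tpm, samples, sigs, None


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute every stage; write outputs when ``config.outdir`` is set."""
    t0 = time.time()
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    timings: dict[str, float] = {}

    def tick(stage: str, start: float) -> None:
        timings[stage] = round(time.time() - start, 3)
        log.info("stage %s done in %.2fs", stage, timings[stage])

    t = time.time()
    counts, tpm, samples, signatures, sim_out = _load_inputs(config)
    if outdir and sim_out is not None:
        sim_out.write(outdir / "simulated")
    tick("load", t)

    # one filter for the whole dataset -> shared gene universe
    t = time.time()
    universe = filter_low_expression(tpm, samples,
                                     threshold=config.filter_threshold)
    if not universe:
        raise RuntimeError("filter stage: no genes retained")
    counts_f = counts.subset_genes(universe)
    tpm_f = tpm.subset_genes(universe)
    if outdir:
        (outdir / "filtered_genes.txt").write_text("\n".join(universe) + "\n")
    tick("filter", t)

    t = time.time()
    de_results: dict[str, DEResults] = {}
    for comp in config.comparisons:
        group_a = samples.select(comp.treatment_a, comp.timepoint)
        group_b = samples.select(comp.treatment_b, comp.timepoint)
        if not group_a or not group_b:
            raise RuntimeError(f"DE stage: comparison {comp.name} has an "
                               "empty group")
        model = DifferentialExpression(counts_f, samples, group_a, group_b,
                                       config.de)
        res = model.fit()
        de_results[comp.name] = res
        if outdir:
            res.to_tsv(outdir / f"de_{comp.name}.tsv")
    if outdir:
        summary = {name: {"n_up": r.n_up, "n_down": r.n_down,
                          "n_genes": len(r.table)}
                   for name, r in de_results.items()}
        (outdir / "de_summary.json").write_text(
            json.dumps(summary, indent=2) + "\n")
    tick("differential_expression", t)

    t = time.time()
    randomization: dict[str, list[RandomizationResult]] = {}
    for name, res in de_results.items():
        rows = []
        for sig in signatures:
            seed = stage_seed(config.seed, f"randomization:{name}:{sig.name}")
            rows.append(randomization_test(res.log2fc, sig, s=config.s,
                                           seed=seed))
        randomization[name] = rows
    if outdir and signatures:
        tables = []
        for name, rows in randomization.items():
            tab = results_table(rows)
            tab.insert(0, "comparison", name)
            tables.append(tab)
        pd.concat(tables, ignore_index=True).to_csv(
            outdir / "randomization_results.tsv", sep="\t", index=False)
    tick("signature_randomization", t)

    t = time.time()
    nets, clusterings = {}, {}
    ns = config.networks

    nets["samples_all_genes"] = correlation_graph(
        tpm_f, axis="samples", threshold=ns.sample_threshold_all)
    de_union = sorted(set().union(*(r.de_genes() for r in de_results.values())))
    if de_union:
        nets["samples_de_genes"] = correlation_graph(
            tpm_f.subset_genes(de_union), axis="samples",
            threshold=ns.sample_threshold_de)
    else:
        log.warning("no DE genes called; skipping the DE-gene sample graph")
    nets["genes"] = correlation_graph(tpm_f, axis="genes",
                                      threshold=ns.gene_threshold)
    for name, graph in nets.items():
        clusterings[name] = mcl_cluster(graph, inflation=ns.inflation)
        if outdir:
            attrs = samples.df if graph.axis == "samples" else None
            export_graph(graph, clusterings[name],
                         outdir / f"graph_{name}.graphml", node_attrs=attrs)
            clusterings[name].to_tsv(outdir / f"clusters_{name}.tsv")
    tick("networks", t)

    manifest = {
        "eeseq_version": __version__,
        "config": _as_jsonable(config),
        "config_hash": config.config_hash(),
        "master_seed": config.seed,
        "stage_seeds": {
            "simulate": stage_seed(config.seed, "simulate"),
            **{f"randomization:{c}:{s.name}":
               stage_seed(config.seed, f"randomization:{c}:{s.name}")
               for c in de_results for s in signatures},
        },
        "n_genes_input": counts.shape[0],
        "n_genes_retained": len(universe),
        "n_samples": counts.shape[1],
        "stage_seconds": timings,
    }
    if outdir:
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                         sort_keys=True) + "\n")
    log.info("pipeline finished in %.2fs", time.time() - t0)
    return PipelineReport(config, universe, de_results, randomization,
                          nets, clusterings, manifest, sim_out)
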