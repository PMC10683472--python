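"""Pipeline orchestration: simulate → preprocess → train → design → analyze.

A run is driven by a :class:`RunConfig` (round-trippable through YAML); each
stage records its outputs and seeds in a JSON manifest so a rerun with the
same config reproduces all deterministic outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .codons import parse_design_spec
from .design import ala_scan, evaluate_design, search_codon_pairs, score_design
from .enrichment import abundance_rank, fitness_trajectory
from .model import FitnessCNN, evaluate, reduced_config, save_model, train
from .oracle import OracleParams, RuleOracle
from .preprocess import build_labeled_dataset, collapse_reads, quality_filter, read_fastq
from .simulate import RoundParams, run_campaign

__all__ = ["RunConfig", "run_pipeline", "dataset_from_campaign"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run; every stochastic stage has an
    explicit seed derived from ``seed``."""

    design: str = "nnk " * 10 + "nnk"
    seed: int = 0
    stages: tuple[str, ...] = ("simulate", "preprocess", "train", "design", "analyze")
    n_rounds: int = 6
    n_variants: int = 20_000
    min_phred: int = 30
    model: dict = field(default_factory=lambda: {"n_conv_layers": 3,
                                                 "channels": 48, "epochs": 6})
    sim_params: dict = field(default_factory=dict)
    oracle: dict = field(default_factory=dict)
    scoring_mode: str = "long"
    design_candidates_a: tuple[str, ...] = ("dsk", "dbk", "nnk")
    design_candidates_b: tuple[str, ...] = ("nnu", "dbk", "nnk")
    eval_sample_size: int = 10_000

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("stages", "design_candidates_a", "design_candidates_b"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def dataset_from_campaign(result, design, round_index=None, min_phred=30, seed=0):
    """Preprocess the final (or given) round's selection/antiselection FASTQ
    pair of a simulated campaign into a labeled dataset."""
    if round_index is None:
        round_index = max(r for (_m, r) in result.fastq_paths)
    pools = {}
    for mode in ("selection", "antiselection"):
        reads = read_fastq(result.fastq_paths[(mode, round_index)])
        kept, _stats = quality_filter(reads, min_phred)
        counts, tally = collapse_reads(kept, design)
        logger.info("%s round %d rejection tally: %s", mode, round_index, dict(tally))
        pools[mode] = counts
    return build_labeled_dataset(pools["selection"], pools["antiselection"],
                                 seed=seed)


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the requested stages in order, returning the manifest dict.

    The manifest lists every produced file (with checksum) and the seed of
    every stochastic stage; it is also written to ``manifest.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design = parse_design_spec(config.design)
    oracle = RuleOracle(OracleParams(**config.oracle))
    manifest: dict = {"config": asdict(config), "stages": {}, "files": {}}

    campaign = None
    dataset = None
    model = None

    def record(path: Path):
        manifest["files"][str(path.relative_to(outdir))] = _sha256(path)

    for stage in config.stages:
        logger.info("pipeline stage: %s", stage)
        try:
            if stage == "simulate":
                campaign = run_campaign(
                    design, oracle, outdir / "sim",
                    n_rounds=config.n_rounds, n_variants=config.n_variants,
                    params=RoundParams(**config.sim_params), seed=config.seed,
                )
                for p in campaign.fastq_paths.values():
                    record(p)
                record(campaign.manifest_path)
                record(outdir / "sim" / "round_summaries.tsv")
                manifest["stages"]["simulate"] = {"seed": config.seed}
            elif stage == "preprocess":
                if campaign is None:
                    raise RuntimeError("preprocess requires the simulate stage")
                dataset = dataset_from_campaign(
                    campaign, design, min_phred=config.min_phred,
                    seed=config.seed + 1,
                )
                path = outdir / "dataset.tsv"
                dataset.write(path)
                record(path)
                manifest["stages"]["preprocess"] = {
                    "seed": config.seed + 1, "n_records": len(dataset),
                    **dataset.provenance,
                }
            elif stage == "train":
                if dataset is None:
                    raise RuntimeError("train requires the preprocess stage")
                model = FitnessCNN(**{**config.model, "seed": config.seed + 2})
                model, history = train(model, dataset)
                ckpt = outdir / "model.npz"
                save_model(model, ckpt)
                metrics = evaluate(model, dataset, "test")
                (outdir / "metrics.json").write_text(json.dumps(
                    {"history": history, "test": metrics}, indent=2))
                record(outdir / "metrics.json")
                manifest["stages"]["train"] = {
                    "seed": config.seed + 2,
                    "test_accuracy": metrics["accuracy"],
                }
            elif stage == "design":
                predictor = model if model is not None else oracle
                scan = ala_scan(predictor, design, n=config.eval_sample_size,
                                seed=config.seed + 3)
                pairs = search_codon_pairs(
                    predictor, design, 1, len(design),
                    config.design_candidates_a, config.design_candidates_b,
                    mode=config.scoring_mode, n=config.eval_sample_size,
                    seed=config.seed + 3,
                )
                best = pairs[0]
                report = {
                    "ala_scan_delta_E": scan.delta_E,
                    "ranked_positions": scan.ranked_positions(),
                    "best_design": best.design.spec,
                    "best_E": best.E, "best_M": best.M,
                    "best_D": str(best.D),
                }
                (outdir / "design_report.json").write_text(
                    json.dumps(report, indent=2))
                record(outdir / "design_report.json")
                manifest["stages"]["design"] = {"seed": config.seed + 3,
                                                "best_design": best.design.spec}
            elif stage == "analyze":
                if campaign is None:
                    raise RuntimeError("analyze requires the simulate stage")
                predictor = model if model is not None else oracle
                per_round = []
                n_rounds = max(r for (_m, r) in campaign.fastq_paths)
                for r in range(1, n_rounds + 1):
                    reads, _ = quality_filter(
                        read_fastq(campaign.fastq_paths[("selection", r)]),
                        config.min_phred)
                    counts, _ = collapse_reads(reads, design)
                    per_round.append(counts)
                traj = fitness_trajectory(predictor, per_round)
                rank = abundance_rank(per_round[-1])
                rank.head(1000).to_csv(outdir / "top_sequences.tsv",
                                       sep="\t", index=False)
                record(outdir / "top_sequences.tsv")
                (outdir / "trajectory.json").write_text(
                    json.dumps({"selection_mean_fitness": traj.tolist()}))
                record(outdir / "trajectory.json")
                manifest["stages"]["analyze"] = {
                    "trajectory": traj.tolist(),
                }
            else:
                raise ValueError(f"unknown stage: {stage}")
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True))
    return manifest
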