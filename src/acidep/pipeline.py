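"""End-to-end orchestration: expression -> fold changes -> Venn ->
(optional) signature comparison -> hit scoring -> stage concordance.

The pipeline is driven by a :class:`PipelineConfig` (YAML-loadable, fully
defaulted). Inputs either come from files in the formats ``expr_io`` reads,
or from the synthetic generator when ``simulate`` is set. Every tunable and
seed is echoed into the JSON summary so a run is auditable, and identical
config + inputs give byte-identical summaries.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import diffexpr, expr_io, hitscore, signature_compare, synthetic_data
from .errors import AcidepError, ConfigError, DataError

logger = logging.getLogger("acidep")


@dataclass
class PipelineConfig:
    """All pipeline tunables, defaulting to the study constants:
    fold-change thresholds 2 and 4, top-100 gene lists, 20% inversion
    tolerance, 50% minimum hit rate."""

    # input: either simulate, or supply matrix/meta paths
    simulate: bool = True
    matrix_path: str | None = None
    meta_path: str | None = None
    matrix_dialect: str = "tsv"
    matrix_scale: str = "linear"
    prognostic_path: str | None = None
    stage_path: str | None = None
    signature_path: str | None = None
    signature_sidecar: str | None = None

    control: str = "pH7.4"
    tests: list[str] = field(default_factory=lambda: ["pH6.8", "pH5.9"])
    thresholds: list[float] = field(default_factory=lambda: [2.0, 4.0])
    top_n: int = 100
    tol: float = 0.20
    hit_rate_min: float = 0.5
    dominance_margin: int = 0
    mean_rule: str = "geometric"
    floor: float = 1.0
    n_permutations: int = 1000
    seed: int = 0

    # synthetic-input knobs (used when simulate=True)
    sim_noise_sd_log2: float = 0.25
    sim_concordance_q: dict[str, float] = field(default_factory=dict)
    sim_missing_rate: float = 0.0
    sim_planted: dict[str, int] | None = None
    sim_n_genes: int = 20000
    sim_stage_concordance: float = 0.5

    def __post_init__(self) -> None:
        if any(t <= 1 for t in self.thresholds):
            raise ConfigError("all thresholds must be > 1")
        if self.top_n < 1:
            raise ConfigError("top_n must be >= 1")
        if not 0.0 <= self.tol <= 1.0:
            raise ConfigError("tol must be in [0, 1]")
        if not 0.0 <= self.hit_rate_min <= 1.0:
            raise ConfigError("hit_rate_min must be in [0, 1]")
        if not self.simulate and not self.matrix_path:
            raise ConfigError("either simulate=True or matrix_path is required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _load_or_simulate(config: PipelineConfig):
    """Return (matrix, truth-or-None, annotation, stage_ann, signature-or-None)."""
    if config.simulate:
        sim = synthetic_data.SimulationConfig(
            n_genes=config.sim_n_genes,
            control=config.control,
            tests=tuple(config.tests),
            noise_sd_log2=config.sim_noise_sd_log2,
            seed=config.seed,
            **(
                {"planted": dict(config.sim_planted)}
                if config.sim_planted is not None
                else {}
            ),
        )
        matrix, truth = synthetic_data.simulate_expression(sim)
        return matrix, truth, None, None, None
    matrix = expr_io.read_expression_table(
        config.matrix_path,
        meta=config.meta_path,
        dialect=config.matrix_dialect,
        scale=config.matrix_scale,
    )
    annotation = (
        hitscore.PrognosticAnnotation.from_table(config.prognostic_path)
        if config.prognostic_path
        else None
    )
    stage_ann = (
        hitscore.StageAnnotation.from_table(config.stage_path)
        if config.stage_path
        else None
    )
    signature = (
        signature_compare.read_signature(config.signature_path, config.signature_sidecar)
        if config.signature_path
        else None
    )
    return matrix, None, annotation, stage_ann, signature


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Run all stages and return the report bundle (a nested dict).

    When ``out_dir`` is given the bundle JSON, fold-change table, gene-set
    files and hit matrix are written there. Any stage failure aborts with
    the stage name attached to the error.
    """
    bundle: dict = {"config": config.as_dict(), "stages": {}}
    stage = "load"
    try:
        matrix, truth, annotation, stage_ann, signature = _load_or_simulate(config)
        cond_a, cond_b = config.tests[0], config.tests[1]

        stage = "diffexpr"
        table = diffexpr.compute_fold_changes(
            matrix, config.control, list(config.tests),
            mean=config.mean_rule, floor=config.floor,
        )
        bundle["stages"]["diffexpr"] = {
            "n_genes": len(table.genes),
            "conditions": table.conditions,
        }

        stage = "venn"
        venn_counts: dict[str, dict] = {}
        gene_sets: dict[str, expr_io.GeneSet] = {}
        for threshold in config.thresholds:
            for direction in ("up", "down"):
                set_a = diffexpr.select_modulated(table, cond_a, threshold, direction)
                set_b = diffexpr.select_modulated(table, cond_b, threshold, direction)
                part = diffexpr.venn_partition(set_a, set_b)
                key = f"{direction}_{threshold:g}x"
                a_only, common, b_only = part.counts
                venn_counts[key] = {
                    f"{cond_a}_only": a_only,
                    "common": common,
                    f"{cond_b}_only": b_only,
                }
                gene_sets[f"{key}_{cond_a}"] = set_a
                gene_sets[f"{key}_{cond_b}"] = set_b
        bundle["stages"]["venn"] = venn_counts

        stage = "signature_compare"
        if config.simulate and signature is None and truth is not None:
            signature = synthetic_data.simulate_reference_signature(
                truth, overlap_with_planted=0.8, seed=config.seed + 1,
            )
        if signature is not None:
            theta = min(config.thresholds)
            contingencies = {}
            for cond in (cond_a, cond_b):
                up = gene_sets[f"up_{theta:g}x_{cond}"]
                down = gene_sets[f"down_{theta:g}x_{cond}"]
                res = signature_compare.build_contingency(signature, up, down)
                signature_compare.chi_square_contingency(res)
                contingencies[cond] = res.as_dict()
            bundle["stages"]["signature_compare"] = {
                "contrast": signature.contrast_name,
                "threshold": theta,
                "contingency": contingencies,
            }

        stage = "hitscore"
        induced = diffexpr.top_n_by_fold_change(table, cond_b, config.top_n, "up")
        reduced = diffexpr.top_n_by_fold_change(table, cond_b, config.top_n, "down")
        role_by_gene = {g: "induced" for g in induced}
        role_by_gene.update({g: "reduced" for g in reduced})
        if config.simulate and annotation is None:
            ann_cfg = synthetic_data.AnnotationSimConfig(
                concordance_q=dict(config.sim_concordance_q),
                missing_rate=config.sim_missing_rate,
                seed=config.seed + 2,
            )
            annotation = synthetic_data.simulate_prognostic_annotations(
                induced, reduced, ann_cfg
            )
        results: list[hitscore.HitScoreResult] = []
        if annotation is not None and annotation.entries:
            for tumor in annotation.tumor_types:
                results.append(
                    hitscore.score_tumor(
                        induced, reduced, annotation, tumor,
                        tol=config.tol, dominance_margin=config.dominance_margin,
                    )
                )
            ranking = hitscore.rank_tumors(results)
            high_rate = hitscore.filter_by_hit_rate(
                induced + reduced, results, min_rate=config.hit_rate_min
            )
            bundle["stages"]["hitscore"] = {
                "top_n": config.top_n,
                "ranking": ranking.to_dict(orient="records"),
                "high_hit_rate_genes": high_rate,
            }
        else:
            results, high_rate = [], []
            bundle["stages"]["hitscore"] = {
                "top_n": config.top_n, "ranking": [], "high_hit_rate_genes": [],
            }

        stage = "stage_concordance"
        if config.simulate and stage_ann is None and high_rate:
            stage_ann = synthetic_data.simulate_stage_annotations(
                high_rate,
                [t for t in synthetic_data.DEFAULT_TUMOR_TYPES if t != "melanoma"],
                concordance=config.sim_stage_concordance,
                seed=config.seed + 3,
                role_by_gene=role_by_gene,
            )
        if stage_ann is not None and high_rate:
            conc = hitscore.stage_concordance(high_rate, stage_ann, role_by_gene)
            bundle["stages"]["stage_concordance"] = conc.reset_index().to_dict(
                orient="records"
            )

        bundle["complete"] = True
    except AcidepError as exc:
        bundle["complete"] = False
        bundle["failed_stage"] = stage
        raise type(exc)(f"[stage {stage}] {exc}") from exc

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "summary.json", "w") as fh:
            json.dump(bundle, fh, indent=2, sort_keys=True)
        table.fc.to_csv(out / "fold_changes.tsv", sep="\t")
        table.p.to_csv(out / "pvalues.tsv", sep="\t")
        for key, gs in gene_sets.items():
            expr_io.write_gene_set(gs, out / f"geneset_{key}.txt")
        if results:
            hitscore.hit_matrix(results).to_csv(out / "hit_matrix.tsv", sep="\t")
    return bundle


def make_report(bundle: dict) -> str:
    """Human-readable summary of a completed bundle."""
    if not bundle.get("complete"):
        raise DataError("cannot report on an incomplete bundle")
    lines = ["Venn partitions (A-only / common / B-only):"]
    for key, counts in bundle["stages"].get("venn", {}).items():
        vals = list(counts.values())
        lines.append(f"  {key:>10}: {vals[0]} / {vals[1]} / {vals[2]}")
    hs = bundle["stages"].get("hitscore", {})
    if hs.get("ranking"):
        lines.append("")
        lines.append(
            f"Hit tallies over top-{hs['top_n']} induced + top-{hs['top_n']} "
            "reduced genes:"
        )
        header = (
            f"  {'tumor_type':<15}{'strict':>8}{'tolerant':>10}  dominance"
        )
        lines.append(header)
        for row in hs["ranking"]:
            lines.append(
                f"  {row['tumor_type']:<15}{row['total_strict']:>8}"
                f"{row['total_tolerant']:>10}  {row['dominance']}"
            )
        lines.append(
            f"Genes with hit rate >= 50%: {len(hs['high_hit_rate_genes'])}"
        )
    sc = bundle["stages"].get("stage_concordance")
    if sc:
        lines.append("")
        lines.append("Stage concordance (concordant/evaluated):")
        for row in sc:
            lines.append(
                f"  {row['gene']:<12}{row['concordant']}/{row['evaluated']}"
            )
    sig = bundle["stages"].get("signature_compare")
    if sig:
        lines.append("")
        lines.append(f"Signature comparison vs {sig['contrast']}:")
        for cond, res in sig["contingency"].items():
            lines.append(
                f"  {cond}: counts={res['counts']} chi2={res['chi2']:.3f} "
                f"p={res['p']:.3g}"
            )
    return "\n".join(lines)
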