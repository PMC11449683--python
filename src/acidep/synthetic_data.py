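"""Synthetic inputs with known ground truth for the whole pipeline.

The expression simulator emulates a normalized two-color microarray
experiment: three pH conditions (control 7.4, mild acidosis 6.8, severe
acidosis 5.9) in quadruplicate, log2-scale intensities with a per-gene
baseline, and planted multiplicative effects assigned to six classes —
up/down at condition A only, at condition B only, or at both — so the
differential-expression and Venn stages have an exact expected answer. The
default planted counts follow the fourfold-threshold Venn structure of the
acidosis experiment this package models (up 25/85/131, down 63/118/82).

Annotation simulators plant a per-tumor concordance probability q: each
(gene, tumor) pair is annotated concordantly with the gene's acid role with
probability q, so downstream hit tallies are Binomial(n, q) and parameter
recovery can be checked against exact binomial intervals.

All randomness flows from one seed through numpy SeedSequence spawns, so
individual generators are reproducible and independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .expr_io import ExpressionMatrix
from .hitscore import (
    CONCORDANT_TREND,
    HIT_DIRECTION,
    INVERTED_DIRECTION,
    AnnEntry,
    PrognosticAnnotation,
    StageAnnotation,
)
from .signature_compare import ReferenceSignature

#: the eight-tumor panel the prognostic screen uses
DEFAULT_TUMOR_TYPES = (
    "breast",
    "colorectal",
    "prostate",
    "gastric",
    "liver",
    "lung",
    "head_and_neck",
    "melanoma",
)

PLANTED_CLASSES = (
    "up_a_only",
    "up_both",
    "up_b_only",
    "down_a_only",
    "down_both",
    "down_b_only",
)


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


@dataclass
class SimulationConfig:
    """Study design of the simulated expression experiment.

    ``planted`` maps each class in :data:`PLANTED_CLASSES` to a gene count;
    A is the first test condition (mild acidosis), B the second (severe).
    ``effect_log2`` is the planted effect size on log2 scale (2.0 = fourfold).
    """

    n_genes: int = 20000
    control: str = "pH7.4"
    tests: tuple[str, str] = ("pH6.8", "pH5.9")
    n_replicates: int = 4
    planted: dict[str, int] = field(
        default_factory=lambda: {
            "up_a_only": 25,
            "up_both": 85,
            "up_b_only": 131,
            "down_a_only": 63,
            "down_both": 118,
            "down_b_only": 82,
        }
    )
    effect_log2: float = 2.0
    noise_sd_log2: float = 0.25
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.planted) - set(PLANTED_CLASSES)
        if unknown:
            raise ConfigError(f"unknown planted classes: {sorted(unknown)}")
        if sum(self.planted.values()) > self.n_genes:
            raise ConfigError(
                f"planted counts ({sum(self.planted.values())}) exceed "
                f"n_genes ({self.n_genes})"
            )
        if self.n_genes < 1 or self.n_replicates < 1:
            raise ConfigError("n_genes and n_replicates must be positive")
        if self.noise_sd_log2 < 0 or self.baseline_log2_sd < 0:
            raise ConfigError("standard deviations must be >= 0")
        if not self.effect_log2 > 0:
            raise ConfigError("effect_log2 must be > 0")
        if len(self.tests) != 2:
            raise ConfigError("exactly two test conditions are required")


def simulate_expression(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate a log2-scale expression matrix plus its planted-truth table.

    Gene g's replicate value in condition c is
    ``baseline[g] + effect[g, c] + Normal(0, noise_sd_log2)`` where the
    effect is ``+effect_log2`` (up classes), ``-effect_log2`` (down classes)
    in the conditions the class covers, else 0. The truth table maps each
    gene to its planted class ("null" for background genes).
    """
    rng_assign, rng_base, rng_noise = _spawn(config.seed, 3)
    genes = np.array([f"G{i:05d}" for i in range(config.n_genes)])

    classes = np.full(config.n_genes, "null", dtype=object)
    order = rng_assign.permutation(config.n_genes)
    pos = 0
    for cls in PLANTED_CLASSES:
        count = config.planted.get(cls, 0)
        classes[order[pos : pos + count]] = cls
        pos += count

    cond_a, cond_b = config.tests
    effect = {config.control: np.zeros(config.n_genes)}
    for cond, tag in ((cond_a, "a"), (cond_b, "b")):
        eff = np.zeros(config.n_genes)
        for sign, prefix in ((1.0, "up"), (-1.0, "down")):
            for suffix in (f"{tag}_only", "both"):
                eff[classes == f"{prefix}_{suffix}"] = sign * config.effect_log2
        effect[cond] = eff

    baseline = rng_base.normal(
        config.baseline_log2_mean, config.baseline_log2_sd, config.n_genes
    )
    columns, data, meta_rows = [], [], []
    for cond in (config.control, *config.tests):
        for rep in range(1, config.n_replicates + 1):
            noise = (
                rng_noise.normal(0.0, config.noise_sd_log2, config.n_genes)
                if config.noise_sd_log2 > 0
                else np.zeros(config.n_genes)
            )
            data.append(baseline + effect[cond] + noise)
            sample_id = f"{cond}_r{rep}"
            columns.append(sample_id)
            meta_rows.append({"sample_id": sample_id, "condition": cond, "replicate": rep})

    values = pd.DataFrame(
        np.column_stack(data), index=pd.Index(genes, name="feature_id"), columns=columns
    )
    sample_meta = pd.DataFrame(meta_rows).set_index("sample_id")
    matrix = ExpressionMatrix(values=values, sample_meta=sample_meta, scale="log2")
    truth = pd.DataFrame(
        {"planted_class": classes}, index=pd.Index(genes, name="gene")
    )
    return matrix, truth


def simulate_reference_signature(
    truth: pd.DataFrame,
    overlap_with_planted: float = 1.0,
    universe_size: int | None = None,
    seed: int = 0,
    contrast_name: str = "synthetic contrast",
) -> ReferenceSignature:
    """A high/low signature whose "high" class overlaps the planted-up genes.

    Each planted-up gene is classified high with probability
    ``overlap_with_planted`` (low otherwise); all remaining universe genes
    are classified high or low at coin-flip rates, so
    ``overlap_with_planted=0.5`` is the chance (null-association) level.
    """
    if not 0.0 <= overlap_with_planted <= 1.0:
        raise ConfigError("overlap_with_planted must be in [0, 1]")
    genes = list(truth.index)
    if universe_size is None:
        universe_size = len(genes)
    if universe_size < len(genes):
        raise ConfigError(
            f"universe_size ({universe_size}) smaller than the truth table "
            f"({len(genes)} genes)"
        )
    if universe_size == 0:
        raise ConfigError("empty signature universe")
    rng = np.random.default_rng(seed)
    up_classes = {"up_a_only", "up_both", "up_b_only"}
    classes: dict[str, str] = {}
    for gene in genes:
        if truth.loc[gene, "planted_class"] in up_classes:
            high = rng.random() < overlap_with_planted
        else:
            high = rng.random() < 0.5
        classes[gene] = "high" if high else "low"
    extra = [f"U{i:05d}" for i in range(universe_size - len(genes))]
    for gene in extra:
        classes[gene] = "high" if rng.random() < 0.5 else "low"
    return ReferenceSignature(
        contrast_name=contrast_name,
        classes=classes,
        universe=frozenset(genes) | frozenset(extra),
    )


@dataclass
class AnnotationSimConfig:
    """Planted prognostic-annotation process for the eight-tumor panel.

    Per (gene, tumor): missing with probability ``missing_rate``; otherwise
    concordant (direction matches the gene's acid role, significant) with
    probability ``concordance_q[tumor]``; otherwise inverted (reversed
    direction, significant, magnitude drawn from ``magnitude_law``) with
    probability ``inversion_fraction``, else direction "none".
    """

    tumor_types: tuple[str, ...] = DEFAULT_TUMOR_TYPES
    concordance_q: dict[str, float] = field(default_factory=dict)
    inversion_fraction: float = 0.5
    magnitude_law: tuple[str, float, float] = ("uniform", 0.0, 0.4)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for tumor in self.tumor_types:
            self.concordance_q.setdefault(tumor, 0.5)
        probs = [*self.concordance_q.values(), self.inversion_fraction, self.missing_rate]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ConfigError("all probabilities must lie in [0, 1]")
        if self.magnitude_law[0] != "uniform":
            raise ConfigError(f"unknown magnitude law {self.magnitude_law[0]!r}")


def simulate_prognostic_annotations(
    induced: list[str],
    reduced: list[str],
    config: AnnotationSimConfig,
) -> PrognosticAnnotation:
    """Prognostic annotations with planted per-tumor concordance."""
    rng = np.random.default_rng(config.seed)
    _, lo, hi = config.magnitude_law
    entries: dict[tuple[str, str], AnnEntry] = {}
    for tumor in config.tumor_types:
        q = config.concordance_q[tumor]
        for role, genes in (("induced", induced), ("reduced", reduced)):
            for gene in genes:
                if rng.random() < config.missing_rate:
                    continue
                if rng.random() < q:
                    entries[(gene, tumor)] = AnnEntry(
                        direction=HIT_DIRECTION[role], significant=True
                    )
                elif rng.random() < config.inversion_fraction:
                    entries[(gene, tumor)] = AnnEntry(
                        direction=INVERTED_DIRECTION[role],
                        significant=True,
                        magnitude=float(rng.uniform(lo, hi)),
                    )
                else:
                    entries[(gene, tumor)] = AnnEntry(
                        direction="none", significant=False
                    )
    return PrognosticAnnotation(entries)


def simulate_stage_annotations(
    genes: list[str],
    tumor_types: list[str] | tuple[str, ...],
    concordance: float,
    seed: int = 0,
    role_by_gene: dict[str, str] | None = None,
) -> StageAnnotation:
    """Stage-trend annotations: concordant-significant with probability
    ``concordance`` per (gene, tumor), else trend "none". Genes default to
    the induced role unless ``role_by_gene`` says otherwise."""
    if not 0.0 <= concordance <= 1.0:
        raise ConfigError("concordance must be in [0, 1]")
    rng = np.random.default_rng(seed)
    entries: dict[tuple[str, str], tuple[str, bool]] = {}
    for gene in genes:
        role = (role_by_gene or {}).get(gene, "induced")
        for tumor in tumor_types:
            if rng.random() < concordance:
                entries[(gene, tumor)] = (CONCORDANT_TREND[role], True)
            else:
                entries[(gene, tumor)] = ("none", False)
    return StageAnnotation(entries)
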