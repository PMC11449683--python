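"""Comparison of acid-modulated gene sets with external reference signatures.

A reference signature is a per-gene high/low classification from a published
contrast (e.g. metastasized vs primary tumor cells). Two analyses are
supported: a 2x2 contingency of signature class against acid-modulated
direction, tested by Pearson's chi-squared (df = 1, continuity correction
off by default), and a Spearman rank-order concordance between the
signature's gene ordering and the acid-response log2 fold changes, with a
seeded permutation p-value.

Cross-species symbol mapping uses a user-supplied ortholog table; a
fallback heuristic uppercases mouse-style symbols (Mmp9 -> MMP9), which is
correct for most mouse/human symbol pairs but not all — hence table first.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import FoldChangeTable
from .errors import ConfigError, DataError, FormatError
from .expr_io import GeneSet

logger = logging.getLogger("acidep")


@dataclass
class ReferenceSignature:
    """Gene -> {high, low} classes for one external contrast."""

    contrast_name: str
    classes: dict[str, str]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        bad = {c for c in self.classes.values() if c not in ("high", "low")}
        if bad:
            raise FormatError(f"invalid signature classes: {sorted(bad)}")
        self.universe = frozenset(self.universe) | set(self.classes)

    @property
    def high(self) -> set[str]:
        return {g for g, c in self.classes.items() if c == "high"}

    @property
    def low(self) -> set[str]:
        return {g for g, c in self.classes.items() if c == "low"}


def read_signature(path: str | Path, sidecar: str | Path | None = None) -> ReferenceSignature:
    """Read a (gene, class) TSV; the optional JSON sidecar holds the contrast
    name and any unclassified universe members."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected columns gene, class")
    name, universe = Path(path).stem, frozenset(df[0])
    if sidecar is not None:
        info = json.loads(Path(sidecar).read_text())
        name = info.get("contrast_name", name)
        universe = universe | frozenset(info.get("universe_extra", []))
    return ReferenceSignature(
        contrast_name=name, classes=dict(zip(df[0], df[1])), universe=universe
    )


@dataclass
class OrthologMap:
    """Deterministic source -> target symbol map (one target per source)."""

    mapping: dict[str, str]


def map_orthologs(
    genes: set[str] | frozenset[str],
    ortholog_map: OrthologMap | None = None,
    fallback_uppercase: bool = True,
) -> tuple[set[str], list[str]]:
    """Map gene symbols across species; returns (mapped set, unmapped list).

    Symbols absent from the table fall back to uppercasing when enabled,
    otherwise they are reported unmapped (and logged, never silently lost).
    """
    table = ortholog_map.mapping if ortholog_map is not None else {}
    if not table and not fallback_uppercase:
        raise ConfigError("empty ortholog map with the uppercase fallback disabled")
    mapped, unmapped = set(), []
    for gene in sorted(genes):
        if gene in table:
            mapped.add(table[gene])
        elif fallback_uppercase:
            mapped.add(gene.upper())
        else:
            unmapped.append(gene)
    if unmapped:
        logger.info("map_orthologs: %d symbols unmapped", len(unmapped))
    return mapped, unmapped


@dataclass
class ContingencyResult:
    """2x2 counts (rows high/low, columns up/down) with the chi-squared test."""

    counts: np.ndarray
    chi2: float | None = None
    p: float | None = None
    df: int = 1
    degenerate: bool = False

    def as_dict(self) -> dict:
        return {
            "counts": self.counts.tolist(),
            "chi2": self.chi2,
            "p": self.p,
            "df": self.df,
            "degenerate": self.degenerate,
        }


def build_contingency(
    signature: ReferenceSignature, up: GeneSet | set, down: GeneSet | set
) -> ContingencyResult:
    """Count signature-classified genes inside the up and down sets.

    Rows are the signature classes (high, low); columns are the acid
    directions (up i.e. >= theta, down i.e. <= 1/theta). Genes in neither
    set, or unclassified by the signature, contribute nothing — matching a
    table whose columns are the two modulated classes only.
    """
    up_genes = up.genes if isinstance(up, GeneSet) else frozenset(up)
    down_genes = down.genes if isinstance(down, GeneSet) else frozenset(down)
    overlap = up_genes & down_genes
    if overlap:
        raise DataError(
            f"up and down sets overlap ({len(overlap)} genes, e.g. "
            f"{sorted(overlap)[0]!r})"
        )
    high, low = signature.high, signature.low
    counts = np.array(
        [
            [len(high & up_genes), len(high & down_genes)],
            [len(low & up_genes), len(low & down_genes)],
        ],
        dtype=int,
    )
    return ContingencyResult(counts=counts)


def chi_square_2x2(
    counts: np.ndarray | list, correction: bool = False
) -> tuple[float, float, bool]:
    """Pearson chi-squared on a 2x2 table; returns (chi2, p, degenerate).

    Continuity (Yates) correction is off by default. A zero row or column
    margin makes the statistic undefined: the degenerate flag is set and
    (0.0, 1.0) returned.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (2, 2):
        raise ConfigError(f"expected a 2x2 table, got shape {counts.shape}")
    if (counts < 0).any():
        raise DataError("negative cell counts")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        return 0.0, 1.0, True
    chi2, p, _, _ = stats.chi2_contingency(counts, correction=correction)
    return float(chi2), float(p), False


def chi_square_contingency(result: ContingencyResult, correction: bool = False) -> ContingencyResult:
    """Fill in chi2/p on a ContingencyResult in place and return it."""
    chi2, p, degenerate = chi_square_2x2(result.counts, correction=correction)
    result.chi2, result.p, result.degenerate = chi2, p, degenerate
    return result


def signature_rank_concordance(
    signature_ordering: list[str],
    table: FoldChangeTable,
    condition: str,
    n_permutations: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Spearman correlation between a reference gene ordering and the
    log2 fold-change ordering, with a permutation p-value.

    The reference rank of a gene is its position in ``signature_ordering``
    (descending reference expression); the test rank comes from the gene's
    log2fc under ``condition``. The permutation null shuffles the fold
    changes across the shared genes ``n_permutations`` times with a seeded
    generator; p is the two-sided tail fraction with the +1 correction.
    """
    table._check_condition(condition)
    shared = [g for g in signature_ordering if g in table.fc.index]
    if len(shared) < 3:
        raise DataError(
            f"only {len(shared)} genes shared between ordering and records (need >= 3)"
        )
    # position 0 = top of the descending reference ordering, so its score is
    # highest; an identical fc ordering then gives rho = +1
    ref_score = -np.arange(len(shared), dtype=float)
    lfc = table.log2fc.loc[shared, condition].to_numpy()
    rho = float(stats.spearmanr(ref_score, lfc).statistic)

    rng = np.random.default_rng(seed)
    ref_ranked = stats.rankdata(ref_score)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(lfc)
        r = np.corrcoef(ref_ranked, stats.rankdata(perm))[0, 1]
        if abs(r) >= abs(rho) - 1e-12:
            exceed += 1
    p_perm = (1 + exceed) / (n_permutations + 1)
    return rho, float(p_perm)
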