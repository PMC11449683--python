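"""Acidic-pH dependency scoring of tumor types against prognostic annotations.

A "hit" is an acid-induced gene annotated as an unfavorable (significant)
prognostic marker in a tumor type, or an acid-reduced gene annotated as
favorable — i.e. the acid response direction is concordant with shortened
respectively prolonged patient survival. Per tumor type the hits over the
top acid-induced and acid-reduced gene lists are tallied twice: strictly,
and tolerantly, where a gene whose prognostic direction is inverted but
whose effect magnitude lies within a tolerance (default 20%) also counts.
Tumors are then typed by which gene role dominates their hits.

The magnitude field is an effect distance from prognostic neutrality on a
[0, 1]-ish scale (e.g. |HR - 1| or a survival-difference fraction); its
exact semantics are supplied by the annotation source and the inversion
predicate can be swapped out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import pandas as pd

from .errors import ConfigError, DataError, FormatError

logger = logging.getLogger("acidep")

DIRECTIONS = ("unfavorable", "favorable", "none")
TRENDS = ("late_stage_high", "late_stage_low", "none")
ROLES = ("induced", "reduced")

#: prognostic direction that makes a gene role a strict hit
HIT_DIRECTION = {"induced": "unfavorable", "reduced": "favorable"}
#: the inverse direction, eligible for the inversion-tolerant tally
INVERTED_DIRECTION = {"induced": "favorable", "reduced": "unfavorable"}
#: stage trend concordant with each role
CONCORDANT_TREND = {"induced": "late_stage_high", "reduced": "late_stage_low"}


@dataclass(frozen=True)
class AnnEntry:
    """One (gene, tumor) prognostic annotation."""

    direction: str
    significant: bool
    magnitude: float | None = None

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise FormatError(f"invalid prognostic direction {self.direction!r}")
        if self.direction == "none" and self.significant:
            raise FormatError("direction 'none' cannot be significant")
        if self.magnitude is not None and self.magnitude < 0:
            raise FormatError("magnitude must be >= 0")


@dataclass
class PrognosticAnnotation:
    """(gene, tumor_type) -> prognostic direction/significance/magnitude."""

    entries: dict[tuple[str, str], AnnEntry] = field(default_factory=dict)

    def get(self, gene: str, tumor_type: str) -> AnnEntry | None:
        return self.entries.get((gene, tumor_type))

    @property
    def tumor_types(self) -> list[str]:
        return sorted({t for _, t in self.entries})

    @classmethod
    def from_table(cls, path: str | Path) -> "PrognosticAnnotation":
        df = pd.read_csv(path, sep="\t", dtype={"gene": str, "tumor_type": str})
        needed = {"gene", "tumor_type", "direction", "significant"}
        if not needed <= set(df.columns):
            raise FormatError(f"{path}: need columns {sorted(needed)}")
        entries: dict[tuple[str, str], AnnEntry] = {}
        for row in df.itertuples(index=False):
            key = (row.gene, row.tumor_type)
            if key in entries:
                raise FormatError(f"{path}: duplicate annotation for {key}")
            mag = getattr(row, "magnitude", None)
            mag = None if mag is None or pd.isna(mag) else float(mag)
            entries[key] = AnnEntry(
                direction=str(row.direction),
                significant=bool(row.significant),
                magnitude=mag,
            )
        return cls(entries)

    def to_table(self, path: str | Path) -> None:
        rows = [
            {
                "gene": g,
                "tumor_type": t,
                "direction": e.direction,
                "significant": e.significant,
                "magnitude": e.magnitude,
            }
            for (g, t), e in sorted(self.entries.items())
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class StageAnnotation:
    """(gene, tumor_type) -> pathological-stage expression trend."""

    entries: dict[tuple[str, str], tuple[str, bool]] = field(default_factory=dict)

    def get(self, gene: str, tumor_type: str) -> tuple[str, bool] | None:
        return self.entries.get((gene, tumor_type))

    @property
    def tumor_types(self) -> list[str]:
        return sorted({t for _, t in self.entries})

    @classmethod
    def from_table(cls, path: str | Path) -> "StageAnnotation":
        df = pd.read_csv(path, sep="\t", dtype={"gene": str, "tumor_type": str})
        needed = {"gene", "tumor_type", "trend", "significant"}
        if not needed <= set(df.columns):
            raise FormatError(f"{path}: need columns {sorted(needed)}")
        entries: dict[tuple[str, str], tuple[str, bool]] = {}
        for row in df.itertuples(index=False):
            key = (row.gene, row.tumor_type)
            if key in entries:
                raise FormatError(f"{path}: duplicate stage annotation for {key}")
            if row.trend not in TRENDS:
                raise FormatError(f"{path}: invalid trend {row.trend!r}")
            entries[key] = (str(row.trend), bool(row.significant))
        return cls(entries)

    def to_table(self, path: str | Path) -> None:
        rows = [
            {"gene": g, "tumor_type": t, "trend": tr, "significant": sig}
            for (g, t), (tr, sig) in sorted(self.entries.items())
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Hit predicates
# ---------------------------------------------------------------------------

def is_hit(gene_role: str, entry: AnnEntry | None) -> bool:
    """Strict hit: prognostic direction concordant with the acid response
    and flagged significant. A missing entry is never a hit."""
    if gene_role not in ROLES:
        raise ConfigError(f"gene_role must be one of {ROLES}, got {gene_role!r}")
    if entry is None:
        return False
    return entry.significant and entry.direction == HIT_DIRECTION[gene_role]


def is_inverted_hit(
    gene_role: str, entry: AnnEntry | None, tol: float = 0.20
) -> bool:
    """Inversion-tolerant hit: direction is the reverse of the hit direction,
    significant, and the effect magnitude is within ``tol`` of neutrality.

    A reversed entry with no magnitude cannot be judged and counts false
    (with a warning) rather than guessing.
    """
    if not 0.0 <= tol <= 1.0:
        raise ConfigError(f"tol must be in [0, 1], got {tol}")
    if entry is None:
        return False
    if not (entry.significant and entry.direction == INVERTED_DIRECTION[gene_role]):
        return False
    if entry.magnitude is None:
        logger.warning("inverted entry lacks a magnitude; counted as non-hit")
        return False
    return entry.magnitude <= tol


# ---------------------------------------------------------------------------
# Per-tumor scoring
# ---------------------------------------------------------------------------

@dataclass
class HitScoreResult:
    """Strict and inversion-tolerant hit tallies for one tumor type.

    ``gene_status`` records, per (role, gene), one of
    {"hit", "inverted", "miss", "missing"} for the hit-matrix report.
    """

    tumor_type: str
    hits_induced_strict: int
    hits_reduced_strict: int
    hits_induced_tolerant: int
    hits_reduced_tolerant: int
    n_induced: int
    n_reduced: int
    n_missing: int
    dominance: str
    gene_status: dict[tuple[str, str], str] = field(default_factory=dict, repr=False)

    @property
    def total_strict(self) -> int:
        return self.hits_induced_strict + self.hits_reduced_strict

    @property
    def total_tolerant(self) -> int:
        return self.hits_induced_tolerant + self.hits_reduced_tolerant

    def as_dict(self) -> dict:
        return {
            "tumor_type": self.tumor_type,
            "hits_induced_strict": self.hits_induced_strict,
            "hits_reduced_strict": self.hits_reduced_strict,
            "hits_induced_tolerant": self.hits_induced_tolerant,
            "hits_reduced_tolerant": self.hits_reduced_tolerant,
            "total_strict": self.total_strict,
            "total_tolerant": self.total_tolerant,
            "n_missing": self.n_missing,
            "dominance": self.dominance,
        }


def score_tumor(
    induced: list[str],
    reduced: list[str],
    annotation: PrognosticAnnotation,
    tumor_type: str,
    tol: float = 0.20,
    dominance_margin: int = 0,
    inversion_predicate: Callable[[str, AnnEntry | None, float], bool] = is_inverted_hit,
) -> HitScoreResult:
    """Tally strict and tolerant hits of the two gene lists for one tumor.

    Dominance is ``induced_type`` when strict induced hits exceed strict
    reduced hits by more than ``dominance_margin``, ``reduced_type`` in the
    mirror case, else ``balanced``.
    """
    tallies = {role: {"strict": 0, "tolerant": 0} for role in ROLES}
    gene_status: dict[tuple[str, str], str] = {}
    n_missing = 0
    for role, genes in (("induced", induced), ("reduced", reduced)):
        for gene in genes:
            entry = annotation.get(gene, tumor_type)
            if entry is None:
                n_missing += 1
                gene_status[(role, gene)] = "missing"
                continue
            if is_hit(role, entry):
                tallies[role]["strict"] += 1
                tallies[role]["tolerant"] += 1
                gene_status[(role, gene)] = "hit"
            elif inversion_predicate(role, entry, tol):
                tallies[role]["tolerant"] += 1
                gene_status[(role, gene)] = "inverted"
            else:
                gene_status[(role, gene)] = "miss"
    diff = tallies["induced"]["strict"] - tallies["reduced"]["strict"]
    if diff > dominance_margin:
        dominance = "induced_type"
    elif diff < -dominance_margin:
        dominance = "reduced_type"
    else:
        dominance = "balanced"
    return HitScoreResult(
        tumor_type=tumor_type,
        hits_induced_strict=tallies["induced"]["strict"],
        hits_reduced_strict=tallies["reduced"]["strict"],
        hits_induced_tolerant=tallies["induced"]["tolerant"],
        hits_reduced_tolerant=tallies["reduced"]["tolerant"],
        n_induced=len(induced),
        n_reduced=len(reduced),
        n_missing=n_missing,
        dominance=dominance,
        gene_status=gene_status,
    )


def rank_tumors(results: list[HitScoreResult]) -> pd.DataFrame:
    """Tumors sorted by strict hit total (descending), ties by tumor name."""
    if not results:
        raise DataError("rank_tumors needs at least one result")
    df = pd.DataFrame([r.as_dict() for r in results])
    df = df.sort_values(
        ["total_strict", "tumor_type"], ascending=[False, True]
    ).reset_index(drop=True)
    df.insert(0, "rank", range(1, len(df) + 1))
    return df


def hit_matrix(results: list[HitScoreResult]) -> pd.DataFrame:
    """Gene x tumor-type status matrix ({hit, inverted, miss, missing})."""
    rows: dict[tuple[str, str], dict[str, str]] = {}
    for res in results:
        for (role, gene), status in res.gene_status.items():
            rows.setdefault((role, gene), {})[res.tumor_type] = status
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index = pd.MultiIndex.from_tuples(df.index, names=["role", "gene"])
    return df.sort_index()


# ---------------------------------------------------------------------------
# Gene-level hit rates and stage concordance
# ---------------------------------------------------------------------------

def gene_hit_rate(gene: str, results: list[HitScoreResult]) -> float:
    """Fraction of tumor types in which ``gene`` scored a strict hit."""
    if not results:
        raise DataError("gene_hit_rate needs at least one tumor result")
    hits = 0
    for res in results:
        for (role, g), status in res.gene_status.items():
            if g == gene and status == "hit":
                hits += 1
                break
    return hits / len(results)


def filter_by_hit_rate(
    genes: list[str], results: list[HitScoreResult], min_rate: float = 0.5
) -> list[str]:
    """Genes whose hit rate across tumor types is >= ``min_rate``."""
    return [g for g in genes if gene_hit_rate(g, results) >= min_rate]


def stage_concordance(
    genes: list[str],
    stage_ann: StageAnnotation,
    role_by_gene: dict[str, str],
) -> pd.DataFrame:
    """Per-gene (k, n): concordant significant stage trends out of evaluated.

    For an acid-induced gene a concordant trend is significantly higher
    expression in late pathological stage; for a reduced gene, lower. Genes
    with no stage annotation in any tumor get (0, 0) with a warning.
    """
    tumors = stage_ann.tumor_types
    rows = []
    for gene in genes:
        role = role_by_gene.get(gene)
        if role not in ROLES:
            raise ConfigError(f"no role for gene {gene!r}")
        k = n = 0
        for tumor in tumors:
            entry = stage_ann.get(gene, tumor)
            if entry is None:
                continue
            n += 1
            trend, significant = entry
            if significant and trend == CONCORDANT_TREND[role]:
                k += 1
        if n == 0:
            logger.warning("gene %s absent from stage annotations", gene)
        rows.append({"gene": gene, "role": role, "concordant": k, "evaluated": n})
    return pd.DataFrame(rows).set_index("gene")
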