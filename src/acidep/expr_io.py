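"""I/O for expression matrices, gene sets, signatures and annotation tables.

The canonical on-disk matrix format is a TSV with features in rows and
samples in columns, accompanied by a sample-metadata TSV with columns
``sample_id``, ``condition``, ``replicate``. A GEO series-matrix dialect is
also accepted: the numeric table between ``!series_matrix_table_begin`` and
``!series_matrix_table_end`` is extracted and the preamble discarded, with
condition/replicate labels taken either from the sidecar metadata file or
from ``!Sample_characteristics_ch1`` preamble lines of the form
``condition: pH6.8`` / ``replicate: 2``.

Expression values may be linear intensities (non-negative) or already on
log2 scale; downstream fold-change code handles both via ``scale``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, FormatError

logger = logging.getLogger("acidep")

VALID_DIRECTIONS = ("up", "down")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Feature x sample expression values plus per-sample condition labels.

    Parameters
    ----------
    values
        DataFrame indexed by feature id (probe or gene symbol), one column
        per sample id.
    sample_meta
        DataFrame indexed by sample id with columns ``condition`` (str) and
        ``replicate`` (positive int).
    scale
        ``"linear"`` (non-negative intensities) or ``"log2"``.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    scale: str = "linear"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ConfigError(f"unknown scale {self.scale!r}")
        if not self.values.index.is_unique:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise FormatError(f"duplicate feature id {dup!r}")
        if list(self.values.columns) != list(self.sample_meta.index):
            missing = set(self.values.columns) ^ set(self.sample_meta.index)
            raise ConfigError(
                f"sample ids in matrix and metadata disagree: {sorted(missing)}"
            )
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise DataError("non-finite expression values")
        if self.scale == "linear" and (arr < 0).any():
            raise DataError("negative values in a linear-scale matrix")
        for col in ("condition", "replicate"):
            if col not in self.sample_meta.columns:
                raise ConfigError(f"sample metadata lacks column {col!r}")
        if (self.sample_meta["replicate"].astype(int) < 1).any():
            raise ConfigError("replicate indices must be positive")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.sample_meta["condition"]))

    def samples_for(self, condition: str) -> list[str]:
        mask = self.sample_meta["condition"] == condition
        if not mask.any():
            raise DataError(f"condition {condition!r} absent from matrix")
        return list(self.sample_meta.index[mask])

    def equals(self, other: "ExpressionMatrix") -> bool:
        return (
            self.scale == other.scale
            and self.values.equals(other.values)
            and self.sample_meta[["condition", "replicate"]].equals(
                other.sample_meta[["condition", "replicate"]]
            )
        )


@dataclass
class ProbeGeneMap:
    """Many-to-one probe id -> gene symbol mapping."""

    mapping: dict[str, str]

    @classmethod
    def from_table(cls, path: str | Path) -> "ProbeGeneMap":
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        if df.shape[1] < 2:
            raise FormatError(f"{path}: expected two tab-separated columns")
        if df[0].duplicated().any():
            dup = df[0][df[0].duplicated()].iloc[0]
            raise FormatError(f"probe id {dup!r} mapped more than once")
        return cls(dict(zip(df[0], df[1])))


@dataclass
class GeneSet:
    """A named, directional set of gene symbols selected at one threshold.

    ``direction`` is ``"up"`` or ``"down"``; ``threshold`` is the linear
    fold-change ratio (> 1) the set was selected at; ``condition`` names the
    contrast (e.g. ``"pH6.8"``).
    """

    name: str
    genes: frozenset[str]
    direction: str
    threshold: float
    condition: str

    def __post_init__(self) -> None:
        if self.direction not in VALID_DIRECTIONS:
            raise FormatError(f"invalid direction {self.direction!r}")
        if not self.threshold > 1:
            raise ConfigError(f"threshold must be > 1, got {self.threshold}")
        self.genes = frozenset(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


# ---------------------------------------------------------------------------
# Matrix reading / writing
# ---------------------------------------------------------------------------

def read_sample_meta(path: str | Path) -> pd.DataFrame:
    """Read the sidecar sample-metadata TSV (sample_id, condition, replicate)."""
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "condition": str})
    for col in ("sample_id", "condition", "replicate"):
        if col not in meta.columns:
            raise ConfigError(f"{path}: metadata lacks column {col!r}")
    return meta.set_index("sample_id")


def _extract_series_matrix_block(lines: list[str]) -> tuple[list[str], pd.DataFrame | None]:
    """Return the data-table lines of a GEO series-matrix file and, when the
    preamble carries them, a sample metadata frame."""
    begin = end = None
    sample_ids: list[str] | None = None
    characteristics: list[list[str]] = []
    for i, line in enumerate(lines):
        if line.startswith("!series_matrix_table_begin"):
            begin = i
        elif line.startswith("!series_matrix_table_end"):
            end = i
        elif line.startswith("!Sample_geo_accession"):
            sample_ids = [f.strip().strip('"') for f in line.rstrip("\n").split("\t")[1:]]
        elif line.startswith("!Sample_characteristics_ch1"):
            characteristics.append(
                [f.strip().strip('"') for f in line.rstrip("\n").split("\t")[1:]]
            )
    if begin is None or end is None or end <= begin:
        raise FormatError("series_matrix_table_begin/_end block not found")
    meta = None
    if sample_ids and characteristics:
        fields: dict[str, dict[str, str]] = {s: {} for s in sample_ids}
        for row in characteristics:
            for sid, cell in zip(sample_ids, row):
                if ":" in cell:
                    key, val = cell.split(":", 1)
                    fields[sid][key.strip()] = val.strip()
        if all("condition" in f and "replicate" in f for f in fields.values()):
            meta = pd.DataFrame(
                {
                    "condition": [fields[s]["condition"] for s in sample_ids],
                    "replicate": [int(fields[s]["replicate"]) for s in sample_ids],
                },
                index=pd.Index(sample_ids, name="sample_id"),
            )
    return lines[begin + 1 : end], meta


def read_expression_table(
    path: str | Path,
    meta: str | Path | pd.DataFrame | None = None,
    dialect: str = "tsv",
    scale: str = "linear",
) -> ExpressionMatrix:
    """Read an expression matrix from ``path``.

    ``meta`` is the sidecar metadata (path or frame); for the
    ``geo_series_matrix`` dialect it may be omitted when the preamble
    carries ``condition``/``replicate`` sample characteristics. Unparseable
    numeric cells raise :class:`FormatError` rather than becoming NA.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    if dialect == "tsv":
        table_lines = path.read_text().splitlines()
        embedded_meta = None
    elif dialect == "geo_series_matrix":
        table_lines, embedded_meta = _extract_series_matrix_block(
            path.read_text().splitlines()
        )
    else:
        raise ConfigError(f"unknown dialect {dialect!r}")

    header, *rows = [ln.rstrip("\n").split("\t") for ln in table_lines if ln.strip()]
    sample_ids = [h.strip().strip('"') for h in header[1:]]
    feature_ids, data = [], []
    for row in rows:
        feature_ids.append(row[0].strip().strip('"'))
        cells = row[1:]
        if len(cells) != len(sample_ids):
            raise FormatError(
                f"feature {feature_ids[-1]!r}: {len(cells)} values for "
                f"{len(sample_ids)} samples"
            )
        try:
            data.append([float(c) for c in cells])
        except ValueError as exc:
            raise FormatError(f"feature {feature_ids[-1]!r}: {exc}") from None
    index = pd.Index(feature_ids, name="feature_id")
    if index.duplicated().any():
        dup = index[index.duplicated()][0]
        raise FormatError(f"duplicate feature id {dup!r}")
    values = pd.DataFrame(data, index=index, columns=sample_ids, dtype=float)

    if isinstance(meta, pd.DataFrame):
        sample_meta = meta
    elif meta is not None:
        sample_meta = read_sample_meta(meta)
    elif embedded_meta is not None:
        sample_meta = embedded_meta
    else:
        raise ConfigError(
            "no sample metadata: pass meta= or embed condition/replicate "
            "characteristics in the series-matrix preamble"
        )
    sample_meta = sample_meta.loc[list(values.columns)]
    return ExpressionMatrix(values=values, sample_meta=sample_meta, scale=scale)


def write_expression_table(
    matrix: ExpressionMatrix, path: str | Path, meta_path: str | Path | None = None
) -> None:
    """Write the matrix TSV and (optionally) its metadata sidecar."""
    matrix.values.to_csv(path, sep="\t", index_label="feature_id")
    if meta_path is not None:
        matrix.sample_meta.to_csv(meta_path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# Probe -> gene collapse
# ---------------------------------------------------------------------------

def collapse_probes(
    matrix: ExpressionMatrix,
    probe_map: ProbeGeneMap,
    method: str = "median",
) -> tuple[ExpressionMatrix, dict]:
    """Collapse probe-level rows to one row per gene symbol.

    ``method="median"`` takes the per-sample median over a gene's probes;
    ``method="max_abs_change"`` keeps, per gene, the probe whose expression
    range across samples is largest (a proxy for the most responsive probe).
    Unmapped probes are dropped and counted in the returned report.
    """
    if method not in ("median", "max_abs_change"):
        raise ConfigError(f"unknown collapse method {method!r}")
    mapped = [p for p in matrix.feature_ids if p in probe_map.mapping]
    unmapped = [p for p in matrix.feature_ids if p not in probe_map.mapping]
    if not mapped:
        raise DataError("probe map covers none of the matrix features")
    if unmapped:
        logger.info("collapse_probes: dropping %d unmapped probes", len(unmapped))
    sub = matrix.values.loc[mapped]
    genes = pd.Series([probe_map.mapping[p] for p in mapped], index=sub.index)
    if method == "median":
        collapsed = sub.groupby(genes).median()
    else:
        span = sub.max(axis=1) - sub.min(axis=1)
        pick = span.groupby(genes).idxmax()
        collapsed = sub.loc[pick]
        collapsed.index = pick.index
    collapsed = collapsed.sort_index()
    collapsed.index.name = "feature_id"
    report = {
        "n_probes_in": len(matrix.feature_ids),
        "n_probes_mapped": len(mapped),
        "n_probes_unmapped": len(unmapped),
        "n_genes_out": collapsed.shape[0],
        "method": method,
    }
    out = ExpressionMatrix(
        values=collapsed, sample_meta=matrix.sample_meta, scale=matrix.scale
    )
    return out, report


# ---------------------------------------------------------------------------
# Gene-set files: JSON header line + one gene per line
# ---------------------------------------------------------------------------

def write_gene_set(gene_set: GeneSet, path: str | Path) -> None:
    header = {
        "name": gene_set.name,
        "direction": gene_set.direction,
        "threshold": gene_set.threshold,
        "condition": gene_set.condition,
    }
    with open(path, "w") as fh:
        fh.write("#" + json.dumps(header, sort_keys=True) + "\n")
        for gene in sorted(gene_set.genes):
            fh.write(gene + "\n")


def read_gene_set(path: str | Path) -> GeneSet:
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("#"):
        raise FormatError(f"{path}: missing JSON header line")
    try:
        header = json.loads(lines[0][1:])
        name, direction = header["name"], header["direction"]
        threshold, condition = header["threshold"], header["condition"]
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise FormatError(f"{path}: malformed header ({exc})") from None
    genes = frozenset(ln.strip() for ln in lines[1:] if ln.strip())
    return GeneSet(
        name=name, genes=genes, direction=direction,
        threshold=threshold, condition=condition,
    )


# ---------------------------------------------------------------------------
# Annotation / signature tables (TSV)
# ---------------------------------------------------------------------------

def read_two_column_map(path: str | Path) -> dict[str, str]:
    """Generic two-column TSV -> dict (e.g. ortholog tables)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected two tab-separated columns")
    return dict(zip(df[0], df[1]))
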