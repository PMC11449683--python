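"""Per-gene fold changes, t-tests, thresholded gene sets and Venn partitions.

The fold change of a test condition against the control is the ratio of the
replicate-group means. Because two-color array intensities are ratio data,
the default mean is geometric (arithmetic mean on log2 scale, then
back-transformed); an arithmetic-mean variant is available for sensitivity
analysis. Linear intensities are floored at a small epsilon before the log
transform so the control mean can never be zero.

Selection follows "theta-fold or more": up-sets take fc >= theta, down-sets
take fc <= 1/theta, boundary values included.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError
from .expr_io import ExpressionMatrix, GeneSet

#: cap applied to -log10(p) when p underflows to zero in volcano tables
NEG_LOG10_P_CAP = 300.0


@dataclass
class FoldChangeTable:
    """Per-gene fold change and test p-value for each test condition.

    All frames are indexed by gene with one column per test condition:
    ``fc`` linear ratios (> 0), ``log2fc = log2(fc)``, ``p`` two-sided
    p-values, ``degenerate`` flags for zero-variance tests.
    """

    fc: pd.DataFrame
    log2fc: pd.DataFrame
    p: pd.DataFrame
    control: str
    degenerate: pd.DataFrame | None = None
    p_bonferroni: pd.DataFrame | None = None

    @property
    def genes(self) -> list[str]:
        return list(self.fc.index)

    @property
    def conditions(self) -> list[str]:
        return list(self.fc.columns)

    def _check_condition(self, condition: str) -> None:
        if condition not in self.fc.columns:
            raise DataError(f"condition {condition!r} not in fold-change table")


def _to_log2(matrix: ExpressionMatrix, floor: float) -> tuple[pd.DataFrame, int]:
    """Return log2-scale values; linear inputs are floored then transformed."""
    if matrix.scale == "log2":
        return matrix.values, 0
    vals = matrix.values
    n_floored = int((vals.to_numpy() < floor).sum())
    return np.log2(vals.clip(lower=floor)), n_floored


def compute_fold_changes(
    matrix: ExpressionMatrix,
    control: str,
    tests: list[str],
    mean: str = "geometric",
    floor: float = 1.0,
    with_pvalues: bool = True,
    bonferroni: bool = False,
) -> FoldChangeTable:
    """Fold changes (and optionally t-test p-values) for each test vs control.

    With ``mean="geometric"`` (default) group means are taken on log2 scale;
    ``mean="arithmetic"`` averages linear intensities directly (log2 values
    are back-transformed first).
    """
    if mean not in ("geometric", "arithmetic"):
        raise ConfigError(f"unknown mean rule {mean!r}")
    ctrl_samples = matrix.samples_for(control)
    log2vals, _ = _to_log2(matrix, floor)

    fc_cols, p_cols, deg_cols = {}, {}, {}
    for cond in tests:
        test_samples = matrix.samples_for(cond)
        if mean == "geometric":
            delta = (
                log2vals[test_samples].mean(axis=1)
                - log2vals[ctrl_samples].mean(axis=1)
            )
            fc = np.power(2.0, delta)
        else:
            linear = np.power(2.0, log2vals)
            fc = linear[test_samples].mean(axis=1) / linear[ctrl_samples].mean(axis=1)
        fc_cols[cond] = fc
        if with_pvalues:
            p, deg = _group_ttest(
                log2vals[ctrl_samples].to_numpy(), log2vals[test_samples].to_numpy()
            )
            p_cols[cond] = pd.Series(p, index=log2vals.index)
            deg_cols[cond] = pd.Series(deg, index=log2vals.index)

    fc_frame = pd.DataFrame(fc_cols)
    p_frame = pd.DataFrame(p_cols) if with_pvalues else pd.DataFrame(
        np.nan, index=fc_frame.index, columns=tests
    )
    table = FoldChangeTable(
        fc=fc_frame,
        log2fc=np.log2(fc_frame),
        p=p_frame,
        control=control,
        degenerate=pd.DataFrame(deg_cols) if with_pvalues else None,
    )
    if bonferroni and with_pvalues:
        table.p_bonferroni = (p_frame * len(fc_frame)).clip(upper=1.0)
    return table


def _group_ttest(
    ctrl: np.ndarray, test: np.ndarray, welch: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised two-sided t-test per row; returns (p, degenerate_flag).

    Degenerate rows (pooled variance zero) get p = 1 when the group means
    are equal, p = 0 otherwise.
    """
    if ctrl.shape[1] < 2 or test.shape[1] < 2:
        raise DataError("per-gene test needs >= 2 replicates per group")
    with warnings.catch_warnings():
        # zero-variance rows are overwritten with degenerate p below
        warnings.filterwarnings(
            "ignore", message="Precision loss occurred", category=RuntimeWarning
        )
        res = stats.ttest_ind(test, ctrl, axis=1, equal_var=not welch)
    p = np.asarray(res.pvalue, dtype=float)
    var0 = (ctrl.var(axis=1) == 0) & (test.var(axis=1) == 0)
    equal_means = np.isclose(ctrl.mean(axis=1), test.mean(axis=1))
    degenerate = var0
    p = np.where(var0 & equal_means, 1.0, p)
    p = np.where(var0 & ~equal_means, 0.0, p)
    return p, degenerate


def per_gene_test(
    matrix: ExpressionMatrix,
    control: str,
    test: str,
    welch: bool = False,
    floor: float = 1.0,
    bonferroni: bool = False,
) -> pd.Series:
    """Two-sided Student's t-test (pooled variance; Welch optional) per gene.

    Values are log2-transformed first when the matrix is linear. Returns a
    Series of p-values indexed by gene; with ``bonferroni`` the p-values are
    multiplied by the number of genes tested (capped at 1).
    """
    log2vals, _ = _to_log2(matrix, floor)
    ctrl = log2vals[matrix.samples_for(control)].to_numpy()
    tst = log2vals[matrix.samples_for(test)].to_numpy()
    p, _ = _group_ttest(ctrl, tst, welch=welch)
    out = pd.Series(p, index=log2vals.index, name="p")
    if bonferroni:
        out = (out * len(out)).clip(upper=1.0)
    return out


#: absolute tolerance on log2 scale for the selection boundary, so a gene at
#: exactly theta-fold is included despite float round-off in the group means
LOG2_BOUNDARY_TOL = 1e-9


def select_modulated(
    table: FoldChangeTable, condition: str, threshold: float, direction: str
) -> GeneSet:
    """Genes with fc >= threshold (up) or fc <= 1/threshold (down).

    The comparison runs on log2 scale with a 1e-9 boundary tolerance so the
    inclusive boundary survives floating-point round-off.
    """
    if not threshold > 1:
        raise ConfigError(f"threshold must be > 1, got {threshold}")
    if direction not in ("up", "down"):
        raise ConfigError(f"direction must be 'up' or 'down', got {direction!r}")
    table._check_condition(condition)
    lfc = table.log2fc[condition]
    cut = np.log2(threshold)
    if direction == "up":
        genes = lfc.index[lfc >= cut - LOG2_BOUNDARY_TOL]
    else:
        genes = lfc.index[lfc <= -cut + LOG2_BOUNDARY_TOL]
    return GeneSet(
        name=f"{direction}_{threshold:g}x_{condition}",
        genes=frozenset(genes),
        direction=direction,
        threshold=float(threshold),
        condition=condition,
    )


@dataclass
class VennPartition:
    """Two-set Venn decomposition into A-only, common and B-only gene sets."""

    a_only: GeneSet
    common: GeneSet
    b_only: GeneSet
    threshold: float
    direction: str

    @property
    def counts(self) -> tuple[int, int, int]:
        return len(self.a_only), len(self.common), len(self.b_only)


def venn_partition(set_a: GeneSet, set_b: GeneSet) -> VennPartition:
    """Exact set algebra on two same-direction, same-threshold gene sets."""
    if set_a.direction != set_b.direction:
        raise DataError(
            f"direction mismatch: {set_a.direction!r} vs {set_b.direction!r}"
        )
    if set_a.threshold != set_b.threshold:
        raise DataError(
            f"threshold mismatch: {set_a.threshold} vs {set_b.threshold}"
        )
    a, b = set_a.genes, set_b.genes

    def _part(genes: frozenset[str], tag: str, condition: str) -> GeneSet:
        return GeneSet(
            name=f"{set_a.direction}_{set_a.threshold:g}x_{tag}",
            genes=genes,
            direction=set_a.direction,
            threshold=set_a.threshold,
            condition=condition,
        )

    return VennPartition(
        a_only=_part(a - b, f"{set_a.condition}_only", set_a.condition),
        common=_part(a & b, "common", f"{set_a.condition}+{set_b.condition}"),
        b_only=_part(b - a, f"{set_b.condition}_only", set_b.condition),
        threshold=set_a.threshold,
        direction=set_a.direction,
    )


def top_n_by_fold_change(
    table: FoldChangeTable, condition: str, n: int, direction: str
) -> list[str]:
    """Top-n genes for a condition ranked by |log2fc| within a direction.

    Ties break by smaller p-value, then lexicographic gene symbol, so the
    ordering is deterministic. Returns min(n, available) genes.
    """
    if n < 1:
        raise ConfigError(f"n must be >= 1, got {n}")
    table._check_condition(condition)
    lfc = table.log2fc[condition]
    if direction == "up":
        eligible = lfc[lfc > 0]
    elif direction == "down":
        eligible = lfc[lfc < 0]
    else:
        raise ConfigError(f"direction must be 'up' or 'down', got {direction!r}")
    df = pd.DataFrame(
        {
            "gene": eligible.index,
            "abs_lfc": eligible.abs().to_numpy(),
            "p": table.p[condition].reindex(eligible.index).fillna(1.0).to_numpy(),
        }
    )
    df = df.sort_values(["abs_lfc", "p", "gene"], ascending=[False, True, True])
    return list(df["gene"][:n])


def volcano_table(table: FoldChangeTable, condition: str) -> pd.DataFrame:
    """Per-gene (log2fc, -log10 p) table for volcano plotting.

    p-values of exactly zero (degenerate tests) map to the documented cap
    ``NEG_LOG10_P_CAP``.
    """
    table._check_condition(condition)
    p = table.p[condition]
    with np.errstate(divide="ignore"):
        neg_log10 = -np.log10(p)
    neg_log10 = neg_log10.clip(upper=NEG_LOG10_P_CAP)
    return pd.DataFrame(
        {"log2fc": table.log2fc[condition], "neg_log10_p": neg_log10}
    )
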