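"""Per-sample cell-population abundance estimators.

Three in-repo estimators stand in for published deconvolution tools:
a marker-mean score, a single-sample rank-enrichment score (the engine
also used for stromal/immune scores), and a constrained least-squares
deconvolution against a reference profile matrix. Exact numeric parity
with any published tool is not claimed; what matters downstream is that
each estimator tracks the underlying fibroblast fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .data import ExpressionMatrix, GeneSet, log_transform

logger = logging.getLogger(__name__)


@dataclass
class AbundanceTable:
    """Named population scores per sample, with a method tag per feature.

    ``table`` is features x samples; ``methods`` maps feature name to the
    estimator that produced it (``marker_mean``, ``ssgsea``, ``nnls``,
    ``external``).
    """

    table: pd.DataFrame
    methods: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.table.to_numpy(dtype=float)).all():
            raise ValueError("abundance table contains non-finite values")
        for feature in self.table.index:
            self.methods.setdefault(feature, "unknown")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.columns)

    def add(self, name: str, scores: pd.Series, method: str) -> None:
        if not self.table.empty and list(scores.index) != list(self.table.columns):
            scores = scores.reindex(self.table.columns)
        self.table.loc[name] = scores
        self.methods[name] = method


@dataclass
class DeconvolutionReference:
    """Non-negative reference expression profiles, genes x cell types."""

    profiles: pd.DataFrame

    def __post_init__(self) -> None:
        if self.profiles.shape[1] < 2:
            raise ValueError("reference needs at least 2 cell types")
        values = self.profiles.to_numpy(dtype=float)
        if (values < 0).any():
            raise ValueError("reference profiles must be non-negative")
        if (values.sum(axis=0) == 0).any():
            raise ValueError("reference contains an all-zero cell-type column")

    @property
    def cell_types(self) -> list[str]:
        return list(self.profiles.columns)


def marker_mean_score(m: ExpressionMatrix, markers: GeneSet) -> pd.Series:
    """Mean log2 expression of the present marker genes, per sample.

    A linear-scale matrix is log2(x+1)-transformed first (with a warning)
    so the mean is not dominated by a single highly expressed marker.
    """
    if m.scale == "linear":
        logger.warning("marker_mean_score: log2(x+1)-transforming linear input")
        m = log_transform(m, 1.0)
    present = [g for g in markers.genes if g in m.data.index]
    if not present:
        raise ValueError(f"no marker of set {markers.name!r} present in the matrix")
    if len(present) < len(markers.genes):
        logger.info(
            "marker_mean_score: %d/%d markers present", len(present), len(markers.genes)
        )
    scores = m.data.loc[present].mean(axis=0)
    scores.name = f"{markers.name}_marker_mean"
    return scores


def _rank_order(values: np.ndarray, gene_ids: np.ndarray) -> np.ndarray:
    """Positions sorting genes by descending value, ties by gene id.

    The lexicographic tie-break keeps every ranking deterministic;
    published enrichment tools differ in how they break ties.
    """
    return np.lexsort((gene_ids, -values))


def ssgsea_score(
    m: ExpressionMatrix,
    s: GeneSet,
    alpha: float = 0.25,
    mode: str = "sum",
) -> pd.Series:
    """Single-sample rank-enrichment score of a gene set, per sample.

    Genes are ranked by expression (descending); the in-set running
    weight at a position is the rank-normalized value (N for the top
    gene, 1 for the bottom) raised to ``alpha``, normalized by the total
    in-set weight; the out-of-set step is 1/(N - |S|). With
    ``mode='sum'`` the score is the sum over all positions of the
    difference between the in-set and out-of-set ECDFs (the ssGSEA
    convention); ``mode='max_dev'`` returns the signed extremum of the
    running difference (the classic enrichment-score statistic).

    With ``alpha=0`` the score depends on ranks only and is invariant
    under any strictly monotone transform of a sample's expression.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if mode not in ("sum", "max_dev"):
        raise ValueError("mode must be 'sum' or 'max_dev'")
    gene_ids = np.asarray(m.gene_ids)
    inset = np.isin(gene_ids, list(s.genes))
    n_in = int(inset.sum())
    n = len(gene_ids)
    if n_in < 2:
        raise ValueError(f"fewer than 2 genes of set {s.name!r} present in the matrix")
    if n - n_in < 1:
        raise ValueError(f"set {s.name!r} covers the whole matrix; no out-of-set gene")

    values = m.values()
    rank_weight = (np.arange(n, 0, -1, dtype=float)) ** alpha  # N..1 by position
    miss_step = 1.0 / (n - n_in)
    out = np.empty(m.n_samples)
    for j in range(m.n_samples):
        order = _rank_order(values[:, j], gene_ids)
        hits = inset[order]
        w = np.where(hits, rank_weight, 0.0)
        ecdf_in = np.cumsum(w) / w.sum()
        ecdf_out = np.cumsum(np.where(hits, 0.0, miss_step))
        diff = ecdf_in - ecdf_out
        if mode == "sum":
            out[j] = diff.sum()
        else:
            out[j] = diff[int(np.argmax(np.abs(diff)))]
    return pd.Series(out, index=m.sample_ids, name=f"{s.name}_{mode}")


def estimate_like_scores(
    m: ExpressionMatrix, stromal_set: GeneSet, immune_set: GeneSet
) -> tuple[pd.Series, pd.Series]:
    """Stromal and immune single-sample enrichment scores.

    Both use the rank-enrichment engine with exponent 0.25 and the
    summed-ECDF-difference statistic, mirroring how stromal/immune
    content is usually scored from bulk expression.
    """
    stromal = ssgsea_score(m, stromal_set, alpha=0.25, mode="sum")
    immune = ssgsea_score(m, immune_set, alpha=0.25, mode="sum")
    stromal.name = "stromal_score"
    immune.name = "immune_score"
    return stromal, immune


@dataclass
class DeconvolutionResult:
    raw: pd.DataFrame        # cell types x samples, non-negative coefficients
    fractions: pd.DataFrame  # raw normalized to sum 1 per sample


def nnls_deconvolution(m: ExpressionMatrix, ref: DeconvolutionReference) -> DeconvolutionResult:
    """Non-negative least-squares mixture fractions per sample.

    Solves min ||R f - x||^2 subject to f >= 0 over the genes shared
    between the matrix and the reference, per sample, then normalizes
    the coefficients to fractions.
    """
    if m.scale != "linear":
        raise ValueError("deconvolution expects a linear-scale matrix")
    shared = [g for g in ref.profiles.index if g in set(m.data.index)]
    k = len(ref.cell_types)
    if len(shared) < k:
        raise ValueError(
            f"only {len(shared)} shared genes for {k} cell types; deconvolution is underdetermined"
        )
    R = ref.profiles.loc[shared].to_numpy(dtype=float)
    if np.linalg.matrix_rank(R) < k:
        raise ValueError("reference profile matrix is rank-deficient over shared genes")
    X = m.data.loc[shared].to_numpy(dtype=float)
    raw = np.empty((k, m.n_samples))
    for j in range(m.n_samples):
        x = X[:, j]
        if not x.any():
            raise ValueError(f"sample {m.sample_ids[j]!r} is all-zero over shared genes")
        raw[:, j], _ = nnls(R, x)
    totals = raw.sum(axis=0)
    if (totals == 0).any():
        bad = [s for s, t in zip(m.sample_ids, totals) if t == 0]
        raise ValueError(f"all-zero NNLS solution for sample(s) {bad}")
    raw_df = pd.DataFrame(raw, index=ref.cell_types, columns=m.sample_ids)
    return DeconvolutionResult(raw=raw_df, fractions=raw_df / totals)


def import_external_abundance(
    path: Union[str, Path], expression: Optional[ExpressionMatrix] = None
) -> AbundanceTable:
    """Load an externally computed abundance table (CSV, sample_id column).

    Rows are samples, columns are populations; the result is transposed
    to the features x samples layout used internally and tagged
    ``external``. A sample mismatch against ``expression`` is a warning
    listing the difference, not an error.
    """
    tab = pd.read_csv(path, index_col="sample_id")
    if tab.empty:
        raise ValueError(f"external abundance table {path} has no data rows")
    if tab.index.has_duplicates:
        raise ValueError(f"duplicate sample ids in {path}")
    if expression is not None:
        missing = sorted(set(expression.sample_ids) - set(tab.index))
        extra = sorted(set(tab.index) - set(expression.sample_ids))
        if missing or extra:
            logger.warning(
                "external abundance sample mismatch: %d missing (%s...), %d extra (%s...)",
                len(missing), missing[:3], len(extra), extra[:3],
            )
    table = tab.T
    return AbundanceTable(table=table, methods={f: "external" for f in table.index})
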