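"""High/low fibroblast-infiltration grouping.

Samples are partitioned by Ward hierarchical clustering of a composite
matrix built from z-scored CAF marker expression plus z-scored
fibroblast-abundance estimates, cut at k = 2; the cluster with the
greater mean composite value is the "high infiltration" group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .data import ExpressionMatrix, GeneSet, log_transform, zscore_genes
from .abundance import AbundanceTable

logger = logging.getLogger(__name__)


@dataclass
class InfiltrationLabeling:
    """Per-sample high/low assignment plus the matrix it was derived from."""

    labels: pd.Series          # sample -> "high" | "low"
    composite: pd.DataFrame    # z-scored rows used for clustering
    method: str = "ward"
    metric: str = "euclidean"
    k: int = 2

    def __post_init__(self) -> None:
        bad = set(self.labels.unique()) - {"high", "low"}
        if bad:
            raise ValueError(f"labels outside {{high, low}}: {bad}")

    def group(self, name: str) -> list[str]:
        return list(self.labels.index[self.labels == name])

    @property
    def n_high(self) -> int:
        return int((self.labels == "high").sum())

    @property
    def n_low(self) -> int:
        return int((self.labels == "low").sum())


def _zscore_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    sd = df.std(axis=1, ddof=1)
    keep = sd > 0
    dropped = list(df.index[~keep])
    z = df.loc[keep].sub(df.loc[keep].mean(axis=1), axis=0).div(sd[keep], axis=0)
    return z, dropped


def build_caf_composite(
    m: ExpressionMatrix,
    markers: GeneSet,
    abundance: AbundanceTable,
    fibro_features: list[str] | None = None,
) -> pd.DataFrame:
    """Stack z-scored marker rows and z-scored fibroblast-abundance rows.

    ``fibro_features`` selects which abundance rows to include; by
    default every feature whose name contains "fibro" (case-insensitive)
    is used. Constant rows are dropped with a warning.
    """
    if m.n_samples < 2:
        raise ValueError("composite needs at least 2 samples (z-score undefined)")
    if m.scale == "linear":
        logger.warning("build_caf_composite: log2(x+1)-transforming linear input")
        m = log_transform(m, 1.0)
    present = [g for g in markers.genes if g in m.data.index]
    if fibro_features is None:
        fibro_features = [f for f in abundance.table.index if "fibro" in f.lower()]
    missing_feats = [f for f in fibro_features if f not in abundance.table.index]
    if missing_feats:
        raise KeyError(f"abundance features not found: {missing_feats}")
    if not present and not fibro_features:
        raise ValueError("no usable marker rows or abundance features for the composite")

    blocks = []
    if present:
        zm, dropped = _zscore_rows(m.data.loc[present])
        if dropped:
            logger.warning("build_caf_composite: constant marker row(s) dropped: %s", dropped)
        blocks.append(zm)
    if fibro_features:
        za, dropped = _zscore_rows(
            abundance.table.loc[fibro_features].reindex(columns=m.sample_ids)
        )
        if dropped:
            logger.warning("build_caf_composite: constant abundance row(s) dropped: %s", dropped)
        blocks.append(za)
    composite = pd.concat(blocks, axis=0)
    if composite.empty:
        raise ValueError("composite has zero usable rows after dropping constant rows")
    return composite


def cluster_infiltration(
    composite: pd.DataFrame, method: str = "ward", k: int = 2
) -> InfiltrationLabeling:
    """Ward-cluster samples on the composite and label high/low.

    Euclidean distance, Ward linkage, cut at ``k`` clusters (k = 2 by
    design; the pipeline defines exactly two infiltration strata). The
    cluster whose column-mean composite is greater is labeled "high".
    """
    n = composite.shape[1]
    if n < 2:
        raise ValueError("clustering needs at least 2 samples")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of samples ({n})")
    X = composite.T.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("composite contains non-finite values")
    Z = linkage(X, method=method, metric="euclidean")
    assign = fcluster(Z, t=k, criterion="maxclust")
    if len(np.unique(assign)) < 2:
        logger.warning("cluster_infiltration: degenerate composite; deterministic half split")
        assign = np.array([1] * (n // 2) + [2] * (n - n // 2))
    col_mean = X.mean(axis=1)
    means = {c: col_mean[assign == c].mean() for c in np.unique(assign)}
    high_cluster = max(means, key=lambda c: (means[c], -c))
    if len(set(means.values())) < len(means):
        logger.warning("cluster_infiltration: tied cluster means; lower cluster id wins")
    labels = pd.Series(
        np.where(assign == high_cluster, "high", "low"),
        index=composite.columns,
        name="infiltration_group",
    )
    return InfiltrationLabeling(labels=labels, composite=composite, method=method, k=k)
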