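"""Core containers for bulk expression analysis.

The pipeline passes three kinds of objects around: a gene-by-sample
expression matrix with a declared measurement scale, named gene sets
(optionally weighted), and per-sample annotation tables. All downstream
scoring operates on these containers; validation happens at construction
so later stages can assume clean input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Declared measurement scales. ``linear`` means FPKM/RPKM/TPM-like
#: non-negative values, ``log2p1`` means log2(x + 1)-transformed values,
#: ``zscore`` marks per-gene standardized values (internal use).
VALID_SCALES = ("linear", "log2p1", "zscore")


@dataclass
class ExpressionMatrix:
    """A gene x sample expression matrix with a declared scale.

    Parameters
    ----------
    data
        DataFrame with gene symbols as the index and sample identifiers
        as columns. Both must be unique; all values must be finite.
    scale
        One of :data:`VALID_SCALES`. The scale is declared by the caller,
        never sniffed from the values: FPKM-vs-log ambiguity in public
        repositories cannot be resolved automatically.
    """

    data: pd.DataFrame
    scale: str = "linear"

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            raise TypeError("data must be a pandas DataFrame")
        if self.scale not in VALID_SCALES:
            raise ValueError(f"scale must be one of {VALID_SCALES}, got {self.scale!r}")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dup[:5]}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dup[:5]}")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite value at gene {self.data.index[bad[0]]!r}, "
                f"sample {self.data.columns[bad[1]]!r}"
            )
        if self.scale == "linear" and (values < 0).any():
            bad = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative value at gene {self.data.index[bad[0]]!r}, "
                f"sample {self.data.columns[bad[1]]!r} but scale is 'linear'"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


@dataclass
class GeneSet:
    """A named, ordered collection of gene symbols, optionally weighted."""

    name: str
    genes: tuple[str, ...]
    weights: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.genes = tuple(self.genes)
        if len(self.genes) < 1:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} contains duplicate genes")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (len(self.genes),):
                raise ValueError(
                    f"gene set {self.name!r}: {len(self.weights)} weights "
                    f"for {len(self.genes)} genes"
                )
            if not np.isfinite(self.weights).all():
                raise ValueError(f"gene set {self.name!r} has non-finite weights")

    def __len__(self) -> int:
        return len(self.genes)

    def weight_of(self, gene: str) -> float:
        if self.weights is None:
            raise ValueError(f"gene set {self.name!r} is unweighted")
        return float(self.weights[self.genes.index(gene)])


@dataclass
class SignatureLibrary:
    """A collection of uniquely named gene sets (e.g. a hallmark library)."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sets:
            raise ValueError("signature library is empty")
        for name, gs in self.sets.items():
            if name != gs.name:
                raise ValueError(f"key {name!r} does not match set name {gs.name!r}")

    @classmethod
    def from_sets(cls, sets: Sequence[GeneSet]) -> "SignatureLibrary":
        out: dict[str, GeneSet] = {}
        for gs in sets:
            if gs.name in out:
                raise ValueError(f"duplicate gene-set name {gs.name!r}")
            out[gs.name] = gs
        return cls(out)

    def __iter__(self):
        return iter(self.sets.values())

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class SampleAnnotations:
    """Per-sample clinical fields and derived labels, keyed by sample id."""

    table: pd.DataFrame

    #: allowed vocabularies for derived label columns
    LABEL_VOCABULARIES = {
        "infiltration_group": {"high", "low"},
        "subtype": {"SCLC-A", "SCLC-N", "SCLC-P", "SCLC-Y"},
        "phenotype": {"NE", "NonNE", "undetermined"},
    }

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ValueError("duplicate sample identifiers in annotations")
        for col, vocab in self.LABEL_VOCABULARIES.items():
            if col in self.table.columns:
                extra = set(self.table[col].dropna()) - vocab
                if extra:
                    raise ValueError(f"column {col!r} has values outside {vocab}: {extra}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)


def log_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Return ``log2(x + pseudocount)`` of a linear-scale matrix.

    Applying the transform to an already-logged matrix is an error rather
    than a silent double transform.
    """
    if m.scale != "linear":
        raise ValueError(f"log_transform expects a linear-scale matrix, got {m.scale!r}")
    if not pseudocount > 0:
        raise ValueError("pseudocount must be > 0")
    out = np.log2(m.data.to_numpy(dtype=float) + pseudocount)
    return ExpressionMatrix(
        pd.DataFrame(out, index=m.data.index, columns=m.data.columns), scale="log2p1"
    )


def zscore_genes(m: ExpressionMatrix, ddof: int = 1) -> tuple[ExpressionMatrix, list[str]]:
    """Standardize every gene row to mean 0, sd 1 (n-1 denominator).

    Zero-variance rows cannot be standardized; they are dropped from the
    result and returned separately so callers can log or report them.

    Returns
    -------
    (standardized matrix with scale ``zscore``, list of dropped genes)
    """
    if m.n_samples < 2:
        raise ValueError("z-scoring needs at least 2 samples")
    values = m.values()
    sd = values.std(axis=1, ddof=ddof)
    keep = sd > 0
    dropped = [g for g, k in zip(m.gene_ids, keep) if not k]
    if dropped:
        logger.warning("zscore_genes: dropping %d zero-variance gene(s)", len(dropped))
    z = (values[keep] - values[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    out = ExpressionMatrix(
        pd.DataFrame(z, index=np.asarray(m.gene_ids)[keep], columns=m.data.columns),
        scale="zscore",
    )
    return out, dropped


def align_genes(m: ExpressionMatrix, s: GeneSet) -> tuple[ExpressionMatrix, list[str]]:
    """Restrict a matrix to the genes of a set, in set order.

    Gene symbols are matched case-sensitively; no alias resolution is
    attempted. Returns the sub-matrix and the list of set genes absent
    from the matrix. A warning is logged when more than half the set is
    missing; a fully absent set is an error.
    """
    index = set(m.data.index)
    present = [g for g in s.genes if g in index]
    missing = [g for g in s.genes if g not in index]
    if not present:
        raise ValueError(f"no gene of set {s.name!r} found in the expression matrix")
    if len(missing) > 0.5 * len(s.genes):
        logger.warning(
            "align_genes: %d/%d genes of set %r missing from the matrix",
            len(missing), len(s.genes), s.name,
        )
    sub = ExpressionMatrix(m.data.loc[present], scale=m.scale)
    return sub, missing
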