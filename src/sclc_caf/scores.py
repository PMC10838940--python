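"""Per-sample phenotype and immune scalar scores.

* NE score: (Pearson with the NE reference vector - Pearson with the
  Non-NE reference vector) / 2 over a shared gene panel; > 0 calls a
  neuroendocrine (NE) phenotype, < 0 non-neuroendocrine (Non-NE).
* CYT: geometric mean of GZMA and PRF1 expression (cytolytic activity).
* APM: per-sample median of z-scored antigen-presentation-machinery
  gene expression.
* T-cell-inflamed GEP: weighted sum of log2(x+1) expression of an
  externally supplied weighted gene panel.
* SCLC subtype: argmax over ASCL1 / NEUROD1 / POU2F3 / YAP1.
* IHC a x b score: proportion bin (0-4) times intensity bin (0-3).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import ExpressionMatrix, GeneSet

logger = logging.getLogger(__name__)


@dataclass
class ReferenceVectors:
    """Reference NE and Non-NE expression over a fixed gene panel."""

    genes: tuple[str, ...]
    vector_ne: np.ndarray
    vector_nonne: np.ndarray

    def __post_init__(self) -> None:
        self.genes = tuple(self.genes)
        self.vector_ne = np.asarray(self.vector_ne, dtype=float)
        self.vector_nonne = np.asarray(self.vector_nonne, dtype=float)
        if len(self.genes) < 3:
            raise ValueError("reference panel needs at least 3 genes")
        for v in (self.vector_ne, self.vector_nonne):
            if v.shape != (len(self.genes),):
                raise ValueError("reference vectors must align with the gene panel")
            if not np.isfinite(v).all():
                raise ValueError("reference vectors must be finite")
        if np.array_equal(self.vector_ne, self.vector_nonne):
            raise ValueError("NE and Non-NE reference vectors are identical")

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "ReferenceVectors":
        """Build from a table with columns ``ne_value`` and ``nonne_value``."""
        return cls(
            tuple(table.index.astype(str)),
            table["ne_value"].to_numpy(dtype=float),
            table["nonne_value"].to_numpy(dtype=float),
        )

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"ne_value": self.vector_ne, "nonne_value": self.vector_nonne},
            index=pd.Index(self.genes, name="gene"),
        )


def _pearson_to_vector(X: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Pearson correlation of each column of X with vector v."""
    Xc = X - X.mean(axis=0, keepdims=True)
    vc = v - v.mean()
    denom = np.sqrt((Xc**2).sum(axis=0) * (vc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        return (Xc * vc[:, None]).sum(axis=0) / denom


def ne_score(m: ExpressionMatrix, ref: ReferenceVectors, min_genes: int = 3) -> pd.DataFrame:
    """NE score and phenotype label per sample.

    score = (corr(x, NE reference) - corr(x, Non-NE reference)) / 2,
    Pearson over the genes shared between the matrix and the panel.
    Samples whose expression is constant over the panel get a NaN score
    flagged ``undetermined`` rather than a silent 0.

    Returns a DataFrame with columns ``ne_score``, ``phenotype`` and
    ``n_genes`` (panel coverage actually used).
    """
    index = set(m.data.index)
    shared = [g for g in ref.genes if g in index]
    if len(shared) < min_genes:
        raise ValueError(
            f"only {len(shared)} reference genes present; need >= {min_genes}"
        )
    if len(shared) < len(ref.genes):
        logger.info("ne_score: %d/%d reference genes present", len(shared), len(ref.genes))
    pos = [ref.genes.index(g) for g in shared]
    v_ne = ref.vector_ne[pos]
    v_nonne = ref.vector_nonne[pos]
    X = m.data.loc[shared].to_numpy(dtype=float)
    constant = X.std(axis=0) == 0
    r_ne = _pearson_to_vector(X, v_ne)
    r_nonne = _pearson_to_vector(X, v_nonne)
    score = (r_ne - r_nonne) / 2.0
    score[constant] = np.nan
    if constant.any():
        logger.warning("ne_score: %d sample(s) constant over the panel; flagged", constant.sum())
    phenotype = np.where(score > 0, "NE", np.where(score < 0, "NonNE", "undetermined"))
    phenotype[constant | np.isnan(score)] = "undetermined"
    return pd.DataFrame(
        {"ne_score": score, "phenotype": phenotype, "n_genes": len(shared)},
        index=m.sample_ids,
    )


def cyt_score(m: ExpressionMatrix, offset: float = 0.01) -> pd.Series:
    """Cytolytic activity: sqrt((GZMA + offset) * (PRF1 + offset)).

    The small offset keeps the geometric mean defined when one gene is
    unexpressed. Requires a linear-scale matrix and both genes present.
    """
    if m.scale != "linear":
        raise ValueError("cyt_score expects a linear-scale matrix")
    if offset < 0:
        raise ValueError("offset must be >= 0")
    for gene in ("GZMA", "PRF1"):
        if gene not in m.data.index:
            raise KeyError(f"gene {gene!r} absent from the matrix")
    gzma = m.data.loc["GZMA"].to_numpy(dtype=float)
    prf1 = m.data.loc["PRF1"].to_numpy(dtype=float)
    return pd.Series(np.sqrt((gzma + offset) * (prf1 + offset)), index=m.sample_ids, name="cyt")


def apm_score(m: ExpressionMatrix, apm_set: GeneSet) -> pd.Series:
    """Median across genes of z-scored APM gene expression, per sample."""
    present = [g for g in apm_set.genes if g in m.data.index]
    if not present:
        raise ValueError(f"no gene of set {apm_set.name!r} present")
    sub = m.data.loc[present]
    sd = sub.std(axis=1, ddof=1)
    usable = sub.loc[sd > 0]
    dropped = list(sub.index[sd <= 0])
    if dropped:
        logger.warning("apm_score: zero-variance gene(s) excluded: %s", dropped)
    if usable.empty:
        raise ValueError(f"all present genes of {apm_set.name!r} are constant")
    z = usable.sub(usable.mean(axis=1), axis=0).div(sd[usable.index], axis=0)
    scores = z.median(axis=0)
    scores.name = "apm"
    return scores


def gep_score(m: ExpressionMatrix, weighted_set: GeneSet) -> pd.Series:
    """Weighted sum of log2(x+1) expression over a weighted gene panel.

    The matrix must already be on the log2(x+1) scale; weights must be
    supplied for every panel gene that is present. Missing panel genes
    are omitted with a log entry.
    """
    if m.scale != "log2p1":
        raise ValueError("gep_score expects a log2(x+1)-scale matrix")
    if weighted_set.weights is None:
        raise ValueError(f"gene set {weighted_set.name!r} has no weights")
    present = [g for g in weighted_set.genes if g in m.data.index]
    if not present:
        raise ValueError(f"no weighted gene of {weighted_set.name!r} present")
    missing = [g for g in weighted_set.genes if g not in m.data.index]
    if missing:
        logger.info("gep_score: %d panel gene(s) absent, omitted: %s", len(missing), missing[:5])
    w = np.array([weighted_set.weight_of(g) for g in present])
    X = m.data.loc[present].to_numpy(dtype=float)
    return pd.Series(w @ X, index=m.sample_ids, name="gep")


#: fixed tie priority for the subtype call
_SUBTYPE_GENES = ("ASCL1", "NEUROD1", "POU2F3", "YAP1")
_SUBTYPE_NAMES = ("SCLC-A", "SCLC-N", "SCLC-P", "SCLC-Y")


def call_subtype(m: ExpressionMatrix) -> pd.DataFrame:
    """SCLC-A/N/P/Y subtype per sample by the single highest of the four
    defining transcription factors; ties resolve by the fixed priority
    A > N > P > Y with a ``tie`` flag.
    """
    missing = [g for g in _SUBTYPE_GENES if g not in m.data.index]
    if missing:
        raise KeyError(f"subtype gene(s) absent: {missing}")
    X = m.data.loc[list(_SUBTYPE_GENES)].to_numpy(dtype=float)
    best = X.argmax(axis=0)  # argmax takes the first maximum: priority A > N > P > Y
    tie = (X == X.max(axis=0, keepdims=True)).sum(axis=0) > 1
    if tie.any():
        logger.warning("call_subtype: %d tied sample(s); priority A > N > P > Y", tie.sum())
    out = pd.DataFrame(
        X.T, index=m.sample_ids, columns=list(_SUBTYPE_GENES)
    )
    out["subtype"] = [_SUBTYPE_NAMES[i] for i in best]
    out["tie"] = tie
    return out


#: staining-intensity vocabulary -> intensity bin b
_INTENSITY_BINS = {"negative": 0, "weak": 1, "medium": 2, "strong": 3}


@dataclass
class IHCRecord:
    """One immunohistochemistry measurement: score = a x b."""

    sample: str
    marker: str
    proportion_bin: int
    intensity_bin: int

    def __post_init__(self) -> None:
        if self.proportion_bin not in range(5):
            raise ValueError("proportion bin must be in 0..4")
        if self.intensity_bin not in range(4):
            raise ValueError("intensity bin must be in 0..3")

    @property
    def score(self) -> int:
        return self.proportion_bin * self.intensity_bin


def proportion_bin(proportion_percent: float) -> int:
    """Bin a percent of positive cells into 0..4.

    Bins: [0, 5] -> 0, (5, 25] -> 1, (25, 50] -> 2, (50, 75] -> 3,
    (75, 100] -> 4. The half-open convention pins down the 5-6% gap
    left between the published bin edges.
    """
    p = float(proportion_percent)
    if not 0 <= p <= 100:
        raise ValueError(f"proportion {p} outside [0, 100]")
    for bin_, hi in enumerate((5, 25, 50, 75, 100)):
        if p <= hi:
            return bin_
    raise AssertionError("unreachable")


def ihc_score(proportion_percent: float, intensity: str, sample: str = "", marker: str = "") -> IHCRecord:
    """Build an IHC record from a raw proportion and an intensity word."""
    if intensity not in _INTENSITY_BINS:
        raise ValueError(f"intensity must be one of {sorted(_INTENSITY_BINS)}")
    return IHCRecord(
        sample=sample,
        marker=marker,
        proportion_bin=proportion_bin(proportion_percent),
        intensity_bin=_INTENSITY_BINS[intensity],
    )
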