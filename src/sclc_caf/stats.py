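"""Group-level inference: GSEA with a permutation NES, single-sample
set scores for pathway libraries, an empirical-Bayes moderated t, and
the elementary tests and correlations used throughout the pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from .data import ExpressionMatrix, GeneSet, SignatureLibrary
from .abundance import ssgsea_score, _rank_order

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# ranking metric

@dataclass
class RankedList:
    """Genes strictly ordered by a ranking metric (descending)."""

    genes: np.ndarray
    metric: np.ndarray
    metric_name: str = "signal2noise"

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes)
        self.metric = np.asarray(self.metric, dtype=float)
        if self.genes.shape != self.metric.shape:
            raise ValueError("genes and metric must align")
        if not np.isfinite(self.metric).all():
            raise ValueError("ranking metric must be finite")
        if not (np.diff(self.metric) <= 0).all():
            raise ValueError("metric must be sorted descending")

    def __len__(self) -> int:
        return len(self.genes)


def _group_masks(labels: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    lab = np.asarray(labels)
    high = lab == "high"
    low = lab == "low"
    if not (high | low).all():
        raise ValueError("labels must be 'high' or 'low'")
    return high, low


def _signal2noise(
    X: np.ndarray, high: np.ndarray, low: np.ndarray,
    floor_frac: float = 0.2, floor_abs: float = 0.2,
) -> np.ndarray:
    """(mu_high - mu_low) / (sd_high + sd_low), sds floored.

    Each group sd is floored at max(floor_frac * |group mean|,
    floor_abs) so near-constant genes do not blow up the metric.
    """
    mu_h = X[:, high].mean(axis=1)
    mu_l = X[:, low].mean(axis=1)
    sd_h = X[:, high].std(axis=1, ddof=1)
    sd_l = X[:, low].std(axis=1, ddof=1)
    sd_h = np.maximum(sd_h, np.maximum(floor_frac * np.abs(mu_h), floor_abs))
    sd_l = np.maximum(sd_l, np.maximum(floor_frac * np.abs(mu_l), floor_abs))
    return (mu_h - mu_l) / (sd_h + sd_l)


def rank_metric(
    m: ExpressionMatrix,
    labels: Sequence[str],
    method: str = "signal2noise",
    precomputed: Optional[pd.Series] = None,
) -> RankedList:
    """Rank genes by a two-group metric, descending, ties broken by
    gene id (lexicographic) for determinism.
    """
    if method == "precomputed":
        if precomputed is None:
            raise ValueError("method='precomputed' needs a metric series")
        genes = np.asarray(precomputed.index)
        metric = precomputed.to_numpy(dtype=float)
    else:
        high, low = _group_masks(labels)
        if high.sum() < 2 or low.sum() < 2:
            raise ValueError("each group needs at least 2 samples for a ranking metric")
        X = m.values()
        if method == "signal2noise":
            metric = _signal2noise(X, high, low)
        elif method == "moderated_t":
            res = moderated_t(m.data, labels)
            metric = res.table["t"].to_numpy()
        else:
            raise ValueError(f"unknown ranking method {method!r}")
        genes = np.asarray(m.gene_ids)
    order = _rank_order(metric, genes)
    return RankedList(genes=genes[order], metric=metric[order], metric_name=method)


# ---------------------------------------------------------------------------
# GSEA enrichment score and permutation NES

def gsea_es(ranked: RankedList, s: GeneSet, p_exponent: float = 1.0) -> float:
    """Weighted Kolmogorov-Smirnov enrichment score.

    Walking down the ranked list, an in-set gene increments the running
    sum by |metric|^p normalized by the in-set total, an out-of-set
    gene decrements it by 1/(N - |S|); the ES is the running-sum
    extremum of largest magnitude.
    """
    inset = np.isin(ranked.genes, list(s.genes))
    n_in = int(inset.sum())
    n = len(ranked)
    if n_in == 0:
        raise ValueError(f"no gene of set {s.name!r} in the ranked list")
    if n_in == n:
        raise ValueError(f"set {s.name!r} equals the whole ranked list")
    w = np.abs(ranked.metric) ** p_exponent
    total = w[inset].sum()
    if total == 0:
        if p_exponent > 0:
            raise ValueError("all in-set metric values are zero; ES undefined")
        total = float(n_in)
    steps = np.where(inset, w / total, -1.0 / (n - n_in))
    running = np.cumsum(steps)
    return float(running[int(np.argmax(np.abs(running)))])


@dataclass
class GseaResult:
    set_name: str
    es: float
    nes: float
    p_value: float
    n_permutations: int
    permutation_mode: str
    seed: int

    def __post_init__(self) -> None:
        if self.es != 0 and self.nes != 0 and np.sign(self.nes) != np.sign(self.es):
            raise ValueError("NES sign must match ES sign")
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0, 1]")


def gsea_nes(
    m: ExpressionMatrix,
    labels: Sequence[str],
    s: GeneSet,
    n_perm: int = 1000,
    mode: str = "phenotype",
    seed: Optional[int] = None,
    p_exponent: float = 1.0,
) -> GseaResult:
    """Observed ES plus a permutation NES and nominal p-value.

    ``mode='phenotype'`` permutes the high/low labels and recomputes the
    signal-to-noise ranking per permutation; ``mode='gene_set'`` draws
    random same-size gene sets on the observed ranking. With fewer than
    7 samples in either group the phenotype null is too coarse and the
    call falls back to gene-set permutation with a warning.

    NES = ES / mean(|null ES| of matching sign); nominal
    p = (1 + #{same-sign nulls at least as extreme}) / (1 + #same-sign
    nulls), so p is never exactly 0.
    """
    if seed is None:
        raise ValueError("gsea_nes requires an explicit seed")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if mode not in ("phenotype", "gene_set"):
        raise ValueError("mode must be 'phenotype' or 'gene_set'")
    high, low = _group_masks(labels)
    if mode == "phenotype" and min(high.sum(), low.sum()) < 7:
        logger.warning(
            "gsea_nes: group sizes %d/%d too small for phenotype permutation; "
            "falling back to gene_set mode", high.sum(), low.sum(),
        )
        mode = "gene_set"
    rng = np.random.default_rng(seed)
    ranked = rank_metric(m, labels, method="signal2noise")
    es = gsea_es(ranked, s, p_exponent)

    genes = np.asarray(m.gene_ids)
    size = int(np.isin(ranked.genes, list(s.genes)).sum())
    null = np.empty(n_perm)
    if mode == "phenotype":
        X = m.values()
        lab = np.asarray(labels)
        for b in range(n_perm):
            perm = rng.permutation(lab)
            ph, pl = perm == "high", perm == "low"
            metric = _signal2noise(X, ph, pl)
            order = _rank_order(metric, genes)
            null[b] = gsea_es(
                RankedList(genes[order], metric[order], "signal2noise"), s, p_exponent
            )
    else:
        for b in range(n_perm):
            rand_genes = rng.choice(genes, size=size, replace=False)
            null[b] = gsea_es(ranked, GeneSet("_null", tuple(rand_genes)), p_exponent)

    same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
    if same_sign.size == 0:
        logger.warning("gsea_nes: no same-sign null ES; normalizing by all nulls")
        same_sign = np.abs(null)
    nes = es / np.mean(np.abs(same_sign)) if np.mean(np.abs(same_sign)) > 0 else np.nan
    p = (1 + int((np.abs(same_sign) >= abs(es)).sum())) / (1 + same_sign.size)
    return GseaResult(
        set_name=s.name, es=es, nes=float(nes), p_value=float(p),
        n_permutations=n_perm, permutation_mode=mode, seed=seed,
    )


def gsva_like_scores(m: ExpressionMatrix, lib: SignatureLibrary) -> pd.DataFrame:
    """Per-set, per-sample rank-enrichment scores for a library.

    Each set is scored by the single-sample engine with exponent 1 on
    rank-normalized values and the signed maximum-deviation statistic —
    a rank-ECDF analog of per-set pathway scoring, suitable for group
    comparison with the moderated t.
    """
    if m.n_samples < 2:
        raise ValueError("need at least 2 samples")
    if len(lib) == 0:
        raise ValueError("empty signature library")
    rows = {gs.name: ssgsea_score(m, gs, alpha=1.0, mode="max_dev") for gs in lib}
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# empirical-Bayes moderated t

def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration.

    Monotone decreasing trigamma makes the iteration globally stable
    from the asymptotic starting point y = 0.5 + 1/x.
    """
    if x <= 0:
        raise ValueError("trigamma inverse needs x > 0")
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(100):
        tri = polygamma(1, y)
        step = tri * (1.0 - tri / x) / polygamma(2, y)
        y += step
        if abs(step) < 1e-10 * y:
            break
    return float(y)


@dataclass
class GroupComparisonResult:
    """Moderated two-group comparison across an ensemble of features."""

    table: pd.DataFrame  # effect, t, df_total, p, q per feature
    prior_df: float      # d0 (may be inf)
    prior_var: float     # s0^2


def moderated_t(
    scores: pd.DataFrame,
    labels: Sequence[str],
    prior_df: Optional[float] = None,
) -> GroupComparisonResult:
    """Empirical-Bayes moderated two-sample t across features.

    Per feature the effect is mean(high) - mean(low) with pooled
    residual variance s^2 on d = n1 + n2 - 2 df. Variance shrinkage
    hyper-parameters are fit by moment matching on
    e = log s^2 - psi(d/2) + log(d/2): the excess variance of e over
    the chi-square noise floor determines the prior df d0 through the
    trigamma inverse, and the prior variance s0^2 through the mean of
    e. The posterior variance (d0 s0^2 + d s^2)/(d0 + d) replaces s^2
    in the t, which gains d0 extra degrees of freedom.

    ``prior_df`` overrides the fitted d0 (0 recovers the ordinary
    pooled t). Features with zero variance in both groups are excluded
    from the hyper-parameter fit but still reported.
    """
    if scores.shape[0] < 2:
        raise ValueError("moderated t needs >= 2 features (shrinkage needs an ensemble)")
    high, low = _group_masks(labels)
    n1, n2 = int(high.sum()), int(low.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >= 2 samples")
    X = scores.to_numpy(dtype=float)
    effect = X[:, high].mean(axis=1) - X[:, low].mean(axis=1)
    v1 = X[:, high].var(axis=1, ddof=1)
    v2 = X[:, low].var(axis=1, ddof=1)
    d = n1 + n2 - 2
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / d
    usable = s2 > 0
    if (~usable).any():
        logger.warning(
            "moderated_t: %d zero-variance feature(s) excluded from the prior fit",
            int((~usable).sum()),
        )
    if usable.sum() < 2:
        raise ValueError("fewer than 2 features with positive variance")

    e = np.log(s2[usable]) - digamma(d / 2.0) + np.log(d / 2.0)
    e_bar = e.mean()
    g = e.size
    excess = ((e - e_bar) ** 2).sum() / (g - 1) - polygamma(1, d / 2.0)
    if prior_df is not None:
        d0 = float(prior_df)
        if d0 < 0:
            raise ValueError("prior_df must be >= 0")
    elif excess > 0:
        d0 = 2.0 * _trigamma_inverse(float(excess))
    else:
        d0 = np.inf
    if np.isfinite(d0) and d0 > 0:
        s0_sq = float(np.exp(e_bar + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # degenerate moment equation (no excess spread): e is already the
        # bias-corrected log variance, so its mean estimates log s0^2
        s0_sq = float(np.exp(e_bar))

    if d0 == 0:
        s2_tilde = s2
        df_total = float(d)
    elif np.isinf(d0):
        s2_tilde = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_tilde = (d0 * s0_sq + d * s2) / (d0 + d)
        df_total = d0 + d
    se = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / se
    p = 2.0 * sps.t.sf(np.abs(t), df_total)
    q = bh_fdr(p)
    table = pd.DataFrame(
        {"effect": effect, "t": t, "df_total": df_total, "p": p, "q": q,
         "zero_variance": ~usable},
        index=scores.index,
    )
    return GroupComparisonResult(table=table, prior_df=float(d0), prior_var=s0_sq)


# ---------------------------------------------------------------------------
# elementary tests

@dataclass
class CorrelationResult:
    r: float
    n: int
    p_value: float
    method: str

    def __post_init__(self) -> None:
        if not -1 <= self.r <= 1:
            raise ValueError("|r| must be <= 1")
        if not 0 <= self.p_value <= 1:
            raise ValueError("p outside [0, 1]")
        if self.n < 3:
            raise ValueError("n must be >= 3")


def pearson_correlation(x, y, method: str = "pearson") -> CorrelationResult:
    """Sample correlation with a two-sided t-based p-value.

    ``method='spearman'`` ranks both vectors first.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equal length")
    n = x.size
    if n < 3:
        raise ValueError("correlation needs n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input vector")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return CorrelationResult(r=float(r), n=n, p_value=float(p), method=method)


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided p for a sample Pearson r at sample size n.

    Uses t = r sqrt((n-2)/(1-r^2)) with n-2 df; lets a printed (r, n)
    pair be checked without the underlying vectors.
    """
    if not -1 < r < 1:
        raise ValueError("|r| must be < 1 for a finite t")
    if n < 3:
        raise ValueError("n must be >= 3")
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * sps.t.sf(abs(t), n - 2))


def group_tests(values, labels, test: str = "welch_t") -> tuple[float, float]:
    """Two-sided location test between labeled groups.

    ``welch_t``, ``student_t`` and ``mann_whitney`` expect exactly two
    groups; ``anova`` needs >= 3. The Mann-Whitney U uses exact
    enumeration for small tie-free samples (total n <= 40) and the
    tie-corrected normal approximation otherwise.
    """
    values = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    groups = [values[lab == g] for g in pd.unique(lab)]
    if any(len(g) == 0 for g in groups) or len(groups) < 2:
        raise ValueError("need >= 2 non-empty groups")
    if test == "anova":
        if len(groups) < 3:
            raise ValueError("anova needs >= 3 groups; use a t-test for 2")
        stat, p = sps.f_oneway(*groups)
    elif len(groups) != 2:
        raise ValueError(f"test {test!r} expects exactly 2 groups, got {len(groups)}")
    elif test == "welch_t":
        stat, p = sps.ttest_ind(groups[0], groups[1], equal_var=False)
    elif test == "student_t":
        stat, p = sps.ttest_ind(groups[0], groups[1], equal_var=True)
    elif test == "mann_whitney":
        total = len(groups[0]) + len(groups[1])
        has_ties = len(np.unique(values)) < total
        method = "exact" if (total <= 40 and not has_ties) else "asymptotic"
        res = sps.mannwhitneyu(groups[0], groups[1], alternative="two-sided", method=method)
        stat, p = res.statistic, res.pvalue
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(stat), float(p)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]
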