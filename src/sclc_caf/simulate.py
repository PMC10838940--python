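"""Synthetic SCLC cohorts with ground truth.

Bulk expression is generated as a convex mixture of four component
profiles — NE tumor, Non-NE tumor, fibroblast and immune — with
per-sample weights drawn so that the cohort has the statistical
structure the downstream analysis assumes:

* the fibroblast fraction f follows a two-component Beta mixture, a
  dominant low-infiltration component and a ~30% high-infiltration
  component, giving the high/low split a ground truth;
* the probability of a Non-NE tumor program increases with f through a
  logistic link, encoding the fibroblast/Non-NE association;
* the immune fraction is positively coupled to f, encoding the
  fibroblast/immune association;
* marker genes are fold-change enriched in their home component, and an
  IL6 gene is assigned to the fibroblast program.

Multiplicative lognormal noise keeps values on a positive, FPKM-like
support. The generator also produces IHC score triples and a linear
drug-response training fixture for the ridge predictor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import ExpressionMatrix, GeneSet, SignatureLibrary
from .abundance import DeconvolutionReference
from .scores import ReferenceVectors

logger = logging.getLogger(__name__)

COMPONENTS = ("NE_tumor", "NonNE_tumor", "Fibroblast", "Immune")

# real marker symbols seed each program so the generic scoring code
# (subtype call, CYT, markers GMT) runs unchanged on synthetic cohorts;
# programs larger than the seed lists are padded with synthetic symbols
CAF_MARKER_SEED = (
    "PDGFRA", "PDGFRB", "PDPN", "FAP", "THY1",
    "COL1A1", "COL1A2", "COL3A1", "ACTA2", "S100A4",
)
NE_SEED = (
    "ASCL1", "NEUROD1", "INSM1", "SYP", "NCAM1", "CHGA", "CHGB", "GRP",
    "DDC", "SCG2", "CALCA", "CRMP1", "STMN3", "SYT4", "RTN1", "SEZ6",
)
NONNE_SEED = (
    "REST", "YAP1", "POU2F3", "MYC", "VIM", "HES1", "NOTCH1", "NOTCH2",
    "CAV1", "CAV2", "ANXA1", "EPHA2", "ITGB1", "S100A10",
)
IMMUNE_SEED = (
    "PTPRC", "GZMA", "PRF1", "CD8A", "CD3E", "CD4", "MS4A1", "NKG7",
    "CD68", "ITGAM", "HLA-A", "HLA-B", "HLA-DRA", "TAP1", "TAP2", "B2M",
    "PSMB8", "PSMB9", "CD274", "PDCD1",
)


@dataclass
class SimulationConfig:
    """Generator settings; the defaults are the study conditions.

    ``n_samples=80`` and ``n_genes=5000`` match the scale of a public
    SCLC cohort; the Beta-mixture weight of 0.3 mirrors a <30%
    prevalence of high fibroblast infiltration; the logistic coupling
    P(Non-NE) = expit(gamma0 + gamma1 * f) with (-2, 6) spans ~0.12 at
    f=0 to ~0.98 at f=1.
    """

    n_samples: int = 80
    n_genes: int = 5000
    n_caf_markers: int = 10
    n_ne_genes: int = 25
    n_nonne_genes: int = 25
    n_immune_genes: int = 30
    high_prob: float = 0.3
    low_beta: tuple[float, float] = (2.0, 18.0)
    high_beta: tuple[float, float] = (10.0, 10.0)
    gamma0: float = -2.0
    gamma1: float = 6.0
    immune_coupling: float = 0.4
    immune_noise_sd: float = 0.05
    marker_fold_change: float = 8.0
    noise_sd: float = 0.3
    noise_model: str = "lognormal"
    baseline_meanlog: float = 3.0
    baseline_sdlog: float = 1.0

    def validate(self) -> None:
        counts = (
            self.n_samples, self.n_genes, self.n_caf_markers,
            self.n_ne_genes, self.n_nonne_genes, self.n_immune_genes,
        )
        if any(c < 1 for c in counts):
            raise ValueError("all counts must be >= 1")
        n_special = (
            self.n_caf_markers + self.n_ne_genes + self.n_nonne_genes
            + self.n_immune_genes + 1  # + IL6
        )
        if n_special > self.n_genes:
            raise ValueError(
                f"marker genes ({n_special}) exceed n_genes ({self.n_genes})"
            )
        if not 0 <= self.high_prob <= 1:
            raise ValueError("high_prob must be in [0, 1]")
        if self.noise_sd < 0 or self.immune_noise_sd < 0:
            raise ValueError("noise sds must be >= 0")
        if self.marker_fold_change <= 0:
            raise ValueError("marker_fold_change must be > 0")
        if self.noise_model not in ("lognormal", "gaussian"):
            raise ValueError("noise_model must be 'lognormal' or 'gaussian'")
        if any(b <= 0 for b in (*self.low_beta, *self.high_beta)):
            raise ValueError("Beta parameters must be > 0")
        if self.immune_coupling < 0:
            raise ValueError("immune_coupling must be >= 0")


def _program_genes(seed: tuple[str, ...], n: int, prefix: str) -> list[str]:
    genes = list(seed[:n])
    genes += [f"{prefix}{i:03d}" for i in range(1, n - len(genes) + 1)]
    return genes


@dataclass
class ComponentProfiles:
    """Per-component reference expression and gene-program memberships."""

    profiles: pd.DataFrame            # genes x components, non-negative
    memberships: SignatureLibrary     # CAF_markers, NE_program, NonNE_program, Immune_program

    def reference(self, signature_only: bool = True) -> DeconvolutionReference:
        """Deconvolution reference from the component profiles.

        By default restricted to the program genes (the informative
        rows, as a curated signature matrix would be); pass
        ``signature_only=False`` for the full gene complement.
        """
        if not signature_only:
            return DeconvolutionReference(self.profiles.copy())
        genes = [g for gs in self.memberships for g in gs.genes] + ["IL6"]
        return DeconvolutionReference(self.profiles.loc[genes].copy())


def _simulate_profiles(config: SimulationConfig, rng: np.random.Generator) -> ComponentProfiles:
    caf = _program_genes(CAF_MARKER_SEED, config.n_caf_markers, "CAFM")
    ne = _program_genes(NE_SEED, config.n_ne_genes, "NEG")
    nonne = _program_genes(NONNE_SEED, config.n_nonne_genes, "NNG")
    immune = _program_genes(IMMUNE_SEED, config.n_immune_genes, "IMG")
    special = caf + ne + nonne + immune + ["IL6"]
    n_bg = config.n_genes - len(special)
    genes = special + [f"BG{i:05d}" for i in range(1, n_bg + 1)]

    # one baseline per gene, shared across components: a program gene then
    # differs between components only through its fold-change, so every
    # marker row carries the same mixture signal up to noise
    base = rng.lognormal(config.baseline_meanlog, config.baseline_sdlog, size=config.n_genes)
    profiles = pd.DataFrame(
        np.tile(base[:, None], (1, len(COMPONENTS))), index=genes, columns=list(COMPONENTS)
    )
    fc = config.marker_fold_change
    profiles.loc[ne, "NE_tumor"] *= fc
    profiles.loc[nonne, "NonNE_tumor"] *= fc
    profiles.loc[caf + ["IL6"], "Fibroblast"] *= fc
    profiles.loc[immune, "Immune"] *= fc

    memberships = SignatureLibrary.from_sets([
        GeneSet("CAF_markers", tuple(caf)),
        GeneSet("NE_program", tuple(ne)),
        GeneSet("NonNE_program", tuple(nonne)),
        GeneSet("Immune_program", tuple(immune)),
    ])
    return ComponentProfiles(profiles=profiles, memberships=memberships)


def simulate_component_profiles(
    config: SimulationConfig, seed: Optional[int] = None
) -> ComponentProfiles:
    """Draw the four component profiles for a configuration.

    Baseline expression is lognormal (meanlog 3, sdlog 1 by default,
    an FPKM-like spread); each program gene is multiplied by the
    fold-change in its home component only.
    """
    config.validate()
    return _simulate_profiles(config, np.random.default_rng(seed))


@dataclass
class SyntheticCohort:
    """A generated cohort: observed expression plus full ground truth."""

    expression: ExpressionMatrix
    truth: pd.DataFrame           # fibro/immune/tumor fractions, phenotype, intended_group
    profiles: ComponentProfiles
    config: SimulationConfig = field(default_factory=SimulationConfig)
    seed: Optional[int] = None

    def reference_vectors(self) -> ReferenceVectors:
        """NE/Non-NE reference vectors over the tumor program panel,
        taken from the generating component profiles."""
        panel = (
            list(self.profiles.memberships["NE_program"].genes)
            + list(self.profiles.memberships["NonNE_program"].genes)
        )
        prof = self.profiles.profiles.loc[panel]
        return ReferenceVectors(
            tuple(panel),
            prof["NE_tumor"].to_numpy(),
            prof["NonNE_tumor"].to_numpy(),
        )

    @property
    def caf_markers(self) -> GeneSet:
        return self.profiles.memberships["CAF_markers"]


def simulate_cohort(config: Optional[SimulationConfig] = None, seed: Optional[int] = None) -> SyntheticCohort:
    """Generate a cohort under a configuration.

    Per sample: the fibroblast fraction f is drawn from the
    low/high Beta mixture (the mixture component is recorded as
    ``intended_group``); the tumor program is Non-NE with probability
    expit(gamma0 + gamma1 f); the immune fraction is
    clip(coupling * f + noise, 0, 1 - f); observed expression is the
    profile mixture under multiplicative lognormal noise. All draws
    come from one seeded stream, so (config, seed) reproduces the
    cohort bit for bit.
    """
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    profiles = _simulate_profiles(config, rng)

    n = config.n_samples
    samples = [f"S{i:03d}" for i in range(1, n + 1)]
    is_high = rng.random(n) < config.high_prob
    f = np.where(
        is_high,
        rng.beta(*config.high_beta, size=n),
        rng.beta(*config.low_beta, size=n),
    )
    is_nonne = rng.random(n) < expit(config.gamma0 + config.gamma1 * f)
    immune = np.clip(
        config.immune_coupling * f + rng.normal(0.0, config.immune_noise_sd, size=n),
        0.0, 1.0 - f,
    )
    tumor = 1.0 - f - immune
    if (tumor < -1e-12).any():
        raise RuntimeError("infeasible mixture weights after clipping")
    tumor = np.clip(tumor, 0.0, 1.0)

    P = profiles.profiles.to_numpy()  # genes x 4
    idx = {c: i for i, c in enumerate(COMPONENTS)}
    W = np.zeros((len(COMPONENTS), n))
    W[idx["NE_tumor"]] = np.where(is_nonne, 0.0, tumor)
    W[idx["NonNE_tumor"]] = np.where(is_nonne, tumor, 0.0)
    W[idx["Fibroblast"]] = f
    W[idx["Immune"]] = immune
    X = P @ W
    if config.noise_sd > 0:
        if config.noise_model == "lognormal":
            X = X * rng.lognormal(0.0, config.noise_sd, size=X.shape)
        else:
            X = np.clip(X + rng.normal(0.0, config.noise_sd, size=X.shape), 0.0, None)

    expression = ExpressionMatrix(
        pd.DataFrame(X, index=profiles.profiles.index, columns=samples), scale="linear"
    )
    truth = pd.DataFrame(
        {
            "fibro_fraction": f,
            "immune_fraction": immune,
            "tumor_fraction": tumor,
            "phenotype": np.where(is_nonne, "NonNE", "NE"),
            "intended_group": np.where(is_high, "high", "low"),
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return SyntheticCohort(
        expression=expression, truth=truth, profiles=profiles, config=config, seed=seed
    )


def simulate_ihc(n: int, rho: float, seed: Optional[int] = None) -> pd.DataFrame:
    """Paired IHC a x b scores for an aSMA-like, REST-like and CD56-like
    marker triple.

    A shared latent (fibroblast content) drives the aSMA-like marker;
    the REST-like latent correlates with it at ``rho`` and the
    CD56-like latent at ``-rho``. Each marker's latent is binned into
    proportion quintiles a in 0..4 and intensity quartiles b in 0..3;
    the reported score is a * b, so binning attenuates the latent
    correlation.

    Returns a wide DataFrame of scores with columns ``aSMA``, ``REST``,
    ``CD56``.
    """
    if n < 3:
        raise ValueError("need n >= 3 IHC samples")
    if not -1 <= rho <= 1:
        raise ValueError("|rho| must be <= 1")
    rng = np.random.default_rng(seed)
    z = rng.normal(size=n)
    resid = np.sqrt(max(1.0 - rho**2, 0.0))
    latents = {
        "aSMA": z,
        "REST": rho * z + resid * rng.normal(size=n),
        "CD56": -rho * z + resid * rng.normal(size=n),
    }
    out = {}
    for marker, u in latents.items():
        a = np.clip(np.searchsorted(np.quantile(u, [0.2, 0.4, 0.6, 0.8]), u, side="right"), 0, 4)
        b = np.clip(np.searchsorted(np.quantile(u, [0.25, 0.5, 0.75]), u, side="right"), 0, 3)
        out[marker] = a * b
    return pd.DataFrame(out, index=[f"T{i:03d}" for i in range(1, n + 1)])


def simulate_drug_training(
    n_lines: int,
    n_genes: int,
    n_causal: int,
    noise_sd: float,
    seed: Optional[int] = None,
    gene_ids: Optional[list[str]] = None,
) -> tuple[ExpressionMatrix, pd.Series, pd.Series]:
    """Linear-response training fixture for the ridge predictor.

    Expression is Gaussian on a log-like scale; the response is
    intercept + sum(true_weight * expression) + Gaussian noise, with
    ``n_causal`` non-zero weights. Returns (expression, response,
    true weights).
    """
    if n_lines < 3:
        raise ValueError("need at least 3 training lines")
    if n_causal > n_genes:
        raise ValueError("n_causal cannot exceed n_genes")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    genes = gene_ids if gene_ids is not None else [f"G{i:04d}" for i in range(1, n_genes + 1)]
    if len(genes) != n_genes:
        raise ValueError("gene_ids length must equal n_genes")
    lines = [f"CL{i:03d}" for i in range(1, n_lines + 1)]
    X = rng.normal(5.0, 1.0, size=(n_genes, n_lines))
    w = np.zeros(n_genes)
    causal = rng.choice(n_genes, size=n_causal, replace=False)
    w[causal] = rng.normal(0.0, 1.0, size=n_causal)
    intercept = 2.0
    y = intercept + w @ X + rng.normal(0.0, noise_sd, size=n_lines)
    expr = ExpressionMatrix(pd.DataFrame(X, index=genes, columns=lines), scale="log2p1")
    return (
        expr,
        pd.Series(y, index=lines, name="response"),
        pd.Series(w, index=genes, name="true_weight"),
    )


def with_noise_sd(config: SimulationConfig, noise_sd: float) -> SimulationConfig:
    """Convenience copy-with-replacement used by tests of the noiseless limit."""
    return replace(config, noise_sd=noise_sd)
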