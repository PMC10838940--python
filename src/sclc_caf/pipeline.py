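"""End-to-end orchestration: cohort -> abundance -> infiltration groups
-> phenotype scores -> group statistics -> enrichment -> drug response.

Every stage writes its table to the output directory; the run report
records the manifest, headline summary and the configuration echo.
Randomized stages draw child seeds derived from the master seed by
fixed offsets, so a stage rerun alone reproduces its output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .abundance import (
    AbundanceTable, DeconvolutionReference, import_external_abundance,
    estimate_like_scores, marker_mean_score, nnls_deconvolution, ssgsea_score,
)
from .cluster import build_caf_composite, cluster_infiltration
from .data import ExpressionMatrix, GeneSet, SignatureLibrary, log_transform
from .drugs import compare_sensitivity, fit_ridge_transfer, predict_sensitivity_table
from .io import (
    read_expression_matrix, read_gmt, read_weights, write_expression_matrix,
    write_gmt, write_table,
)
from .scores import ReferenceVectors, apm_score, call_subtype, cyt_score, gep_score, ne_score
from .simulate import SimulationConfig, SyntheticCohort, simulate_cohort, simulate_drug_training
from .stats import gsea_nes, gsva_like_scores, moderated_t, pearson_correlation, group_tests

logger = logging.getLogger(__name__)

# fixed per-stage seed offsets off the master seed (kept below 2^31)
_STAGE_OFFSETS = {"simulate": 11, "gsea": 23, "drugs": 37}


def stage_seed(master: int, stage: str) -> int:
    return (int(master) * 1009 + _STAGE_OFFSETS[stage]) % (2**31 - 1)


@dataclass
class RunConfig:
    """Everything a full run needs; YAML-serializable."""

    out_dir: str = "run_out"
    seed: int = 0
    synthetic: bool = True
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    # paths for user-supplied data (ignored when synthetic)
    expression_path: Optional[str] = None
    expression_format: str = "tsv"
    scale: str = "linear"
    markers_gmt: Optional[str] = None
    reference_vectors_path: Optional[str] = None
    deconv_reference_path: Optional[str] = None
    gep_gmt: Optional[str] = None
    gep_weights_path: Optional[str] = None
    external_abundance_path: Optional[str] = None
    signature_gmt: Optional[str] = None
    n_permutations: int = 1000
    with_drugs: bool = True
    drug_panel_size: int = 8

    def validate(self) -> None:
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer")
        if not self.synthetic:
            if self.expression_path is None or self.markers_gmt is None:
                raise ValueError("non-synthetic runs need expression_path and markers_gmt")
            for name in (
                "expression_path", "markers_gmt", "reference_vectors_path",
                "deconv_reference_path", "gep_gmt", "gep_weights_path",
                "external_abundance_path", "signature_gmt",
            ):
                p = getattr(self, name)
                if p is not None and not Path(p).exists():
                    raise FileNotFoundError(f"{name}: {p}")
        if self.gep_gmt is not None and self.gep_weights_path is None:
            raise ValueError("GEP scoring enabled but no weight file given")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimulationConfig(**payload.pop("sim", {}))
        cfg = cls(sim=sim, **payload)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class RunReport:
    manifest: dict[str, str]
    summary: dict
    version: str
    config: dict

    def to_json(self) -> str:
        return json.dumps(
            {"manifest": self.manifest, "summary": self.summary,
             "version": self.version, "config": self.config},
            indent=2, default=_jsonable,
        )


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, (tuple, set)):
        return list(x)
    raise TypeError(f"not JSON-serializable: {type(x)}")


def _load_inputs(config: RunConfig, out: Path):
    """Stage 0: simulate or ingest. Returns (expression, markers,
    reference_vectors|None, deconv_reference|None, library|None,
    cohort|None)."""
    if config.synthetic:
        cohort = simulate_cohort(config.sim, seed=stage_seed(config.seed, "simulate"))
        expr = cohort.expression
        markers = cohort.caf_markers
        refvec = cohort.reference_vectors()
        deconv_ref = cohort.profiles.reference()
        library = cohort.profiles.memberships
        write_expression_matrix(expr, out / "expression.tsv")
        write_table(cohort.truth, out / "truth.csv", "csv")
        write_gmt(library, out / "memberships.gmt")
        write_table(refvec.to_table(), out / "reference_vectors.tsv", "tsv")
        write_table(deconv_ref.profiles, out / "deconv_reference.tsv", "tsv")
        return expr, markers, refvec, deconv_ref, library, cohort
    expr = read_expression_matrix(
        config.expression_path, format=config.expression_format, scale=config.scale
    )
    markers_lib = read_gmt(config.markers_gmt)
    markers = next(iter(markers_lib))
    refvec = None
    if config.reference_vectors_path:
        tab = pd.read_csv(config.reference_vectors_path, sep="\t", index_col=0)
        refvec = ReferenceVectors.from_table(tab)
    deconv_ref = None
    if config.deconv_reference_path:
        deconv_ref = DeconvolutionReference(
            pd.read_csv(config.deconv_reference_path, sep="\t", index_col=0)
        )
    library = read_gmt(config.signature_gmt) if config.signature_gmt else None
    return expr, markers, refvec, deconv_ref, library, None


def run_all(config: RunConfig) -> RunReport:
    """Execute the full pipeline under a validated configuration."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config_echo.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
    manifest: dict[str, str] = {"config_echo": str(out / "config_echo.yaml")}
    summary: dict = {}

    def _stage(name):
        logger.info("stage: %s", name)

    try:
        _stage("inputs")
        expr, markers, refvec, deconv_ref, library, cohort = _load_inputs(config, out)
        if config.synthetic:
            for key in ("expression", "truth", "memberships", "reference_vectors", "deconv_reference"):
                ext = "gmt" if key == "memberships" else ("tsv" if key in ("expression", "reference_vectors", "deconv_reference") else "csv")
                manifest[key] = str(out / f"{key}.{ext}")
    except Exception as err:
        raise RuntimeError(f"stage 'inputs' failed: {err}") from err

    try:
        _stage("abundance")
        logged = log_transform(expr, 1.0) if expr.scale == "linear" else expr
        features = {"Fibroblast_marker": marker_mean_score(logged, markers)}
        methods = {"Fibroblast_marker": "marker_mean"}
        features["Fibroblast_enrich"] = ssgsea_score(logged, markers, alpha=0.25, mode="sum")
        methods["Fibroblast_enrich"] = "ssgsea"
        if deconv_ref is not None and expr.scale == "linear":
            decon = nnls_deconvolution(expr, deconv_ref)
            for ct in decon.fractions.index:
                name = f"{ct}_decon" if "fibro" not in ct.lower() else "Fibroblast_decon"
                features[name] = decon.fractions.loc[ct]
                methods[name] = "nnls"
        if library is not None and "Immune_program" in library.names():
            stromal, immune = estimate_like_scores(
                logged, markers, library["Immune_program"]
            )
            features["stromal_score"] = stromal
            features["immune_score"] = immune
            methods["stromal_score"] = methods["immune_score"] = "ssgsea"
        if config.external_abundance_path:
            ext = import_external_abundance(config.external_abundance_path, expr)
            for f in ext.table.index:
                features[f"external_{f}"] = ext.table.loc[f]
                methods[f"external_{f}"] = "external"
        abundance = AbundanceTable(table=pd.DataFrame(features).T, methods=methods)
        write_table(abundance.table, out / "abundance.csv", "csv")
        manifest["abundance"] = str(out / "abundance.csv")
    except Exception as err:
        raise RuntimeError(f"stage 'abundance' failed: {err}") from err

    try:
        _stage("cluster")
        fibro_feats = [f for f in abundance.table.index if f.startswith("Fibroblast")]
        composite = build_caf_composite(logged, markers, abundance, fibro_feats)
        labeling = cluster_infiltration(composite)
        write_table(composite, out / "composite.tsv", "tsv")
        write_table(labeling.labels.to_frame(), out / "labels.csv", "csv")
        manifest["composite"] = str(out / "composite.tsv")
        manifest["labels"] = str(out / "labels.csv")
        summary["group_sizes"] = {"high": labeling.n_high, "low": labeling.n_low}
    except Exception as err:
        raise RuntimeError(f"stage 'cluster' failed: {err}") from err

    try:
        _stage("scores")
        score_cols = {}
        if refvec is not None:
            nes_tab = ne_score(logged, refvec)
            score_cols["ne_score"] = nes_tab["ne_score"]
            score_cols["phenotype"] = nes_tab["phenotype"]
        if expr.scale == "linear" and {"GZMA", "PRF1"} <= set(expr.data.index):
            score_cols["cyt"] = cyt_score(expr)
        if library is not None and "Immune_program" in library.names():
            score_cols["apm"] = apm_score(logged, library["Immune_program"])
        if config.gep_gmt:
            gep_lib = read_gmt(config.gep_gmt)
            gep_set = next(iter(gep_lib))
            weights = read_weights(config.gep_weights_path)
            missing_w = [g for g in gep_set.genes if g not in weights.index]
            if missing_w:
                raise ValueError(f"weight file lacks genes: {missing_w[:5]}")
            weighted = GeneSet(
                gep_set.name, gep_set.genes,
                np.array([weights[g] for g in gep_set.genes]),
            )
            score_cols["gep"] = gep_score(logged, weighted)
        if set(("ASCL1", "NEUROD1", "POU2F3", "YAP1")) <= set(expr.data.index):
            score_cols["subtype"] = call_subtype(logged)["subtype"]
        scores_tab = pd.DataFrame(score_cols)
        write_table(scores_tab, out / "scores.csv", "csv")
        manifest["scores"] = str(out / "scores.csv")
    except Exception as err:
        raise RuntimeError(f"stage 'scores' failed: {err}") from err

    try:
        _stage("comparisons")
        lab = labeling.labels.reindex(scores_tab.index)
        rows = []
        for col in ("ne_score", "cyt", "apm", "gep"):
            if col in scores_tab:
                vals = scores_tab[col].astype(float)
                ok = vals.notna()
                stat, p = group_tests(vals[ok], lab[ok], test="welch_t")
                rows.append({
                    "score": col,
                    "mean_high": float(vals[ok][lab[ok] == "high"].mean()),
                    "mean_low": float(vals[ok][lab[ok] == "low"].mean()),
                    "t": stat, "p": p,
                })
        comparisons = pd.DataFrame(rows).set_index("score")
        if "ne_score" in scores_tab:
            corr = pearson_correlation(
                abundance.table.loc["Fibroblast_marker"].reindex(scores_tab.index),
                scores_tab["ne_score"].astype(float),
            )
            summary["caf_vs_ne_score"] = {"r": corr.r, "p": corr.p_value, "sign": int(np.sign(corr.r))}
            summary["mean_ne_score"] = {
                "high": comparisons.loc["ne_score", "mean_high"],
                "low": comparisons.loc["ne_score", "mean_low"],
                "p": comparisons.loc["ne_score", "p"],
            }
        write_table(comparisons, out / "comparisons.csv", "csv")
        manifest["comparisons"] = str(out / "comparisons.csv")
    except Exception as err:
        raise RuntimeError(f"stage 'comparisons' failed: {err}") from err

    try:
        _stage("gsea")
        gsea_rows = []
        if library is not None:
            gsea_sets = [n for n in ("NE_program", "NonNE_program") if n in library.names()]
            for name in gsea_sets:
                res = gsea_nes(
                    logged, labeling.labels.reindex(logged.sample_ids), library[name],
                    n_perm=config.n_permutations, mode="phenotype",
                    seed=stage_seed(config.seed, "gsea"),
                )
                gsea_rows.append({
                    "set": name, "es": res.es, "nes": res.nes, "p": res.p_value,
                    "mode": res.permutation_mode, "n_perm": res.n_permutations,
                })
            if gsea_rows:
                gsea_tab = pd.DataFrame(gsea_rows).set_index("set")
                write_table(gsea_tab, out / "gsea.csv", "csv")
                manifest["gsea"] = str(out / "gsea.csv")
                summary["nes"] = {r["set"]: r["nes"] for r in gsea_rows}
    except Exception as err:
        raise RuntimeError(f"stage 'gsea' failed: {err}") from err

    try:
        _stage("set_scores")
        if library is not None:
            set_scores = gsva_like_scores(logged, library)
            res = moderated_t(set_scores, labeling.labels.reindex(logged.sample_ids))
            write_table(set_scores, out / "set_scores.tsv", "tsv")
            write_table(res.table, out / "set_comparison.csv", "csv")
            manifest["set_scores"] = str(out / "set_scores.tsv")
            manifest["set_comparison"] = str(out / "set_comparison.csv")
    except Exception as err:
        raise RuntimeError(f"stage 'set_scores' failed: {err}") from err

    try:
        _stage("drugs")
        if config.with_drugs and config.synthetic:
            table = _synthetic_drug_stage(config, cohort, logged, out)
            comp = compare_sensitivity(table, labeling.labels.reindex(logged.sample_ids))
            write_table(comp, out / "drug_comparison.csv", "csv")
            manifest["drug_sensitivity"] = str(out / "drug_sensitivity.csv")
            manifest["drug_comparison"] = str(out / "drug_comparison.csv")
            summary["drug_directions"] = comp["direction"].value_counts().to_dict()
    except Exception as err:
        raise RuntimeError(f"stage 'drugs' failed: {err}") from err

    report = RunReport(
        manifest=manifest, summary=summary, version=__version__, config=config.to_dict()
    )
    (out / "report.json").write_text(report.to_json())
    return report


def _synthetic_drug_stage(
    config: RunConfig, cohort: SyntheticCohort, logged: ExpressionMatrix, out: Path
):
    """Train a small synthetic drug panel and predict on the cohort.

    Half the panel's drugs have causal genes drawn from the fibroblast
    program (their predicted resistance should rise with infiltration),
    half from background genes.
    """
    rng = np.random.default_rng(stage_seed(config.seed, "drugs"))
    caf_genes = list(cohort.caf_markers.genes)
    bg_genes = [g for g in logged.gene_ids if g.startswith("BG")][:200]
    models = []
    from .data import ExpressionMatrix as EM  # local alias for clarity
    for d in range(config.drug_panel_size):
        caf_linked = d % 2 == 0
        pool = caf_genes if caf_linked else bg_genes
        n_genes = 40
        causal = list(pool[:10])
        extra_pool = [g for g in bg_genes if g not in causal]
        gene_ids = causal + [
            g for g in rng.choice(extra_pool, size=n_genes - 10, replace=False)
        ]
        train_seed = int(rng.integers(0, 2**31 - 1))
        train_rng = np.random.default_rng(train_seed)
        lines = [f"CL{i:03d}" for i in range(1, 101)]
        X = train_rng.normal(5.0, 1.0, size=(n_genes, len(lines)))
        w = np.zeros(n_genes)
        w[:10] = np.abs(train_rng.normal(1.0, 0.2, size=10)) if caf_linked else train_rng.normal(0.0, 0.5, size=10)
        y = 1.0 + w @ X + train_rng.normal(0.0, 0.5, size=len(lines))
        train = EM(pd.DataFrame(X, index=gene_ids, columns=lines), scale="log2p1")
        model = fit_ridge_transfer(
            train, pd.Series(y, index=lines), cv_folds=5, seed=train_seed % 1000,
            drug=f"drug_{'caf' if caf_linked else 'bg'}_{d:02d}",
        )
        models.append(model)
    table = predict_sensitivity_table(models, logged)
    write_table(table.scores, out / "drug_sensitivity.csv", "csv")
    return table
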