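"""End-to-end discovery pipeline with recorded seeds and artifacts.

Chains the stages of the serum-metabolomics workflow: cohort simulation
(or loading), spectral bucketing, Pareto scaling, OPLS-DA with
permutation validation and VIP selection, univariate testing over the
VIP-selected metabolites, the logistic biomarker panel and its
cross-validation guard on the univariate-significant set, clinical-score
correlation, and pathway over-representation.  Every stochastic stage
draws its seed deterministically from the global seed plus the stage
name, so any stage can be re-run in isolation, and every artifact is
written with a checksummed manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .clincorr import correlate_panel
from .enrich import hypergeometric_ora, load_builtin_library, pathway_network
from .oplsda import cross_validate, fit_oplsda, permutation_test, vip
from .panel import cv_and_permute, fit_logistic
from .scaling import pareto_scale
from .spectra import exclude_region, intelligent_bucket, normalize_total_area
from .synth import DapsaLink, GroupParams, generate_cohort
from .univariate import compare_groups, relative_concentrations

logger = logging.getLogger("psametab")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "stage_seed"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2 ** 31)


@dataclass
class PipelineConfig:
    """Parameters of every stage plus the global seed.

    Round-trips losslessly through YAML (`to_yaml`/`from_yaml`).
    """

    seed: int = 0
    n_psa: int = 29
    n_hc: int = 33
    simulate: bool = True
    spectra: bool = False
    conc_path: str | None = None
    cohort_path: str | None = None
    bucket_width: float = 0.04
    bucket_looseness: float = 0.5
    bucket_region: tuple[float, float] = (0.80, 8.50)
    exclude: tuple[float, float] = (4.70, 5.20)
    scaling: str = "pareto"
    n_orthogonal: int = 1
    folds: int = 7
    n_permutations: int = 500
    alpha: float = 0.05
    panel_cv: int = 100
    panel_permutations: int = 1000
    positive_class: str = "HC"
    library_path: str | None = None
    out: str | None = None

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["bucket_region"] = list(self.bucket_region)
        d["exclude"] = list(self.exclude)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("bucket_region", "exclude"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class PipelineResult:
    """Bundle of every stage's output."""

    config: PipelineConfig
    cohort: pd.DataFrame
    concentrations: pd.DataFrame
    buckets: object | None
    opls_model: object
    opls_q2: float
    permutation: object
    vip_table: pd.DataFrame
    selected: list[str]
    univariate: pd.DataFrame
    significant: list[str]
    panel_model: object | None
    panel_cv_auc: np.ndarray | None
    panel_permutation_p: float | None
    correlations: pd.DataFrame | None
    enrichment: object | None
    network: object | None
    manifest_path: Path | None = None


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full workflow; see the module docstring for the order.

    With ``simulate=False`` the tabular branch runs on the supplied
    concentration/cohort files; the spectral branch runs only when
    spectra are simulated or supplied.
    """
    cfg = config
    # --- inputs -----------------------------------------------------------
    if cfg.simulate:
        sc = generate_cohort(GroupParams.default(), DapsaLink(),
                             n_psa=cfg.n_psa, n_hc=cfg.n_hc,
                             seed=stage_seed(cfg.seed, "simulate"),
                             spectra=cfg.spectra)
        cohort, conc, spectra = sc.cohort, sc.concentrations, sc.spectra
    else:
        if not (cfg.conc_path and cfg.cohort_path):
            raise ValueError("simulate=False requires conc_path and cohort_path")
        conc = pio.read_concentrations(cfg.conc_path)
        cohort = pio.read_cohort(cfg.cohort_path)
        spectra = None
    logger.info("inputs: %d samples x %d metabolites", *conc.shape)

    # --- spectral branch --------------------------------------------------
    buckets = None
    if spectra is not None:
        buckets = intelligent_bucket(spectra, cfg.bucket_width,
                                     cfg.bucket_looseness, cfg.bucket_region)
        buckets = exclude_region(buckets, *cfg.exclude)
        buckets = normalize_total_area(buckets)
        logger.info("bucketing: %d buckets", buckets.n_buckets)

    # --- multivariate model on the concentration table --------------------
    rel = relative_concentrations(conc)
    y = cohort["group"].to_numpy(str)
    Xs, scale_model = pareto_scale(rel.to_numpy(float), columns=list(rel.columns),
                                   method=cfg.scaling)
    model = fit_oplsda(Xs, y, n_orthogonal=cfg.n_orthogonal,
                       columns=list(rel.columns), scaling=scale_model)
    q2 = cross_validate(rel.to_numpy(float), y, n_orthogonal=cfg.n_orthogonal,
                        folds=cfg.folds, scaling=cfg.scaling)
    model.Q2_cum = q2
    perm = permutation_test(rel.to_numpy(float), y,
                            n_orthogonal=cfg.n_orthogonal, folds=cfg.folds,
                            n_perm=cfg.n_permutations,
                            seed=stage_seed(cfg.seed, "permutation"),
                            scaling=cfg.scaling)
    vip_table = vip(model)
    selected = list(vip_table.index[vip_table["selected"]])
    logger.info("OPLS-DA: R2X=%.3f R2Y=%.3f Q2=%.3f, %d VIP>1",
                model.R2X_cum, model.R2Y_cum, q2, len(selected))

    # --- univariate on the VIP-selected set -------------------------------
    uni = compare_groups(rel, cohort, metabolites=selected or None,
                         alpha=cfg.alpha)
    significant = list(uni.index[uni["significant"]])
    logger.info("univariate: %d significant of %d tested",
                len(significant), len(uni))

    # --- panel + correlation + enrichment on the significant set ----------
    panel_model = cv_auc = perm_p = corr = enr = net = None
    if len(significant) >= 1:
        panel_model = fit_logistic(rel[significant], y,
                                   positive_class=cfg.positive_class)
        cv_auc, perm_p, _ = cv_and_permute(
            rel[significant], y, positive_class=cfg.positive_class,
            n_cv=cfg.panel_cv, n_perm=cfg.panel_permutations,
            seed=stage_seed(cfg.seed, "panel"))
        if "dapsa" in cohort.columns and cohort["dapsa"].notna().any():
            corr = correlate_panel(rel, cohort, significant)
        library = load_builtin_library()
        try:
            enr = hypergeometric_ora(significant, library)
            net = pathway_network(enr)
        except ValueError as exc:
            logger.warning("enrichment skipped: %s", exc)

    result = PipelineResult(config=cfg, cohort=cohort, concentrations=conc,
                            buckets=buckets, opls_model=model, opls_q2=q2,
                            permutation=perm, vip_table=vip_table,
                            selected=selected, univariate=uni,
                            significant=significant, panel_model=panel_model,
                            panel_cv_auc=cv_auc, panel_permutation_p=perm_p,
                            correlations=corr, enrichment=enr, network=net)
    if cfg.out:
        result.manifest_path = _write_artifacts(result, Path(cfg.out))
    return result


def _write_artifacts(res: PipelineResult, outdir: Path) -> Path:
    outdir.mkdir(parents=True, exist_ok=True)
    entries = {}

    def put(name, path):
        entries[name] = path

    pio.write_cohort(res.cohort, outdir / "cohort.tsv")
    put("cohort", outdir / "cohort.tsv")
    pio.write_concentrations(res.concentrations, outdir / "concentrations.tsv")
    put("concentrations", outdir / "concentrations.tsv")
    if res.buckets is not None:
        res.buckets.to_tsv(outdir / "buckets.tsv")
        put("buckets", outdir / "buckets.tsv")
    res.vip_table.to_csv(outdir / "vip.tsv", sep="\t")
    put("vip", outdir / "vip.tsv")
    m = res.opls_model
    scores = pd.DataFrame({"t": m.t}, index=res.cohort.index)
    for a in range(m.n_orthogonal):
        scores[f"t_o{a + 1}"] = m.T_o[:, a]
    scores.to_csv(outdir / "opls_scores.tsv", sep="\t")
    put("opls_scores", outdir / "opls_scores.tsv")
    loadings = pd.DataFrame({"w": m.w, "p": m.p},
                            index=m.columns or range(m.w.size))
    for a in range(m.n_orthogonal):
        loadings[f"w_o{a + 1}"] = m.W_o[:, a]
        loadings[f"p_o{a + 1}"] = m.P_o[:, a]
    loadings.to_csv(outdir / "opls_loadings.tsv", sep="\t")
    put("opls_loadings", outdir / "opls_loadings.tsv")
    res.univariate.to_csv(outdir / "univariate.tsv", sep="\t")
    put("univariate", outdir / "univariate.tsv")
    model_summary = {
        "components": f"1P + {res.opls_model.n_orthogonal}O",
        "R2X_cum": res.opls_model.R2X_cum,
        "R2Y_cum": res.opls_model.R2Y_cum,
        "Q2_cum": res.opls_q2,
        "R2_intercept": res.permutation.R2_intercept,
        "Q2_intercept": res.permutation.Q2_intercept,
        "n_permutations": res.permutation.n_permutations,
        "vip_selected": res.selected,
    }
    if res.panel_model is not None:
        model_summary["panel"] = {
            "intercept": res.panel_model.intercept,
            "coefficients": res.panel_model.coefficients.to_dict(),
            "threshold": res.panel_model.threshold,
            "auc": res.panel_model.auc,
            "auc_ci": list(res.panel_model.auc_ci),
            "cv_auc_mean": float(np.mean(res.panel_cv_auc)),
            "permutation_p": res.panel_permutation_p,
        }
    (outdir / "model.json").write_text(json.dumps(model_summary, indent=2))
    put("model", outdir / "model.json")
    if res.correlations is not None:
        res.correlations.to_csv(outdir / "dapsa_correlations.tsv", sep="\t")
        put("dapsa_correlations", outdir / "dapsa_correlations.tsv")
    if res.enrichment is not None:
        res.enrichment.table.to_csv(outdir / "enrichment.tsv", sep="\t")
        put("enrichment", outdir / "enrichment.tsv")
        edges = [{"a": a, "b": b, "shared": d["weight"]}
                 for a, b, d in res.network.edges(data=True)]
        (outdir / "network_edges.tsv").write_text(
            "a\tb\tshared\n" + "\n".join(
                f"{e['a']}\t{e['b']}\t{e['shared']}" for e in edges) + "\n")
        put("network", outdir / "network_edges.tsv")
    res.config.to_yaml(outdir / "config.yaml")
    put("config", outdir / "config.yaml")
    seeds = {stage: stage_seed(res.config.seed, stage)
             for stage in ("simulate", "permutation", "panel")}
    return pio.write_manifest(outdir, entries,
                              extra={"seed": res.config.seed, "stage_seeds": seeds})
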