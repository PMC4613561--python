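"""End-to-end orchestration: simulate -> preprocess -> fit -> validate -> report.

A run executes, for each comparison pair (lesion vs healthy adjacent tissue,
malignant vs benign by default), the full discrimination analysis: PCA for
clustering inspection, OPLS-DA, stratified 7-fold cross-validation, CV-ANOVA,
ROC from the cross-validated predicted y values, correlation-scaled loadings
and the metabolite change table. Fatty-acid and glutathione tables (if
generated or supplied) are summarized and compared pairwise.

Every run writes a manifest JSON recording the configuration hash, seed,
package version and all artifact paths; reruns with the same configuration
and seed are bit-identical apart from the timestamp.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .biomarkers import (build_change_table, compare_groups_univariate,
                         correlation_loadings, format_change_table)
from .chemometrics import fit_oplsda, fit_pca
from .errors import ValidationError
from .fatty_acids import FattyAcidTable, compare_groups, composition_summary
from .preprocess import (DEFAULT_BUCKET_WIDTH, DEFAULT_PPM_RANGE,
                         DEFAULT_WATER_REGION, BucketTable, preprocess,
                         read_tidy_spectra)
from .simulate import (SimulationConfig, generate_fatty_acid_table,
                       generate_glutathione_table, generate_spectra,
                       spectra_to_tidy_csv)
from .validation import cross_validate, cv_anova, model_summary, roc_curve

logger = logging.getLogger(__name__)

DEFAULT_COMPARISONS = (("lesion", "healthy"), ("malignant", "benign"))


@dataclass
class PipelineConfig:
    """Run configuration; defaults are the published analysis parameters
    (0.004 ppm buckets over delta 0.5-9.0, water window delta 4.20-5.20,
    7-fold CV, alpha 0.05) applied to the default simulated cohort."""

    spectra_csv: str | None = None  # tidy CSV input; None -> simulate
    fatty_acid_csv: str | None = None
    simulate: bool = True
    group_sizes: tuple[int, int, int] = (46, 25, 28)
    tissue_mode: str = "intact"
    noise_sd: float = 2.0
    effect_magnitude: float = 0.5
    bucket_width: float = DEFAULT_BUCKET_WIDTH
    ppm_range: tuple[float, float] = DEFAULT_PPM_RANGE
    water_region: tuple[float, float] = DEFAULT_WATER_REGION
    normalization: str | None = None  # None -> by tissue mode
    comparisons: tuple = DEFAULT_COMPARISONS
    n_ortho: int = 1
    k_folds: int = 7
    alpha: float = 0.05
    seed: int = 0
    out_dir: str = "thyromet_run"
    plots: bool = True
    with_fatty_acids: bool = True
    with_glutathione: bool = True

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValidationError("k_folds must be >= 2")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) \
            else json.loads(text)
        cfg = cls(**data)
        for key in ("group_sizes", "ppm_range", "water_region"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        cfg.comparisons = tuple(tuple(c) for c in cfg.comparisons)
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _comparison_mask(groups: np.ndarray, pair: tuple[str, str]) -> tuple[np.ndarray, np.ndarray]:
    """Boolean mask + binary labels for one comparison; 'lesion' pools the
    benign and malignant groups."""
    expand = {"lesion": ("benign", "malignant")}
    sets = [expand.get(g, (g,)) for g in pair]
    m0 = np.isin(groups, sets[1])  # reference class -> 0
    m1 = np.isin(groups, sets[0])  # case class -> 1
    mask = m0 | m1
    return mask, m1[mask].astype(int)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return the manifest dict (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def save(name: str, writer) -> Path:
        path = out / name
        writer(path)
        artifacts[name] = str(path)
        return path

    # --- inputs -----------------------------------------------------------
    truth = None
    if config.spectra_csv is not None:
        spectra = read_tidy_spectra(config.spectra_csv, tissue_mode=config.tissue_mode)
        logger.info("loaded %d spectra from %s", len(spectra), config.spectra_csv)
    else:
        sim = SimulationConfig(group_sizes=config.group_sizes,
                               noise_sd=config.noise_sd, seed=config.seed,
                               ppm_range=config.ppm_range,
                               tissue_mode=config.tissue_mode)
        from .simulate import default_effects
        effects = default_effects(config.effect_magnitude, config.tissue_mode)
        spectra, truth = generate_spectra(sim, effects=effects)
        logger.info("simulated %d spectra (seed %d)", len(spectra), config.seed)
        save("spectra.csv", lambda p: spectra_to_tidy_csv(spectra, p))
        save("ground_truth.json", truth.to_json)

    # --- preprocessing ----------------------------------------------------
    table = preprocess(spectra, width=config.bucket_width,
                       ppm_range=config.ppm_range,
                       water_region=config.water_region,
                       normalization=config.normalization)
    save("bucket_table.csv", table.to_csv)
    artifacts["bucket_table.csv.json"] = str(out / "bucket_table.csv.json")

    # --- PCA on the full table --------------------------------------------
    pca = fit_pca(table, n_components=3)
    import pandas as pd
    save("pca_scores.csv", lambda p: pd.DataFrame(
        pca.scores, columns=[f"PC{i+1}" for i in range(pca.scores.shape[1])]
    ).assign(sample_id=table.sample_ids, group=table.groups).to_csv(p, index=False))
    if config.plots:
        from .plots import scores_plot
        save("pca_scores.svg", lambda p: scores_plot(
            pca.scores, table.groups, title="PCA scores", path=p))

    # --- per-comparison OPLS-DA -------------------------------------------
    summaries = {}
    for pair in config.comparisons:
        name = f"{pair[0]}_vs_{pair[1]}"
        mask, y = _comparison_mask(table.groups, pair)
        if mask.sum() < 4 or len(set(y.tolist())) < 2:
            raise ValidationError(f"comparison {name}: not enough samples per class")
        sub = table.subset(mask)
        model = fit_oplsda(sub, y, n_ortho=config.n_ortho)
        cv = cross_validate(sub, y, n_ortho=config.n_ortho, K=config.k_folds,
                            seed=config.seed)
        anova = cv_anova(cv, n_ortho=config.n_ortho)
        roc = roc_curve(y, cv.y_pred_cv)
        summary = model_summary(model, cv, anova, roc)
        summaries[name] = summary

        report = correlation_loadings(model, sub, alpha=config.alpha)
        changes = build_change_table(report, comparison=name)

        save(f"oplsda_{name}.json", model.to_json)
        save(f"cv_{name}.csv", lambda p, cv=cv: cv.to_frame().to_csv(p, index=False))
        save(f"roc_{name}.csv", lambda p, roc=roc: roc.to_frame().to_csv(p, index=False))
        save(f"loadings_{name}.csv",
             lambda p, r=report: r.to_frame().to_csv(p, index=False))
        save(f"changes_{name}.csv",
             lambda p, c=changes: c.to_csv(p, index=False))
        save(f"changes_{name}_display.csv",
             lambda p, c=changes: format_change_table(c).to_csv(p, index=False))
        save(f"summary_{name}.json",
             lambda p, s=summary: Path(p).write_text(json.dumps(s, indent=1)))
        if config.plots:
            from .plots import coefficient_plot, roc_plot, scores_plot
            t_all = np.column_stack([model.t, model.T_o[:, 0] if model.n_ortho
                                     else np.zeros_like(model.t)])
            save(f"scores_{name}.svg", lambda p, s=t_all, g=sub.groups:
                 scores_plot(s, g, title=f"OPLS-DA scores {name}", path=p))
            save(f"coefficients_{name}.svg", lambda p, r=report:
                 coefficient_plot(r, title=name, path=p))
            save(f"roc_{name}.svg", lambda p, r=roc:
                 roc_plot(r, title=name, path=p))
        logger.info("%s: R2X=%.3f R2Y=%.3f Q2=%.3f p=%.2e AUC=%.3f", name,
                    summary["R2X"], summary["R2Y"], summary["Q2"],
                    summary["cv_anova_p"], summary["auc"])

    # --- fatty acids -------------------------------------------------------
    if config.fatty_acid_csv is not None or (config.simulate and config.with_fatty_acids
                                             and config.spectra_csv is None):
        if config.fatty_acid_csv is not None:
            fa = FattyAcidTable.from_csv(config.fatty_acid_csv)
        else:
            fa, _ = generate_fatty_acid_table(SimulationConfig(
                group_sizes=config.group_sizes, seed=config.seed))
            save("fatty_acids.csv", fa.to_csv)
        fa_summary = composition_summary(fa)
        fa_tests = compare_groups(fa_summary, alpha=config.alpha)
        save("fatty_acid_summary.json", lambda p: Path(p).write_text(
            json.dumps(fa_summary.group_summary(), indent=1)))
        save("fatty_acid_tests.csv", lambda p: fa_tests.to_csv(p, index=False))
        if config.plots:
            from .plots import fatty_acid_panel
            save("fatty_acid_panel.svg",
                 lambda p: fatty_acid_panel(fa_summary, path=p))

    # --- glutathione -------------------------------------------------------
    if config.simulate and config.with_glutathione and config.spectra_csv is None:
        gsh = generate_glutathione_table(SimulationConfig(
            group_sizes=config.group_sizes, seed=config.seed))
        save("glutathione.csv", lambda p: gsh.to_csv(p, index=False))
        gsh_tests = compare_groups_univariate(gsh, ["GSH", "GSSG"],
                                              alpha=config.alpha)
        save("glutathione_tests.csv", lambda p: gsh_tests.to_csv(p, index=False))

    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "summaries": summaries,
        "artifacts": artifacts,
        "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
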