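"""End-to-end orchestration: simulate -> phenotype -> rank -> model -> validate.

A single global seed is fanned out to per-stage substreams via
``numpy.random.SeedSequence`` so each stage is independently reproducible.
All artifacts are written as CSV/JSON (YAML for configs).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from audiotwin import bivariate as biv
from audiotwin import phenotypes as ph
from audiotwin import univariate as uni
from audiotwin import validation as val
from audiotwin.cohort import TwinCohort, read_cohort, write_cohort
from audiotwin.simulate import SimConfig, repeat_measurement, simulate_cohort

logger = logging.getLogger(__name__)

STAGES = ("simulate", "phenotype", "rank", "univariate", "bivariate", "validate")


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    log_offset: float = 25.0
    log_base: float = 10.0
    pca_components: int | None = None
    models: tuple[str, ...] = ("ACE", "AE", "CE", "E")
    phenotypes: tuple[str, ...] = ph.PHENOTYPE_COLUMNS
    compute_ci: bool = True
    n_restarts: int = 5
    run_snr_stages: bool = True
    reference_rules: tuple[dict, ...] = ({"pta_gt": 40.0}, {"pc_diff_gt": 3.4})
    repeat_n: int = 17
    repeat_noise_sd: float = 0.5
    snr_transform: str = "cuberoot"
    out_dir: str = "audiotwin_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", {})
        if "var_components" in sim_raw:
            sim_raw["var_components"] = {
                k: tuple(v) for k, v in sim_raw["var_components"].items()
            }
        for key in ("age_range", "freqs", "mean_profile", "age_slope",
                    "size_loadings", "slope_loadings", "srt_params"):
            if key in sim_raw:
                sim_raw[key] = tuple(sim_raw[key])
        cfg = cls(sim=SimConfig(**sim_raw))
        for k, v in raw.items():
            if not hasattr(cfg, k):
                raise ValueError(f"unknown config key {k!r}")
            if k in ("models", "phenotypes"):
                v = tuple(v)
            if k == "reference_rules":
                v = tuple(v)
            setattr(cfg, k, v)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


@dataclass
class ReportBundle:
    cohort_summary: pd.DataFrame | None = None
    ranking: pd.DataFrame | None = None
    snr_summary: pd.DataFrame | None = None
    univariate: pd.DataFrame | None = None
    bivariate: list[dict] = field(default_factory=list)
    validation: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _summarize_cohort(table: pd.DataFrame) -> pd.DataFrame:
    rows = []
    groups = list(table.groupby("zygosity")) + [("total", table)]
    for zyg, grp in groups:
        row = {"zygosity": zyg, "n": len(grp)}
        row["age_min"] = grp["age"].min()
        row["age_max"] = grp["age"].max()
        row["mean_age"] = grp["age"].mean()
        for col in ("pta", "pc1", "pc2", "pc1_minus_pc2", "behl", "snr"):
            if col in grp:
                row[f"mean_{col}"] = grp[col].mean()
                row[f"sd_{col}"] = grp[col].std(ddof=1)
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig, cohort: TwinCohort | None = None) -> ReportBundle:
    """Execute all stages in dependency order and return a report bundle."""
    seeds = np.random.SeedSequence(config.seed).spawn(len(STAGES))
    stage_seed = {name: int(s.generate_state(1)[0] % (2**31)) for name, s in
                  zip(STAGES, seeds)}
    bundle = ReportBundle()
    bundle.metadata = {
        "seed": config.seed,
        "stage_seeds": stage_seed,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }

    def timed(stage):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s: start (seed %d)", stage, stage_seed[stage])
                return self

            def __exit__(self, exc_type, exc, tb):
                dt = time.perf_counter() - self.t0
                bundle.metadata["stages"][stage] = round(dt, 3)
                if exc is not None:
                    logger.error("stage %s failed after %.2fs", stage, dt)
                    raise StageError(stage, exc) from exc
                logger.info("stage %s: done in %.2fs", stage, dt)
                return False

        return _Timer()

    # -- simulate ----------------------------------------------------------
    with timed("simulate"):
        if cohort is None:
            sim_cfg = dataclasses.replace(config.sim, seed=stage_seed["simulate"])
            cohort = simulate_cohort(sim_cfg)
        bundle.metadata["n_subjects"] = len(cohort)

    # -- phenotype ---------------------------------------------------------
    with timed("phenotype"):
        matrix = ph.audiogram_matrix(cohort, offset=config.log_offset, base=config.log_base)
        pca = ph.fit_pca(matrix, n_components=config.pca_components)
        if pca.n_retained < 2:
            pca = ph.fit_pca(matrix, n_components=2)
        table = ph.build_phenotypes(cohort, pca, offset=config.log_offset,
                                    base=config.log_base)
        bundle.cohort_summary = _summarize_cohort(table)
        kw = {}
        for col in ("age", "pta", "pc1", "pc2", "pc1_minus_pc2", "behl"):
            h, p = ph.kruskal_wallis(table[col].to_numpy(), table["zygosity"].to_numpy())
            kw[col] = {"H": h, "p": p}
        bundle.validation["kruskal_wallis_by_zygosity"] = kw
        bundle.metadata["pca_eigenvalues"] = [float(v) for v in pca.eigenvalues]
        bundle.metadata["pca_var_explained"] = [float(v) for v in pca.var_explained]

    # -- rank --------------------------------------------------------------
    with timed("rank"):
        bundle.ranking = ph.rank_phenotypes(table, phenotypes=config.phenotypes,
                                            seed=stage_seed["rank"])

    # -- univariate --------------------------------------------------------
    with timed("univariate"):
        rows = []
        for col in config.phenotypes:
            adj = uni.age_adjust(table, col)
            work = table.copy()
            adj_col = f"{col}_age_adj"
            work[adj_col] = adj
            fits = {}
            for model in config.models:
                fits[model] = uni.fit_univariate(
                    work, adj_col, model=model,
                    compute_ci=config.compute_ci and model in ("ACE", "AE"),
                    n_restarts=config.n_restarts, seed=stage_seed["univariate"],
                )
            full = fits.get("ACE")
            for model, fit in fits.items():
                row = {
                    "phenotype": col,
                    "model": model,
                    "minus2logl": fit.minus2logl,
                    "df": fit.df,
                    "a2": fit.components.a2,
                    "c2": fit.components.c2,
                    "e2": fit.components.e2,
                }
                if fit.ci95:
                    for k, (lo, hi) in fit.ci95.items():
                        row[f"{k}_lo"], row[f"{k}_hi"] = lo, hi
                if full is not None and model != "ACE":
                    cmp_ = uni.compare_models(full, fit)
                    row.update(
                        delta_minus2logl=cmp_.delta_minus2logl,
                        delta_df=cmp_.delta_df,
                        p_value=cmp_.p_value,
                        aic=cmp_.aic,
                    )
                rows.append(row)
        bundle.univariate = pd.DataFrame(rows)

    # -- bivariate ---------------------------------------------------------
    if not config.run_snr_stages or table["snr"].notna().sum() == 0:
        bundle.skipped["bivariate"] = "SNR stages disabled or no SNR data"
        bundle.skipped["validate"] = "SNR stages disabled or no SNR data"
        bundle.metadata["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        bundle._cohort = cohort
        bundle._table = table
        return bundle

    with timed("bivariate"):
        work = table.copy()
        snr_t, meta = biv.cubic_transform(work["snr"].to_numpy(), mode=config.snr_transform)
        work["snr_t"] = snr_t
        work["snr_adj"] = uni.age_adjust(work, "snr_t")
        for trait in ("pta", "pc1_minus_pc2"):
            work[f"{trait}_adj"] = uni.age_adjust(work, trait)
            fit = biv.fit_bivariate(
                work, f"{trait}_adj", "snr_adj",
                n_restarts=config.n_restarts, seed=stage_seed["bivariate"],
            )
            bundle.bivariate.append(
                {
                    "trait_x": trait,
                    "trait_y": "snr",
                    "snr_transform": meta,
                    "a2_x": fit.a_x**2,
                    "e2_x": fit.e_x**2,
                    "a2_y": fit.a_y**2,
                    "e2_y": fit.e_y**2,
                    "r_a": fit.r_a,
                    "r_e": fit.r_e,
                    "r_p": fit.r_p,
                    "prop_genetic_pct": biv.genetic_share(fit)
                    if abs(fit.r_p) > 1e-12
                    else None,
                    "minus2logl": fit.minus2logl,
                    "df": fit.df,
                }
            )

    # -- validate ----------------------------------------------------------
    with timed("validate"):
        scores = table["snr"].to_numpy(dtype=float)
        mask = np.isfinite(scores)
        for rule in config.reference_rules:
            labels = val.binary_reference(table[mask], rule)
            if labels.sum() == 0 or labels.sum() == len(labels):
                bundle.validation[f"roc_{list(rule)[0]}"] = {
                    "skipped": "single-class reference"
                }
                continue
            curve = val.roc(scores[mask], labels, reference_rule=str(rule))
            point = val.best_operating_point(curve)
            bundle.validation[f"roc_{list(rule)[0]}"] = {
                "rule": rule,
                "auc": curve.auc,
                "best_cutoff": point.cutoff,
                "sensitivity": point.sensitivity,
                "specificity": point.specificity,
                "youden_j": point.youden_j,
                "curve": {
                    "cutoff": curve.thresholds.tolist(),
                    "sensitivity": curve.sensitivity.tolist(),
                    "specificity": curve.specificity.tolist(),
                },
            }
        rng = np.random.default_rng(stage_seed["validate"])
        with_snr = [r for r in cohort.records if r.snr is not None]
        idx = rng.choice(len(with_snr), size=min(config.repeat_n, len(with_snr)),
                         replace=False)
        sub = TwinCohort(
            records=[
                dataclasses.replace(with_snr[i], zygosity="singleton",
                                    pair_id=f"RT{i:04d}")
                for i in sorted(idx)
            ],
            freqs=cohort.freqs,
            config="observed",
        )
        repeats = repeat_measurement(sub, noise_sd=config.repeat_noise_sd,
                                     seed=stage_seed["validate"])
        if len(repeats) >= 3:
            ba = val.bland_altman(repeats["first"], repeats["second"])
            bundle.validation["bland_altman"] = dataclasses.asdict(ba)
        bundle.validation["correlations"] = val.correlate_tests(table).to_dict("records")
        bundle.snr_summary = _summarize_cohort(table[table["snr"].notna()])

    bundle.metadata["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    bundle._cohort = cohort  # retained for write_report
    bundle._table = table
    return bundle


def write_report(bundle: ReportBundle, out_dir: str | Path) -> Path:
    """Write every bundle section as CSV/JSON under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if getattr(bundle, "_cohort", None) is not None:
        write_cohort(bundle._cohort, out / "cohort.csv")
    if getattr(bundle, "_table", None) is not None:
        bundle._table.to_csv(out / "phenotypes.csv", index=False)
    for name in ("cohort_summary", "ranking", "snr_summary", "univariate"):
        frame = getattr(bundle, name)
        if frame is not None:
            frame.to_csv(out / f"{name}.csv", index=False)
    with open(out / "bivariate.json", "w") as fh:
        json.dump(bundle.bivariate, fh, indent=2, default=float)
    with open(out / "validation.json", "w") as fh:
        json.dump(bundle.validation, fh, indent=2, default=float)
    meta = dict(bundle.metadata)
    meta["skipped"] = bundle.skipped
    with open(out / "metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2, default=float)
    return out
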