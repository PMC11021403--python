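"""Readers/writers, configuration and end-to-end pipeline orchestration.

The pipeline reproduces the full analysis order on synthetic or
user-supplied data: hierarchical discounting fits (frame and magnitude
models), predictive-accuracy evaluation, framing-effect tests, factor
extraction from the questionnaire items, and the association layer. Every
artifact is recorded in a manifest carrying the seed and a config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import associations as assoc
from . import effects as eff
from . import factors as fac
from .cohort import CohortConfig, FACTORS, generate_cohort
from .discounting import (
    CHOICE_COLUMNS,
    fit_hierarchical,
    point_estimates,
    validate_choice_table,
)

log = logging.getLogger("tempdisc")


def read_choice_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a long choice table (CSV or TSV by extension)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    table = pd.read_csv(path, sep=sep)
    return validate_choice_table(table)


def write_choice_table(table: pd.DataFrame, path: str | Path) -> None:
    validate_choice_table(table)
    table[CHOICE_COLUMNS].to_csv(path, index=False)


def write_cohort(cohort: pd.DataFrame, codebook: pd.DataFrame, path: str | Path) -> None:
    """Cohort CSV with a sidecar YAML codebook mapping items to scales/factors."""
    path = Path(path)
    cohort.to_csv(path, index=False)
    sidecar = path.with_suffix(".codebook.yaml")
    entries = codebook.to_dict(orient="records")
    sidecar.write_text(yaml.safe_dump({"items": entries}, sort_keys=False))


@dataclass
class PipelineConfig:
    """Settings for one pipeline run."""

    seed: int = 0
    out_dir: str = "results/run"
    choices_path: str | None = None      # if None, a synthetic cohort is generated
    cohort_path: str | None = None
    cohort: dict = field(default_factory=dict)   # CohortConfig overrides
    family: str = "hyperbolic"
    mcmc: dict = field(default_factory=lambda: {"chains": 4, "warmup": 1000, "draws": 1000})
    best_iterations: int = 30_000
    n_boot: int = 0                      # bootstrap loading CIs (0 = skip)
    hc_type: str = "HC3"
    max_factor_items: int | None = None  # subsample items for quick runs
    run_loo: bool = False
    n_factors: int | None = None         # None = CNG-selected

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        valid = set(cls.__dataclass_fields__)
        unknown = sorted(set(d) - valid)
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {unknown}")
        return cls(**d)

    def config_hash(self) -> str:
        js = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(js.encode()).hexdigest()[:12]


def _descriptives(df: pd.DataFrame) -> pd.DataFrame:
    from scipy.stats import skew

    rows = []
    for c in df.columns:
        x = df[c].dropna().to_numpy(dtype=float)
        mask = assoc.exclude_outliers(x) if x.std(ddof=1) > 0 else np.ones(x.size, bool)
        x = x[mask]
        rows.append(
            {
                "variable": c,
                "n": x.size,
                "min": x.min(),
                "max": x.max(),
                "mean": x.mean(),
                "sd": x.std(ddof=1),
                "skewness": skew(x, bias=False),
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages in order; returns the run directory.

    Stage failures abort with the stage name; artifacts produced by earlier
    stages are left in place.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "pipeline.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    manifest: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "stages": {},
        "artifacts": {},
    }
    rng = np.random.default_rng(config.seed)

    def _register(name: str, path: Path, stage: str, **params) -> None:
        manifest["artifacts"][str(path.name)] = {"stage": stage, **params}

    stage = "setup"
    try:
        t0 = time.time()
        # ---------------------------------------------------------- data
        stage = "data"
        if config.choices_path:
            choices = read_choice_table(config.choices_path)
            cohort_tab = pd.read_csv(config.cohort_path) if config.cohort_path else None
            codebook = None
        else:
            cc = CohortConfig.from_dict(config.cohort) if config.cohort else CohortConfig()
            sim = generate_cohort(cc, seed=config.seed)
            choices, cohort_tab, codebook = sim["choices"], sim["cohort"], sim["codebook"]
            write_choice_table(choices, out / "choices.csv")
            write_cohort(cohort_tab, codebook, out / "cohort.csv")
            _register("data", out / "choices.csv", stage, seed=config.seed)
            _register("data", out / "cohort.csv", stage, seed=config.seed)
        if cohort_tab is not None and "attention_check_fail" in cohort_tab:
            keep = ~cohort_tab["attention_check_fail"].astype(bool)
            kept_ids = set(cohort_tab.loc[keep, "participant_id"])
            log.info("attention-check exclusion: %d of %d retained", keep.sum(), len(keep))
            cohort_tab = cohort_tab.loc[keep].reset_index(drop=True)
            choices = choices[choices["participant_id"].isin(kept_ids)].reset_index(drop=True)
        manifest["stages"]["data"] = round(time.time() - t0, 2)

        # ----------------------------------------------------------- fits
        stage = "fit_frame"
        t0 = time.time()
        fit_frame = fit_hierarchical(
            choices, family=config.family, condition_var="frame",
            mcmc_opts=config.mcmc, seed=int(rng.integers(2**31)),
        )
        if not fit_frame.converged:
            log.warning("frame model: max R-hat %.3f", fit_frame.diagnostics["max_rhat"])
        fit_frame.summary().to_csv(out / "posterior_summary_frame.csv", index=False)
        manifest["stages"]["fit_frame"] = round(time.time() - t0, 2)

        stage = "fit_magnitude"
        t0 = time.time()
        fit_mag = fit_hierarchical(
            choices, family=config.family, condition_var="magnitude_band",
            mcmc_opts=config.mcmc, seed=int(rng.integers(2**31)),
        )
        fit_mag.summary().to_csv(out / "posterior_summary_magnitude.csv", index=False)
        manifest["stages"]["fit_magnitude"] = round(time.time() - t0, 2)

        stage = "point_estimates"
        t0 = time.time()
        est = point_estimates(fit_frame)
        est_mag = point_estimates(fit_mag)
        est = est.merge(
            est_mag[["participant_id"] + [c for c in est_mag.columns
                                          if c.startswith("ln_k_") or c == "me"]],
            on="participant_id",
        )
        est.to_csv(out / "estimates.csv", index=False)
        _register("estimates", out / "estimates.csv", stage)
        manifest["stages"]["point_estimates"] = round(time.time() - t0, 2)

        if config.run_loo:
            stage = "model_eval"
            t0 = time.time()
            from .model_eval import psis_loo

            loo_f = psis_loo(fit_frame.log_likelihood())
            loo_m = psis_loo(fit_mag.log_likelihood())
            (out / "loo.json").write_text(json.dumps({
                "frame": {"elpd": loo_f.elpd_estimate, "se": loo_f.se,
                          "flagged_k": loo_f.n_flagged},
                "magnitude": {"elpd": loo_m.elpd_estimate, "se": loo_m.se,
                              "flagged_k": loo_m.n_flagged},
            }, indent=1))
            manifest["stages"]["model_eval"] = round(time.time() - t0, 2)

        # -------------------------------------------------------- effects
        stage = "framing_effects"
        t0 = time.time()
        reports = []
        dde = est["dde"].to_numpy()
        best_seed = int(rng.integers(2**31))
        reports.append(
            eff.FramingTestReport(
                label="date_delay_effect",
                best=eff.best_paired(dde, iterations=config.best_iterations, seed=best_seed),
                paired=eff.paired_t(est["ln_k_delay"].to_numpy(), est["ln_k_date"].to_numpy()),
            )
        )
        mags = est[["ln_k_small", "ln_k_medium", "ln_k_large"]]
        reports.append(
            eff.FramingTestReport(
                label="magnitude_small_vs_medium",
                best=eff.best_paired(
                    (est["ln_k_small"] - est["ln_k_medium"]).to_numpy(),
                    iterations=config.best_iterations, seed=best_seed + 1,
                ),
            )
        )
        reports.append(
            eff.FramingTestReport(
                label="magnitude_medium_vs_large",
                best=eff.best_paired(
                    (est["ln_k_medium"] - est["ln_k_large"]).to_numpy(),
                    iterations=config.best_iterations, seed=best_seed + 2,
                ),
            )
        )
        reports.append(
            eff.FramingTestReport(label="magnitude_anova", anova=eff.rm_anova(mags))
        )
        (out / "effects.json").write_text(
            json.dumps([r.to_dict() for r in reports], indent=1)
        )
        manifest["stages"]["framing_effects"] = round(time.time() - t0, 2)

        # -------------------------------------------------------- factors
        scores = None
        if codebook is not None:
            stage = "hetcor_factors"
            t0 = time.time()
            item_cols = list(codebook["item"])
            if config.max_factor_items:
                per = max(1, config.max_factor_items // codebook["scale"].nunique())
                item_cols = list(
                    codebook.groupby("scale", sort=False).head(per)["item"]
                )
            table = cohort_tab[item_cols]
            var_types = {c: "ordinal" for c in item_cols}
            het = fac.hetcor_matrix(table, var_types)
            het.to_frame().to_csv(out / "hetcor.csv")
            pd.DataFrame({"eigenvalue": het.eigenvalues}).to_csv(
                out / "eigenvalues.csv", index=False
            )
            nf = config.n_factors or fac.cng_factor_count(het.eigenvalues)
            labels = FACTORS[:nf] if nf <= 3 else [f"F{j+1}" for j in range(nf)]
            sol = fac.fit_ml_efa(het, nf, labels=labels)
            sol.loadings.to_csv(out / "loadings.csv")
            scores = fac.factor_scores(sol, table)
            scores.insert(0, "participant_id", cohort_tab["participant_id"].to_numpy())
            scores.to_csv(out / "factor_scores.csv", index=False)
            if config.n_boot:
                cis = fac.bootstrap_loading_cis(
                    table, var_types, nf, n_boot=config.n_boot,
                    seed=int(rng.integers(2**31)), reference=sol,
                )
                cis.to_csv(out / "loading_cis.csv")
            manifest["stages"]["hetcor_factors"] = round(time.time() - t0, 2)

        # ---------------------------------------------------- associations
        if cohort_tab is not None and codebook is not None:
            stage = "associations"
            t0 = time.time()
            sums = {}
            for scale, grp in codebook.groupby("scale", sort=False):
                cols = [c for c in grp["item"] if c in cohort_tab.columns]
                sums[scale] = cohort_tab[cols].sum(axis=1)
            scales_tab = pd.DataFrame(sums)
            td = est.set_index("participant_id").loc[
                cohort_tab["participant_id"], ["ln_k_delay", "ln_k_date"]
            ].reset_index(drop=True)
            corr_tab = assoc.pearson_with_holm(td, scales_tab)
            extra = est.set_index("participant_id").loc[
                cohort_tab["participant_id"], ["dde", "me", "waic"]
            ].reset_index(drop=True)
            corr_extra = assoc.pearson_with_holm(extra, scales_tab)
            corr_extra["p_c"] = corr_extra["p"]  # single-DV analyses: uncorrected
            pd.concat([corr_tab, corr_extra]).to_csv(out / "correlations.csv", index=False)

            gender = pd.get_dummies(cohort_tab["gender"]).reindex(
                columns=["male", "diverse"], fill_value=0
            )
            covars = pd.DataFrame(
                {
                    "age": cohort_tab["age"],
                    "gender1": gender["male"],
                    "gender2": gender["diverse"],
                    "cognitive_ability": cohort_tab["cognitive_ability"],
                }
            )
            # drop unrepresented categories (e.g. no 'diverse' respondents)
            covars = covars.loc[:, covars.nunique() > 1]
            reg_rows = []
            predictors = {s: scales_tab[s] for s in scales_tab.columns}
            if scores is not None:
                for f in [c for c in scores.columns if c != "participant_id"]:
                    predictors[f"factor_{f}"] = scores[f]
            for pname, pvals in predictors.items():
                fits = []
                for dv in ["ln_k_delay", "ln_k_date"]:
                    X = covars.copy()
                    X[pname] = pvals.to_numpy()
                    y = td[dv].to_numpy()
                    mask = assoc.exclude_outliers(y) & assoc.exclude_outliers(
                        pvals.to_numpy()
                    )
                    fits.append(
                        assoc.robust_ols(
                            y[mask], X.loc[mask], hc_type=config.hc_type, outcome=dv
                        )
                    )
                assoc.holm_across_outcomes(fits)
                for f in fits:
                    row = f.table[f.table["term"] == pname].iloc[0]
                    reg_rows.append(
                        {
                            "outcome": f.outcome,
                            "predictor": pname,
                            "beta": row["beta"],
                            "se": row["se"],
                            "ci_low": row["ci_low"],
                            "ci_high": row["ci_high"],
                            "p": row["p"],
                            "p_c": row["p_c"],
                            "breusch_pagan_p": f.breusch_pagan_p,
                            "n": f.n,
                        }
                    )
            pd.DataFrame(reg_rows).to_csv(out / "regressions.csv", index=False)
            manifest["stages"]["associations"] = round(time.time() - t0, 2)

        # -------------------------------------------------------- summary
        stage = "summary"
        t0 = time.time()
        desc_cols = [c for c in est.columns if c != "participant_id"]
        _descriptives(est[desc_cols]).to_csv(out / "descriptives.csv", index=False)
        manifest["stages"]["summary"] = round(time.time() - t0, 2)
    except Exception as exc:
        log.error("stage %s failed: %s", stage, exc)
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        log.removeHandler(fh)
        fh.close()

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return out
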