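"""End-to-end pipeline: simulate -> fit both models -> compare -> report."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path


from . import io as ub_io
from .cohort import CohortConfig, simulate_cohort
from .inference import (
    correlate_components_with_bias,
    group_bias_hdi,
    pca_varimax,
    ppc_bias_vs_empirical,
)
from .model import MCMCSettings, ModelSpec, check_convergence, extract_bias, fit_model
from .model_selection import compare_models, kfold_elpd, kfold_split

logger = logging.getLogger("updatebias")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of a full reproducible run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    profile: str = "ci"
    k_folds: int = 10
    compare: bool = True
    seed_simulate: int = 1
    seed_fit: int = 2
    seed_compare: int = 3
    out_dir: str = "run"

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "cohort": dataclasses.asdict(self.cohort),
                "profile": self.profile,
                "k_folds": self.k_folds,
                "compare": self.compare,
                "seeds": [self.seed_simulate, self.seed_fit, self.seed_compare],
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception:
                logger.exception("stage %s: FAILED", name)
                raise RuntimeError(f"pipeline stage '{name}' failed") from None
            logger.info("stage %s: done in %.1fs", name, time.perf_counter() - t0)
            return out

        return wrapped

    return deco


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis on a simulated cohort and write a run directory.

    Writes the ratings/truth/questionnaire tables, the fitted bias indices,
    the model-comparison verdict, the group-level HDI decisions, the symptom
    profile and a manifest with the config hash and seeds. Returns the run
    directory path.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": config.config_hash(),
        "seeds": {
            "simulate": config.seed_simulate,
            "fit": config.seed_fit,
            "compare": config.seed_compare,
        },
        "profile": config.profile,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    cohort = _stage("simulate")(simulate_cohort)(config.cohort, config.seed_simulate)
    ub_io.write_ratings(cohort.ratings, out / "ratings.csv")
    cohort.truth.to_csv(out / "truth.csv", index=False)
    cohort.questionnaires.to_csv(out / "questionnaires.csv", index=False)

    mcmc = MCMCSettings.profile(config.profile, seed=config.seed_fit)
    spec = ModelSpec(kind="valence_split")
    draws = _stage("fit_valence")(fit_model)(cohort.ratings, spec, mcmc, check=False)
    bias = extract_bias(draws)
    bias.point_estimates.to_csv(out / "bias_indices.csv", index=False)
    diagnostics = check_convergence(draws)

    report: dict = {"diagnostics": diagnostics}
    if config.compare:
        folds = kfold_split(cohort.ratings, config.k_folds, config.seed_compare, spec)
        elpd_val = _stage("elpd_valence")(kfold_elpd)(
            spec, cohort.ratings, config.k_folds, mcmc, config.seed_compare, folds
        )
        elpd_pe = _stage("elpd_pe")(kfold_elpd)(
            ModelSpec(kind="pe_split"),
            cohort.ratings,
            config.k_folds,
            mcmc,
            config.seed_compare,
            folds,
        )
        report["model_comparison"] = compare_models(elpd_val, elpd_pe)

    for which in ("self_eval", "self_efficacy"):
        hdi = group_bias_hdi(bias, which)
        report[f"group_{which}"] = {
            "median": hdi.point,
            "hdi_low": hdi.hdi_low,
            "hdi_high": hdi.hdi_high,
            "decision": hdi.decision,
        }
    r_ppc, _ = _stage("ppc")(ppc_bias_vs_empirical)(bias, cohort.ratings)
    report["ppc_bias_vs_empirical_r"] = r_ppc

    n_scales = cohort.questionnaires.shape[1] - 1
    if len(cohort.truth) > n_scales:
        profile = _stage("pca")(pca_varimax)(cohort.questionnaires)
        delta_pe = cohort.truth["delta_pe"].to_numpy()
        corr = correlate_components_with_bias(
            profile, bias.point_estimates, delta_pe,
            components=[c for c in profile.scores.columns if c != "subject_id"][:2],
        )
        report["pca"] = {
            "eigenvalues": profile.eigenvalues[: profile.n_retained],
            "explained_variance_pct": profile.explained_variance_pct[: profile.n_retained],
            "n_retained": profile.n_retained,
        }
        report["component_bias_correlations"] = corr
    else:
        logger.info("stage pca: skipped (fewer subjects than questionnaire scales)")
        report["pca"] = {"skipped": "fewer subjects than questionnaire scales"}

    ub_io.write_json(report, out / "report.json")
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    ub_io.write_json(manifest, out / "manifest.json")
    return out
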