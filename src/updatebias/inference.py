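"""Group-level inference, posterior predictive checks and symptom profiling.

Covers the downstream stages of the analysis: deciding whether a positive
update bias exists at the group level (highest-density interval of the
posterior across-subject median), checking the fitted bias indices against
model-free empirical correlation differences, regressing out the per-subject
prediction-error imbalance, profiling the questionnaire battery with a
varimax-rotated PCA, correlating the emerging components with the bias
indices, and a case-resampling bootstrap mediation utility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.multivariate.factor_rotation import rotate_factors
from statsmodels.stats.multitest import multipletests

from .cohort import SCORE_TYPES, sample_ratings, SubjectParams
from .model import BiasIndices, PosteriorDraws, extract_bias, ratings_to_wide

__all__ = [
    "HDIResult",
    "bias_decision",
    "retained_count",
    "ComponentProfile",
    "MediationResult",
    "group_bias_hdi",
    "empirical_bias",
    "ppc_bias_vs_empirical",
    "ppc_correlation_table",
    "residualize_on_pe",
    "pca_varimax",
    "correlate_components_with_bias",
    "mediation_bootstrap",
]


@dataclass
class HDIResult:
    """Posterior of the across-subject median bias with its shortest 95% interval."""

    median_draws: np.ndarray = field(repr=False)
    point: float = 0.0
    hdi_low: float = 0.0
    hdi_high: float = 0.0
    level: float = 0.95
    decision: str = "not_established"


def group_bias_hdi(
    draws: PosteriorDraws | BiasIndices,
    which: str = "self_efficacy",
    level: float = 0.95,
) -> HDIResult:
    """Group-level bias assessment.

    On every posterior iteration the median of the per-subject bias is taken
    across subjects, giving a posterior distribution of the group median; the
    decision is ``positive_bias`` only when the shortest ``level`` interval of
    that distribution lies entirely above zero (``negative_bias`` when entirely
    below).
    """
    bias = draws if isinstance(draws, BiasIndices) else extract_bias(draws)
    series = {"self_eval": bias.self_eval, "self_efficacy": bias.self_efficacy}[which]
    med = np.median(series, axis=-1).ravel()  # across subjects, per draw
    lo, hi = az.hdi(med, hdi_prob=level)
    decision = bias_decision(lo, hi)
    return HDIResult(
        median_draws=med,
        point=float(np.median(med)),
        hdi_low=float(lo),
        hdi_high=float(hi),
        level=level,
        decision=decision,
    )


def bias_decision(hdi_low: float, hdi_high: float) -> str:
    """Group-level verdict from an HDI: bias is established only when the
    whole interval sits on one side of zero."""
    if hdi_low > 0:
        return "positive_bias"
    if hdi_high < 0:
        return "negative_bias"
    return "not_established"


def retained_count(eigenvalues, cutoff: float = 1.0) -> int:
    """Number of principal components retained under the eigenvalue rule."""
    return int((np.asarray(eigenvalues, dtype=float) > cutoff).sum())


def empirical_bias(
    ratings: pd.DataFrame, subject: int, target: str = "y5", threshold: float = 7.0
) -> float:
    """Model-free bias: Pearson r(y3, target) in positive minus neutral items."""
    if target not in ("y4", "y5"):
        raise ValueError("target must be 'y4' or 'y5'")
    wide = ratings_to_wide(ratings)
    sub = wide[wide.subject_id == subject]
    if sub.empty:
        raise ValueError(f"no rows for subject {subject}")
    rs = {}
    for name, mask in (
        ("positive", sub["y3"] >= threshold),
        ("neutral", sub["y3"] < threshold),
    ):
        grp = sub[mask]
        if len(grp) < 3 or grp["y3"].std() == 0 or grp[target].std() == 0:
            raise ValueError(
                f"subject {subject}, condition {name}: need >=3 items with variance"
            )
        rs[name] = float(np.corrcoef(grp["y3"], grp[target])[0, 1])
    return rs["positive"] - rs["neutral"]


def ppc_bias_vs_empirical(
    bias: BiasIndices, ratings: pd.DataFrame, which: str = "self_efficacy"
) -> tuple[float, pd.DataFrame]:
    """Posterior predictive check: model bias vs. empirical correlation difference.

    Correlates, across subjects, the posterior-mean update bias with the
    model-free difference between within-subject Pearson correlations of the
    feedback and the relevant post-feedback score in the two conditions.
    """
    target = {"self_eval": "y4", "self_efficacy": "y5"}[which]
    est = bias.point_estimates.set_index("subject_id")[f"{which}_bias"]
    emp = pd.Series(
        {s: empirical_bias(ratings, s, target) for s in bias.subjects}, name="empirical"
    )
    if len(est) < 3:
        raise ValueError("need at least 3 subjects")
    table = pd.DataFrame({"model_bias": est, "empirical_bias": emp})
    r = float(np.corrcoef(table["model_bias"], table["empirical_bias"])[0, 1])
    return r, table.reset_index(names="subject_id")


def ppc_correlation_table(
    draws: PosteriorDraws,
    ratings: pd.DataFrame,
    schedules: dict,
    n_sim: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Observed vs. posterior-simulated pairwise score correlations.

    For ``n_sim`` random posterior draws, a full cohort is re-simulated from
    that draw's subject parameters (reusing the conditional sampler and each
    subject's actual feedback schedule) and all 10 pairwise correlations among
    the 5 scores, averaged across subjects, are tabulated against the observed
    ones with a 95% simulation interval.
    """
    rng = np.random.default_rng(seed)
    wide = ratings_to_wide(ratings)
    pairs = [(i, j) for i in range(5) for j in range(i + 1, 5)]

    def cohort_corrs(w: pd.DataFrame) -> np.ndarray:
        per = []
        for _, grp in w.groupby("subject_id"):
            arr = grp[list(SCORE_TYPES)].to_numpy()
            cc = np.corrcoef(arr.T)
            per.append([cc[i, j] for i, j in pairs])
        return np.nanmean(np.array(per), axis=0)

    observed = cohort_corrs(wide)
    mu = draws.flat("mu")
    tp, tn = draws.flat("tau_pos"), draws.flat("tau_neu")
    op, on = draws.flat("omega_pos"), draws.flat("omega_neu")
    pick = rng.choice(mu.shape[0], size=min(n_sim, mu.shape[0]), replace=False)
    sims = []
    for d in pick:
        tables = []
        for i, s in enumerate(draws.subjects):
            params = SubjectParams(mu[d, i], tp[d, i], tn[d, i], op[d, i], on[d, i])
            tables.append(
                sample_ratings(
                    params,
                    schedules[s],
                    seed=int(rng.integers(2**31 - 1)),
                    subject_id=int(s),
                )
            )
        sim_wide = ratings_to_wide(pd.concat(tables, ignore_index=True))
        sims.append(cohort_corrs(sim_wide))
    sims = np.array(sims)
    names = [f"{SCORE_TYPES[i]}-{SCORE_TYPES[j]}" for i, j in pairs]
    return pd.DataFrame(
        {
            "pair": names,
            "observed": observed,
            "simulated_mean": sims.mean(axis=0),
            "simulated_low": np.percentile(sims, 2.5, axis=0),
            "simulated_high": np.percentile(sims, 97.5, axis=0),
        }
    )


def residualize_on_pe(values: np.ndarray, delta_pe: np.ndarray) -> np.ndarray:
    """Regress the prediction-error imbalance out of per-subject values.

    Ordinary least squares of ``values`` on ``delta_pe`` (mean PE on positive
    minus neutral trials); returns residuals re-centered at the original mean,
    so only the association with the imbalance is removed.
    """
    values = np.asarray(values, dtype=float)
    delta_pe = np.asarray(delta_pe, dtype=float)
    if values.shape != delta_pe.shape:
        raise ValueError("values and delta_pe must be aligned")
    if np.std(delta_pe) == 0:
        warnings.warn("delta_pe is constant; returning values unchanged", stacklevel=2)
        return values.copy()
    x = np.column_stack([np.ones_like(delta_pe), delta_pe])
    beta, *_ = np.linalg.lstsq(x, values, rcond=None)
    resid = values - x @ beta
    return resid + values.mean()


@dataclass
class ComponentProfile:
    """Varimax-rotated principal components of the questionnaire battery."""

    loadings: pd.DataFrame = field(repr=False)  # scales x components, rotated
    eigenvalues: np.ndarray = field(repr=False)  # all eigenvalues, descending
    explained_variance_pct: np.ndarray = field(repr=False)
    scores: pd.DataFrame = field(repr=False)  # subjects x components
    n_retained: int = 0


def pca_varimax(questionnaires: pd.DataFrame, eigenvalue_cutoff: float = 1.0) -> ComponentProfile:
    """PCA of the standardized questionnaire battery with varimax rotation.

    Components with eigenvalue > 1 of the scale correlation matrix are
    retained and varimax-rotated; subject component scores use the regression
    method. Percent variance explained refers to the unrotated eigenvalues.
    """
    scales = [c for c in questionnaires.columns if c != "subject_id"]
    x = questionnaires[scales].to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [s for s, v in zip(scales, sd) if v == 0]
        raise ValueError(f"constant questionnaire scales: {bad}")
    z = (x - x.mean(axis=0)) / sd
    corr = np.corrcoef(z.T)
    if np.linalg.matrix_rank(corr) < len(scales):
        raise ValueError("singular correlation matrix")
    vals, vecs = np.linalg.eigh(corr)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    n_keep = retained_count(vals, eigenvalue_cutoff)
    if n_keep == 0:
        raise ValueError("no eigenvalue exceeds the retention cutoff")
    loadings = vecs[:, :n_keep] * np.sqrt(vals[:n_keep])
    if n_keep > 1:
        rotated, _ = rotate_factors(loadings, "varimax")
    else:
        rotated = loadings
    # orient each component so the bulk of its loadings is positive
    signs = np.sign(rotated.sum(axis=0))
    signs[signs == 0] = 1.0
    rotated = rotated * signs
    # regression-method scores: Z @ R^{-1} @ rotated loadings
    scores = z @ np.linalg.solve(corr, rotated)
    comp_names = [f"component_{i + 1}" for i in range(n_keep)]
    score_df = pd.DataFrame(scores, columns=comp_names)
    if "subject_id" in questionnaires.columns:
        score_df.insert(0, "subject_id", questionnaires["subject_id"].to_numpy())
    return ComponentProfile(
        loadings=pd.DataFrame(rotated, index=scales, columns=comp_names),
        eigenvalues=vals,
        explained_variance_pct=100.0 * vals / len(scales),
        scores=score_df,
        n_retained=n_keep,
    )


def _pearson_with_ci(x: np.ndarray, y: np.ndarray, level: float = 0.95):
    n = len(x)
    r, p = stats.pearsonr(x, y)
    zcrit = stats.norm.ppf(0.5 + level / 2)
    fz = np.arctanh(np.clip(r, -0.999999, 0.999999))
    half = zcrit / np.sqrt(n - 3)
    return float(r), float(p), float(np.tanh(fz - half)), float(np.tanh(fz + half))


def correlate_components_with_bias(
    profile: ComponentProfile,
    bias: pd.DataFrame,
    delta_pe: np.ndarray,
    components: list[str] | None = None,
    residualize: str = "both",
) -> pd.DataFrame:
    """Pearson correlations of component scores with the update-bias indices.

    ``bias`` must contain ``subject_id``, ``self_eval_bias`` and
    ``self_efficacy_bias`` rows aligned with ``profile.scores``. The mean
    prediction-error difference is regressed out of components and/or biases
    first (``residualize`` in {"both", "components", "bias", "none"}). Raw
    two-tailed p values are reported alongside Benjamini-Hochberg adjusted
    ones; decisions in the original analysis used the raw values.
    """
    if residualize not in ("both", "components", "bias", "none"):
        raise ValueError("residualize must be both/components/bias/none")
    merged = profile.scores.merge(bias, on="subject_id", validate="one_to_one")
    if len(merged) < 4:
        raise ValueError("need at least 4 subjects")
    delta_pe = np.asarray(delta_pe, dtype=float)
    components = components or [c for c in profile.scores.columns if c != "subject_id"]
    rows = []
    for comp in components:
        c = merged[comp].to_numpy()
        if residualize in ("both", "components"):
            c = residualize_on_pe(c, delta_pe)
        for which in ("self_eval_bias", "self_efficacy_bias"):
            b = merged[which].to_numpy()
            if residualize in ("both", "bias"):
                b = residualize_on_pe(b, delta_pe)
            r, p, lo, hi = _pearson_with_ci(c, b)
            rows.append(
                {"component": comp, "bias": which, "r": r, "p": p, "ci_low": lo, "ci_high": hi}
            )
    out = pd.DataFrame(rows)
    out["p_fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


@dataclass
class MediationResult:
    """Simple mediation X -> M -> Y with a percentile bootstrap on a*b."""

    a: float
    b: float
    c_total: float
    c_prime: float
    indirect: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int
    significant: bool


def _ols_paths(x: np.ndarray, m: np.ndarray, y: np.ndarray):
    one = np.ones_like(x)
    a = np.linalg.lstsq(np.column_stack([one, x]), m, rcond=None)[0][1]
    bc = np.linalg.lstsq(np.column_stack([one, x, m]), y, rcond=None)[0]
    c = np.linalg.lstsq(np.column_stack([one, x]), y, rcond=None)[0][1]
    return a, bc[2], c, bc[1]


def mediation_bootstrap(
    x, m, y, n_boot: int = 5000, seed: int = 0, level: float = 0.95
) -> MediationResult:
    """Case-resampling percentile bootstrap of the indirect effect a*b.

    ``a`` is the X->M slope, ``b`` the M->Y slope adjusting for X, ``c`` the
    total and ``c'`` the direct X->Y effect; the indirect effect a*b is deemed
    significant when the percentile interval excludes zero.
    """
    x, m, y = (np.asarray(v, dtype=float) for v in (x, m, y))
    n = len(x)
    if not (len(m) == len(y) == n):
        raise ValueError("x, m, y must be aligned")
    if n < 10:
        raise ValueError("need at least 10 cases")
    if np.std(x) == 0 or np.std(m) == 0:
        raise ValueError("degenerate predictor or mediator")
    a, b, c, c_prime = _ols_paths(x, m, y)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        ab = _ols_paths(x[idx], m[idx], y[idx])
        boots[i] = ab[0] * ab[1]
    alpha = (1 - level) / 2
    lo, hi = np.percentile(boots, [100 * alpha, 100 * (1 - alpha)])
    return MediationResult(
        a=float(a),
        b=float(b),
        c_total=float(c),
        c_prime=float(c_prime),
        indirect=float(a * b),
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=n_boot,
        seed=seed,
        significant=bool(lo > 0 or hi < 0),
    )
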