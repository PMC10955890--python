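"""Hierarchical Bayesian covariance model of the five speech-rating series.

Each (subject s, item q) observation is the 5-vector of scores
(y1 pre-speech self-efficacy, y2 post-speech self-evaluation, y3 judges'
feedback, y4 post-feedback self-evaluation, y5 post-feedback self-efficacy),
modelled as multivariate normal with subject-level means (the mean of y3 is
known and fixed per condition, because the feedback is experimenter-controlled)
and a condition-specific subject-level covariance:

    y_{s,q} ~ N(mu_s, Sigma_pos_s)   if item q is a "positive" item
    y_{s,q} ~ N(mu_s, Sigma_neu_s)   otherwise

with Sigma_s = diag(tau_s) @ Omega_s @ diag(tau_s). Two model variants differ
only in how items are labelled: the valence-split model labels by the absolute
feedback score (>= 7 positive, 4-6 neutral), the prediction-error model labels
by the sign of y3 - y2; items with exactly zero prediction error are modelled
with the element-wise average of the two conditions' tau and Omega.

The per-subject positive update bias indices are contrasts of the posterior
correlation matrices:

    self-evaluation update bias = Omega_pos(y3, y4) - Omega_neu(y3, y4)
    self-efficacy  update bias  = Omega_pos(y3, y5) - Omega_neu(y3, y5)

Inference uses a blocked Gibbs sampler with conjugate full conditionals:
Gaussian updates for subject and group means, inverse-Wishart updates for the
subject covariances (Metropolis-corrected where zero-prediction-error items
couple the two matrices), a conjugate inverse-gamma update for the
between-subject mean spread, and a conjugate Wishart update for the group-level
inverse-Wishart scale matrices, which partially pools subject covariances
toward a learned group covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd

from .cohort import NEUTRAL_Y3_MEAN, POSITIVE_Y3_MEAN, SCORE_TYPES

__all__ = [
    "ModelSpec",
    "MCMCSettings",
    "PosteriorDraws",
    "BiasIndices",
    "ConvergenceError",
    "partition_by_condition",
    "fit_model",
    "fit_model_pe",
    "extract_bias",
    "check_convergence",
    "pointwise_loglik",
]

_P = 5  # scores per observation
_Y3 = 2
_FREE = np.array([0, 1, 3, 4])
_LOG2PI = np.log(2.0 * np.pi)


class ConvergenceError(RuntimeError):
    """Raised when MCMC diagnostics fail the R-hat < 1.1 / ESS > 1000 rule."""


@dataclass(frozen=True)
class ModelSpec:
    """Model variant and prior hyperparameters.

    Parameters
    ----------
    kind
        ``"valence_split"`` labels items by absolute feedback score
        (``positive_threshold`` and above vs. below); ``"pe_split"`` labels by
        the sign of the prediction error y3 - y2.
    fixed_y3_means
        The known per-condition means of the judges' score. Defaults to the
        means implied by the fixed feedback inventory for the valence split
        (5.05 neutral / 8.25 positive); for the prediction-error split they
        are computed from the data at fit time (the feedback schedule, hence
        these means, is experimenter-controlled).
    nu_subject
        Degrees of freedom of the inverse-Wishart prior on each subject
        covariance; larger values pool subjects more strongly toward the
        group-level scale matrix.
    scale_df, scale_guess
        Wishart hyperprior on the group-level scale matrix: ``scale_df``
        degrees of freedom around a diagonal guess with score scale
        ``scale_guess`` (VAS points).
    mean_loc, mean_scale
        Normal hyperprior on the group-level mean of the free score means.
    var_shape, var_rate
        Inverse-gamma hyperprior on the between-subject variance of the means.
    """

    kind: str = "valence_split"
    positive_threshold: float = 7.0
    fixed_y3_means: dict | None = None
    nu_subject: float = 10.0
    scale_df: float = 7.0
    scale_guess: float = 1.5
    mean_loc: float = 5.0
    mean_scale: float = 2.5
    var_shape: float = 2.0
    var_rate: float = 2.0

    def __post_init__(self):
        if self.kind not in ("valence_split", "pe_split"):
            raise ValueError(f"unknown model kind: {self.kind}")
        if not 0 < self.positive_threshold < 10:
            raise ValueError("positive_threshold must be inside the rating scale")
        if min(self.nu_subject - _P - 1, self.scale_df - _P + 1) <= 0:
            raise ValueError("prior degrees of freedom too small")


@dataclass(frozen=True)
class MCMCSettings:
    """Gibbs sampler schedule. ``iterations`` counts post-warmup sweeps per chain."""

    chains: int = 4
    warmup: int = 500
    iterations: int = 500
    thin: int = 1
    seed: int = 0

    @classmethod
    def profile(cls, name: str, seed: int = 0) -> "MCMCSettings":
        if name == "ci":
            return cls(chains=4, warmup=500, iterations=500, thin=1, seed=seed)
        if name == "paper":
            return cls(chains=4, warmup=1500, iterations=10000, thin=4, seed=seed)
        raise ValueError(f"unknown MCMC profile: {name}")

    @property
    def retained_per_chain(self) -> int:
        return self.iterations // self.thin


@dataclass
class PosteriorDraws:
    """Posterior draws and pointwise log-likelihood from one model fit.

    Array layout is (chain, draw, subject, ...). ``log_lik`` is
    (chain, draw, observation) aligned with the rows of ``obs``.
    """

    subjects: np.ndarray
    obs: pd.DataFrame = field(repr=False)
    mu: np.ndarray = field(repr=False)
    tau_pos: np.ndarray = field(repr=False)
    tau_neu: np.ndarray = field(repr=False)
    omega_pos: np.ndarray = field(repr=False)
    omega_neu: np.ndarray = field(repr=False)
    group_mean: np.ndarray = field(repr=False)
    group_var: np.ndarray = field(repr=False)
    scale_pos: np.ndarray = field(repr=False)
    scale_neu: np.ndarray = field(repr=False)
    log_lik: np.ndarray = field(repr=False)
    y3_means: dict = field(default_factory=dict)
    spec: ModelSpec = field(default_factory=ModelSpec)
    settings: MCMCSettings = field(default_factory=MCMCSettings)

    @property
    def n_chains(self) -> int:
        return self.mu.shape[0]

    @property
    def n_draws(self) -> int:
        return self.mu.shape[1]

    def flat(self, name: str) -> np.ndarray:
        """Stack chains: (chain, draw, ...) -> (chain*draw, ...)."""
        arr = getattr(self, name)
        return arr.reshape((-1,) + arr.shape[2:])


@dataclass
class BiasIndices:
    """Per-draw and summarized positive update-bias indices (one per subject)."""

    subjects: np.ndarray
    self_eval: np.ndarray  # (chain, draw, subject)
    self_efficacy: np.ndarray

    @property
    def point_estimates(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subjects,
                "self_eval_bias": self.self_eval.mean(axis=(0, 1)),
                "self_efficacy_bias": self.self_efficacy.mean(axis=(0, 1)),
            }
        )


# ---------------------------------------------------------------------------
# data preparation


def ratings_to_wide(ratings: pd.DataFrame) -> pd.DataFrame:
    """Long (subject, item, score_type, value) -> one row per (subject, item)."""
    required = {"subject_id", "item_id", "score_type", "value"}
    if not required.issubset(ratings.columns):
        raise ValueError(f"ratings table must have columns {sorted(required)}")
    wide = ratings.pivot_table(
        index=["subject_id", "item_id"], columns="score_type", values="value"
    )
    missing = [c for c in SCORE_TYPES if c not in wide.columns]
    if missing or wide[list(SCORE_TYPES)].isna().any().any():
        raise ValueError(f"every (subject, item) needs all 5 score types; missing {missing}")
    return wide[list(SCORE_TYPES)].reset_index()


def partition_by_condition(ratings: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Label each (subject, item) observation with its model condition.

    Valence split: positive iff y3 >= threshold (7 by default). Prediction-error
    split: by the sign of y3 - y2; exact ties are ``zero_pe``.
    """
    wide = ratings_to_wide(ratings)
    if spec.kind == "valence_split":
        label = np.where(wide["y3"] >= spec.positive_threshold, "positive", "neutral")
    else:
        pe = wide["y3"] - wide["y2"]
        label = np.where(pe > 0, "positive", np.where(pe < 0, "neutral", "zero_pe"))
    out = wide[["subject_id", "item_id"]].copy()
    out["condition"] = label
    return out


# ---------------------------------------------------------------------------
# batched linear-algebra helpers


def _sample_invwishart(df: np.ndarray, scale: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Batched inverse-Wishart draws, one per leading index.

    ``df`` is (n,), ``scale`` is (n, p, p). Uses the Bartlett decomposition of
    the Wishart with the inverted scale; any square root L with L @ L.T equal
    to the inverse scale yields the correct distribution.
    """
    n, p = scale.shape[0], scale.shape[-1]
    chol = np.linalg.cholesky(scale)
    eye = np.broadcast_to(np.eye(p), (n, p, p))
    inv_chol = np.linalg.solve(chol, eye)  # chol^{-1}, lower
    lfac = np.transpose(inv_chol, (0, 2, 1))  # L with L L^T = scale^{-1}
    bart = np.zeros((n, p, p))
    rows, cols = np.tril_indices(p, k=-1)
    bart[:, rows, cols] = rng.standard_normal((n, len(rows)))
    dfs = df[:, None] - np.arange(p)[None, :]
    bart[:, np.arange(p), np.arange(p)] = np.sqrt(rng.chisquare(dfs))
    root = lfac @ bart
    wish = root @ np.transpose(root, (0, 2, 1))
    return np.linalg.inv(wish)


def _cov_to_corr(sigma: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(..., p, p) covariance -> (tau, omega)."""
    tau = np.sqrt(np.diagonal(sigma, axis1=-2, axis2=-1))
    omega = sigma / (tau[..., :, None] * tau[..., None, :])
    return tau, omega


def _mvn_loglik(resid: np.ndarray, prec: np.ndarray, logdet_cov: np.ndarray) -> np.ndarray:
    """Batched MVN log density from residuals, precision and covariance log-det."""
    quad = np.einsum("...i,...ij,...j->...", resid, prec, resid)
    return -0.5 * (_P * _LOG2PI + logdet_cov + quad)


def _avg_sigma(sig_a: np.ndarray, sig_b: np.ndarray) -> np.ndarray:
    """Element-wise average of (tau, Omega) of two covariances, recomposed."""
    tau_a, om_a = _cov_to_corr(sig_a)
    tau_b, om_b = _cov_to_corr(sig_b)
    tau = (tau_a + tau_b) / 2
    om = (om_a + om_b) / 2
    return om * (tau[..., :, None] * tau[..., None, :])


# ---------------------------------------------------------------------------
# the Gibbs sampler


class _SubjectData:
    """Per-subject sufficient statistics for the two (three) conditions."""

    def __init__(self, y: dict[str, np.ndarray]):
        self.y = y  # condition -> (n_c, 5) raw observations
        self.n = {c: len(v) for c, v in y.items()}
        self.sum_y = {c: v.sum(axis=0) for c, v in y.items()}
        self.sum_yy = {c: v.T @ v for c, v in y.items()}


def _prepare(wide: pd.DataFrame, labels: pd.DataFrame, spec: ModelSpec):
    merged = wide.merge(labels, on=["subject_id", "item_id"], validate="one_to_one")
    subjects = np.sort(merged["subject_id"].unique())
    y3 = merged["y3"].to_numpy(dtype=float)
    if spec.fixed_y3_means is not None:
        y3_means = dict(spec.fixed_y3_means)
    elif spec.kind == "valence_split":
        y3_means = {"neutral": NEUTRAL_Y3_MEAN, "positive": POSITIVE_Y3_MEAN}
    else:
        y3_means = {
            c: float(y3[merged["condition"] == c].mean()) for c in ("neutral", "positive")
        }
    if spec.kind == "pe_split":
        y3_means.setdefault(
            "zero_pe", (y3_means["neutral"] + y3_means["positive"]) / 2.0
        )

    data: list[_SubjectData] = []
    for s in subjects:
        sub = merged[merged.subject_id == s]
        per = {
            c: sub.loc[sub.condition == c, list(SCORE_TYPES)].to_numpy(dtype=float)
            for c in sub["condition"].unique()
        }
        per.setdefault("neutral", np.empty((0, _P)))
        per.setdefault("positive", np.empty((0, _P)))
        if spec.kind == "valence_split":
            # both conditions are experimenter-controlled at 20 items each;
            # fewer than 2 leaves the condition covariance unidentified
            for c in ("neutral", "positive"):
                if len(per[c]) < 2:
                    raise ValueError(
                        f"subject {s}: need at least 2 items in condition '{c}'"
                    )
        elif len(per["neutral"]) + len(per["positive"]) < 2:
            # prediction-error signs are not controlled; empty cells are pooled
            # toward the group covariance, but a subject with (almost) only
            # zero-PE items carries no sign information at all
            raise ValueError(
                f"subject {s}: fewer than 2 items with nonzero prediction error"
            )
        data.append(_SubjectData(per))
    obs = merged[["subject_id", "item_id", "condition"]].reset_index(drop=True)
    return subjects, data, obs, merged, y3_means


def _mean_vector(mu_free: np.ndarray, y3_mean: float) -> np.ndarray:
    """(n, 4) free means -> (n, 5) full mean vector with the fixed y3 mean."""
    out = np.empty(mu_free.shape[:-1] + (_P,))
    out[..., _FREE] = mu_free
    out[..., _Y3] = y3_mean
    return out


def _run_chain(
    data: list[_SubjectData],
    spec: ModelSpec,
    settings: MCMCSettings,
    y3_means: dict,
    merged: pd.DataFrame,
    rng: np.random.Generator,
):
    n = len(data)
    conds = ("neutral", "positive")
    nu = spec.nu_subject
    # Wishart hyperprior on the group scale: mean scale_df * phi0 should be a
    # plausible IW scale, i.e. (nu - p - 1) * diag(scale_guess^2).
    phi0 = (nu - _P - 1) * np.eye(_P) * spec.scale_guess**2 / spec.scale_df
    phi0_inv = np.linalg.inv(phi0)

    counts = {c: np.array([d.n.get(c, 0) for d in data]) for c in ("neutral", "positive", "zero_pe")}
    sums = {
        c: np.array([d.sum_y.get(c, np.zeros(_P)) for d in data])
        for c in ("neutral", "positive", "zero_pe")
    }
    sums_yy = {
        c: np.array([d.sum_yy.get(c, np.zeros((_P, _P))) for d in data])
        for c in ("neutral", "positive", "zero_pe")
    }
    zero_subjects = np.flatnonzero(counts["zero_pe"] > 0)

    # --- initialization from empirical moments
    mu_free = np.array(
        [
            np.concatenate([d.y[c] for c in d.y]).mean(axis=0)[_FREE]
            for d in data
        ]
    )
    sigma = {}
    for c in conds:
        emp = []
        for d in data:
            arr = d.y.get(c, np.empty((0, _P)))
            cov = np.cov(arr.T) if len(arr) > 6 else np.eye(_P)
            emp.append(cov + 0.5 * np.eye(_P))
        sigma[c] = np.array(emp)
    g = mu_free.mean(axis=0)
    v = mu_free.var(axis=0) + 0.1
    scale_mat = {c: (nu - _P - 1) * sigma[c].mean(axis=0) for c in conds}

    n_keep = settings.retained_per_chain
    store = {
        "mu": np.empty((n_keep, n, 4)),
        "tau_pos": np.empty((n_keep, n, _P)),
        "tau_neu": np.empty((n_keep, n, _P)),
        "omega_pos": np.empty((n_keep, n, _P, _P)),
        "omega_neu": np.empty((n_keep, n, _P, _P)),
        "group_mean": np.empty((n_keep, 4)),
        "group_var": np.empty((n_keep, 4)),
        "scale_pos": np.empty((n_keep, _P, _P)),
        "scale_neu": np.empty((n_keep, _P, _P)),
        "log_lik": np.empty((n_keep, len(merged))),
    }
    cond_col = merged["condition"].to_numpy()
    subj_col = merged["subject_id"].to_numpy()
    subj_idx_of = {s: i for i, s in enumerate(np.sort(merged["subject_id"].unique()))}
    subj_idx = np.array([subj_idx_of[s] for s in subj_col])
    y_all = merged[list(SCORE_TYPES)].to_numpy(dtype=float)
    cond_rows = {c: np.flatnonzero(cond_col == c) for c in np.unique(cond_col)}

    kept = 0
    total = settings.warmup + settings.iterations
    from scipy import stats as sps

    for it in range(total):
        prec = {c: np.linalg.inv(sigma[c]) for c in conds}

        # ---- subject means (Gaussian full conditional)
        pmat = np.zeros((n, 4, 4))
        bvec = np.zeros((n, 4))
        for c in conds:
            pc = prec[c]
            pmat += counts[c][:, None, None] * pc[np.ix_(np.arange(n), _FREE, _FREE)]
            resid_sum = sums[c] - counts[c][:, None] * _unit_y3(y3_means[c])
            bvec += np.einsum("nij,nj->ni", pc[:, _FREE, :], resid_sum)
        if len(zero_subjects):
            sig_avg = _avg_sigma(sigma["positive"][zero_subjects], sigma["neutral"][zero_subjects])
            pz = np.linalg.inv(sig_avg)
            nz = counts["zero_pe"][zero_subjects]
            pmat[zero_subjects] += nz[:, None, None] * pz[np.ix_(np.arange(len(zero_subjects)), _FREE, _FREE)]
            rz = sums["zero_pe"][zero_subjects] - nz[:, None] * _unit_y3(y3_means["zero_pe"])
            bvec[zero_subjects] += np.einsum("nij,nj->ni", pz[:, _FREE, :], rz)
        pmat += np.diag(1.0 / v)[None]
        bvec += (g / v)[None]
        chol_p = np.linalg.cholesky(pmat)
        mean = np.linalg.solve(pmat, bvec[..., None])[..., 0]
        z = rng.standard_normal((n, 4, 1))
        mu_free = mean + np.linalg.solve(np.transpose(chol_p, (0, 2, 1)), z)[..., 0]

        # ---- subject covariances (inverse-Wishart; MH-corrected if zero-PE items)
        for c in conds:
            m_c = _mean_vector(mu_free, y3_means[c])
            ss = (
                sums_yy[c]
                - np.einsum("ni,nj->nij", m_c, sums[c])
                - np.einsum("ni,nj->nij", sums[c], m_c)
                + counts[c][:, None, None] * np.einsum("ni,nj->nij", m_c, m_c)
            )
            # guard against cancellation error on (near-)constant scores
            ss = (ss + np.transpose(ss, (0, 2, 1))) / 2 + 1e-8 * np.eye(_P)
            proposal = _sample_invwishart(nu + counts[c], scale_mat[c][None] + ss, rng)
            if len(zero_subjects) == 0 or spec.kind == "valence_split":
                sigma[c] = proposal
            else:
                accept = np.ones(n, dtype=bool)
                m_z = _mean_vector(mu_free, y3_means["zero_pe"])
                other = "positive" if c == "neutral" else "neutral"
                for j in zero_subjects:
                    yz = data[j].y["zero_pe"]
                    rz = yz - m_z[j]
                    cur = _avg_sigma(sigma[c][j], sigma[other][j])
                    new = _avg_sigma(proposal[j], sigma[other][j])
                    ll_cur = _mvn_loglik(rz, np.linalg.inv(cur), np.linalg.slogdet(cur)[1]).sum()
                    ll_new = _mvn_loglik(rz, np.linalg.inv(new), np.linalg.slogdet(new)[1]).sum()
                    accept[j] = np.log(rng.uniform()) < ll_new - ll_cur
                sigma[c] = np.where(accept[:, None, None], proposal, sigma[c])

        # ---- group-level mean and spread
        prec_g = 1.0 / spec.mean_scale**2 + n / v
        mean_g = (spec.mean_loc / spec.mean_scale**2 + mu_free.sum(axis=0) / v) / prec_g
        g = rng.normal(mean_g, 1.0 / np.sqrt(prec_g))
        dev = ((mu_free - g) ** 2).sum(axis=0)
        v = 1.0 / rng.gamma(spec.var_shape + n / 2.0, 1.0 / (spec.var_rate + dev / 2.0))

        # ---- group-level covariance scale (conjugate Wishart)
        for c in conds:
            rate = phi0_inv + np.linalg.inv(sigma[c]).sum(axis=0)
            df_post = spec.scale_df + n * nu
            scale_mat[c] = sps.wishart.rvs(df_post, np.linalg.inv(rate), random_state=rng)

        # ---- store
        if it >= settings.warmup and (it - settings.warmup) % settings.thin == 0:
            tau_p, om_p = _cov_to_corr(sigma["positive"])
            tau_n, om_n = _cov_to_corr(sigma["neutral"])
            store["mu"][kept] = mu_free
            store["tau_pos"][kept], store["omega_pos"][kept] = tau_p, om_p
            store["tau_neu"][kept], store["omega_neu"][kept] = tau_n, om_n
            store["group_mean"][kept] = g
            store["group_var"][kept] = v
            store["scale_pos"][kept] = scale_mat["positive"]
            store["scale_neu"][kept] = scale_mat["neutral"]
            ll = np.empty(len(merged))
            sig_z = (
                _avg_sigma(sigma["positive"], sigma["neutral"])
                if "zero_pe" in cond_rows
                else None
            )
            for c, rows in cond_rows.items():
                sig_c = sig_z if c == "zero_pe" else sigma[c]
                prec_c = np.linalg.inv(sig_c)
                logdet = np.linalg.slogdet(sig_c)[1]
                m_c = _mean_vector(mu_free, y3_means[c])
                idx = subj_idx[rows]
                resid = y_all[rows] - m_c[idx]
                ll[rows] = _mvn_loglik(resid, prec_c[idx], logdet[idx])
            store["log_lik"][kept] = ll
            kept += 1
    return store


def _unit_y3(value: float) -> np.ndarray:
    vec = np.zeros(_P)
    vec[_Y3] = value
    return vec


def fit_model(
    ratings: pd.DataFrame,
    spec: ModelSpec | None = None,
    mcmc: MCMCSettings | None = None,
    check: bool = True,
) -> PosteriorDraws:
    """Fit the update-bias model to a long-format ratings table.

    Runs ``mcmc.chains`` independent Gibbs chains and returns retained draws of
    all subject- and group-level parameters plus the pointwise log-likelihood of
    every (subject, item) observation under each draw.

    With ``check=True`` convergence diagnostics are computed; the fit raises
    :class:`ConvergenceError` when R-hat >= 1.1, and additionally when the
    effective sample size is <= 1000 at full-scale (>= 4000 retained draws)
    settings; short exploratory runs only warn.
    """
    spec = spec or ModelSpec()
    mcmc = mcmc or MCMCSettings.profile("ci")
    wide = ratings_to_wide(ratings)
    labels = partition_by_condition(ratings, spec)
    if spec.kind == "pe_split" and (labels["condition"] == "zero_pe").all():
        raise ValueError(
            "all observations have zero prediction error; the averaged covariance "
            "leaves the bias indices undefined"
        )
    subjects, data, obs, merged, y3_means = _prepare(wide, labels, spec)

    ss = np.random.SeedSequence(mcmc.seed)
    stores = [
        _run_chain(data, spec, mcmc, y3_means, merged, np.random.default_rng(child))
        for child in ss.spawn(mcmc.chains)
    ]
    stacked = {k: np.stack([st[k] for st in stores]) for k in stores[0]}
    draws = PosteriorDraws(
        subjects=subjects,
        obs=obs,
        y3_means=y3_means,
        spec=spec,
        settings=mcmc,
        **stacked,
    )
    if check:
        report = check_convergence(draws)
        full_scale = mcmc.chains * mcmc.retained_per_chain >= 4000
        if report["max_rhat"] >= 1.1:
            raise ConvergenceError(f"R-hat {report['max_rhat']:.3f} >= 1.1")
        if full_scale and report["min_ess"] <= 1000:
            raise ConvergenceError(f"ESS {report['min_ess']:.0f} <= 1000")
        if not full_scale and report["min_ess"] <= 100:
            warnings.warn(
                f"low effective sample size ({report['min_ess']:.0f}) at reduced settings",
                stacklevel=2,
            )
    return draws


def fit_model_pe(
    ratings: pd.DataFrame,
    spec: ModelSpec | None = None,
    mcmc: MCMCSettings | None = None,
    check: bool = True,
) -> PosteriorDraws:
    """Fit the prediction-error variant (labels by sign of y3 - y2)."""
    base = spec or ModelSpec()
    import dataclasses

    return fit_model(ratings, dataclasses.replace(base, kind="pe_split"), mcmc, check)


def extract_bias(draws: PosteriorDraws) -> BiasIndices:
    """Per-draw update-bias indices from the posterior correlation matrices."""
    y4, y5 = 3, 4
    return BiasIndices(
        subjects=draws.subjects,
        self_eval=draws.omega_pos[..., _Y3, y4] - draws.omega_neu[..., _Y3, y4],
        self_efficacy=draws.omega_pos[..., _Y3, y5] - draws.omega_neu[..., _Y3, y5],
    )


def check_convergence(draws: PosteriorDraws) -> dict:
    """Split-R-hat and effective sample size over the monitored parameters.

    Monitors the subject means, scales, the two bias cells per subject and the
    group-level means; passes when max R-hat < 1.1 and min bulk ESS > 1000.
    """
    bias = extract_bias(draws)
    ds = az.convert_to_dataset(
        {
            "mu": draws.mu,
            "tau_pos": draws.tau_pos,
            "tau_neu": draws.tau_neu,
            "self_eval_bias": bias.self_eval,
            "self_efficacy_bias": bias.self_efficacy,
            "group_mean": draws.group_mean,
        }
    )
    rhat = az.rhat(ds, method="split")
    ess = az.ess(ds)
    max_rhat = float(max(rhat[v].max() for v in rhat.data_vars))
    min_ess = float(min(ess[v].min() for v in ess.data_vars))
    return {
        "max_rhat": max_rhat,
        "min_ess": min_ess,
        "passed": bool(max_rhat < 1.1 and min_ess > 1000),
    }


def pointwise_loglik(
    draws: PosteriorDraws, ratings: pd.DataFrame
) -> tuple[np.ndarray, pd.DataFrame]:
    """Log-likelihood of (possibly held-out) observations under each draw.

    Returns ``(loglik, obs)`` where ``loglik`` has shape
    (chain * draw, n_observations) and ``obs`` labels the columns. Subjects in
    ``ratings`` must have been part of the fit.
    """
    spec = draws.spec
    wide = ratings_to_wide(ratings)
    labels = partition_by_condition(ratings, spec)
    merged = wide.merge(labels, on=["subject_id", "item_id"], validate="one_to_one")
    subj_idx_of = {s: i for i, s in enumerate(draws.subjects)}
    unknown = set(merged["subject_id"]) - set(draws.subjects.tolist())
    if unknown:
        raise ValueError(f"subjects not in the fitted model: {sorted(unknown)}")
    subj_idx = merged["subject_id"].map(subj_idx_of).to_numpy()
    y = merged[list(SCORE_TYPES)].to_numpy(dtype=float)
    cond = merged["condition"].to_numpy()

    mu = draws.flat("mu")  # (D, n, 4)
    sig = {
        "positive": _compose(draws.flat("tau_pos"), draws.flat("omega_pos")),
        "neutral": _compose(draws.flat("tau_neu"), draws.flat("omega_neu")),
    }
    if "zero_pe" in cond:
        sig["zero_pe"] = _avg_sigma(sig["positive"], sig["neutral"])
    n_draws = mu.shape[0]
    out = np.empty((n_draws, len(merged)))
    chunk = max(1, int(2e7 // max(len(merged), 1)))  # bound temporaries
    for c in np.unique(cond):
        rows = np.flatnonzero(cond == c)
        y3_mean = draws.y3_means[c]
        m = _mean_vector(mu, y3_mean)  # (D, n, 5)
        sc = sig[c]
        prec = np.linalg.inv(sc)
        logdet = np.linalg.slogdet(sc)[1]
        idx = subj_idx[rows]
        for lo in range(0, n_draws, chunk):
            sl = slice(lo, lo + chunk)
            resid = y[rows][None, :, :] - m[sl, :, :][:, idx, :]  # (d, R, 5)
            quad = np.einsum("dri,drij,drj->dr", resid, prec[sl][:, idx], resid)
            out[sl, rows] = -0.5 * (_P * _LOG2PI + logdet[sl][:, idx] + quad)
    return out, merged[["subject_id", "item_id", "condition"]].reset_index(drop=True)


def _compose(tau: np.ndarray, omega: np.ndarray) -> np.ndarray:
    return omega * (tau[..., :, None] * tau[..., None, :])
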