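"""Synthetic cohort generator with known ground-truth update-bias parameters.

The generator mirrors the data-generating process the rating model assumes:
for each subject, the five speech scores -- pre-speech self-efficacy (y1),
post-speech self-evaluation (y2), judges' feedback (y3), post-feedback
self-evaluation (y4) and post-feedback self-efficacy (y5) -- are jointly
multivariate normal with subject-specific means and a condition-specific
covariance Sigma = diag(tau) @ Omega @ diag(tau). The judges' score y3 is not
sampled: it is experimenter-controlled, so each item's y3 is taken from the
feedback schedule and the remaining four scores are drawn from the conditional
normal given y3 (Schur-complement conditioning).

The per-subject "update bias" ground truth is the difference between the
positive- and neutral-condition correlations of feedback with the post-feedback
scores: Omega_pos(y3,y4) - Omega_neu(y3,y4) (self-evaluation) and
Omega_pos(y3,y5) - Omega_neu(y3,y5) (self-efficacy).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .task_design import FeedbackSchedule, assign_feedback

__all__ = [
    "SCORE_TYPES",
    "NEUTRAL_Y3_MEAN",
    "POSITIVE_Y3_MEAN",
    "NEUTRAL_Y3_SD",
    "POSITIVE_Y3_SD",
    "CohortConfig",
    "SubjectParams",
    "CohortData",
    "draw_subject_parameters",
    "sample_ratings",
    "simulate_cohort",
    "simulate_questionnaires",
    "reverse_code",
    "QUESTIONNAIRE_SCALES",
]

SCORE_TYPES = ("y1", "y2", "y3", "y4", "y5")

# Per-condition moments of the judges' score implied by the printed inventory
# {4x6, 5x7, 6x7} and {7x5, 8x7, 9x6, 10x2}: means 101/20 and 165/20.
NEUTRAL_Y3_MEAN = 5.05
POSITIVE_Y3_MEAN = 8.25
NEUTRAL_Y3_SD = 0.80467  # sqrt(0.6475)
POSITIVE_Y3_SD = 0.94207  # sqrt(0.8875)

# index of y3 within the 5-score vector
_Y3 = 2
_FREE = np.array([0, 1, 3, 4])  # y1, y2, y4, y5


def _base_omega(r34: float, r35: float) -> np.ndarray:
    """Population correlation template with the feedback-coupling cells set."""
    om = np.array(
        [
            #  y1    y2    y3    y4    y5
            [1.00, 0.50, 0.15, 0.40, 0.50],
            [0.50, 1.00, 0.25, 0.50, 0.40],
            [0.15, 0.25, 1.00, r34, r35],
            [0.40, 0.50, r34, 1.00, 0.50],
            [0.50, 0.40, r35, 0.50, 1.00],
        ]
    )
    return om


@dataclass
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate the design: 50 subjects x 40 items, subject means around
    the mid-scale with a realistic between-subject spread, within-subject score
    scales of ~1.5 VAS points, and the judges'-score scale matched to the
    within-condition spread of the fixed feedback inventory. The bias ranges
    define each subject's true update bias (positive- minus neutral-condition
    feedback coupling), drawn uniformly per subject.
    """

    n_subjects: int = 50
    n_items: int = 40
    # population means of (y1, y2, y4, y5) and their between-subject SD
    mu_pop: tuple[float, ...] = (5.3, 5.0, 5.6, 5.9)
    mu_sd: float = 1.3
    # within-subject scales (y1, y2, y3, y4, y5); y3 matched to the schedule
    tau_pos: tuple[float, ...] = (1.5, 1.5, POSITIVE_Y3_SD, 1.5, 1.5)
    tau_neu: tuple[float, ...] = (1.5, 1.5, NEUTRAL_Y3_SD, 1.5, 1.5)
    # midpoints of the feedback-coupling correlations; per-subject values are
    # midpoint +/- bias/2 with bias ~ U(range). Mid-0.5s coupling reflects how
    # strongly post-feedback ratings track the (well-recalled) feedback scores
    omega34_mid: float = 0.55
    omega35_mid: float = 0.55
    self_eval_bias_range: tuple[float, float] = (-0.3, 0.5)
    self_efficacy_bias_range: tuple[float, float] = (-0.3, 0.5)
    # Fisher-z jitter of the remaining correlations around the template
    omega_jitter: float = 0.05
    tau_jitter: float = 0.10  # lognormal sd on the scales
    discretize: bool = False
    questionnaire_bias_r: float = -0.29


@dataclass
class SubjectParams:
    """One subject's generating parameters (all invariants enforced on creation)."""

    mu: np.ndarray  # free means (y1, y2, y4, y5)
    tau_pos: np.ndarray
    tau_neu: np.ndarray
    omega_pos: np.ndarray
    omega_neu: np.ndarray

    def __post_init__(self) -> None:
        for om in (self.omega_pos, self.omega_neu):
            if not np.allclose(om, om.T) or not np.allclose(np.diag(om), 1.0):
                raise ValueError("Omega must be symmetric with unit diagonal")
            if np.linalg.eigvalsh(om).min() <= 0:
                raise ValueError("Omega must be positive definite")
        if np.any(self.tau_pos <= 0) or np.any(self.tau_neu <= 0):
            raise ValueError("tau must be positive")

    def sigma(self, condition: str) -> np.ndarray:
        tau = self.tau_pos if condition == "positive" else self.tau_neu
        omega = self.omega_pos if condition == "positive" else self.omega_neu
        return np.diag(tau) @ omega @ np.diag(tau)

    @property
    def self_eval_bias(self) -> float:
        return float(self.omega_pos[2, 3] - self.omega_neu[2, 3])

    @property
    def self_efficacy_bias(self) -> float:
        return float(self.omega_pos[2, 4] - self.omega_neu[2, 4])


@dataclass
class CohortData:
    ratings: pd.DataFrame
    truth: pd.DataFrame
    schedules: dict[int, FeedbackSchedule]
    params: list[SubjectParams]
    questionnaires: pd.DataFrame | None = None


def nearest_correlation(mat: np.ndarray, eig_floor: float = 1e-6) -> np.ndarray:
    """Project a symmetric matrix to a valid correlation matrix.

    Eigenvalues are clipped at ``eig_floor`` and the diagonal renormalized to
    one; for mild perturbations this leaves the matrix essentially unchanged.
    """
    sym = (mat + mat.T) / 2
    vals, vecs = np.linalg.eigh(sym)
    vals = np.clip(vals, eig_floor, None)
    out = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out


def _jitter_correlation(
    base: np.ndarray, sd: float, rng: np.random.Generator, max_tries: int = 100
) -> np.ndarray:
    """Perturb off-diagonal correlations on the Fisher-z scale, keep validity."""
    iu = np.triu_indices_from(base, k=1)
    for _ in range(max_tries):
        z = np.arctanh(np.clip(base[iu], -0.999, 0.999))
        z = z + rng.normal(0.0, sd, size=z.shape)
        cand = np.eye(base.shape[0])
        cand[iu] = np.tanh(z)
        cand = cand + cand.T - np.diag(np.diag(cand))
        cand = nearest_correlation(cand)
        if np.linalg.eigvalsh(cand).min() > 0:
            return cand
    raise RuntimeError("failed to produce a positive-definite correlation matrix")


def draw_subject_parameters(
    config: CohortConfig, seed: int
) -> list[SubjectParams]:
    """Draw per-subject generating parameters around the population values."""
    rng = np.random.default_rng(seed)
    params: list[SubjectParams] = []
    for _ in range(config.n_subjects):
        bias_ev = rng.uniform(*config.self_eval_bias_range)
        bias_se = rng.uniform(*config.self_efficacy_bias_range)
        om_pos = _base_omega(
            config.omega34_mid + bias_ev / 2, config.omega35_mid + bias_se / 2
        )
        om_neu = _base_omega(
            config.omega34_mid - bias_ev / 2, config.omega35_mid - bias_se / 2
        )
        if config.omega_jitter > 0:
            om_pos = _jitter_correlation(om_pos, config.omega_jitter, rng)
            om_neu = _jitter_correlation(om_neu, config.omega_jitter, rng)
        else:
            om_pos = nearest_correlation(om_pos)
            om_neu = nearest_correlation(om_neu)
        mu = rng.normal(config.mu_pop, config.mu_sd)
        jit = np.exp(rng.normal(0.0, config.tau_jitter, size=5)) if config.tau_jitter else 1.0
        tau_pos = np.asarray(config.tau_pos) * jit
        jit = np.exp(rng.normal(0.0, config.tau_jitter, size=5)) if config.tau_jitter else 1.0
        tau_neu = np.asarray(config.tau_neu) * jit
        params.append(SubjectParams(mu, tau_pos, tau_neu, om_pos, om_neu))
    return params


def conditional_given_y3(
    params: SubjectParams, condition: str, y3_mean: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Schur-complement conditioning of (y1,y2,y4,y5) on y3.

    Returns ``(mean_base, slope, cond_cov)`` such that the conditional mean for
    feedback value v is ``mean_base + slope * (v - y3_mean)``.
    """
    sigma = params.sigma(condition)
    s33 = sigma[_Y3, _Y3]
    s_f3 = sigma[_FREE, _Y3]
    slope = s_f3 / s33
    cond_cov = sigma[np.ix_(_FREE, _FREE)] - np.outer(s_f3, s_f3) / s33
    return params.mu.copy(), slope, cond_cov


def sample_ratings(
    params: SubjectParams,
    schedule: FeedbackSchedule,
    seed: int,
    subject_id: int = 1,
    discretize: bool = False,
) -> pd.DataFrame:
    """Sample one subject's long-format rating rows given a feedback schedule."""
    rng = np.random.default_rng(seed)
    rows = []
    for condition, y3_mean in (("neutral", NEUTRAL_Y3_MEAN), ("positive", POSITIVE_Y3_MEAN)):
        sub = schedule.table[schedule.table.condition == condition]
        if sub.empty:
            continue
        mu, slope, cond_cov = conditional_given_y3(params, condition, y3_mean)
        chol = np.linalg.cholesky(cond_cov)
        y3 = sub["score"].to_numpy(dtype=float)
        means = mu[None, :] + np.outer(y3 - y3_mean, slope)
        draws = means + rng.standard_normal((len(y3), 4)) @ chol.T
        if discretize:
            draws = np.clip(np.round(draws, 1), 0.0, 10.0)
        for item, y3v, vec in zip(sub["item_id"].to_numpy(), y3, draws):
            y = [vec[0], vec[1], y3v, vec[2], vec[3]]
            for st, val in zip(SCORE_TYPES, y):
                rows.append((subject_id, int(item), st, float(val)))
    out = pd.DataFrame(rows, columns=["subject_id", "item_id", "score_type", "value"])
    return out.sort_values(["item_id", "score_type"], ignore_index=True)


def simulate_cohort(config: CohortConfig, seed: int) -> CohortData:
    """Simulate ratings, schedules and questionnaires for a full cohort.

    Each subject gets an independent feedback schedule built from their own
    expected scores (drawn around the subject's y2 mean), exactly as the task
    generates it, and ratings sampled from the subject's generating parameters.
    """
    ss = np.random.SeedSequence(seed)
    param_seed, sched_seed, rate_seed, q_seed = ss.spawn(4)
    params = draw_subject_parameters(config, param_seed.generate_state(1)[0])

    rng = np.random.default_rng(sched_seed.generate_state(1)[0])
    tables = []
    schedules: dict[int, FeedbackSchedule] = {}
    truth_rows = []
    rate_children = rate_seed.spawn(config.n_subjects)
    for s, p in enumerate(params, start=1):
        expected = np.clip(
            rng.normal(p.mu[1], p.tau_neu[1], size=config.n_items), 0.0, 10.0
        )
        schedule = assign_feedback(expected, seed=int(rng.integers(2**31 - 1)))
        schedules[s] = schedule
        tables.append(
            sample_ratings(
                p,
                schedule,
                seed=rate_children[s - 1].generate_state(1)[0],
                subject_id=s,
                discretize=config.discretize,
            )
        )
        truth_rows.append(
            {
                "subject_id": s,
                "self_eval_bias": p.self_eval_bias,
                "self_efficacy_bias": p.self_efficacy_bias,
                "delta_pe": schedule.pe_contrast(),
            }
        )
    ratings = pd.concat(tables, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    quest = simulate_questionnaires(
        config,
        truth["self_efficacy_bias"].to_numpy(),
        seed=q_seed.generate_state(1)[0],
    )
    return CohortData(ratings, truth, schedules, params, quest)


# ---------------------------------------------------------------------------
# questionnaire battery

#: Scale name -> (social-sensitivity loading, self-negativity loading).
#: RSE (self-esteem) loads negatively on self-negativity; the reward-sensitivity
#: scale is left mostly unique, emulating a battery where one questionnaire
#: separates into its own minor component.
QUESTIONNAIRE_SCALES: dict[str, tuple[float, float]] = {
    "LSAS_SR": (0.85, 0.20),
    "SPIN": (0.85, 0.20),
    "BFNE": (0.80, 0.25),
    "FPES": (0.75, 0.10),
    "DPSOS_other": (0.65, 0.15),
    "DPSOS_self": (0.30, 0.60),
    "RSE": (-0.15, -0.75),
    "STAI": (0.30, 0.70),
    "NEO_neuroticism": (0.30, 0.70),
    "BDI_II": (0.20, 0.75),
    "SPSRQ_punishment": (0.45, 0.45),
    "SPSRQ_reward": (0.10, 0.10),
}


def simulate_questionnaires(
    config: CohortConfig, true_bias: np.ndarray, seed: int
) -> pd.DataFrame:
    """Generate the 12-scale battery from two latent factors plus unique noise.

    The self-negativity factor is given a configurable correlation
    (``config.questionnaire_bias_r``, default -0.29) with the true per-subject
    self-efficacy update bias, so that the symptom-profiling stage has a known
    effect to recover.
    """
    rng = np.random.default_rng(seed)
    n = len(true_bias)
    rho = float(config.questionnaire_bias_r)
    if not -1.0 <= rho <= 1.0:
        raise ValueError("questionnaire_bias_r must be a correlation")
    z = (true_bias - true_bias.mean()) / max(true_bias.std(), 1e-12)
    f_selfneg = rho * z + np.sqrt(1 - rho**2) * rng.standard_normal(n)
    f_social = rng.standard_normal(n)
    data = {}
    for scale, (l_soc, l_neg) in QUESTIONNAIRE_SCALES.items():
        unique_var = max(1.0 - l_soc**2 - l_neg**2, 0.10)
        raw = (
            l_soc * f_social
            + l_neg * f_selfneg
            + np.sqrt(unique_var) * rng.standard_normal(n)
        )
        data[scale] = 50.0 + 10.0 * raw  # arbitrary reporting units
    out = pd.DataFrame(data)
    out.insert(0, "subject_id", np.arange(1, n + 1))
    return out


def reverse_code(values, scale_max: float = 10.0):
    """Reverse-code negatively valenced items: value -> scale_max - value."""
    arr = np.asarray(values, dtype=float)
    if np.any((arr < 0) | (arr > scale_max)):
        raise ValueError(f"values must lie in [0, {scale_max}]")
    out = scale_max - arr
    return float(out) if np.isscalar(values) else out
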