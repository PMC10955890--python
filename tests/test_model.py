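"""Condition labelling, likelihood, bias extraction and sampler behaviour."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from updatebias.cohort import (
    CohortConfig,
    SubjectParams,
    draw_subject_parameters,
    sample_ratings,
    simulate_cohort,
)
from updatebias.model import (
    MCMCSettings,
    ModelSpec,
    check_convergence,
    extract_bias,
    fit_model,
    fit_model_pe,
    partition_by_condition,
    pointwise_loglik,
    ratings_to_wide,
)

from conftest import make_schedule


def _toy_ratings(rows):
    """rows: list of (subject, item, y1..y5)."""
    recs = []
    for s, q, *ys in rows:
        for name, v in zip(("y1", "y2", "y3", "y4", "y5"), ys):
            recs.append((s, q, name, v))
    return pd.DataFrame(recs, columns=["subject_id", "item_id", "score_type", "value"])


def test_partition_valence_threshold_boundary():
    ratings = _toy_ratings(
        [(1, 1, 5, 5, 7.0, 5, 5), (1, 2, 5, 5, 6.99, 5, 5), (1, 3, 5, 5, 4, 5, 5)]
    )
    lab = partition_by_condition(ratings, ModelSpec(kind="valence_split"))
    got = lab.set_index("item_id")["condition"]
    assert got[1] == "positive"
    assert got[2] == "neutral"
    assert got[3] == "neutral"


def test_partition_pe_sign_and_zero():
    ratings = _toy_ratings(
        [(1, 1, 5, 4, 7, 5, 5), (1, 2, 5, 8, 7, 5, 5), (1, 3, 5, 7, 7, 5, 5)]
    )
    lab = partition_by_condition(ratings, ModelSpec(kind="pe_split"))
    got = lab.set_index("item_id")["condition"]
    assert got[1] == "positive"  # y3 > y2
    assert got[2] == "neutral"  # y3 < y2
    assert got[3] == "zero_pe"  # y3 == y2


def test_partition_labels_match_recount_oracle(small_cohort):
    spec = ModelSpec(kind="pe_split")
    lab = partition_by_condition(small_cohort.ratings, spec)
    wide = ratings_to_wide(small_cohort.ratings)
    merged = wide.merge(lab, on=["subject_id", "item_id"])
    for _, row in merged.iterrows():
        pe = row.y3 - row.y2
        want = "positive" if pe > 0 else "neutral" if pe < 0 else "zero_pe"
        assert row.condition == want


def test_stored_loglik_matches_density_oracle(small_fit, small_cohort):
    """Stored pointwise log-likelihoods equal a direct multivariate-normal
    density evaluation at randomly chosen posterior draws."""
    draws = small_fit
    wide = ratings_to_wide(small_cohort.ratings)
    rng = np.random.default_rng(0)
    mu = draws.flat("mu")
    tp, tn = draws.flat("tau_pos"), draws.flat("tau_neu")
    op, on = draws.flat("omega_pos"), draws.flat("omega_neu")
    ll = draws.log_lik.reshape(-1, draws.log_lik.shape[-1])
    for d in rng.choice(mu.shape[0], size=5, replace=False):
        for row_i in rng.choice(len(draws.obs), size=8, replace=False):
            obs = draws.obs.iloc[row_i]
            i = np.flatnonzero(draws.subjects == obs.subject_id)[0]
            cond = obs.condition
            tau = (tp if cond == "positive" else tn)[d, i]
            om = (op if cond == "positive" else on)[d, i]
            sigma = np.diag(tau) @ om @ np.diag(tau)
            mean = np.insert(mu[d, i], 2, draws.y3_means[cond])
            y = (
                wide.set_index(["subject_id", "item_id"])
                .loc[(obs.subject_id, obs.item_id), ["y1", "y2", "y3", "y4", "y5"]]
                .to_numpy(dtype=float)
            )
            want = stats.multivariate_normal.logpdf(y, mean, sigma)
            assert ll[d, row_i] == pytest.approx(want, abs=1e-8)


def test_heldout_loglik_matches_stored(small_fit, small_cohort):
    """pointwise_loglik on the training data reproduces the stored matrix."""
    ll, obs = pointwise_loglik(small_fit, small_cohort.ratings)
    stored = small_fit.log_lik.reshape(-1, small_fit.log_lik.shape[-1])
    key = ["subject_id", "item_id"]
    order = obs.reset_index().merge(
        small_fit.obs.reset_index(), on=key, suffixes=("_new", "_old")
    )
    new_idx = order["index_new"].to_numpy()
    old_idx = order["index_old"].to_numpy()
    assert np.allclose(ll[:, new_idx], stored[:, old_idx], atol=1e-10)


def test_extract_bias_is_matrix_cell_difference(small_fit):
    bias = extract_bias(small_fit)
    op, on = small_fit.omega_pos, small_fit.omega_neu
    rng = np.random.default_rng(1)
    for _ in range(10):
        c = rng.integers(small_fit.n_chains)
        d = rng.integers(small_fit.n_draws)
        i = rng.integers(len(small_fit.subjects))
        assert bias.self_eval[c, d, i] == op[c, d, i, 2, 3] - on[c, d, i, 2, 3]
        assert bias.self_efficacy[c, d, i] == op[c, d, i, 2, 4] - on[c, d, i, 2, 4]
    assert np.all(np.abs(bias.self_eval) <= 2)
    assert np.all(np.abs(bias.self_efficacy) <= 2)


def test_omega_draws_are_valid_correlation_matrices(small_fit):
    for name in ("omega_pos", "omega_neu"):
        om = small_fit.flat(name).reshape(-1, 5, 5)
        sel = om[:: max(1, len(om) // 500)]
        assert np.allclose(np.diagonal(sel, axis1=1, axis2=2), 1.0, atol=1e-10)
        assert np.allclose(sel, np.transpose(sel, (0, 2, 1)), atol=1e-12)
        assert np.linalg.eigvalsh(sel).min() > 0


def test_single_subject_large_n_recovery():
    """With 2000 items the posterior mean of the feedback-coupling cells
    recovers the generating correlations to within 0.05."""
    om_pos = np.eye(5)
    om_neu = np.eye(5)
    for (a, b), (vp, vn) in {(2, 4): (0.6, 0.2), (2, 3): (0.5, 0.3)}.items():
        om_pos[a, b] = om_pos[b, a] = vp
        om_neu[a, b] = om_neu[b, a] = vn
    from updatebias.cohort import NEUTRAL_Y3_SD, POSITIVE_Y3_SD, nearest_correlation

    params = SubjectParams(
        mu=np.array([5.0, 5.0, 5.5, 6.0]),
        tau_pos=np.array([1.5, 1.5, POSITIVE_Y3_SD, 1.5, 1.5]),
        tau_neu=np.array([1.5, 1.5, NEUTRAL_Y3_SD, 1.5, 1.5]),
        omega_pos=nearest_correlation(om_pos),
        omega_neu=nearest_correlation(om_neu),
    )
    sched = make_schedule(2000, seed=0)
    ratings = sample_ratings(params, sched, seed=1)
    draws = fit_model(
        ratings,
        ModelSpec(),
        MCMCSettings(chains=2, warmup=200, iterations=400, seed=2),
        check=False,
    )
    assert float(draws.omega_pos[..., 2, 4].mean()) == pytest.approx(0.6, abs=0.05)
    assert float(draws.omega_neu[..., 2, 4].mean()) == pytest.approx(0.2, abs=0.05)


def test_null_bias_posteriors_cover_zero():
    """With identical condition covariances the per-subject 95% intervals of
    the bias indices cover zero for nearly all subjects."""
    cfg = CohortConfig(
        n_subjects=12,
        self_eval_bias_range=(0.0, 0.0),
        self_efficacy_bias_range=(0.0, 0.0),
        omega_jitter=0.0,
        tau_jitter=0.0,
    )
    cohort = simulate_cohort(cfg, seed=33)
    draws = fit_model(
        cohort.ratings,
        ModelSpec(),
        MCMCSettings(chains=2, warmup=200, iterations=400, seed=5),
        check=False,
    )
    bias = extract_bias(draws)
    flat = bias.self_efficacy.reshape(-1, len(bias.subjects))
    lo, hi = np.percentile(flat, [2.5, 97.5], axis=0)
    covered = ((lo <= 0) & (0 <= hi)).mean()
    assert covered >= 0.9


def test_pe_and_valence_agree_when_labels_coincide():
    """A dataset where y3 >= 7 exactly when PE > 0 makes the two models the
    same model; fitted biases agree within Monte Carlo error."""
    cohort = simulate_cohort(CohortConfig(n_subjects=4), seed=17)
    wide = ratings_to_wide(cohort.ratings)
    # force y2 so that sign(y3 - y2) == (y3 >= 7), leaving no zero PEs
    rng = np.random.default_rng(0)
    jitter = rng.uniform(-0.2, 0.2, size=len(wide))
    wide["y2"] = np.where(
        wide["y3"] >= 7, wide["y2"].clip(upper=6.5), 6.8 + jitter
    )
    long = wide.melt(
        id_vars=["subject_id", "item_id"], var_name="score_type", value_name="value"
    )
    lab_v = partition_by_condition(long, ModelSpec(kind="valence_split"))
    lab_p = partition_by_condition(long, ModelSpec(kind="pe_split"))
    assert (lab_v["condition"] == lab_p["condition"]).all()
    mcmc = MCMCSettings(chains=2, warmup=200, iterations=300, seed=6)
    spec = ModelSpec(fixed_y3_means={"neutral": 5.05, "positive": 8.25})
    bv = extract_bias(fit_model(long, spec, mcmc, check=False))
    import dataclasses

    spec_pe = dataclasses.replace(spec, kind="pe_split")
    bp = extract_bias(fit_model(long, spec_pe, mcmc, check=False))
    assert np.allclose(
        bv.self_efficacy.mean(axis=(0, 1)), bp.self_efficacy.mean(axis=(0, 1)), atol=0.08
    )


def test_all_zero_pe_is_flagged():
    rows = [(1, q, 5.0, 6.0, 6.0, 5.0, 5.0) for q in range(1, 11)]
    with pytest.raises(ValueError, match="zero prediction error"):
        fit_model_pe(_toy_ratings(rows), mcmc=MCMCSettings(chains=1, warmup=5, iterations=5))


def test_convergence_report_matches_split_rhat_oracle(small_fit):
    """The reported maximum R-hat agrees with the textbook split-chain
    formula applied directly to the stored draws."""
    report = check_convergence(small_fit)
    assert report["max_rhat"] < 1.1

    def split_rhat(x):  # x: (chains, draws)
        c, d = x.shape
        h = x.reshape(2 * c, d // 2)
        w = h.var(axis=1, ddof=1).mean()
        b = h.shape[1] * h.mean(axis=1).var(ddof=1)
        return np.sqrt(((h.shape[1] - 1) / h.shape[1] * w + b / h.shape[1]) / w)

    bias = extract_bias(small_fit)
    vals = [
        split_rhat(bias.self_efficacy[:, :, i]) for i in range(len(small_fit.subjects))
    ]
    import arviz as az

    ds = az.convert_to_dataset({"b": bias.self_efficacy})
    got = az.rhat(ds, method="split")["b"].to_numpy()
    assert np.allclose(got, vals, atol=1e-6)
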