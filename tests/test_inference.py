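"""HDI, posterior predictive checks, PE control, PCA profiling, mediation."""

import numpy as np
import pandas as pd
import pytest

from updatebias.inference import (
    ComponentProfile,
    correlate_components_with_bias,
    empirical_bias,
    group_bias_hdi,
    mediation_bootstrap,
    pca_varimax,
    ppc_bias_vs_empirical,
    ppc_correlation_table,
    residualize_on_pe,
)
from updatebias.model import BiasIndices, extract_bias


def _hdi_bruteforce(draws, level=0.95):
    """Shortest contiguous window on the sorted draws containing `level` mass."""
    x = np.sort(draws)
    n = len(x)
    m = int(np.ceil(level * n))
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return x[i], x[i + m - 1]


def test_hdi_matches_shortest_window_oracle():
    rng = np.random.default_rng(0)
    for draws in (
        rng.standard_normal(10_000),
        rng.gamma(2.0, 1.0, 5_000),
        rng.uniform(-1, 1, 2_000),
    ):
        bias = BiasIndices(
            subjects=np.array([1]),
            self_eval=draws.reshape(1, -1, 1),
            self_efficacy=draws.reshape(1, -1, 1),
        )
        res = group_bias_hdi(bias, "self_efficacy")
        lo, hi = _hdi_bruteforce(draws)
        spacing = np.diff(np.sort(draws)).max()
        assert abs(res.hdi_low - lo) <= spacing
        assert abs(res.hdi_high - hi) <= spacing


def test_group_hdi_median_and_decisions():
    rng = np.random.default_rng(1)
    # strictly positive group median posterior -> positive_bias
    pos = rng.normal(0.3, 0.05, size=(2, 1000, 9))
    bias = BiasIndices(np.arange(9), pos, pos)
    res = group_bias_hdi(bias, "self_eval")
    assert res.decision == "positive_bias"
    assert res.hdi_low <= res.point <= res.hdi_high
    # the per-draw median across subjects is what is summarized
    med = np.median(pos, axis=-1).ravel()
    assert res.point == pytest.approx(np.median(med))
    # constant draws give a degenerate interval decided by sign
    const = np.full((1, 100, 5), -0.2)
    res2 = group_bias_hdi(BiasIndices(np.arange(5), const, const), "self_efficacy")
    assert (res2.hdi_low, res2.hdi_high) == (-0.2, -0.2)
    assert res2.decision == "negative_bias"


def test_interval_straddling_zero_is_not_established():
    """An HDI like the reported [-0.05, 0.06] does not establish group bias."""
    rng = np.random.default_rng(2)
    draws = rng.uniform(-0.05, 0.06, size=(1, 4000, 1))
    res = group_bias_hdi(BiasIndices(np.array([1]), draws, draws), "self_eval")
    assert res.hdi_low < 0 < res.hdi_high
    assert res.decision == "not_established"


def _ratings_one_subject(y3, y4, y5, subject=1):
    rows = []
    for q, (a, b, c) in enumerate(zip(y3, y4, y5), start=1):
        for name, v in (("y1", 5.0), ("y2", 5.0), ("y3", a), ("y4", b), ("y5", c)):
            rows.append((subject, q, name, v))
    return pd.DataFrame(rows, columns=["subject_id", "item_id", "score_type", "value"])


def test_empirical_bias_trivial_and_oracle():
    rng = np.random.default_rng(3)
    y3 = np.array([4, 5, 6, 5, 4, 6, 7, 8, 9, 10, 8, 7], dtype=float)
    noise = rng.normal(0, 0.3, len(y3))
    # y5 tracks y3 perfectly in both conditions -> difference of r's ~ 0
    ratings = _ratings_one_subject(y3, y3 + noise, y3)
    assert empirical_bias(ratings, 1, "y5") == pytest.approx(0.0, abs=1e-12)
    # oracle: textbook Pearson formula per condition
    y4 = y3 + noise
    ratings = _ratings_one_subject(y3, y4, y3)
    pos, neu = y3 >= 7, y3 < 7

    def pearson(x, y):
        xc, yc = x - x.mean(), y - y.mean()
        return (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))

    want = pearson(y3[pos], y4[pos]) - pearson(y3[neu], y4[neu])
    assert empirical_bias(ratings, 1, "y4") == pytest.approx(want, abs=1e-12)


def test_ppc_bias_vs_empirical_on_cohort(small_fit, small_cohort):
    bias = extract_bias(small_fit)
    r, table = ppc_bias_vs_empirical(bias, small_cohort.ratings)
    assert set(table.columns) == {"subject_id", "model_bias", "empirical_bias"}
    # correlation is invariant to affine rescaling of either series
    r2 = np.corrcoef(3 * table.model_bias + 1, -0.5 * table.empirical_bias)[0, 1]
    assert abs(abs(r2) - abs(r)) < 1e-12
    # identical series give r = 1
    ident = np.corrcoef(table.model_bias, table.model_bias)[0, 1]
    assert ident == pytest.approx(1.0)


def test_ppc_correlation_table_covers_generator(small_fit, small_cohort):
    """Simulating from the posterior reproduces the observed pre/post score
    correlations: observed values fall inside the simulation intervals."""
    table = ppc_correlation_table(
        small_fit, small_cohort.ratings, small_cohort.schedules, n_sim=30, seed=5
    )
    assert len(table) == 10
    inside = (
        (table.observed >= table.simulated_low - 0.05)
        & (table.observed <= table.simulated_high + 0.05)
    ).mean()
    assert inside >= 0.9


def test_residualize_on_pe_cases():
    rng = np.random.default_rng(4)
    bias = rng.normal(0, 1, 50)
    dpe = rng.normal(3, 0.5, 50)
    # orthogonal fixture: make dpe exactly uncorrelated with bias
    dpe_orth = dpe - np.polyval(np.polyfit(bias, dpe, 1), bias) + dpe.mean()
    adj = residualize_on_pe(bias, dpe_orth)
    assert np.allclose(adj, bias, atol=1e-10)
    # perfectly explained: residuals collapse to the mean
    adj2 = residualize_on_pe(2 * dpe, dpe)
    assert np.allclose(adj2, (2 * dpe).mean())
    # normal-equations oracle
    x = np.column_stack([np.ones(50), dpe])
    beta = np.linalg.solve(x.T @ x, x.T @ bias)
    want = bias - x @ beta + bias.mean()
    assert np.allclose(residualize_on_pe(bias, dpe), want, atol=1e-10)
    with pytest.warns(UserWarning, match="constant"):
        out = residualize_on_pe(bias, np.full(50, 2.0))
    assert np.allclose(out, bias)


def test_pca_trace_and_communalities():
    rng = np.random.default_rng(5)
    f = rng.standard_normal((300, 3))
    load = rng.uniform(-0.8, 0.8, size=(12, 3))
    data = f @ load.T + 0.6 * rng.standard_normal((300, 12))
    q = pd.DataFrame(data, columns=[f"s{i}" for i in range(12)])
    q.insert(0, "subject_id", np.arange(300))
    prof = pca_varimax(q)
    # eigenvalues of a correlation matrix sum to its trace
    assert prof.eigenvalues.sum() == pytest.approx(12.0, abs=1e-8)
    assert prof.explained_variance_pct.sum() == pytest.approx(100.0, abs=1e-8)
    # varimax preserves per-scale communalities
    unrot = np.linalg.eigh(np.corrcoef(
        ((data - data.mean(0)) / data.std(0, ddof=1)).T
    ))
    vals = unrot.eigenvalues[::-1][: prof.n_retained]
    vecs = unrot.eigenvectors[:, ::-1][:, : prof.n_retained]
    communal_unrot = ((vecs * np.sqrt(vals)) ** 2).sum(axis=1)
    communal_rot = (prof.loadings.to_numpy() ** 2).sum(axis=1)
    assert np.allclose(np.sort(communal_rot), np.sort(communal_unrot), atol=1e-8)


def test_pca_independent_scales_have_flat_spectrum():
    rng = np.random.default_rng(6)
    q = pd.DataFrame(
        rng.standard_normal((10_000, 12)), columns=[f"s{i}" for i in range(12)]
    )
    prof = pca_varimax(q)
    assert np.all(np.abs(prof.eigenvalues - 1.0) < 0.15)
    # retention keeps exactly the eigenvalues above the cutoff
    assert prof.n_retained == int((prof.eigenvalues > 1.0).sum())


def test_retention_rule_on_prescribed_spectrum():
    """A battery whose correlation spectrum has three eigenvalues above one
    (6.86, 1.76, 1.08 pattern) retains exactly three components."""
    target = np.array(
        [6.86, 1.76, 1.08, 0.7, 0.5, 0.35, 0.25, 0.2, 0.15, 0.1, 0.03, 0.02]
    )
    target = target / target.sum() * 12
    rng = np.random.default_rng(7)
    # alternating projections: a correlation matrix (unit diagonal) whose
    # spectrum approximates the target
    corr = np.linalg.qr(rng.standard_normal((12, 12))).Q
    corr = corr @ np.diag(target) @ corr.T
    for _ in range(500):
        vals, vecs = np.linalg.eigh(corr)
        corr = vecs @ np.diag(np.sort(target)) @ vecs.T
        corr = (corr + corr.T) / 2
        np.fill_diagonal(corr, 1.0)
    # data whose sample correlation equals corr exactly: whiten, then color
    z = rng.standard_normal((4000, 12))
    z = (z - z.mean(0)) / z.std(0, ddof=1)
    evals, evecs = np.linalg.eigh(np.corrcoef(z.T))
    white = z @ evecs @ np.diag(1 / np.sqrt(evals)) @ evecs.T
    data = white @ np.linalg.cholesky(corr).T
    q = pd.DataFrame(data, columns=[f"s{i}" for i in range(12)])
    prof = pca_varimax(q)
    assert prof.n_retained == 3
    assert np.all(np.abs(prof.eigenvalues[:3] - np.sort(target)[::-1][:3]) < 0.25)


def test_correlate_components_with_bias_identity_and_fdr():
    rng = np.random.default_rng(8)
    n = 60
    comp = rng.standard_normal(n)
    dpe = rng.normal(3, 0.3, n)
    profile = ComponentProfile(
        loadings=pd.DataFrame(),
        eigenvalues=np.array([]),
        explained_variance_pct=np.array([]),
        scores=pd.DataFrame({"subject_id": np.arange(n), "component_1": comp}),
        n_retained=1,
    )
    bias = pd.DataFrame(
        {
            "subject_id": np.arange(n),
            "self_eval_bias": comp.copy(),
            "self_efficacy_bias": rng.standard_normal(n),
        }
    )
    out = correlate_components_with_bias(profile, bias, dpe, residualize="none")
    row = out[(out.component == "component_1") & (out.bias == "self_eval_bias")].iloc[0]
    assert row.r == pytest.approx(1.0)
    assert set(out.columns) >= {"r", "p", "ci_low", "ci_high", "p_fdr"}
    assert (out.p_fdr >= out.p - 1e-12).all()
    # Fisher-z CI oracle
    from scipy import stats as sps

    row2 = out[(out.component == "component_1") & (out.bias == "self_efficacy_bias")].iloc[0]
    z = np.arctanh(row2.r)
    half = sps.norm.ppf(0.975) / np.sqrt(n - 3)
    assert row2.ci_low == pytest.approx(np.tanh(z - half), abs=1e-10)
    assert row2.ci_high == pytest.approx(np.tanh(z + half), abs=1e-10)


def test_mediation_identity_and_recovery():
    rng = np.random.default_rng(9)
    n = 500
    x = rng.standard_normal(n)
    m = 0.5 * x + rng.standard_normal(n) * 0.8
    y = 0.6 * m + 0.3 * x + rng.standard_normal(n) * 0.8
    res = mediation_bootstrap(x, m, y, n_boot=800, seed=1)
    assert res.c_total == pytest.approx(res.c_prime + res.indirect, abs=1e-8)
    assert res.indirect == pytest.approx(0.3, abs=0.1)
    assert res.significant


def test_mediation_null_indirect_covers_zero():
    rng = np.random.default_rng(10)
    n = 300
    x = rng.standard_normal(n)
    m = 0.5 * x + rng.standard_normal(n)
    y = 0.4 * x + rng.standard_normal(n)  # b = 0
    res = mediation_bootstrap(x, m, y, n_boot=600, seed=2)
    assert res.ci_low <= 0 <= res.ci_high


def test_mediation_ci_width_shrinks_with_n():
    rng = np.random.default_rng(11)
    widths = []
    for n in (50, 200, 800):
        x = rng.standard_normal(n)
        m = 0.5 * x + rng.standard_normal(n)
        y = 0.6 * m + rng.standard_normal(n)
        res = mediation_bootstrap(x, m, y, n_boot=500, seed=3)
        widths.append(res.ci_high - res.ci_low)
    assert widths[0] > widths[1] > widths[2]
    # roughly 1/sqrt(n): a factor-16 n increase shrinks width ~4x
    assert widths[0] / widths[2] == pytest.approx(4.0, rel=0.5)
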