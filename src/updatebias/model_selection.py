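"""K-fold cross-validated model comparison by expected log predictive density.

Candidate labellings of the feedback conditions are compared by fitting each
model on K-1 folds of items and scoring the held-out (subject, item) score
vectors by their log posterior-predictive density. The expected log pointwise
predictive density (ELPD) is the sum of held-out log densities; a model is
preferred when the ELPD difference is at least twice the standard error of the
(paired, pointwise) difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .model import MCMCSettings, ModelSpec, fit_model, partition_by_condition, pointwise_loglik

__all__ = ["ELPDResult", "kfold_split", "kfold_elpd", "compare_models"]


@dataclass
class ELPDResult:
    """Total ELPD, its standard error and the pointwise contributions."""

    elpd: float
    se: float
    pointwise: pd.Series = field(repr=False)  # indexed by (subject_id, item_id)
    n: int = 0
    model: str = ""

    @classmethod
    def from_pointwise(cls, pointwise: pd.Series, model: str = "") -> "ELPDResult":
        vals = pointwise.to_numpy()
        n = len(vals)
        return cls(
            elpd=float(vals.sum()),
            se=float(np.sqrt(n) * vals.std(ddof=1)) if n > 1 else 0.0,
            pointwise=pointwise,
            n=n,
            model=model,
        )


def kfold_split(
    ratings: pd.DataFrame,
    k: int = 10,
    seed: int = 0,
    spec: ModelSpec | None = None,
) -> pd.DataFrame:
    """Assign each (subject, item) to one of ``k`` folds.

    Items are stratified by condition within subject: each subject's items in
    each condition are shuffled and dealt round-robin, so every fold holds a
    near-equal share of both conditions for every subject.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    labels = partition_by_condition(ratings, spec or ModelSpec())
    rng = np.random.default_rng(seed)
    fold = np.empty(len(labels), dtype=int)
    for (_, _), grp in labels.groupby(["subject_id", "condition"]):
        order = rng.permutation(len(grp))
        start = rng.integers(k)
        fold[grp.index.to_numpy()[order]] = (start + np.arange(len(grp))) % k
    out = labels[["subject_id", "item_id"]].copy()
    out["fold"] = fold
    return out


def kfold_elpd(
    spec: ModelSpec,
    ratings: pd.DataFrame,
    k: int = 10,
    mcmc: MCMCSettings | None = None,
    seed: int = 0,
    folds: pd.DataFrame | None = None,
) -> ELPDResult:
    """K-fold ELPD of one model specification.

    For each fold the model is refit on the complement and every held-out
    observation's log predictive density is the log of its posterior-draw-
    averaged likelihood. Fold fits use their own seeds derived from ``seed``.
    """
    mcmc = mcmc or MCMCSettings.profile("ci")
    if folds is None:
        folds = kfold_split(ratings, k, seed, spec)
    merged = ratings.merge(folds, on=["subject_id", "item_id"], validate="many_to_one")
    pointwise = {}
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(k)
    for f in range(k):
        train = merged[merged.fold != f].drop(columns="fold")
        test = merged[merged.fold == f].drop(columns="fold")
        if test.empty:
            continue
        fit_seed = int(children[f].generate_state(1)[0] % (2**31 - 1))
        import dataclasses

        draws = fit_model(
            train, spec, dataclasses.replace(mcmc, seed=fit_seed), check=False
        )
        ll, obs = pointwise_loglik(draws, test)
        lpd = logsumexp(ll, axis=0) - np.log(ll.shape[0])
        for (s, q), val in zip(zip(obs["subject_id"], obs["item_id"]), lpd):
            pointwise[(s, q)] = val
    series = pd.Series(pointwise).sort_index()
    series.index.names = ["subject_id", "item_id"]
    return ELPDResult.from_pointwise(series, model=spec.kind)


def compare_models(a: ELPDResult, b: ELPDResult) -> dict:
    """Pairwise ELPD comparison with the 2-standard-error preference rule.

    The standard error of the difference comes from the paired pointwise
    differences (not from the per-model standard errors).
    """
    pa, pb = a.pointwise.sort_index(), b.pointwise.sort_index()
    if not pa.index.equals(pb.index):
        raise ValueError("models were scored on different held-out points")
    diff = (pa - pb).to_numpy()
    n = len(diff)
    delta = float(diff.sum())
    se = float(np.sqrt(n) * diff.std(ddof=1)) if n > 1 else 0.0
    if se > 0 and abs(delta) >= 2 * se:
        preferred = a.model or "model_a" if delta > 0 else b.model or "model_b"
    else:
        preferred = "none"
    return {
        "elpd_a": a.elpd,
        "elpd_b": b.elpd,
        "delta": delta,
        "se_delta": se,
        "preferred": preferred,
        "model_a": a.model or "model_a",
        "model_b": b.model or "model_b",
    }
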