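"""Fictitious-feedback schedule generation for the public-speaking feedback task.

The task presents 40 performance attributes. For each attribute the participant
has stated an expected judges' score (0-10 VAS); the "judges" then return a
fixed inventory of scores -- 20 neutral (4-6) and 20 positive (7-10) -- assigned
so that the prediction error (feedback minus expected score) stays within a
believable, positively biased band of [-2, +4] wherever the remaining inventory
allows, with at most four exact hits (prediction error of zero). Trials are then
ordered with no more than two consecutive trials from the same condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FEEDBACK_COMPOSITION",
    "N_ITEMS",
    "N_POSITIVE_ITEMS",
    "N_NEGATIVE_ITEMS",
    "PE_BAND",
    "MAX_NULL_PE",
    "NEUTRAL_SCORES",
    "POSITIVE_SCORES",
    "FeedbackSchedule",
    "ScheduleSummary",
    "build_attribute_catalog",
    "assign_feedback",
    "order_trials",
    "schedule_summary",
]

#: Judges' score inventory, score -> number of occurrences.
FEEDBACK_COMPOSITION: dict[int, int] = {4: 6, 5: 7, 6: 7, 7: 5, 8: 7, 9: 6, 10: 2}

N_ITEMS = 40
#: Valence split of the 40 speech-performance attributes.
N_POSITIVE_ITEMS = 29
N_NEGATIVE_ITEMS = 11

#: Admissible prediction-error band (inclusive).
PE_BAND = (-2, 4)
#: Cap on items whose feedback equals the (rounded) expected score.
MAX_NULL_PE = 4

NEUTRAL_SCORES = (4, 5, 6)
POSITIVE_SCORES = (7, 8, 9, 10)


class InfeasibleScheduleError(RuntimeError):
    """Raised when no assignment of the score inventory satisfies the constraints."""


@dataclass(frozen=True)
class FeedbackSchedule:
    """Per-item judge score, condition label and prediction error.

    ``table`` has one row per item with columns ``item_id``, ``expected``,
    ``score``, ``condition`` and ``pe`` (``score`` minus ``expected`` rounded to
    the integer VAS grid).
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"item_id", "expected", "score", "condition", "pe"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"schedule table missing columns: {sorted(missing)}")

    @property
    def scores(self) -> np.ndarray:
        return self.table["score"].to_numpy()

    @property
    def conditions(self) -> np.ndarray:
        return self.table["condition"].to_numpy()

    @property
    def pe(self) -> np.ndarray:
        return self.table["pe"].to_numpy()

    def pe_contrast(self) -> float:
        """Mean prediction error on positive minus neutral trials (the per-subject nuisance)."""
        t = self.table
        return float(
            t.loc[t.condition == "positive", "pe"].mean()
            - t.loc[t.condition == "neutral", "pe"].mean()
        )

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeedbackSchedule":
        return cls(pd.read_csv(path))


@dataclass(frozen=True)
class ScheduleSummary:
    n_neutral: int
    n_positive: int
    mean_score_neutral: float
    mean_score_positive: float
    mean_pe_neutral: float
    mean_pe_positive: float
    n_null_pe: int
    delta_pe: float


def build_attribute_catalog() -> pd.DataFrame:
    """Return the 40-attribute catalog (29 positively, 11 negatively valenced).

    Attribute texts are placeholders; downstream analysis only uses item
    identity and valence (negative items are reverse-coded at scoring time).
    """
    valence = ["positive"] * N_POSITIVE_ITEMS + ["negative"] * N_NEGATIVE_ITEMS
    return pd.DataFrame(
        {
            "item_id": np.arange(1, N_ITEMS + 1),
            "label": [f"attribute_{i:02d}" for i in range(1, N_ITEMS + 1)],
            "valence": valence,
        }
    )


def _condition_of(score: int) -> str:
    return "neutral" if score <= 6 else "positive"


def _attempt_assignment(
    expected_rounded: np.ndarray, item_ids: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame | None:
    """One randomized greedy pass; returns None on dead-end inventory states."""
    n = len(item_ids)
    half = n // 2
    lo, hi = PE_BAND
    # Random condition split, but items whose expectation admits an in-band
    # error in only one condition are forced there first (an expectation of 2
    # cannot meet a positive score within +4; one of 9 cannot meet a neutral
    # score within -2). The remaining slots are filled uniformly at random.
    neu_ok = np.array(
        [any(lo <= s - e <= hi for s in NEUTRAL_SCORES) for e in expected_rounded]
    )
    pos_ok = np.array(
        [any(lo <= s - e <= hi for s in POSITIVE_SCORES) for e in expected_rounded]
    )
    forced_neu = np.flatnonzero(neu_ok & ~pos_ok).tolist()
    free = np.flatnonzero(neu_ok == pos_ok).tolist()  # feasible in both (or neither)
    neutral_items = set(forced_neu[:half])
    need = half - len(neutral_items)
    if need > 0:
        take = rng.permutation(len(free))[:need]
        neutral_items |= {free[j] for j in take}
    if len(neutral_items) < half:  # not enough eligible items: top up anyway
        rest = [i for i in range(n) if i not in neutral_items]
        for j in rng.permutation(len(rest))[: half - len(neutral_items)]:
            neutral_items.add(rest[j])

    inventory = {s: c for s, c in FEEDBACK_COMPOSITION.items()}
    # Scale inventory for reduced instances (testing convenience): keep the
    # printed composition exactly when n == 40, otherwise trim proportionally.
    if n != N_ITEMS:
        inventory = _reduced_inventory(n)

    order = rng.permutation(n)
    scores = np.zeros(n, dtype=int)
    null_count = 0
    lo, hi = PE_BAND
    for idx in order:
        pool = NEUTRAL_SCORES if idx in neutral_items else POSITIVE_SCORES
        avail = [s for s in pool if inventory.get(s, 0) > 0]
        if not avail:
            return None
        exp = expected_rounded[idx]
        in_band = [s for s in avail if lo <= s - exp <= hi]
        if null_count >= MAX_NULL_PE:
            in_band = [s for s in in_band if s - exp != 0]
        if in_band:
            score = int(rng.choice(in_band))
        else:
            # Fallback: smallest excess beyond the band; ties broken toward the
            # positive direction (the believable, positively biased choice).
            def excess(s: int) -> tuple[float, int]:
                pe = s - exp
                over = lo - pe if pe < lo else (pe - hi if pe > hi else 0)
                return (over, -np.sign(pe))

            candidates = [s for s in avail if s - exp != 0] or avail
            if null_count >= MAX_NULL_PE:
                candidates = [s for s in candidates if s - exp != 0]
                if not candidates:
                    return None
            score = min(candidates, key=excess)
        inventory[score] -= 1
        scores[idx] = score
        if score - exp == 0:
            null_count += 1
    if null_count > MAX_NULL_PE:
        return None
    table = pd.DataFrame(
        {
            "item_id": item_ids,
            "expected": expected_rounded,
            "score": scores,
            "condition": [_condition_of(s) for s in scores],
            "pe": scores - expected_rounded,
        }
    )
    pe = table["pe"].to_numpy()
    lo, hi = PE_BAND
    excess = np.maximum(lo - pe, 0) + np.maximum(pe - hi, 0)
    return table, int((excess > 0).sum()), float(excess.sum())


def _reduced_inventory(n: int) -> dict[int, int]:
    """Proportionally reduced score inventory with an equal neutral/positive split."""
    if n % 2:
        raise ValueError("number of items must be even")
    half = n // 2
    inv: dict[int, int] = {}
    for side in (NEUTRAL_SCORES, POSITIVE_SCORES):
        weights = np.array([FEEDBACK_COMPOSITION[s] for s in side], dtype=float)
        counts = np.floor(weights / weights.sum() * half).astype(int)
        # distribute the remainder to the largest fractional parts
        frac = weights / weights.sum() * half - counts
        for i in np.argsort(-frac)[: half - counts.sum()]:
            counts[i] += 1
        inv.update({s: int(c) for s, c in zip(side, counts)})
    return inv


def assign_feedback(
    expected: pd.Series | np.ndarray | dict,
    seed: int,
    max_retries: int = 1000,
) -> FeedbackSchedule:
    """Assign the fixed feedback-score inventory to items under the PE constraints.

    Parameters
    ----------
    expected
        Expected judges' score per item (0-10, may be fractional VAS values);
        a mapping / Series indexed by item_id, or an array in item order.
    seed
        Seed for the randomized condition split, processing order and
        within-band score choice.
    max_retries
        Number of fresh randomized passes before declaring infeasibility.

    The returned schedule preserves the score inventory exactly, splits items
    20/20 between neutral and positive feedback, keeps every prediction error
    within [-2, +4] whenever the remaining inventory admits it (otherwise the
    nearest admissible error is used), and has at most four zero prediction
    errors. Expected scores are rounded to the integer grid before prediction
    errors are booked, since "feedback equal to expectation" is an event on
    that grid.
    """
    if isinstance(expected, dict):
        expected = pd.Series(expected)
    if isinstance(expected, pd.Series):
        item_ids = expected.index.to_numpy()
        values = expected.to_numpy(dtype=float)
    else:
        values = np.asarray(expected, dtype=float)
        item_ids = np.arange(1, len(values) + 1)
    if np.any((values < 0) | (values > 10)):
        raise ValueError("expected scores must lie in [0, 10]")
    if len(values) % 2:
        raise ValueError("number of items must be even")

    expected_rounded = np.rint(values).astype(int)
    rng = np.random.default_rng(seed)
    best = None
    # Randomized restarts: keep the attempt with the fewest (then smallest)
    # out-of-band errors, so the fallback is used only when no restart avoids it.
    for _ in range(max_retries):
        out = _attempt_assignment(expected_rounded, item_ids, rng)
        if out is None:
            continue
        table, n_out, total_excess = out
        if best is None or (n_out, total_excess) < best[1:]:
            best = (table, n_out, total_excess)
        if n_out == 0:
            break
    if best is not None:
        table = best[0]
        table["expected"] = values  # keep the un-rounded expectations in the table
        table["pe"] = table["score"] - expected_rounded
        return FeedbackSchedule(table)
    raise InfeasibleScheduleError(
        "no assignment of the fixed score inventory satisfied the "
        f"null-PE cap (<= {MAX_NULL_PE}) within {max_retries} randomized passes"
    )


def order_trials(schedule: FeedbackSchedule, seed: int, max_run: int = 2) -> np.ndarray:
    """Uniformly random trial order with no run of more than ``max_run`` same-condition trials.

    Implemented by rejection sampling over uniform permutations, which is
    exactly uniform over the constraint-satisfying orderings.
    """
    rng = np.random.default_rng(seed)
    items = schedule.table["item_id"].to_numpy()
    is_pos = (schedule.conditions == "positive").astype(np.int8)
    n = len(items)
    while True:
        perm = rng.permutation(n)
        seq = is_pos[perm]
        if _max_run_length(seq) <= max_run:
            return items[perm]


def _max_run_length(seq: np.ndarray) -> int:
    best = run = 1
    for a, b in zip(seq[:-1], seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def schedule_summary(schedule: FeedbackSchedule) -> ScheduleSummary:
    """Condition counts, per-condition means and the PE contrast of a schedule."""
    t = schedule.table
    neu = t[t.condition == "neutral"]
    pos = t[t.condition == "positive"]
    return ScheduleSummary(
        n_neutral=len(neu),
        n_positive=len(pos),
        mean_score_neutral=float(neu["score"].mean()),
        mean_score_positive=float(pos["score"].mean()),
        mean_pe_neutral=float(neu["pe"].mean()),
        mean_pe_positive=float(pos["pe"].mean()),
        n_null_pe=int((t["pe"] == 0).sum()),
        delta_pe=float(pos["pe"].mean() - neu["pe"].mean()),
    )
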