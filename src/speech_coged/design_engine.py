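"""Experiment structure and the adaptive reward-titration state machine.

The discounting paradigm offers, on every trial, a fixed $2.00 reward for a
sentence at a hard signal-to-noise ratio (SNR) against a smaller, titrated
reward for the same task at an easy reference SNR (+20 dB).  Within a
six-trial block the easy offer follows a binary search: it starts at $1.00,
moves up after a "harder" choice and down after an "easier" choice, and the
adjustment magnitude halves each trial.  The smallest easy amount a listener
accepts estimates their indifference point for that SNR.

Offers live on an exact dyadic grid.  With the default $1/$2 bounds the
grid unit is $1/32 = $0.03125, so all arithmetic is carried out on integer
multiples of the unit and no floating-point drift can accumulate (every
multiple of 1/32 is also exactly representable in binary floating point,
which makes the dollar-valued views exact too).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SNRCondition",
    "TitrationState",
    "ChoiceRecord",
    "FamiliarizationTrial",
    "DiscountingBlock",
    "ExperimentSchedule",
    "BlockComplete",
    "ConfigurationError",
    "DEFAULT_CONDITIONS",
    "TRIALS_PER_BLOCK",
    "BLOCKS_PER_CONDITION",
    "default_conditions",
    "hard_conditions",
    "reference_condition",
    "init_titration",
    "next_offer",
    "run_block",
    "offer_sequence",
    "block_condition_sequence",
    "build_schedule",
    "build_familiarization",
    "match_lists",
]

TRIALS_PER_BLOCK = 6
BLOCKS_PER_CONDITION = 4
FAMILIARIZATION_CYCLES = 4
FAMILIARIZATION_BLOCK_SIZE = 4

EASIER = "easier"
HARDER = "harder"


class ConfigurationError(ValueError):
    """Raised when an experiment configuration violates a precondition."""


class BlockComplete(RuntimeError):
    """Signals that a six-trial block has no further offers to generate."""


@dataclass(frozen=True)
class SNRCondition:
    """One listening difficulty level, keyed by its SNR in dB.

    ``label`` is the color shown to participants in place of the numeric
    SNR (to avoid anchoring); it is cosmetic metadata and never enters any
    computation.
    """

    snr_db: float
    label: str = ""
    is_reference: bool = False


DEFAULT_CONDITIONS: tuple[SNRCondition, ...] = (
    SNRCondition(20.0, "black", is_reference=True),
    SNRCondition(4.0, "green"),
    SNRCondition(0.0, "blue"),
    SNRCondition(-4.0, "purple"),
    SNRCondition(-8.0, "yellow"),
    SNRCondition(-12.0, "red"),
)


def default_conditions() -> tuple[SNRCondition, ...]:
    return DEFAULT_CONDITIONS


def validate_conditions(conditions: Sequence[SNRCondition]) -> None:
    refs = [c for c in conditions if c.is_reference]
    if len(refs) != 1:
        raise ConfigurationError(
            f"exactly one reference condition required, got {len(refs)}"
        )
    snrs = [c.snr_db for c in conditions]
    if len(set(snrs)) != len(snrs):
        raise ConfigurationError("snr_db values must be distinct")


def hard_conditions(
    conditions: Sequence[SNRCondition] = DEFAULT_CONDITIONS,
) -> tuple[SNRCondition, ...]:
    """Non-reference conditions, ordered easiest (highest SNR) to hardest."""
    validate_conditions(conditions)
    hard = [c for c in conditions if not c.is_reference]
    return tuple(sorted(hard, key=lambda c: -c.snr_db))


def reference_condition(
    conditions: Sequence[SNRCondition] = DEFAULT_CONDITIONS,
) -> SNRCondition:
    validate_conditions(conditions)
    return next(c for c in conditions if c.is_reference)


@dataclass(frozen=True)
class TitrationState:
    """Adaptive-offer state within one block.

    The easy offer is stored as an integer offset (in grid units of
    ``(hard - low_start) / 32`` dollars) from the starting offer, and the
    pending adjustment as an integer number of units.  ``step_units`` is the
    adjustment that *will* be applied to produce the next trial's offer;
    after the sixth trial it is 0 (no seventh offer exists).
    """

    trial_index: int
    offset_units: int
    step_units: int
    low_start: float
    unit: float
    hard_offer: float

    @property
    def easy_offer(self) -> float:
        return self.low_start + self.offset_units * self.unit

    @property
    def step(self) -> float:
        return self.step_units * self.unit


def init_titration(low_start: float = 1.0, hard: float = 2.0) -> TitrationState:
    """Open a block: easy offer at ``low_start``, $`hard` fixed alternative.

    The first adjustment is half the gap between the two initial offers,
    giving a standard binary search with terminal resolution ``gap/32``
    ($0.03125 for the default $1/$2 bounds).
    """
    if not low_start < hard:
        raise ConfigurationError(
            f"easy starting offer ({low_start}) must be below the hard offer ({hard})"
        )
    if low_start <= 0:
        raise ConfigurationError("easy starting offer must be positive")
    gap = hard - low_start
    unit = gap / 32.0
    if low_start - 31 * unit <= 0:
        raise ConfigurationError(
            "bounds allow the easy offer to reach $0: need low_start > 31/32 of the gap"
        )
    return TitrationState(
        trial_index=1,
        offset_units=0,
        step_units=16,
        low_start=low_start,
        unit=unit,
        hard_offer=hard,
    )


def next_offer(state: TitrationState, choice: str) -> TitrationState:
    """Advance the titration given the choice made at the current offer.

    A "harder" choice raises the next easy offer by the pending step, an
    "easier" choice lowers it; the step then halves.  Calling this on the
    sixth trial raises :class:`BlockComplete`.
    """
    if choice not in (EASIER, HARDER):
        raise ValueError(f"choice must be 'easier' or 'harder', got {choice!r}")
    if state.trial_index >= TRIALS_PER_BLOCK:
        raise BlockComplete("block finished after six trials; no further offer")
    sign = 1 if choice == HARDER else -1
    return replace(
        state,
        trial_index=state.trial_index + 1,
        offset_units=state.offset_units + sign * state.step_units,
        step_units=state.step_units // 2,
    )


def run_block(
    choose: Callable[[TitrationState], str],
    low_start: float = 1.0,
    hard: float = 2.0,
) -> list[tuple[int, float, str, float]]:
    """Drive one six-trial block with a choice callback.

    Returns ``(trial_index, easy_offer, choice, chosen_amount)`` tuples,
    where ``chosen_amount`` is the easy offer for "easier" choices and the
    fixed hard reward otherwise.
    """
    state = init_titration(low_start, hard)
    rows = []
    for _ in range(TRIALS_PER_BLOCK):
        choice = choose(state)
        amount = state.easy_offer if choice == EASIER else state.hard_offer
        rows.append((state.trial_index, state.easy_offer, choice, amount))
        if state.trial_index < TRIALS_PER_BLOCK:
            state = next_offer(state, choice)
    return rows


def offer_sequence(choices: Iterable[str], low_start: float = 1.0, hard: float = 2.0) -> list[float]:
    """Easy-offer sequence produced by a fixed choice string (length ≤ 6)."""
    choices = list(choices)
    if len(choices) > TRIALS_PER_BLOCK:
        raise ValueError("at most six choices per block")
    state = init_titration(low_start, hard)
    offers = [state.easy_offer]
    for choice in choices[:-1]:
        state = next_offer(state, choice)
        offers.append(state.easy_offer)
    return offers


@dataclass(frozen=True)
class ChoiceRecord:
    """Immutable outcome of a single discounting trial."""

    subject_id: str
    block_index: int
    snr_db: float
    trial_index: int
    easy_offer: float
    choice: str
    chosen_amount: float
    keywords_correct: Optional[int] = None

    def __post_init__(self) -> None:
        if self.choice not in (EASIER, HARDER):
            raise ValueError(f"invalid choice {self.choice!r}")
        expected = self.easy_offer if self.choice == EASIER else 2.0
        if abs(self.chosen_amount - expected) > 1e-9:
            raise ValueError(
                f"chosen_amount {self.chosen_amount} inconsistent with "
                f"choice {self.choice!r} at offer {self.easy_offer}"
            )


@dataclass(frozen=True)
class FamiliarizationTrial:
    cycle: int
    snr_db: float
    sentence_id: str
    is_filler: bool


@dataclass(frozen=True)
class DiscountingBlock:
    block_index: int
    snr_db: float
    list_id: int
    sentence_ids: tuple[str, ...]


@dataclass(frozen=True)
class ExperimentSchedule:
    familiarization: tuple[FamiliarizationTrial, ...]
    discounting_blocks: tuple[DiscountingBlock, ...]
    seed: int

    @property
    def n_discounting_trials(self) -> int:
        return sum(len(b.sentence_ids) for b in self.discounting_blocks)


def block_condition_sequence(
    conditions: Sequence[SNRCondition] = DEFAULT_CONDITIONS,
    blocks_per_condition: int = BLOCKS_PER_CONDITION,
    rng: np.random.Generator | None = None,
) -> list[SNRCondition]:
    """Seed-shuffled sequence of hard conditions, each appearing equally often."""
    rng = rng if rng is not None else np.random.default_rng()
    hard = hard_conditions(conditions)
    seq = [c for c in hard for _ in range(blocks_per_condition)]
    perm = rng.permutation(len(seq))
    return [seq[i] for i in perm]


def build_schedule(
    sentence_lists: Mapping[int, Sequence[str]],
    conditions: Sequence[SNRCondition] = DEFAULT_CONDITIONS,
    blocks_per_condition: int = BLOCKS_PER_CONDITION,
    seed: int = 0,
) -> ExperimentSchedule:
    """Assign matched sentence lists and hard SNRs to discounting blocks.

    Block order and the list-to-block pairing are independent seeded
    permutations, so every seed yields a unique combination and order while
    each sentence list is used exactly once.
    """
    hard = hard_conditions(conditions)
    n_blocks = len(hard) * blocks_per_condition
    if len(sentence_lists) != n_blocks:
        raise ConfigurationError(
            f"need {n_blocks} sentence lists (one per block), got {len(sentence_lists)}"
        )
    rng = np.random.default_rng(seed)
    cond_seq = block_condition_sequence(conditions, blocks_per_condition, rng)
    list_ids = list(sentence_lists)
    list_order = [list_ids[i] for i in rng.permutation(len(list_ids))]
    blocks = tuple(
        DiscountingBlock(
            block_index=i + 1,
            snr_db=cond.snr_db,
            list_id=lid,
            sentence_ids=tuple(sentence_lists[lid]),
        )
        for i, (cond, lid) in enumerate(zip(cond_seq, list_order))
    )
    fam = ()  # familiarization is built separately when sentence pools are given
    return ExperimentSchedule(familiarization=fam, discounting_blocks=blocks, seed=seed)


def build_familiarization(
    target_ids: Sequence[str],
    filler_ids: Sequence[str],
    conditions: Sequence[SNRCondition] = DEFAULT_CONDITIONS,
    seed: int = 0,
) -> tuple[FamiliarizationTrial, ...]:
    """Build the 80-trial familiarization phase.

    Four cycles, each visiting the five hard SNRs from easiest to hardest in
    four-trial blocks of two target and two filler sentences (alternating,
    with a seeded coin flip deciding which kind leads each block).  Each
    condition receives 8 target and 8 filler sentences overall.
    """
    hard = hard_conditions(conditions)
    n_cond = len(hard)
    per_cond = FAMILIARIZATION_CYCLES * FAMILIARIZATION_BLOCK_SIZE // 2  # 8
    need = n_cond * per_cond
    if len(target_ids) < need or len(filler_ids) < need:
        raise ConfigurationError(
            f"familiarization needs {need} target and {need} filler sentences; "
            f"got {len(target_ids)} targets, {len(filler_ids)} fillers"
        )
    rng = np.random.default_rng(seed)
    targets = [target_ids[i] for i in rng.permutation(len(target_ids))[:need]]
    fillers = [filler_ids[i] for i in rng.permutation(len(filler_ids))[:need]]
    # deal 8 targets + 8 fillers to each condition
    t_pool = {c.snr_db: targets[i * per_cond : (i + 1) * per_cond] for i, c in enumerate(hard)}
    f_pool = {c.snr_db: fillers[i * per_cond : (i + 1) * per_cond] for i, c in enumerate(hard)}
    trials: list[FamiliarizationTrial] = []
    for cycle in range(1, FAMILIARIZATION_CYCLES + 1):
        for cond in hard:  # easiest → hardest within every cycle
            block_targets = [t_pool[cond.snr_db].pop() for _ in range(2)]
            block_fillers = [f_pool[cond.snr_db].pop() for _ in range(2)]
            filler_first = bool(rng.integers(2))
            pair = (block_fillers, block_targets) if filler_first else (block_targets, block_fillers)
            for a, b in zip(*pair):
                for sid, kind_filler in ((a, filler_first), (b, not filler_first)):
                    trials.append(
                        FamiliarizationTrial(
                            cycle=cycle,
                            snr_db=cond.snr_db,
                            sentence_id=sid,
                            is_filler=kind_filler,
                        )
                    )
    return tuple(trials)


def _spread(sums: np.ndarray, m: int) -> float:
    means = sums / m
    return float(means.max() - means.min())


def match_lists(
    sentences: pd.DataFrame | Mapping[str, float],
    k: int,
    m: int,
) -> list[list[str]]:
    """Partition sentences into ``k`` lists of ``m`` matched on intelligibility.

    Greedy serpentine seeding by descending score followed by pairwise-swap
    descent on the spread (max − min) of list-mean scores, with the variance
    of list means as a tie-break so the descent cannot cycle.  The result is
    locally optimal: no single cross-list swap reduces the spread.
    """
    if isinstance(sentences, pd.DataFrame):
        ids = sentences.iloc[:, 0].astype(str).tolist()
        scores = np.asarray(sentences.iloc[:, 1], dtype=float)
    else:
        ids = [str(i) for i in sentences.keys()]
        scores = np.asarray(list(sentences.values()), dtype=float)
    if len(ids) != k * m:
        raise ValueError(f"need exactly k*m = {k * m} sentences, got {len(ids)}")
    if np.any(scores < 0) or np.any(scores > 1):
        raise ValueError("intelligibility scores must lie in [0, 1]")

    order = np.argsort(-scores, kind="stable")
    assign = np.empty(len(ids), dtype=int)
    for row in range(m):  # serpentine deal
        cols = range(k) if row % 2 == 0 else range(k - 1, -1, -1)
        for j, col in enumerate(cols):
            assign[order[row * k + j]] = col

    sums = np.zeros(k)
    np.add.at(sums, assign, scores)

    def objective(s: np.ndarray) -> tuple[float, float]:
        means = s / m
        return (round(float(means.max() - means.min()), 12), round(float(means.var()), 12))

    best = objective(sums)
    improved = True
    while improved:
        improved = False
        for i, j in itertools.combinations(range(len(ids)), 2):
            li, lj = assign[i], assign[j]
            if li == lj:
                continue
            delta = scores[j] - scores[i]
            trial = sums.copy()
            trial[li] += delta
            trial[lj] -= delta
            cand = objective(trial)
            if cand < best:
                best = cand
                sums = trial
                assign[i], assign[j] = lj, li
                improved = True
    return [[ids[idx] for idx in np.flatnonzero(assign == col)] for col in range(k)]
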