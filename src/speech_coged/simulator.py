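"""Synthetic listeners for the speech effort-discounting paradigm.

Every downstream stage (titration, summaries, group statistics, the mixed
model) is exercised against simulated participants whose latent structure is
known.  A simulated listener has two parts:

* a *decision* model — one latent indifference point per hard SNR (the easy
  reward at which the two offers are subjectively equal) plus a logistic
  choice-noise temperature; and
* a *performance* model — the probability of recognizing each of a
  sentence's four keywords, anchored per SNR to published group norms
  (mean and SD of the proportion of keywords correct for young and older
  adults at the five hard SNRs), with a fitted logistic psychometric
  function used for SNRs outside the calibrated set.

Calibration note: the group norms are not logistic-shaped (the young means
are non-monotone near ceiling), so a two-parameter logistic alone cannot
reproduce them.  The calibration therefore keeps the logistic core for
interpolation but, at the five study SNRs, draws each agent's keyword
probability from a clamped Gaussian whose latent location is solved
numerically so the *clamped* mean equals the published group mean exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares
from scipy.special import expit
from scipy.stats import norm

from . import design_engine as de
from .design_engine import (
    DEFAULT_CONDITIONS,
    EASIER,
    HARDER,
    SNRCondition,
    hard_conditions,
    reference_condition,
)

__all__ = [
    "GROUP_INTELLIGIBILITY_NORMS",
    "KEYWORDS_PER_SENTENCE",
    "ParticipantProfile",
    "AgentParams",
    "EffectConfig",
    "GroupPsychometric",
    "calibrate_psychometric",
    "simulate_choice",
    "simulate_intelligibility",
    "generate_cohort",
    "run_experiment",
    "run_familiarization",
    "default_sentence_table",
]

KEYWORDS_PER_SENTENCE = 4

#: Group mean (SD) proportion of sentence keywords correctly repeated at each
#: hard SNR, for normal-hearing young adults (18-24 y) and older adults
#: (65-79 y) listening to sentences in speech-shaped noise.  These norms are
#: the calibration target for the simulated listeners.
GROUP_INTELLIGIBILITY_NORMS: dict[str, dict[float, tuple[float, float]]] = {
    "young": {
        4.0: (0.95, 0.05),
        0.0: (0.97, 0.05),
        -4.0: (0.91, 0.08),
        -8.0: (0.56, 0.16),
        -12.0: (0.17, 0.09),
    },
    "older": {
        4.0: (0.90, 0.14),
        0.0: (0.86, 0.17),
        -4.0: (0.66, 0.25),
        -8.0: (0.30, 0.16),
        -12.0: (0.07, 0.07),
    },
}

#: sentences per SNR entering the norm means (half of the 16 familiarization
#: sentences per SNR are analyzed targets), used to strip the binomial
#: measurement component out of the published SDs.
_NORM_SENTENCES_PER_SNR = 8

# audiogram generation: median threshold (dB HL) per frequency
_AUDIOGRAM_BASE = {
    "young": {250: 8.0, 500: 7.0, 1000: 5.0, 2000: 5.0, 4000: 8.0, 8000: 12.0},
    "older": {250: 15.0, 500: 15.0, 1000: 17.0, 2000: 22.0, 4000: 35.0, 8000: 50.0},
}
_AUDIOGRAM_SUBJECT_SD = {"young": 4.0, "older": 8.0}
_AUDIOGRAM_EAR_SD = {"young": 3.0, "older": 4.0}

_AGE_RANGE = {"young": (18, 24), "older": (65, 79)}
_AGE_MEAN_SD = {"young": (19.9, 1.5), "older": (70.9, 3.6)}
_WM_MEAN_SD = {"young": (0.55, 0.08), "older": (0.42, 0.12)}
_MOTIVATION_MONEY = {"young": (5.5, 1.2), "older": (4.5, 1.4)}
_MOTIVATION_DESIRE = {"young": (5.31, 1.2), "older": (5.94, 1.0)}
_PTA_CENTER = {"young": 5.5, "older": 17.0}
_PTA_SCALE = {"young": 4.0, "older": 8.0}


@dataclass(frozen=True)
class ParticipantProfile:
    """Covariates of one (simulated) participant."""

    subject_id: str
    subject_index: int
    age_group: str
    age_years: int
    thresholds: Mapping[str, Mapping[int, float]]  # ear -> frequency (Hz) -> dB HL
    wm_score: float
    income_band: int
    motivation_money: int
    motivation_desire: int
    hhie_score: Optional[float] = None  # older group only


@dataclass(frozen=True)
class AgentParams:
    """Latent decision and performance parameters of a simulated listener."""

    indifference: Mapping[float, float]  # hard SNR (dB) -> dollars in [0, 2]
    temperature: float = 0.0
    psychometric_midpoint: float = -8.0
    psychometric_slope: float = 0.45
    keyword_p: Mapping[float, float] = field(default_factory=dict)

    def keyword_probability(self, snr_db: float) -> float:
        if snr_db in self.keyword_p:
            return float(self.keyword_p[snr_db])
        p = expit(self.psychometric_slope * (snr_db - self.psychometric_midpoint))
        return float(np.clip(p, 0.0, 1.0))


@dataclass(frozen=True)
class GroupPsychometric:
    """Calibrated group-level performance model.

    ``midpoint``/``slope`` are the least-squares logistic fit to the group
    mean proportions; ``anchors`` maps each calibrated SNR to the latent
    (mean, SD) of the clamped-Gaussian distribution of individual keyword
    probabilities, with the latent mean bias-corrected so that the clamped
    mean reproduces the group norm.
    """

    group: str
    midpoint: float
    slope: float
    anchors: Mapping[float, tuple[float, float]]


def _clamped_normal_mean(mu: float, sd: float) -> float:
    """E[min(max(X, 0), 1)] for X ~ N(mu, sd)."""
    if sd <= 0:
        return float(np.clip(mu, 0.0, 1.0))
    a = (0.0 - mu) / sd
    b = (1.0 - mu) / sd
    return float(
        norm.sf(b) + mu * (norm.cdf(b) - norm.cdf(a)) - sd * (norm.pdf(b) - norm.pdf(a))
    )


def calibrate_psychometric(
    group: str,
    norms: Mapping[str, Mapping[float, tuple[float, float]]] | None = None,
    sentences_per_snr: int = _NORM_SENTENCES_PER_SNR,
) -> GroupPsychometric:
    """Fit the group performance model to published intelligibility norms."""
    norms = norms if norms is not None else GROUP_INTELLIGIBILITY_NORMS
    if group not in norms:
        raise ValueError(f"unknown group {group!r}; have {sorted(norms)}")
    table = norms[group]
    snrs = np.array(sorted(table, reverse=True), dtype=float)
    means = np.array([table[s][0] for s in snrs])
    sds = np.array([table[s][1] for s in snrs])

    def resid(theta: np.ndarray) -> np.ndarray:
        mid, slope = theta
        return expit(slope * (snrs - mid)) - means

    fit = least_squares(resid, x0=[-8.0, 0.5])
    midpoint, slope = map(float, fit.x)

    n_draws = sentences_per_snr * KEYWORDS_PER_SENTENCE
    anchors: dict[float, tuple[float, float]] = {}
    for s, mean, sd in zip(snrs, means, sds):
        binom_var = mean * (1.0 - mean) / n_draws
        latent_sd = math.sqrt(max(sd**2 - binom_var, 0.0))
        if latent_sd == 0.0:
            anchors[float(s)] = (mean, 0.0)
            continue
        latent_mu = brentq(
            lambda mu: _clamped_normal_mean(mu, latent_sd) - mean, -2.0, 3.0, xtol=1e-12
        )
        anchors[float(s)] = (float(latent_mu), latent_sd)
    return GroupPsychometric(group=group, midpoint=midpoint, slope=slope, anchors=anchors)


@dataclass(frozen=True)
class EffectConfig:
    """Generative links between covariates and discounting behavior.

    Baseline indifference points encode the group-level discounting curves
    (older adults give up more reward at the hardest SNRs).  Within the
    older group, indifference points fall with better-ear PTA and rise with
    working memory; the young group's covariates carry no effect, mirroring
    the null relationships observed in normal-hearing young listeners.
    All dollar values are clamped to [0, 2].
    """

    baseline_indifference: Mapping[str, Mapping[float, float]] = field(
        default_factory=lambda: {
            "young": {4.0: 1.90, 0.0: 1.85, -4.0: 1.70, -8.0: 1.45, -12.0: 1.25},
            "older": {4.0: 1.80, 0.0: 1.70, -4.0: 1.45, -8.0: 0.95, -12.0: 0.75},
        }
    )
    pta_coef: Mapping[str, float] = field(
        default_factory=lambda: {"young": 0.0, "older": -0.011}
    )  # dollars per dB of better-ear PTA, centered
    wm_coef: Mapping[str, float] = field(
        default_factory=lambda: {"young": 0.0, "older": 0.83}
    )  # dollars per unit working-memory proportion, centered
    subject_noise_sd: float = 0.10  # shared shift across conditions, dollars
    condition_noise_sd: float = 0.15  # per-condition jitter, dollars
    temperature: float = 0.15  # logistic choice noise, dollars
    performance_sensitivity: float = 0.0  # dollars per SD of listening ability
    monotone: bool = False  # force indifference non-increasing with difficulty

    @classmethod
    def zero_noise(cls, **overrides) -> "EffectConfig":
        base = dict(
            pta_coef={"young": 0.0, "older": 0.0},
            wm_coef={"young": 0.0, "older": 0.0},
            subject_noise_sd=0.0,
            condition_noise_sd=0.0,
            temperature=0.0,
        )
        base.update(overrides)
        return cls(**base)


def simulate_choice(
    agent: AgentParams,
    easy_offer: float,
    condition: SNRCondition | float,
    rng: np.random.Generator,
) -> str:
    """One offer decision: "easier" (take the titrated reward) or "harder".

    A zero-temperature agent is a pure threshold: it takes the easier option
    whenever the offer is at least its indifference point (ties go to
    "easier").  With temperature t > 0 the probability of choosing easier is
    logistic((offer − indifference) / t).
    """
    snr = condition.snr_db if isinstance(condition, SNRCondition) else float(condition)
    if snr not in agent.indifference:
        raise ValueError(f"agent has no indifference point for SNR {snr} dB")
    v = agent.indifference[snr]
    if agent.temperature == 0.0:
        return EASIER if easy_offer >= v else HARDER
    p_easier = expit((easy_offer - v) / agent.temperature)
    return EASIER if rng.random() < p_easier else HARDER


def simulate_intelligibility(
    agent: AgentParams,
    condition: SNRCondition | float,
    rng: np.random.Generator,
    n_keywords: int = KEYWORDS_PER_SENTENCE,
) -> int:
    """Number of keywords (0..4) recognized in one sentence at a given SNR."""
    snr = condition.snr_db if isinstance(condition, SNRCondition) else float(condition)
    p = agent.keyword_probability(snr)
    return int(rng.binomial(n_keywords, p))


def _subject_rng(seed: int, subject_index: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, subject_index, stage)))


def _draw_profile_and_agent(
    group: str,
    subject_id: str,
    subject_index: int,
    effects: EffectConfig,
    psychometrics: Mapping[str, GroupPsychometric],
    rng: np.random.Generator,
    conditions: Sequence[SNRCondition],
) -> tuple[ParticipantProfile, AgentParams]:
    lo, hi = _AGE_RANGE[group]
    mu, sd = _AGE_MEAN_SD[group]
    age = int(np.clip(round(rng.normal(mu, sd)), lo, hi))

    shift = rng.normal(0.0, _AUDIOGRAM_SUBJECT_SD[group])
    thresholds: dict[str, dict[int, float]] = {}
    for ear in ("left", "right"):
        thresholds[ear] = {
            f: float(
                np.clip(
                    5 * round((base + shift + rng.normal(0.0, _AUDIOGRAM_EAR_SD[group])) / 5),
                    -10,
                    90,
                )
            )
            for f, base in _AUDIOGRAM_BASE[group].items()
        }
    pta_per_ear = [
        np.mean([thresholds[ear][f] for f in (500, 1000, 2000)]) for ear in ("left", "right")
    ]
    better_pta = float(min(pta_per_ear))

    wm_mu, wm_sd = _WM_MEAN_SD[group]
    wm = float(np.clip(rng.normal(wm_mu, wm_sd), 0.0, 1.0))
    income = int(rng.integers(1, 9))

    def rating(pair: tuple[float, float]) -> int:
        return int(np.clip(round(rng.normal(*pair)), 1, 7))

    z_pta = (better_pta - _PTA_CENTER[group]) / _PTA_SCALE[group]
    hhie = None
    if group == "older":
        latent = 0.75 * z_pta + 0.66 * rng.normal()
        hhie = float(np.clip(2 * round((12.0 + 6.0 * latent) / 2), 0, 40))

    profile = ParticipantProfile(
        subject_id=subject_id,
        subject_index=subject_index,
        age_group=group,
        age_years=age,
        thresholds=thresholds,
        wm_score=wm,
        income_band=income,
        motivation_money=rating(_MOTIVATION_MONEY[group]),
        motivation_desire=rating(_MOTIVATION_DESIRE[group]),
        hhie_score=hhie,
    )

    # listening ability partially tracks hearing status
    ability = -0.5 * z_pta + math.sqrt(1 - 0.25) * rng.normal()
    psych = psychometrics[group]
    keyword_p = {
        snr: float(np.clip(mu_l + sd_l * ability, 0.0, 1.0))
        for snr, (mu_l, sd_l) in psych.anchors.items()
    }

    base = effects.baseline_indifference[group]
    subject_shift = (
        effects.pta_coef[group] * (better_pta - _PTA_CENTER[group])
        + effects.wm_coef[group] * (wm - _WM_MEAN_SD[group][0])
        + effects.performance_sensitivity * ability
        + rng.normal(0.0, effects.subject_noise_sd)
    )
    hard = hard_conditions(conditions)
    values = []
    for cond in hard:  # easiest -> hardest
        v = base[cond.snr_db] + subject_shift + rng.normal(0.0, effects.condition_noise_sd)
        values.append(v)
    if effects.monotone:
        values = list(np.minimum.accumulate(values))
    indifference = {
        cond.snr_db: float(np.clip(v, 0.0, 2.0)) for cond, v in zip(hard, values)
    }
    agent = AgentParams(
        indifference=indifference,
        temperature=effects.temperature,
        psychometric_midpoint=psych.midpoint,
        psychometric_slope=psych.slope,
        keyword_p=keyword_p,
    )
    return profile, agent


def generate_cohort(
    n_young: int,
    n_older: int,
    effects: EffectConfig | None = None,
    seed: int = 0,
    conditions: Sequence[SNRCondition] = DEFAULT_CONDITIONS,
) -> tuple[list[ParticipantProfile], list[AgentParams]]:
    """Draw a synthetic cohort (profiles plus matched decision agents).

    Each subject is generated from its own child random stream derived from
    the root seed and the subject's index, so cohorts are reproducible and
    insensitive to generation order.
    """
    if n_young < 0 or n_older < 0 or n_young + n_older < 1:
        raise ValueError("cohort sizes must be non-negative and total at least 1")
    effects = effects if effects is not None else EffectConfig()
    psychometrics = {g: calibrate_psychometric(g) for g in ("young", "older")}
    profiles: list[ParticipantProfile] = []
    agents: list[AgentParams] = []
    specs = [("young", i, f"Y{i + 1:03d}") for i in range(n_young)]
    specs += [("older", n_young + i, f"O{i + 1:03d}") for i in range(n_older)]
    for group, idx, sid in specs:
        rng = _subject_rng(seed, idx, stage=0)
        profile, agent = _draw_profile_and_agent(
            group, sid, idx, effects, psychometrics, rng, conditions
        )
        profiles.append(profile)
        agents.append(agent)
    return profiles, agents


def run_experiment(
    profiles: Sequence[ParticipantProfile],
    agents: Sequence[AgentParams],
    seed: int = 0,
    conditions: Sequence[SNRCondition] = DEFAULT_CONDITIONS,
    blocks_per_condition: int = de.BLOCKS_PER_CONDITION,
    low_start: float = 1.0,
    hard: float = 2.0,
) -> pd.DataFrame:
    """Simulate the full discounting phase for every subject.

    Each subject completes ``5 × blocks_per_condition`` six-trial blocks in
    a subject-specific seeded order; within a block the titration of
    :mod:`~speech_coged.design_engine` is driven by :func:`simulate_choice`,
    and a sentence at the chosen difficulty is "heard" to produce simulated
    keywords correct.
    """
    if len(profiles) != len(agents):
        raise ValueError("one agent per profile required")
    ref = reference_condition(conditions)
    rows = []
    for profile, agent in zip(profiles, agents):
        rng = _subject_rng(seed, profile.subject_index, stage=2)
        cond_seq = de.block_condition_sequence(conditions, blocks_per_condition, rng)
        for block_idx, cond in enumerate(cond_seq, start=1):
            state = de.init_titration(low_start, hard)
            for _ in range(de.TRIALS_PER_BLOCK):
                choice = simulate_choice(agent, state.easy_offer, cond, rng)
                chosen_amount = state.easy_offer if choice == EASIER else state.hard_offer
                heard = ref if choice == EASIER else cond
                kw = simulate_intelligibility(agent, heard, rng)
                rows.append(
                    (
                        profile.subject_id,
                        block_idx,
                        cond.snr_db,
                        state.trial_index,
                        state.easy_offer,
                        choice,
                        chosen_amount,
                        kw,
                    )
                )
                if state.trial_index < de.TRIALS_PER_BLOCK:
                    state = de.next_offer(state, choice)
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "block",
            "snr_db",
            "trial",
            "easy_offer",
            "choice",
            "chosen_amount",
            "keywords_correct",
        ],
    )


def run_familiarization(
    profiles: Sequence[ParticipantProfile],
    agents: Sequence[AgentParams],
    seed: int = 0,
    conditions: Sequence[SNRCondition] = DEFAULT_CONDITIONS,
) -> pd.DataFrame:
    """Simulate the 80-trial familiarization phase for every subject.

    Target-sentence trials (fillers excluded) provide the per-subject,
    per-SNR intelligibility used as a covariate in the discounting model.
    """
    if len(profiles) != len(agents):
        raise ValueError("one agent per profile required")
    targets = [f"T{i + 1:03d}" for i in range(40)]
    fillers = [f"F{i + 1:03d}" for i in range(40)]
    rows = []
    for profile, agent in zip(profiles, agents):
        sub_seed = int(
            np.random.SeedSequence((seed, profile.subject_index, 1)).generate_state(1)[0]
            % 2**31
        )
        trials = de.build_familiarization(targets, fillers, conditions, seed=sub_seed)
        rng = _subject_rng(seed, profile.subject_index, stage=3)
        for t_idx, trial in enumerate(trials, start=1):
            kw = simulate_intelligibility(agent, trial.snr_db, rng)
            rows.append(
                (
                    profile.subject_id,
                    trial.cycle,
                    trial.snr_db,
                    t_idx,
                    trial.sentence_id,
                    trial.is_filler,
                    kw,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "cycle",
            "snr_db",
            "trial",
            "sentence_id",
            "is_filler",
            "keywords_correct",
        ],
    )


def default_sentence_table(
    n_targets: int = 160, n_fillers: int = 40, seed: int = 0
) -> tuple[pd.DataFrame, list[str]]:
    """Synthetic sentence pool: target ids with prior intelligibility scores
    (for list matching) plus filler ids.

    Prior scores are drawn from a Beta(8, 2) distribution (mean 0.8),
    emulating normative sentence-level recognition scores from an easier
    listening condition.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 999)))
    ids = [f"S{i + 1:03d}" for i in range(n_targets)]
    scores = rng.beta(8.0, 2.0, size=n_targets)
    targets = pd.DataFrame({"sentence_id": ids, "intelligibility": np.round(scores, 4)})
    fillers = [f"H{i + 1:03d}" for i in range(n_fillers)]
    return targets, fillers
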