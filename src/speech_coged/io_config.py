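"""Configuration, CSV/JSON artifacts, and the end-to-end pipeline.

Currency columns are serialized as fixed-point decimal strings with five
fractional digits, which represents every value on the titration's
1/32-dollar grid exactly and makes pipeline outputs byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__, analysis, design_engine as de, simulator as sim

__all__ = [
    "RunConfig",
    "ValidationError",
    "CHOICE_LOG_COLUMNS",
    "AUDIOGRAM_FREQUENCIES",
    "profiles_to_frame",
    "write_choice_log",
    "read_choice_log",
    "write_profiles",
    "read_profiles",
    "build_subject_schedule",
    "schedule_to_frame",
    "run_pipeline",
]

CHOICE_LOG_COLUMNS = [
    "subject_id",
    "block",
    "snr_db",
    "trial",
    "easy_offer",
    "choice",
    "chosen_amount",
    "keywords_correct",
]
CURRENCY_COLUMNS = ("easy_offer", "chosen_amount", "lowest")
AUDIOGRAM_FREQUENCIES = (250, 500, 1000, 2000, 4000, 8000)


class ValidationError(ValueError):
    """Raised when an on-disk artifact violates the documented schema."""


@dataclass(frozen=True)
class RunConfig:
    """Parameters of a full simulated study run."""

    n_young: int = 50
    n_older: int = 50
    seed: int = 0
    easy_start: float = 1.0
    hard_reward: float = 2.0
    blocks_per_condition: int = 4

    def validate(self) -> "RunConfig":
        if self.n_young < 0 or self.n_older < 0 or self.n_young + self.n_older < 1:
            raise ValidationError("cohort sizes must be non-negative, total >= 1")
        if not 0 < self.easy_start < self.hard_reward:
            raise ValidationError("need 0 < easy_start < hard_reward")
        if self.blocks_per_condition < 1:
            raise ValidationError("blocks_per_condition must be >= 1")
        return self

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = json.load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload).validate()

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def sha256(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


# ---------------------------------------------------------------------------
# profiles


def profiles_to_frame(profiles: Sequence[sim.ParticipantProfile]) -> pd.DataFrame:
    """Flatten participant profiles, adding per-ear and better-ear PTA."""
    rows = []
    for p in profiles:
        pta = analysis.compute_pta(p.thresholds, subject_id=p.subject_id)
        row: dict = {
            "subject_id": p.subject_id,
            "age_group": p.age_group,
            "age_years": p.age_years,
            "wm_score": p.wm_score,
            "income_band": p.income_band,
            "motivation_money": p.motivation_money,
            "motivation_desire": p.motivation_desire,
            "hhie_score": p.hhie_score,
            "left_pta": pta.left_pta,
            "right_pta": pta.right_pta,
            "better_ear_pta": pta.better_ear_pta,
        }
        for ear in ("left", "right"):
            for f in AUDIOGRAM_FREQUENCIES:
                row[f"{ear}_{f}"] = p.thresholds[ear][f]
        rows.append(row)
    return pd.DataFrame(rows)


def write_profiles(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False, float_format="%.5f")


def read_profiles(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    if "subject_id" not in frame.columns:
        raise ValidationError("profiles CSV must have a subject_id column")
    if "better_ear_pta" not in frame.columns:
        ear_cols = [f"{ear}_{f}" for ear in ("left", "right") for f in (500, 1000, 2000)]
        missing = [c for c in ear_cols if c not in frame.columns]
        if missing:
            raise ValidationError(f"cannot derive better_ear_pta; missing {missing}")
        left = frame[[f"left_{f}" for f in (500, 1000, 2000)]].mean(axis=1)
        right = frame[[f"right_{f}" for f in (500, 1000, 2000)]].mean(axis=1)
        frame["better_ear_pta"] = np.minimum(left, right)
    return frame


# ---------------------------------------------------------------------------
# choice logs


def write_choice_log(log: pd.DataFrame, path: str | Path) -> None:
    out = log[CHOICE_LOG_COLUMNS].copy()
    for col in CURRENCY_COLUMNS:
        if col in out.columns:
            out[col] = out[col].map(lambda v: f"{v:.5f}")
    out.to_csv(path, index=False)


def read_choice_log(path: str | Path, hard_reward: float = 2.0) -> pd.DataFrame:
    """Load and validate a trial-level choice log.

    Checks column presence and types, the choice/chosen_amount contract
    (the chosen amount is the easy offer for "easier" choices and the fixed
    hard reward otherwise), and that every block holds trials 1..6.
    """
    log = pd.read_csv(path)
    missing = [c for c in CHOICE_LOG_COLUMNS if c not in log.columns]
    if missing:
        raise ValidationError(f"choice log missing columns {missing}")
    for i, row in enumerate(log.itertuples(index=False), start=2):  # header = line 1
        if row.choice not in (de.EASIER, de.HARDER):
            raise ValidationError(f"line {i}: field 'choice' has invalid value {row.choice!r}")
        expected = row.easy_offer if row.choice == de.EASIER else hard_reward
        if abs(row.chosen_amount - expected) > 1e-6:
            raise ValidationError(
                f"line {i}: field 'chosen_amount' ({row.chosen_amount}) inconsistent "
                f"with choice {row.choice!r} at offer {row.easy_offer}"
            )
    for (sid, block), g in log.groupby(["subject_id", "block"]):
        trials = sorted(g["trial"])
        if trials != list(range(1, de.TRIALS_PER_BLOCK + 1)):
            raise ValidationError(
                f"subject {sid} block {block}: expected trials 1..6, got {trials}"
            )
    return log


# ---------------------------------------------------------------------------
# schedules


def build_subject_schedule(seed: int = 0) -> de.ExperimentSchedule:
    """One participant's full schedule from the default sentence pool.

    A seeded shuffle reserves 40 of the 160 target sentences for the
    familiarization phase; the remaining 120 are partitioned into 20
    intelligibility-matched lists of six for the discounting blocks.
    """
    targets, fillers = sim.default_sentence_table(seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 7)))
    order = rng.permutation(len(targets))
    fam_targets = targets.iloc[order[:40]]
    disc_targets = targets.iloc[order[40:]]
    lists = de.match_lists(disc_targets, k=20, m=6)
    sentence_lists = {i + 1: lst for i, lst in enumerate(lists)}
    schedule = de.build_schedule(sentence_lists, seed=seed)
    fam = de.build_familiarization(
        fam_targets["sentence_id"].tolist(), fillers, seed=seed
    )
    return de.ExperimentSchedule(
        familiarization=fam, discounting_blocks=schedule.discounting_blocks, seed=seed
    )


def schedule_to_frame(schedule: de.ExperimentSchedule) -> pd.DataFrame:
    """Tidy trial-level view of a schedule (both phases)."""
    rows = []
    for i, t in enumerate(schedule.familiarization, start=1):
        rows.append(
            ("familiarization", i, t.cycle, t.snr_db, None, t.sentence_id, t.is_filler)
        )
    pos = 0
    for b in schedule.discounting_blocks:
        for sid in b.sentence_ids:
            pos += 1
            rows.append(("discounting", pos, b.block_index, b.snr_db, b.list_id, sid, False))
    return pd.DataFrame(
        rows,
        columns=["phase", "position", "block", "snr_db", "list_id", "sentence_id", "is_filler"],
    )


# ---------------------------------------------------------------------------
# pipeline


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict[str, Path]:
    """simulate → analyze → report, fully determined by the config seed.

    Writes profiles, choice log, familiarization log, block summaries,
    per-subject summaries (condition means + AUC), group curves, the planned
    correlation battery, a JSON report (group contrasts, model comparison,
    REML estimates) and a manifest sufficient to reproduce every artifact.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _stage(name: str):
        return f"[{name}]"

    try:
        profiles, agents = sim.generate_cohort(config.n_young, config.n_older, seed=config.seed)
        prof_frame = profiles_to_frame(profiles)
    except Exception as err:
        raise RuntimeError(f"{_stage('simulate-cohort')} {err}") from err

    try:
        fam = sim.run_familiarization(profiles, agents, seed=config.seed)
        log = sim.run_experiment(
            profiles,
            agents,
            seed=config.seed,
            blocks_per_condition=config.blocks_per_condition,
            low_start=config.easy_start,
            hard=config.hard_reward,
        )
    except Exception as err:
        raise RuntimeError(f"{_stage('simulate-trials')} {err}") from err

    paths["profiles"] = out / "profiles.csv"
    write_profiles(prof_frame, paths["profiles"])
    paths["familiarization"] = out / "familiarization.csv"
    fam.to_csv(paths["familiarization"], index=False)
    paths["choice_log"] = out / "choice_log.csv"
    write_choice_log(log, paths["choice_log"])

    try:
        blocks = analysis.block_summary(log)
        summary = analysis.discounting_summary(blocks, hard_reward=config.hard_reward)
        cond_means = analysis.condition_means(blocks)
        curves = analysis.group_curves(cond_means, prof_frame)
    except Exception as err:
        raise RuntimeError(f"{_stage('summarize')} {err}") from err

    paths["block_summary"] = out / "block_summary.csv"
    blocks_out = blocks.copy()
    blocks_out["lowest"] = blocks_out["lowest"].map(lambda v: f"{v:.5f}")
    blocks_out.to_csv(paths["block_summary"], index=False)

    summary_out = summary.rename(
        columns={c: f"mean_lowest_{c:+g}dB" for c in summary.columns if isinstance(c, float)}
    )
    paths["summaries"] = out / "summaries.csv"
    summary_out.to_csv(paths["summaries"], index=False, float_format="%.6f")
    paths["curves"] = out / "curves.csv"
    curves.to_csv(paths["curves"], index=False, float_format="%.6f")

    report: dict = {"seed": config.seed, "config_sha256": config.sha256()}

    both_groups = config.n_young >= 1 and config.n_older >= 1
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            battery = analysis.correlation_battery(summary, prof_frame)
        paths["correlations"] = out / "correlations.csv"
        battery.to_csv(paths["correlations"], index=False, float_format="%.6f")
        report["correlation_threshold"] = analysis.bonferroni_threshold()
        if not both_groups:
            warnings.warn("single-group cohort: group-specific correlations were skipped")
    except Exception as err:
        raise RuntimeError(f"{_stage('correlations')} {err}") from err

    try:
        if both_groups and config.n_young + config.n_older >= 4:
            merged = summary.merge(prof_frame[["subject_id", "age_group"]], on="subject_id")
            contrasts = {}
            for snr in (-8.0, -12.0):
                young = merged.loc[merged.age_group == "young", snr]
                older = merged.loc[merged.age_group == "older", snr]
                res = analysis.group_contrast(older, young)
                contrasts[f"{snr:+g} dB"] = {
                    "rank_sum": res.statistic,
                    "p": res.pvalue,
                    "method": res.method,
                }
            report["group_contrasts"] = contrasts

            intel = analysis.intelligibility_by_condition(fam)
            frame = analysis.prepare_model_frame(blocks, prof_frame, intel)
            fitted = analysis.fit_discounting_model(frame)
            report["model"] = {
                "formula": fitted.formula,
                "estimates": {
                    k: {"estimate": float(v), "se": float(s)}
                    for (k, v), s in zip(fitted.params.items(), fitted.bse)
                },
                "comparison": fitted.comparison.to_dict(orient="records"),
            }
        else:
            warnings.warn("group statistics skipped: need both age groups")
    except Exception as err:
        raise RuntimeError(f"{_stage('model')} {err}") from err

    paths["report"] = out / "report.json"
    with open(paths["report"], "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")

    import scipy
    import statsmodels

    manifest = {
        "package": {"speech-coged": __version__},
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "statsmodels": statsmodels.__version__,
        },
        "seed": config.seed,
        "config": asdict(config),
        "config_sha256": config.sha256(),
        "artifacts": {k: str(v.name) for k, v in paths.items()},
    }
    paths["manifest"] = out / "manifest.json"
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
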