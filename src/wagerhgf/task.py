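"""Wager-task environment: probability schedule and trial-input generation.

The task is a 160-trial binary card game. On each trial the participant
predicts which card colour (blue or green) will win, after watching an
advisor recommend one of the two colours, and then wagers 1-10 points on
the prediction. Two independent contingencies drive the trial stream:

* the probability that the blue card wins (nonsocial source), and
* the probability that the advisor intends to be helpful (social source).

Both follow piecewise-constant schedules with stable and volatile phases.
The advisor privately observes the true winning colour with a constant
information accuracy (default 0.80) and then either passes on the believed
winner (helpful intention) or the opposite colour (misleading intention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

COLORS = ("blue", "green")

#: Default phase boundaries (1-based inclusive trial ranges).
STABLE_NONSOCIAL = ((1, 25), (100, 160))
STABLE_SOCIAL = ((1, 49), (70, 99))

#: Default piecewise-constant probability segments (start, end, p), 1-based
#: inclusive. Values approximate the published schedule shape (0.8 in stable
#: phases, 0.8/0.2 alternations within volatile phases); they are a
#: configurable stand-in, not a reproduction of the original trial list.
DEFAULT_CARD_SEGMENTS = (
    (1, 25, 0.8),
    (26, 37, 0.2),
    (38, 49, 0.8),
    (50, 61, 0.2),
    (62, 73, 0.8),
    (74, 86, 0.2),
    (87, 99, 0.8),
    (100, 160, 0.8),
)
DEFAULT_ADVISOR_SEGMENTS = (
    (1, 49, 0.8),
    (50, 59, 0.2),
    (60, 69, 0.8),
    (70, 99, 0.8),
    (100, 111, 0.2),
    (112, 123, 0.8),
    (124, 135, 0.2),
    (136, 147, 0.8),
    (148, 160, 0.2),
)


@dataclass
class ScheduleConfig:
    """Configuration for :func:`build_default_schedule`.

    Segments are ``(first_trial, last_trial, probability)`` triples with
    1-based inclusive boundaries that must tile ``1..n_trials`` contiguously.
    ``stable_nonsocial`` / ``stable_social`` list the stable trial ranges;
    every other trial is labelled volatile.
    """

    n_trials: int = 160
    card_segments: Sequence[tuple] = DEFAULT_CARD_SEGMENTS
    advisor_segments: Sequence[tuple] = DEFAULT_ADVISOR_SEGMENTS
    stable_nonsocial: Sequence[tuple] = STABLE_NONSOCIAL
    stable_social: Sequence[tuple] = STABLE_SOCIAL
    advisor_info_accuracy: float = 0.80
    break_after: int | None = 70  # metadata only; no computational effect


@dataclass
class TaskSchedule:
    """Per-trial task probabilities and phase labels.

    All arrays have length ``n_trials`` and are indexed 0-based internally;
    every public interface reports 1-based trial numbers.
    """

    n_trials: int
    p_card_blue: np.ndarray
    p_advisor_helpful: np.ndarray
    phase_nonsocial: np.ndarray  # 'stable' | 'volatile'
    phase_social: np.ndarray
    advisor_info_accuracy: float
    break_after: int | None = None

    def __post_init__(self) -> None:
        for name in ("p_card_blue", "p_advisor_helpful"):
            p = np.asarray(getattr(self, name), dtype=float)
            if p.shape != (self.n_trials,):
                raise ValueError(f"{name} must have length n_trials={self.n_trials}")
            if np.any(p < 0) or np.any(p > 1):
                raise ValueError(f"{name} must lie in [0, 1]")
            setattr(self, name, p)
        if not 0 <= self.advisor_info_accuracy <= 1:
            raise ValueError("advisor_info_accuracy must lie in [0, 1]")
        for name in ("phase_nonsocial", "phase_social"):
            lab = np.asarray(getattr(self, name))
            if lab.shape != (self.n_trials,):
                raise ValueError(f"{name} must have length n_trials")
            if not set(np.unique(lab)) <= {"stable", "volatile"}:
                raise ValueError(f"{name} labels must be 'stable' or 'volatile'")
            setattr(self, name, lab)

    # -- serialization -----------------------------------------------------
    def to_config_dict(self) -> dict:
        def segments(p):
            # re-derive piecewise-constant segments from the per-trial array
            out, start = [], 0
            for k in range(1, self.n_trials + 1):
                if k == self.n_trials or p[k] != p[start]:
                    out.append([start + 1, k, float(p[start])])
                    start = k
            return out

        def stable(lab):
            out, start = [], None
            for k in range(self.n_trials + 1):
                is_stable = k < self.n_trials and lab[k] == "stable"
                if is_stable and start is None:
                    start = k
                elif not is_stable and start is not None:
                    out.append([start + 1, k])
                    start = None
            return out

        return {
            "n_trials": int(self.n_trials),
            "card_segments": segments(self.p_card_blue),
            "advisor_segments": segments(self.p_advisor_helpful),
            "stable_nonsocial": stable(self.phase_nonsocial),
            "stable_social": stable(self.phase_social),
            "advisor_info_accuracy": float(self.advisor_info_accuracy),
            "break_after": self.break_after,
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_config_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "TaskSchedule":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        cfg = ScheduleConfig(
            n_trials=d["n_trials"],
            card_segments=[tuple(s) for s in d["card_segments"]],
            advisor_segments=[tuple(s) for s in d["advisor_segments"]],
            stable_nonsocial=[tuple(s) for s in d["stable_nonsocial"]],
            stable_social=[tuple(s) for s in d["stable_social"]],
            advisor_info_accuracy=d["advisor_info_accuracy"],
            break_after=d.get("break_after"),
        )
        return build_default_schedule(cfg)


def _expand_segments(segments: Sequence[tuple], n_trials: int, what: str) -> np.ndarray:
    """Expand (start, end, p) segments into a per-trial array, validating
    that the segments tile 1..n_trials contiguously."""
    p = np.full(n_trials, np.nan)
    expected_start = 1
    for start, end, prob in segments:
        if start != expected_start:
            raise ValueError(
                f"{what}: segment starting at {start} does not follow "
                f"previous segment (expected start {expected_start})"
            )
        if end < start or end > n_trials:
            raise ValueError(f"{what}: invalid segment ({start}, {end})")
        if not 0 <= prob <= 1:
            raise ValueError(f"{what}: probability {prob} outside [0, 1]")
        p[start - 1 : end] = prob
        expected_start = end + 1
    if expected_start != n_trials + 1:
        raise ValueError(f"{what}: segments do not cover 1..{n_trials}")
    return p


def _phase_labels(stable_ranges: Sequence[tuple], n_trials: int) -> np.ndarray:
    lab = np.full(n_trials, "volatile", dtype=object)
    for start, end in stable_ranges:
        if start < 1 or end > n_trials or end < start:
            raise ValueError(f"invalid stable range ({start}, {end})")
        lab[start - 1 : end] = "stable"
    return lab


def build_default_schedule(config: ScheduleConfig | None = None) -> TaskSchedule:
    """Build the task schedule from a segment configuration.

    With the default configuration this yields the 160-trial schedule:
    nonsocial stable on trials 1-25 and 100-160, social stable on 1-49 and
    70-99, all other trials volatile (trial 160 is labelled volatile for the
    social source, continuing the final volatile block).
    """
    cfg = config or ScheduleConfig()
    return TaskSchedule(
        n_trials=cfg.n_trials,
        p_card_blue=_expand_segments(cfg.card_segments, cfg.n_trials, "card_segments"),
        p_advisor_helpful=_expand_segments(
            cfg.advisor_segments, cfg.n_trials, "advisor_segments"
        ),
        phase_nonsocial=_phase_labels(cfg.stable_nonsocial, cfg.n_trials),
        phase_social=_phase_labels(cfg.stable_social, cfg.n_trials),
        advisor_info_accuracy=cfg.advisor_info_accuracy,
        break_after=cfg.break_after,
    )


def generate_trial_inputs(
    schedule: TaskSchedule, rng_seed: int | np.random.Generator
) -> pd.DataFrame:
    """Sample the exogenous trial stream (winning colours and advice).

    Per trial: the winning colour is Bernoulli(p_card_blue); the advisor
    privately observes the true winner with probability
    ``advisor_info_accuracy`` (otherwise the wrong colour); a helpful
    intention (Bernoulli(p_advisor_helpful)) passes the believed winner on,
    a misleading intention advises the opposite colour.

    Returns a DataFrame with 1-based ``trial`` plus ``advice_color``,
    ``winning_color``, ``advice_correct`` and the two phase-label columns.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    n = schedule.n_trials
    win_blue = rng.random(n) < schedule.p_card_blue
    observed_true = rng.random(n) < schedule.advisor_info_accuracy
    helpful = rng.random(n) < schedule.p_advisor_helpful
    believed_blue = np.where(observed_true, win_blue, ~win_blue)
    advice_blue = np.where(helpful, believed_blue, ~believed_blue).astype(bool)

    return pd.DataFrame(
        {
            "trial": np.arange(1, n + 1),
            "advice_color": np.where(advice_blue, "blue", "green"),
            "winning_color": np.where(win_blue, "blue", "green"),
            "advice_correct": (advice_blue == win_blue).astype(int),
            "phase_nonsocial": schedule.phase_nonsocial,
            "phase_social": schedule.phase_social,
        }
    )


def advice_accuracy_rate(p_helpful: float, info_accuracy: float) -> float:
    """Closed-form long-run probability that the advice names the winner."""
    return p_helpful * info_accuracy + (1.0 - p_helpful) * (1.0 - info_accuracy)


def score_trials(table: pd.DataFrame) -> pd.DataFrame:
    """Summarize accuracy, advice-taking and wager per phase x source cell.

    Returns one row per cell (``overall`` plus the four phase x source
    cells) with percent-correct accuracy, mean advice-taking rate (y) and
    mean wager. Empty cells yield NaN with ``n = 0`` rather than silent
    zeros.
    """
    required = {"choice_correct", "y", "wager", "phase_nonsocial", "phase_social"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"TrialTable missing columns: {sorted(missing)}")

    def cell(mask: np.ndarray, label: str) -> dict:
        sub = table.loc[mask]
        n = len(sub)
        return {
            "cell": label,
            "n": n,
            "accuracy": sub["choice_correct"].mean() if n else np.nan,
            "advice_taking": sub["y"].mean() if n else np.nan,
            "mean_wager": sub["wager"].mean() if n else np.nan,
        }

    rows = [cell(np.ones(len(table), bool), "overall")]
    for source, col in (("nonsocial", "phase_nonsocial"), ("social", "phase_social")):
        for phase in ("stable", "volatile"):
            rows.append(cell((table[col] == phase).to_numpy(), f"{phase}_{source}"))
    return pd.DataFrame(rows)
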