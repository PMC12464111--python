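"""Simulate complete sessions: task inputs -> beliefs -> responses.

A session couples the exogenous trial stream (advice and winning colours)
with an agent's belief filters and response model. Because neither filter
input depends on the agent's own choices (advice accuracy and the winning
colour are exogenous), the filters run once per session and responses are
sampled afterwards.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .perceptual import PerceptualParams, hgf2_filter, hgf3_filter
from .response import ResponseParams, simulate_responses
from .task import TaskSchedule, generate_trial_inputs

TRIAL_COLUMNS = [
    "trial", "advice_color", "winning_color", "choice_color", "y",
    "advice_correct", "choice_correct", "wager", "cumulative_score",
    "phase_nonsocial", "phase_social",
]


def filter_predictions(
    inputs: pd.DataFrame, pparams: PerceptualParams, model: str = "hgf3"
):
    """Run the perceptual filters of ``model`` on a trial-input frame.

    Returns ``(muhat_a, muhat_c, vol)``: per-trial predicted advice
    accuracy, blue-win probability, and mean predicted log-volatility of
    the two sources (zeros for the 2-level model, which tracks none).
    Baseline models (RW, Kalman) are handled by the fitting layer, which
    owns their parameterization.
    """
    u_a = inputs["advice_correct"].to_numpy(dtype=float)
    u_c = (inputs["winning_color"] == "blue").to_numpy(dtype=float)
    if model == "hgf3":
        ta = hgf3_filter(u_a, pparams.social)
        tc = hgf3_filter(u_c, pparams.nonsocial)
        # prediction = previous trial's posterior (initial state on trial 1),
        # expressed relative to the initial volatility belief so the wager
        # offset psi0 keeps its interpretation
        v3a = np.concatenate(([pparams.social.mu3_0], ta.mu3[:-1])) - pparams.social.mu3_0
        v3c = np.concatenate(([pparams.nonsocial.mu3_0], tc.mu3[:-1])) - pparams.nonsocial.mu3_0
        return ta.muhat1, tc.muhat1, (v3a + v3c) / 2.0
    if model == "hgf2":
        ta = hgf2_filter(u_a, pparams.social)
        tc = hgf2_filter(u_c, pparams.nonsocial)
        return ta.muhat1, tc.muhat1, np.zeros(len(u_a))
    raise ValueError(f"unknown model '{model}' (baselines live in wagerhgf.inversion)")


def simulate_session(
    schedule: TaskSchedule,
    pparams: PerceptualParams,
    rparams: ResponseParams,
    rng_seed: int | np.random.Generator,
    trial_inputs: pd.DataFrame | None = None,
    model: str = "hgf3",
) -> pd.DataFrame:
    """Simulate one participant session; returns a complete TrialTable.

    If ``trial_inputs`` is given (e.g. the fixed trial order every
    participant experienced), only the responses are sampled; otherwise a
    fresh input stream is drawn first from the same generator.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    inputs = trial_inputs if trial_inputs is not None else generate_trial_inputs(schedule, rng)
    muhat_a, muhat_c, vol = filter_predictions(inputs, pparams, model=model)
    resp = simulate_responses(
        muhat_a, muhat_c, inputs["advice_color"].to_numpy(), rparams, rng, vol=vol
    )

    table = inputs.copy()
    for col in ("b", "p_take", "y", "choice_color", "wager_pred", "wager"):
        table[col] = resp[col].to_numpy()
    table["choice_correct"] = (table["choice_color"] == table["winning_color"]).astype(int)
    signed = np.where(table["choice_correct"] == 1, table["wager"], -table["wager"])
    table["cumulative_score"] = np.cumsum(signed)
    return table


def simulate_admissible_session(
    schedule: TaskSchedule,
    params: dict,
    rng: np.random.Generator,
    trial_inputs: pd.DataFrame | None = None,
    model: str = "hgf3",
    max_shrink: int = 8,
) -> tuple[pd.DataFrame, dict]:
    """Simulate a session, shrinking inadmissible volatility parameters.

    A rare draw of (kappa, theta) can destabilize the filter on a given
    input realization. Such an agent is not a valid generating process for
    that session, so its volatility parameters are contracted toward the
    admissible centre (logit-space x0.8 per step) until the filter runs;
    the adjusted values are returned as the agent's true parameters.
    """
    from .perceptual import FilterInstabilityError
    from scipy.special import expit, logit

    d = dict(params)
    for _ in range(max_shrink):
        from .recovery import dict_to_params  # late import avoids a cycle

        pp, rp = dict_to_params(d)
        try:
            return simulate_session(schedule, pp, rp, rng, trial_inputs=trial_inputs, model=model), d
        except FilterInstabilityError:
            for name in ("kappa_a", "kappa_c", "theta_a", "theta_c"):
                d[name] = float(expit(0.8 * logit(d[name])))
    raise RuntimeError("could not find admissible volatility parameters")


def write_trial_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_trial_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - {"cumulative_score"} - set(table.columns)
    if missing:
        raise ValueError(f"trial table at {path} missing columns {sorted(missing)}")
    return table
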