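"""Response model: from source predictions to advice-taking and wagers.

The integrated belief b that the advised card wins is a precision-weighted
average of the social prediction (advice accuracy) and the nonsocial
prediction (advised-colour win probability), with the social side scaled
by the arbitration weight zeta (> 1 = social bias, prior mean 1 = equal
weighting). Reliability of a binary prediction muhat is its precision
1 / (muhat (1 - muhat)).

Choice: P(y = 1) = b^beta / (b^beta + (1-b)^beta) (unit-square sigmoid with
inverse decision temperature beta). Wager: expected wager
w* = 1 + 9 logistic(psi0 + psi1 |2b - 1| - psi_vol volbar) — a compressive
confidence mapping onto the 1..10 point scale in which confidence rises
with the decisiveness of the integrated belief and falls with the mean
perceived log-volatility of the two sources (volbar) — with Gaussian
observation noise sigma_w; simulated wagers are rounded and clamped to
the integer range. Models without a volatility level simply have no
volatility term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

P_EPS = 1e-8


@dataclass
class ResponseParams:
    zeta: float = 1.0      # social weighting ratio, > 0
    beta: float = 2.0      # inverse decision temperature, > 0
    psi0: float = 0.0      # wager confidence offset
    psi1: float = 1.5      # wager confidence slope on |2b - 1|
    psi_vol: float = 0.0   # wager confidence drop per unit perceived volatility
    sigma_w: float = 2.0   # wager noise SD (points), > 0

    def validate(self) -> None:
        if self.zeta <= 0 or self.beta <= 0 or self.sigma_w <= 0:
            raise ValueError("zeta, beta and sigma_w must be positive")


def _check_prob(x, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0) or np.any(x >= 1):
        raise ValueError(f"{name} must lie strictly in (0, 1)")
    return x


def integrate_sources(mu1hat_a, mu1hat_c_adv, zeta: float) -> np.ndarray:
    """Precision-weighted integration of the two sources.

    ``mu1hat_a``: predicted advice accuracy; ``mu1hat_c_adv``: card
    prediction re-expressed as the probability that the *advised* colour
    wins. Returns the integrated probability b that the advised card wins.
    """
    ma = _check_prob(mu1hat_a, "mu1hat_a")
    mc = _check_prob(mu1hat_c_adv, "mu1hat_c_adv")
    if zeta <= 0:
        raise ValueError("zeta must be positive")
    pia = 1.0 / (ma * (1.0 - ma))
    pic = 1.0 / (mc * (1.0 - mc))
    return (zeta * pia * ma + pic * mc) / (zeta * pia + pic)


def choice_probability(b, beta: float) -> np.ndarray:
    """P(y = 1 | b) under the unit-square sigmoid."""
    b = np.clip(np.asarray(b, dtype=float), P_EPS, 1 - P_EPS)
    lb = beta * np.log(b)
    lnb = beta * np.log(1.0 - b)
    return np.exp(lb - np.logaddexp(lb, lnb))


def choice_likelihood(b, beta: float, y) -> np.ndarray:
    """Probability of the observed take/reject response(s)."""
    p1 = choice_probability(b, beta)
    y = np.asarray(y)
    return np.where(y == 1, p1, 1.0 - p1)


def predicted_wager(
    b, psi0: float, psi1: float, psi_vol: float = 0.0, vol=0.0
) -> np.ndarray:
    """Expected wager w* in [1, 10].

    ``vol`` is the mean predicted log-volatility of the two sources
    (0 for models without a volatility level, making w* a pure function
    of belief decisiveness).
    """
    b = np.asarray(b, dtype=float)
    return 1.0 + 9.0 * expit(psi0 + psi1 * np.abs(2.0 * b - 1.0) - psi_vol * np.asarray(vol, dtype=float))


def wager_likelihood(
    b, psi0: float, psi1: float, sigma_w: float, observed_wager,
    psi_vol: float = 0.0, vol=0.0,
):
    """Gaussian density of the observed wager around w*.

    The likelihood is continuous even though observed wagers are integers;
    the approximation is documented in the methods note.
    """
    w = np.asarray(observed_wager, dtype=float)
    if np.any(w < 1) or np.any(w > 10):
        raise ValueError("observed wagers must lie in [1, 10]")
    if sigma_w <= 0:
        raise ValueError("sigma_w must be positive")
    wstar = predicted_wager(b, psi0, psi1, psi_vol, vol)
    z = (w - wstar) / sigma_w
    return np.exp(-0.5 * z * z) / (sigma_w * np.sqrt(2.0 * np.pi))


def simulate_responses(
    mu1hat_a,
    mu1hat_c,
    advice_color,
    params: ResponseParams,
    rng_seed: int | np.random.Generator,
    vol=0.0,
) -> pd.DataFrame:
    """Sample advice-taking and wagers from the response model.

    ``mu1hat_c`` is the blue-win prediction; it is flipped into the advice
    frame per trial. ``vol`` is the per-trial mean predicted
    log-volatility (scalar 0 when the perceptual model has no volatility
    level). Returns per-trial b, p_take, sampled y, choice colour,
    predicted wager w* and the sampled integer wager.
    """
    params.validate()
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    advice_color = np.asarray(advice_color)
    advice_blue = advice_color == "blue"
    mc = np.asarray(mu1hat_c, dtype=float)
    mc_adv = np.where(advice_blue, mc, 1.0 - mc)
    ma = np.clip(np.asarray(mu1hat_a, dtype=float), P_EPS, 1 - P_EPS)
    mc_adv = np.clip(mc_adv, P_EPS, 1 - P_EPS)
    b = integrate_sources(ma, mc_adv, params.zeta)
    p_take = choice_probability(b, params.beta)
    y = (rng.random(len(b)) < p_take).astype(int)
    choice_blue = np.where(y == 1, advice_blue, ~advice_blue)
    wstar = predicted_wager(b, params.psi0, params.psi1, params.psi_vol, vol)
    wager = np.rint(wstar + params.sigma_w * rng.standard_normal(len(b)))
    wager = np.clip(wager, 1, 10).astype(int)
    return pd.DataFrame(
        {
            "b": b,
            "p_take": p_take,
            "y": y,
            "choice_color": np.where(choice_blue, "blue", "green"),
            "wager_pred": wstar,
            "wager": wager,
        }
    )
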