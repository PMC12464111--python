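"""Trial-by-trial belief-update filters.

Two parallel binary 3-level hierarchical Gaussian filters (HGFs) model how
an agent tracks (a) the advisor's trustworthiness (social source, input =
advice accuracy) and (b) the card-colour contingency (nonsocial source,
input = blue-win indicator). Each source has its own coupling strength
kappa (how strongly the volatility level modulates contingency updating)
and meta-volatility theta (how changeable the volatility itself is).
Level-2 tonic log-volatility omega is a fixed constant: the four free
learning parameters are kappa and theta per source.

Baselines with the same input/trajectory interface: a 2-level HGF (no
volatility tracking), a Rescorla-Wagner delta rule, and a scalar Kalman
filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels

# Tonic level-2 log-volatility. Fixed (not estimated): kappa and theta
# carry the individual differences. The value is chosen so the effective
# tonic step exp(kappa*mu3 + omega) at typical states (kappa ~ 0.5,
# mu3_0 = 1) matches the canonical binary-HGF toolbox default of e^-2;
# far more negative values decouple the volatility level entirely and
# make kappa/theta unidentifiable.
DEFAULT_OMEGA = -2.5


class FilterInstabilityError(RuntimeError):
    """Raised when a filter produces a non-finite state or non-positive
    variance; carries the 1-based trial index where it happened."""

    def __init__(self, trial: int, what: str = "hgf"):
        self.trial = trial
        super().__init__(
            f"{what}: numerical instability (non-positive precision or "
            f"non-finite state) at trial {trial}"
        )


@dataclass
class SourceParams:
    """HGF learning parameters for one information source."""

    kappa: float = 0.5     # level 2-3 coupling, in [0, 1]
    theta: float = 0.3     # meta-volatility (level-3 walk variance), > 0
    omega: float = DEFAULT_OMEGA  # tonic level-2 log-volatility (fixed)
    mu2_0: float = 0.0     # equiprobable start
    sigma2_0: float = 1.0
    mu3_0: float = 1.0
    sigma3_0: float = 1.0

    def validate(self) -> None:
        if not 0.0 <= self.kappa <= 1.0:
            raise ValueError("kappa must lie in [0, 1]")
        if self.theta < 0.0:
            raise ValueError("theta must be >= 0")
        if self.sigma2_0 <= 0 or self.sigma3_0 <= 0:
            raise ValueError("initial variances must be positive")


@dataclass
class PerceptualParams:
    """Learning parameters for both sources (a = social, c = nonsocial)."""

    social: SourceParams = field(default_factory=SourceParams)
    nonsocial: SourceParams = field(default_factory=SourceParams)


@dataclass
class BeliefTrajectory:
    """Per-trial filter states for one source.

    ``muhat1`` is the pre-update outcome prediction on each trial; levels
    missing from a model (e.g. level 3 for the 2-level HGF) are None.
    """

    muhat1: np.ndarray
    delta1: np.ndarray
    mu2: np.ndarray
    sigma2: np.ndarray
    delta2: np.ndarray | None = None
    mu3: np.ndarray | None = None
    sigma3: np.ndarray | None = None
    floor_hits: int = 0

    @property
    def n_trials(self) -> int:
        return len(self.muhat1)

    def to_frame(self) -> pd.DataFrame:
        d = {
            "trial": np.arange(1, self.n_trials + 1),
            "muhat1": self.muhat1,
            "delta1": self.delta1,
            "mu2": self.mu2,
            "sigma2": self.sigma2,
        }
        for name in ("delta2", "mu3", "sigma3"):
            v = getattr(self, name)
            if v is not None:
                d[name] = v
        return pd.DataFrame(d)


def _as_binary(u) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    if u.ndim != 1 or u.size == 0:
        raise ValueError("input sequence must be a non-empty 1-D array")
    if not np.all((u == 0) | (u == 1)):
        raise ValueError("input sequence must be binary (0/1)")
    return u


def hgf3_filter(u, params: SourceParams) -> BeliefTrajectory:
    """Run the 3-level binary HGF over a 0/1 input sequence.

    Raises :class:`FilterInstabilityError` (naming the 1-based trial) if
    the level-3 posterior precision becomes non-positive or a state goes
    non-finite.
    """
    u = _as_binary(u)
    params.validate()
    mh1, d1, m2, s2, d2, m3, s3, bad, floors = _kernels.hgf3_core(
        u, params.kappa, params.theta, params.omega,
        params.mu2_0, params.sigma2_0, params.mu3_0, params.sigma3_0,
    )
    if bad >= 0:
        raise FilterInstabilityError(bad + 1, "hgf3")
    return BeliefTrajectory(mh1, d1, m2, s2, d2, m3, s3, floor_hits=int(floors))


def hgf2_filter(u, params: SourceParams) -> BeliefTrajectory:
    """2-level binary HGF: constant level-2 step variance exp(omega)."""
    u = _as_binary(u)
    params.validate()
    mh1, d1, m2, s2, bad, floors = _kernels.hgf2_core(
        u, params.omega, params.mu2_0, params.sigma2_0
    )
    if bad >= 0:
        raise FilterInstabilityError(bad + 1, "hgf2")
    return BeliefTrajectory(mh1, d1, m2, s2, floor_hits=int(floors))


def rescorla_wagner_filter(u, alpha: float, v0: float = 0.5) -> pd.DataFrame:
    """Delta-rule value learning: v_k = v_{k-1} + alpha (u_k - v_{k-1}).

    Returns a frame with ``vhat`` (prediction before the trial's input)
    and ``v`` (post-update value).
    """
    u = _as_binary(u)
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    vhat, v = _kernels.rw_core(u, float(alpha), float(v0))
    return pd.DataFrame({"trial": np.arange(1, len(u) + 1), "vhat": vhat, "v": v})


def kalman_filter(
    u, process_var: float, obs_var: float, v0: float = 0.5, p0: float = 1.0
) -> pd.DataFrame:
    """Scalar Kalman filter on u as noisy observations of a latent value.

    Returns per-trial prediction ``vhat``, posterior mean ``v``, posterior
    variance ``pvar`` and Kalman gain.
    """
    u = _as_binary(u)
    if process_var < 0 or obs_var <= 0 or p0 < 0:
        raise ValueError("variances must be positive (process_var may be 0)")
    vhat, v, pvar, gain = _kernels.kalman_core(
        u, float(process_var), float(obs_var), float(v0), float(p0)
    )
    return pd.DataFrame(
        {
            "trial": np.arange(1, len(u) + 1),
            "vhat": vhat,
            "v": v,
            "pvar": pvar,
            "gain": gain,
        }
    )
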