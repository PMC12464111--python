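"""MAP model inversion, Laplace model evidence, and group model selection.

Each candidate model (3-level HGF, 2-level HGF, Rescorla-Wagner, Kalman
filter; all sharing the arbitration response model) is fitted per
participant by maximizing the log-joint of choices, wagers and a Gaussian
prior over transformed parameters, with seeded multistart L-BFGS-B.
Model evidence is approximated by Laplace's method at the MAP; BIC uses
the likelihood alone with n_obs = 2 x n_trials (one choice and one wager
observation per trial). Group-level comparison reports fixed-effects sums
and the random-effects variational-Dirichlet scheme over model identities
(expected frequencies and exceedance probabilities).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats
from scipy.special import digamma, expit, logit

from . import _kernels
from .perceptual import DEFAULT_OMEGA, PerceptualParams, SourceParams
from .response import ResponseParams, predicted_wager

MODELS = ("hgf3", "hgf2", "rw", "kalman")

_RESPONSE_PRIORS = [
    # (name, transform, prior mean, prior var) in transformed space
    ("zeta", "log", 0.0, 1.0),      # native prior mean 1: equal weighting
    ("beta", "log", 0.0, 4.0),
    ("psi0", "identity", 0.0, 4.0),
    ("psi1", "identity", 0.0, 4.0),
    ("sigma_w", "log", 0.0, 4.0),
]

_MODEL_PRIORS = {
    "hgf3": [
        ("kappa_a", "logit", 0.0, 1.0),
        ("kappa_c", "logit", 0.0, 1.0),
        ("theta_a", "logit", 0.0, 1.0),
        ("theta_c", "logit", 0.0, 1.0),
        # volatility weight of the wager model: only meaningful for models
        # that track volatility
        ("psi_vol", "identity", 0.0, 4.0),
    ] + _RESPONSE_PRIORS,
    "hgf2": [
        ("omega_a", "identity", DEFAULT_OMEGA, 4.0),
        ("omega_c", "identity", DEFAULT_OMEGA, 4.0),
    ] + _RESPONSE_PRIORS,
    "rw": [
        ("alpha_a", "logit", -1.0, 1.0),
        ("alpha_c", "logit", -1.0, 1.0),
    ] + _RESPONSE_PRIORS,
    "kalman": [
        ("q_a", "log", -3.0, 4.0),   # process variance per source
        ("q_c", "log", -3.0, 4.0),
        ("r", "log", -1.4, 4.0),     # shared observation variance
    ] + _RESPONSE_PRIORS,
}

_XCLIP = 30.0  # transformed-space clamp before exp/expit


@dataclass
class PriorSpec:
    """Gaussian priors over transformed parameters for one model."""

    model_id: str
    names: list[str]
    transforms: list[str]
    mean: np.ndarray
    var: np.ndarray

    @classmethod
    def default(cls, model_id: str) -> "PriorSpec":
        if model_id not in _MODEL_PRIORS:
            raise ValueError(f"unknown model '{model_id}'")
        rows = _MODEL_PRIORS[model_id]
        return cls(
            model_id=model_id,
            names=[r[0] for r in rows],
            transforms=[r[1] for r in rows],
            mean=np.array([r[2] for r in rows], dtype=float),
            var=np.array([r[3] for r in rows], dtype=float),
        )

    def __post_init__(self) -> None:
        if np.any(self.var <= 0):
            raise ValueError("prior variances must be positive")

    @property
    def n_params(self) -> int:
        return len(self.names)

    def to_native(self, x: np.ndarray) -> dict:
        out = {}
        for name, tr, xi in zip(self.names, self.transforms, x):
            xi = float(np.clip(xi, -_XCLIP, _XCLIP))
            if tr == "log":
                out[name] = float(np.exp(xi))
            elif tr == "logit":
                out[name] = float(expit(xi))
            else:
                out[name] = xi
        return out

    def to_transformed(self, native: dict) -> np.ndarray:
        x = np.empty(self.n_params)
        for i, (name, tr) in enumerate(zip(self.names, self.transforms)):
            v = native[name]
            if tr == "log":
                x[i] = np.log(v)
            elif tr == "logit":
                x[i] = logit(v)
            else:
                x[i] = v
        return x

    def log_pdf(self, x: np.ndarray) -> float:
        z = (x - self.mean) ** 2 / self.var
        return float(-0.5 * np.sum(z + np.log(2 * np.pi * self.var)))


@dataclass
class FitOptions:
    n_starts: int = 8
    seed: int = 0
    tol: float = 1e-6
    maxiter: int = 500
    start_scale: float = 0.5  # multistart spread as a fraction of prior SD


@dataclass
class FitResult:
    model_id: str
    params: dict               # MAP estimates, native space
    params_transformed: dict
    neg_log_joint: float
    log_lik: float             # likelihood alone at the MAP
    lme: float | None          # Laplace log model evidence (nats)
    bic: float
    n_free_params: int
    n_obs: int
    n_trials: int
    converged: bool
    diagnostics: dict = field(default_factory=dict)

    def to_yaml(self, path) -> None:
        d = {
            "format_version": 1,
            "model_id": self.model_id,
            "params": {k: float(v) for k, v in self.params.items()},
            "params_transformed": {k: float(v) for k, v in self.params_transformed.items()},
            "neg_log_joint": float(self.neg_log_joint),
            "log_lik": float(self.log_lik),
            "lme": None if self.lme is None else float(self.lme),
            "bic": float(self.bic),
            "n_free_params": self.n_free_params,
            "n_obs": self.n_obs,
            "n_trials": self.n_trials,
            "converged": bool(self.converged),
            "diagnostics": {
                k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
                for k, v in self.diagnostics.items()
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "FitResult":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d.pop("format_version", None)
        return cls(**d)


def _extract_arrays(table: pd.DataFrame):
    u_a = table["advice_correct"].to_numpy(dtype=np.float64)
    u_c = (table["winning_color"] == "blue").to_numpy(dtype=np.float64)
    adv_blue = (table["advice_color"] == "blue").to_numpy(dtype=np.int64)
    y = table["y"].to_numpy(dtype=np.int64)
    wager = table["wager"].to_numpy(dtype=np.float64)
    if np.any((wager < 1) | (wager > 10)):
        raise ValueError("wagers must lie in [1, 10]")
    return u_a, u_c, adv_blue, y, wager


_PENALTY = 1e10


def _model_predictions(model_id: str, p: dict, u_a: np.ndarray, u_c: np.ndarray):
    """Per-trial source predictions (muhat_a, muhat_c, vol) for native
    params; vol is the mean predicted log-volatility (zeros for models
    without a volatility level).

    Returns None if the filter is unstable for these parameters (used as
    an optimizer penalty)."""
    if model_id == "hgf3":
        out_a = _kernels.hgf3_core(u_a, p["kappa_a"], p["theta_a"], DEFAULT_OMEGA, 0.0, 1.0, 1.0, 1.0)
        out_c = _kernels.hgf3_core(u_c, p["kappa_c"], p["theta_c"], DEFAULT_OMEGA, 0.0, 1.0, 1.0, 1.0)
        if out_a[7] >= 0 or out_c[7] >= 0:
            return None
        # predicted log-volatility relative to the initial belief (mu3_0 = 1)
        v3a = np.concatenate(([1.0], out_a[5][:-1])) - 1.0
        v3c = np.concatenate(([1.0], out_c[5][:-1])) - 1.0
        return out_a[0], out_c[0], (v3a + v3c) / 2.0
    zeros = np.zeros(len(u_a))
    if model_id == "hgf2":
        out_a = _kernels.hgf2_core(u_a, p["omega_a"], 0.0, 1.0)
        out_c = _kernels.hgf2_core(u_c, p["omega_c"], 0.0, 1.0)
        if out_a[4] >= 0 or out_c[4] >= 0:
            return None
        return out_a[0], out_c[0], zeros
    if model_id == "rw":
        return (
            _kernels.rw_core(u_a, p["alpha_a"], 0.5)[0],
            _kernels.rw_core(u_c, p["alpha_c"], 0.5)[0],
            zeros,
        )
    if model_id == "kalman":
        return (
            _kernels.kalman_core(u_a, p["q_a"], p["r"], 0.5, 1.0)[0],
            _kernels.kalman_core(u_c, p["q_c"], p["r"], 0.5, 1.0)[0],
            zeros,
        )
    raise ValueError(f"unknown model '{model_id}'")


def negative_log_likelihood(
    model_id: str, native: dict, u_a, u_c, adv_blue, y, wager
) -> float:
    preds = _model_predictions(model_id, native, u_a, u_c)
    if preds is None:
        return _PENALTY
    nll = _kernels.response_nll_core(
        preds[0], preds[1], preds[2], adv_blue, y, wager,
        native["zeta"], native["beta"], native["psi0"], native["psi1"],
        native.get("psi_vol", 0.0), native["sigma_w"],
    )
    if not np.isfinite(nll):
        return _PENALTY
    return float(nll)


def _numerical_hessian(f, x: np.ndarray, rel_step: float = 1e-3) -> np.ndarray:
    """Central-difference Hessian of scalar f at x."""
    d = len(x)
    h = rel_step * (1.0 + np.abs(x))
    hess = np.empty((d, d))
    f0 = f(x)
    for i in range(d):
        ei = np.zeros(d); ei[i] = h[i]
        fpp = f(x + ei); fmm = f(x - ei)
        hess[i, i] = (fpp - 2.0 * f0 + fmm) / h[i] ** 2
        for j in range(i + 1, d):
            ej = np.zeros(d); ej[j] = h[j]
            fij = f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            hess[i, j] = hess[j, i] = fij / (4.0 * h[i] * h[j])
    return hess


def fit_map(
    trial_table: pd.DataFrame,
    model_id: str = "hgf3",
    prior: PriorSpec | None = None,
    options: FitOptions | None = None,
) -> FitResult:
    """Fit one participant's TrialTable by MAP over transformed parameters.

    Multistart (seeded) L-BFGS-B on the negative log-joint; the Laplace
    log model evidence is log-joint at the MAP plus the Gaussian-volume
    correction from the numerical Hessian. Raises RuntimeError if every
    start fails.
    """
    prior = prior or PriorSpec.default(model_id)
    if prior.model_id != model_id:
        raise ValueError("prior/model mismatch")
    opts = options or FitOptions()
    u_a, u_c, adv_blue, y, wager = _extract_arrays(trial_table)
    n_trials = len(y)

    def nlj(x: np.ndarray) -> float:
        native = prior.to_native(x)
        nll = negative_log_likelihood(model_id, native, u_a, u_c, adv_blue, y, wager)
        if nll >= _PENALTY:
            return _PENALTY
        return nll - prior.log_pdf(x)

    rng = np.random.default_rng(opts.seed)
    sd = np.sqrt(prior.var)
    starts = [prior.mean.copy()]
    for _ in range(opts.n_starts - 1):
        starts.append(prior.mean + opts.start_scale * sd * rng.standard_normal(prior.n_params))

    best, best_fun, n_failed = None, np.inf, 0
    for x0 in starts:
        try:
            res = optimize.minimize(
                nlj, x0, method="L-BFGS-B",
                options={"maxiter": opts.maxiter, "ftol": opts.tol, "gtol": 1e-6},
            )
        except Exception:
            n_failed += 1
            continue
        if not np.isfinite(res.fun) or res.fun >= _PENALTY:
            n_failed += 1
            continue
        if res.fun < best_fun:
            best, best_fun = res, res.fun
    if best is None:
        raise RuntimeError(
            f"fit_map({model_id}): all {opts.n_starts} starts failed "
            f"({n_failed} failures)"
        )

    x_map = best.x
    native = prior.to_native(x_map)
    nll_map = negative_log_likelihood(model_id, native, u_a, u_c, adv_blue, y, wager)
    log_lik = -nll_map
    n_obs = 2 * n_trials
    bic = prior.n_params * np.log(n_obs) - 2.0 * log_lik

    # Laplace evidence; retry with shrinking steps if the MAP sits close to
    # the filter-instability boundary (where probes hit the penalty region)
    lme = None
    hessian_pd = False
    for rel_step in (1e-3, 2e-4, 4e-5):
        try:
            hess = _numerical_hessian(nlj, x_map, rel_step=rel_step)
            if not np.all(np.isfinite(hess)) or np.max(np.abs(hess)) > 1e8:
                continue
            np.linalg.cholesky((hess + hess.T) / 2.0)
            _, logdet = np.linalg.slogdet(hess)
            lme = float(-best_fun + 0.5 * prior.n_params * np.log(2 * np.pi) - 0.5 * logdet)
            hessian_pd = True
            break
        except np.linalg.LinAlgError:
            continue

    boundary = [
        n for n, xv in zip(prior.names, x_map)
        if abs(xv) > 0.9 * _XCLIP
    ]
    return FitResult(
        model_id=model_id,
        params=native,
        params_transformed=dict(zip(prior.names, map(float, x_map))),
        neg_log_joint=float(best_fun),
        log_lik=float(log_lik),
        lme=lme,
        bic=float(bic),
        n_free_params=prior.n_params,
        n_obs=n_obs,
        n_trials=n_trials,
        converged=bool(best.success),
        diagnostics={
            "n_starts": opts.n_starts,
            "n_failed_starts": n_failed,
            "hessian_pd": hessian_pd,
            "boundary_params": boundary,
        },
    )


def hgf_params_from_fit(fit: FitResult) -> tuple[PerceptualParams, ResponseParams]:
    """Convert an hgf3/hgf2 FitResult into simulation parameter structs."""
    p = fit.params
    if fit.model_id == "hgf3":
        pp = PerceptualParams(
            social=SourceParams(kappa=p["kappa_a"], theta=p["theta_a"]),
            nonsocial=SourceParams(kappa=p["kappa_c"], theta=p["theta_c"]),
        )
    elif fit.model_id == "hgf2":
        pp = PerceptualParams(
            social=SourceParams(omega=p["omega_a"]),
            nonsocial=SourceParams(omega=p["omega_c"]),
        )
    else:
        raise ValueError("only HGF fits map onto PerceptualParams")
    rp = ResponseParams(
        zeta=p["zeta"], beta=p["beta"], psi0=p["psi0"], psi1=p["psi1"],
        psi_vol=p.get("psi_vol", 0.0), sigma_w=p["sigma_w"],
    )
    return pp, rp


# ---------------------------------------------------------------------------
# group model selection
# ---------------------------------------------------------------------------

def bms(
    lme: np.ndarray,
    alpha0: float = 1.0,
    max_iter: int = 500,
    tol: float = 1e-8,
    n_samples: int = 100_000,
    seed: int = 0,
) -> dict:
    """Random-effects Bayesian model selection (variational Dirichlet).

    ``lme``: subjects x models log-evidence matrix. Returns the Dirichlet
    parameters, expected model frequencies and Monte-Carlo exceedance
    probabilities.
    """
    lme = np.asarray(lme, dtype=float)
    n_subj, n_models = lme.shape
    alpha = np.full(n_models, alpha0, dtype=float)
    for _ in range(max_iter):
        w = lme + (digamma(alpha) - digamma(alpha.sum()))
        w = w - w.max(axis=1, keepdims=True)
        g = np.exp(w)
        g /= g.sum(axis=1, keepdims=True)
        alpha_new = alpha0 + g.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    r = alpha / alpha.sum()
    rng = np.random.default_rng(seed)
    samples = rng.dirichlet(alpha, size=n_samples)
    xp = np.bincount(np.argmax(samples, axis=1), minlength=n_models) / n_samples
    return {"alpha": alpha, "expected_freq": r, "exceedance_prob": xp, "posterior_resp": g}


def group_model_comparison(
    fit_results: dict[str, dict],
    n_samples: int = 100_000,
    seed: int = 0,
) -> dict:
    """Compare models across participants.

    ``fit_results``: {model_id: {participant_id: FitResult}}. Participants
    missing any model are excluded (with a warning and a reported count).
    BIC summaries use all common participants; the LME summaries and the
    random-effects BMS use the subset whose Laplace evidence is available
    under every model (a non-PD Hessian flags the LME unavailable but
    leaves BIC usable).
    """
    models = list(fit_results)
    common = set.intersection(*(set(f) for f in fit_results.values()))
    n_excluded = len(set.union(*(set(f) for f in fit_results.values()))) - len(common)
    if n_excluded:
        warnings.warn(f"excluding {n_excluded} participants missing >=1 model fit")
    subjects = sorted(common)
    lme_subjects = [
        s for s in subjects if all(fit_results[m][s].lme is not None for m in models)
    ]
    n_lme_excluded = len(subjects) - len(lme_subjects)
    if n_lme_excluded:
        warnings.warn(
            f"{n_lme_excluded} participants lack a usable LME under >=1 model; "
            "excluded from LME sums and BMS"
        )
    if len(lme_subjects) < 2:
        raise ValueError("fewer than 2 participants with usable LMEs in every model")

    rows, lme_mat = [], np.empty((len(lme_subjects), len(models)))
    for j, m in enumerate(models):
        bics = np.array([fit_results[m][s].bic for s in subjects])
        lme_mat[:, j] = [fit_results[m][s].lme for s in lme_subjects]
        rows.append(
            {
                "model": m,
                "n_subjects": len(subjects),
                "n_lme_subjects": len(lme_subjects),
                "sum_bic": bics.sum(),
                "mean_bic": bics.mean(),
                "sum_lme": lme_mat[:, j].sum(),
                "mean_lme": lme_mat[:, j].mean(),
            }
        )
    table = pd.DataFrame(rows)
    out = bms(lme_mat, n_samples=n_samples, seed=seed)
    table["expected_freq"] = out["expected_freq"]
    table["exceedance_prob"] = out["exceedance_prob"]
    return {
        "table": table,
        "bms": out,
        "n_excluded": n_excluded,
        "n_lme_excluded": n_lme_excluded,
        "subjects": subjects,
    }


def validity_check_wagers(fit: FitResult, trial_table: pd.DataFrame) -> dict:
    """Spearman rho between predicted and observed wagers per phase cell."""
    u_a, u_c, adv_blue, y, wager = _extract_arrays(trial_table)
    preds = _model_predictions(fit.model_id, fit.params, u_a, u_c)
    if preds is None:
        raise RuntimeError("fitted parameters are unstable on this table")
    mh_a, mh_c, vol = preds
    mc_adv = np.where(adv_blue == 1, mh_c, 1.0 - mh_c)
    from .response import integrate_sources

    b = integrate_sources(
        np.clip(mh_a, 1e-8, 1 - 1e-8), np.clip(mc_adv, 1e-8, 1 - 1e-8), fit.params["zeta"]
    )
    wstar = predicted_wager(
        b, fit.params["psi0"], fit.params["psi1"], fit.params.get("psi_vol", 0.0), vol
    )
    out = {}
    for source, col in (("nonsocial", "phase_nonsocial"), ("social", "phase_social")):
        for phase in ("stable", "volatile"):
            mask = (trial_table[col] == phase).to_numpy()
            if mask.sum() < 3 or np.all(wager[mask] == wager[mask][0]):
                out[f"{phase}_{source}"] = np.nan
                continue
            rho, _ = stats.spearmanr(wstar[mask], wager[mask])
            out[f"{phase}_{source}"] = rho
    return out


def kalman_prior_divergence(fit: FitResult, prior: PriorSpec | None = None) -> float:
    """Normalized distance of the MAP from the prior mean (max |z| over
    parameters). Values near 0 mean the posterior sat on the prior — the
    criterion used to flag the Kalman model as unfittable."""
    prior = prior or PriorSpec.default(fit.model_id)
    x = np.array([fit.params_transformed[n] for n in prior.names])
    return float(np.max(np.abs(x - prior.mean) / np.sqrt(prior.var)))
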