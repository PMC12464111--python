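"""Numba kernels for the sequential belief filters and the joint likelihood.

These loops run once per objective evaluation inside MAP optimization, so
they are compiled with numba. Public, validated entry points live in
:mod:`wagerhgf.perceptual` and :mod:`wagerhgf.response`; nothing here
validates its inputs.

State conventions (binary hierarchical Gaussian filter):

* level 1: ``muhat1 = logistic(mu2_prev)`` is the predicted outcome
  probability, ``delta1 = u - muhat1`` the outcome prediction error;
* level 2: Gaussian belief (mu2, sigma2) over the outcome tendency, with
  prediction variance ``sigma2_prev + exp(kappa * mu3_prev + omega)``;
* level 3: Gaussian belief (mu3, sigma3) over log-volatility, updated by
  the precision-weighted volatility prediction error delta2; its own
  random-walk variance is the meta-volatility theta.

A non-positive level-3 posterior precision means the filter became
numerically unstable for the given parameters; kernels report the trial
index instead of raising, and callers turn that into an error or an
optimizer penalty.
"""

import math

import numpy as np
from numba import njit

VAR_FLOOR = 1e-8
P_EPS = 1e-8


@njit(cache=True)
def hgf3_core(u, kappa, theta, omega, mu2_0, sigma2_0, mu3_0, sigma3_0):
    """3-level binary HGF. Returns (muhat1, delta1, mu2, sigma2, delta2,
    mu3, sigma3, bad_trial, floor_hits); bad_trial is -1 on success, else
    the 0-based trial where the level-3 precision became non-positive."""
    n = u.shape[0]
    muhat1 = np.empty(n)
    delta1 = np.empty(n)
    mu2 = np.empty(n)
    sigma2 = np.empty(n)
    delta2 = np.empty(n)
    mu3 = np.empty(n)
    sigma3 = np.empty(n)
    m2, s2, m3, s3 = mu2_0, sigma2_0, mu3_0, sigma3_0
    bad = -1
    floor_hits = 0
    for k in range(n):
        mh1 = 1.0 / (1.0 + math.exp(-m2))
        if mh1 < P_EPS:
            mh1 = P_EPS
        elif mh1 > 1.0 - P_EPS:
            mh1 = 1.0 - P_EPS
        w = math.exp(kappa * m3 + omega)
        sh2 = s2 + w  # level-2 prediction variance
        d1 = u[k] - mh1
        s2_new = 1.0 / (1.0 / sh2 + mh1 * (1.0 - mh1))
        if s2_new < VAR_FLOOR:
            s2_new = VAR_FLOOR
            floor_hits += 1
        m2_new = m2 + s2_new * d1
        # volatility prediction error: realized change + uncertainty vs
        # predicted variance
        d2 = (s2_new + (m2_new - m2) ** 2) / sh2 - 1.0
        sh3 = s3 + theta
        w2 = w / sh2
        pi3 = 1.0 / sh3 + 0.5 * kappa * kappa * w2 * (w2 + (2.0 * w2 - 1.0) * d2)
        if not math.isfinite(pi3) or pi3 <= 0.0:
            bad = k
            break
        s3_new = 1.0 / pi3
        if s3_new < VAR_FLOOR:
            s3_new = VAR_FLOOR
            floor_hits += 1
        m3_new = m3 + 0.5 * s3_new * kappa * w2 * d2
        if not (math.isfinite(m2_new) and math.isfinite(m3_new)):
            bad = k
            break
        muhat1[k] = mh1
        delta1[k] = d1
        mu2[k] = m2_new
        sigma2[k] = s2_new
        delta2[k] = d2
        mu3[k] = m3_new
        sigma3[k] = s3_new
        m2, s2, m3, s3 = m2_new, s2_new, m3_new, s3_new
    return muhat1, delta1, mu2, sigma2, delta2, mu3, sigma3, bad, floor_hits


@njit(cache=True)
def hgf2_core(u, omega, mu2_0, sigma2_0):
    """2-level binary HGF: fixed level-2 step variance exp(omega)."""
    n = u.shape[0]
    muhat1 = np.empty(n)
    delta1 = np.empty(n)
    mu2 = np.empty(n)
    sigma2 = np.empty(n)
    m2, s2 = mu2_0, sigma2_0
    bad = -1
    floor_hits = 0
    w = math.exp(omega)
    for k in range(n):
        mh1 = 1.0 / (1.0 + math.exp(-m2))
        if mh1 < P_EPS:
            mh1 = P_EPS
        elif mh1 > 1.0 - P_EPS:
            mh1 = 1.0 - P_EPS
        sh2 = s2 + w
        d1 = u[k] - mh1
        s2_new = 1.0 / (1.0 / sh2 + mh1 * (1.0 - mh1))
        if s2_new < VAR_FLOOR:
            s2_new = VAR_FLOOR
            floor_hits += 1
        m2_new = m2 + s2_new * d1
        if not math.isfinite(m2_new):
            bad = k
            break
        muhat1[k] = mh1
        delta1[k] = d1
        mu2[k] = m2_new
        sigma2[k] = s2_new
        m2, s2 = m2_new, s2_new
    return muhat1, delta1, mu2, sigma2, bad, floor_hits


@njit(cache=True)
def rw_core(u, alpha, v0):
    """Rescorla-Wagner: vhat[k] is the prediction before seeing u[k]."""
    n = u.shape[0]
    vhat = np.empty(n)
    v = np.empty(n)
    prev = v0
    for k in range(n):
        vhat[k] = prev
        prev = prev + alpha * (u[k] - prev)
        v[k] = prev
    return vhat, v


@njit(cache=True)
def kalman_core(u, process_var, obs_var, v0, p0):
    """Scalar Kalman filter treating u as noisy observations of a latent
    value. Returns (vhat, v, pvar, gain); vhat is the one-step-ahead
    prediction (= previous posterior mean under a random-walk latent)."""
    n = u.shape[0]
    vhat = np.empty(n)
    v = np.empty(n)
    pvar = np.empty(n)
    gain = np.empty(n)
    m, p = v0, p0
    for k in range(n):
        vhat[k] = m
        p_pred = p + process_var
        kgain = p_pred / (p_pred + obs_var)
        m = m + kgain * (u[k] - m)
        p = (1.0 - kgain) * p_pred
        v[k] = m
        pvar[k] = p
        gain[k] = kgain
    return vhat, v, pvar, gain


@njit(cache=True)
def response_nll_core(
    mh_a, mh_c, vol, advice_blue, y, wager, zeta, beta, psi0, psi1, psi_vol, sigma_w
):
    """Joint negative log-likelihood of choices and wagers.

    mh_a: predicted advice accuracy per trial; mh_c: predicted probability
    that blue wins; vol: predicted mean log-volatility of the two sources
    (zeros for models without a volatility level); advice_blue: 1 if the
    advice names blue. The card prediction is re-expressed as the
    probability that the *advised* colour wins, then the two sources are
    precision-weighted with social weight zeta. Choice: unit-square
    sigmoid with inverse temperature beta; wager: Gaussian density around
    the logistic confidence mapping to [1, 10], with confidence rising in
    |2b-1| and falling in perceived volatility.
    """
    n = mh_a.shape[0]
    nll = 0.0
    log_sw = math.log(sigma_w)
    for k in range(n):
        ma = mh_a[k]
        if ma < P_EPS:
            ma = P_EPS
        elif ma > 1.0 - P_EPS:
            ma = 1.0 - P_EPS
        mc = mh_c[k]
        if advice_blue[k] == 0:
            mc = 1.0 - mc
        if mc < P_EPS:
            mc = P_EPS
        elif mc > 1.0 - P_EPS:
            mc = 1.0 - P_EPS
        pia = 1.0 / (ma * (1.0 - ma))
        pic = 1.0 / (mc * (1.0 - mc))
        b = (zeta * pia * ma + pic * mc) / (zeta * pia + pic)
        if b < P_EPS:
            b = P_EPS
        elif b > 1.0 - P_EPS:
            b = 1.0 - P_EPS
        lb = beta * math.log(b)
        lnb = beta * math.log(1.0 - b)
        mx = lb if lb > lnb else lnb
        lse = mx + math.log(math.exp(lb - mx) + math.exp(lnb - mx))
        if y[k] == 1:
            nll -= lb - lse
        else:
            nll -= lnb - lse
        conf = psi0 + psi1 * abs(2.0 * b - 1.0) - psi_vol * vol[k]
        wstar = 1.0 + 9.0 / (1.0 + math.exp(-conf))
        z = (wager[k] - wstar) / sigma_w
        nll += 0.5 * z * z + log_sw + 0.9189385332046727  # ln sqrt(2 pi)
    return nll
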