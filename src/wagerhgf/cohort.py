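"""Synthetic study generator: traits, trait-linked agents, behaviour, EEG.

The cohort emulates the study design: participants selected on self-report
psychopathy (SRP-SF total + interpersonal / affective / lifestyle /
antisocial facets) with oversampled top and bottom quartiles
(20/40/26 of 86 by default), HGF-governed agents whose social coupling
kappa_a is negatively rank-correlated with traits, and a per-participant
midfrontal theta coefficient negatively rank-correlated with traits.

Rank correlations are planted through a Gaussian copula on the trait
ranks' normal scores; the noise component is orthogonalized in-sample so
each finite cohort realizes the requested correlation (up to the
rank-vs-linear mismatch) instead of only in expectation. Trait margins are
untouched by the plant (rank-preservation property).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .eeg import EEGConfig, EpochedEEG, extract_theta, morlet_tfr, synthesize_epochs
from .task import TaskSchedule, build_default_schedule, generate_trial_inputs

#: SRP-SF facet item counts (29 items, scored 1-5).
FACETS = {"interpersonal": 7, "affective": 7, "lifestyle": 7, "antisocial": 8}
N_ITEMS = sum(FACETS.values())

PARAM_DISTS = {
    # (transform-space mean, SD); log/logit per parameter. Centres follow
    # the reported group values (kappa_c 0.62, kappa_a 0.46); dispersions
    # keep native ranges admissible.
    "kappa_a": ("logit", float(logit(0.46)), 0.7),
    "kappa_c": ("logit", float(logit(0.62)), 0.7),
    "theta_a": ("logit", float(logit(0.30)), 0.7),
    "theta_c": ("logit", float(logit(0.30)), 0.7),
    "zeta": ("log", 0.25, 0.5),
    # beta centred so cohort accuracy (~0.63) and advice-taking (~0.62)
    # approximate the reported 60.1% / 57.6%
    "beta": ("log", float(np.log(1.2)), 0.4),
    # psi0 centred so the cohort's overall mean wager sits near the
    # reported 5.4 points
    "psi0": ("identity", -0.7, 0.5),
    "psi1": ("identity", 1.5, 0.5),
    # positive volatility weight: lower wagers in volatile phases. The
    # centre is calibrated so the simulated cohort reproduces the reported
    # within-subject wager phase effect (d ~ 1.1)
    "psi_vol": ("log", float(np.log(5.0)), 0.3),
    "sigma_w": ("log", 0.55, 0.25),
    "theta_coef": ("log", 0.0, 0.4),
}


@dataclass
class EffectConfig:
    """Planted trait-parameter rank correlations and cohort composition."""

    param_trait_rho: dict = field(default_factory=lambda: {
        "kappa_a": -0.235,   # reduced social volatility coupling with traits
        "theta_coef": -0.385,  # reduced midfrontal theta with traits
    })
    quartile_split: tuple = (0.2326, 0.4651, 0.3023)  # low / middle / high
    exact: bool = True  # orthogonalize the copula noise in-sample
    trait_mean: float = 62.0
    trait_sd: float = 18.0

    def validate(self) -> None:
        for name, rho in self.param_trait_rho.items():
            if name not in PARAM_DISTS:
                raise ValueError(f"unknown parameter '{name}'")
            if not -1.0 < rho < 1.0:
                raise ValueError(f"rho for {name} outside (-1, 1)")
            if abs(2.0 * np.sin(np.pi * rho / 6.0)) >= 1.0:
                raise ValueError(f"infeasible rank correlation for {name}")
        if abs(sum(self.quartile_split) - 1.0) > 1e-6:
            raise ValueError("quartile split must sum to 1")


def _group_counts(n: int, split: tuple) -> np.ndarray:
    """Largest-remainder apportionment of n into the three groups."""
    raw = np.asarray(split) * n
    counts = np.floor(raw).astype(int)
    for i in np.argsort(raw - counts)[::-1][: n - counts.sum()]:
        counts[i] += 1
    return counts


def _sample_truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    u = rng.uniform(stats.norm.cdf(a), stats.norm.cdf(b), size)
    return mean + sd * stats.norm.ppf(u)


def _normal_scores(x: np.ndarray) -> np.ndarray:
    """Standardized van der Waerden scores of the ranks of x."""
    r = stats.rankdata(x, method="average")
    z = stats.norm.ppf(r / (len(x) + 1.0))
    return (z - z.mean()) / z.std()


def _correlated_scores(z_base: np.ndarray, rho_s: float, rng, exact: bool) -> np.ndarray:
    """Latent normal scores with target Spearman correlation to z_base.

    Uses the Gaussian-copula mapping rho_pearson = 2 sin(pi rho_s / 6).
    With ``exact`` the noise is residualized against z_base in-sample and
    the mixing weight is then solved by bisection so the *realized* rank
    correlation in this finite cohort equals the requested value (to
    rank-resolution) rather than only in expectation.
    """
    n = len(z_base)
    rho_p = 2.0 * np.sin(np.pi * rho_s / 6.0)
    eps = rng.standard_normal(n)
    if not exact:
        return rho_p * z_base + np.sqrt(1.0 - rho_p**2) * eps

    eps = eps - z_base * (eps @ z_base) / (z_base @ z_base)
    eps = (eps - eps.mean()) / eps.std()

    def realized(w: float) -> float:
        return stats.spearmanr(z_base, w * z_base + np.sqrt(1.0 - w * w) * eps)[0]

    lo, hi = -0.9999, 0.9999
    if realized(lo) > rho_s:
        return lo * z_base + np.sqrt(1.0 - lo * lo) * eps
    if realized(hi) < rho_s:
        return hi * z_base + np.sqrt(1.0 - hi * hi) * eps
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if realized(mid) < rho_s:
            lo = mid
        else:
            hi = mid
    w = 0.5 * (lo + hi)
    return w * z_base + np.sqrt(1.0 - w * w) * eps


def _facets_from_total(total: np.ndarray, rng) -> pd.DataFrame:
    """Split totals into facet scores (noisy shares, largest-remainder
    rounding so facets sum to the total)."""
    names = list(FACETS)
    shares = np.array([FACETS[f] for f in names], dtype=float) / N_ITEMS
    out = np.empty((len(total), 4), dtype=int)
    for i, t in enumerate(total):
        w = shares * np.exp(0.15 * rng.standard_normal(4))
        w /= w.sum()
        raw = w * t
        f = np.floor(raw).astype(int)
        for j in np.argsort(raw - f)[::-1][: int(t) - f.sum()]:
            f[j] += 1
        # facet bounds: items scored 1..5
        f = np.clip(f, [FACETS[x] for x in names], [5 * FACETS[x] for x in names])
        out[i] = f
    df = pd.DataFrame(out, columns=names)
    df["srp_total"] = df.sum(axis=1)
    return df


def generate_cohort(
    n: int = 86,
    effects: EffectConfig | None = None,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Generate participant records: traits, agent parameters, theta coef.

    Totals are drawn from a truncated normal with the top/bottom quartiles
    of the reference distribution oversampled per ``quartile_split``;
    facet scores are noisy shares summing to the total. Planted
    correlations act on the trait ranks via the Gaussian copula; all other
    parameters are independent of traits.
    """
    effects = effects or EffectConfig()
    effects.validate()
    rng = np.random.default_rng(rng_seed)

    counts = _group_counts(n, effects.quartile_split)
    m, s = effects.trait_mean, effects.trait_sd
    q1, q3 = m + s * stats.norm.ppf([0.25, 0.75])
    lo_hi = [(N_ITEMS, q1), (q1, q3), (q3, 5 * N_ITEMS)]
    totals, groups = [], []
    for cnt, (lo, hi), g in zip(counts, lo_hi, ("low", "middle", "high")):
        totals.append(np.round(_sample_truncnorm(rng, m, s, lo, hi, cnt)))
        groups.extend([g] * cnt)
    total = np.concatenate(totals)
    order = rng.permutation(n)
    total = total[order]
    groups = np.asarray(groups, dtype=object)[order]

    facets = _facets_from_total(total, rng)
    z_trait = _normal_scores(facets["srp_total"].to_numpy(float))

    cohort = pd.DataFrame(
        {"id": [f"p{i + 1:03d}" for i in range(n)], "group": groups}
    )
    cohort = pd.concat([cohort, facets[["srp_total", *FACETS]]], axis=1)

    for name, (tr, mu, sd) in PARAM_DISTS.items():
        rho = effects.param_trait_rho.get(name, 0.0)
        z = (
            _correlated_scores(z_trait, rho, rng, effects.exact)
            if rho != 0.0
            else rng.standard_normal(n)
        )
        x = mu + sd * z
        cohort[name] = np.exp(x) if tr == "log" else expit(x) if tr == "logit" else x
    return cohort.set_index("id")


# ---------------------------------------------------------------------------
# full study (behaviour + EEG)
# ---------------------------------------------------------------------------

@dataclass
class StudyData:
    """A generated study: cohort, shared trial inputs, behaviour, EEG."""

    cohort: pd.DataFrame
    schedule: TaskSchedule
    trial_inputs: pd.DataFrame
    trial_tables: dict
    eeg_config: EEGConfig
    _epoch_seeds: dict = field(default_factory=dict)

    def epochs(self, participant_id: str) -> EpochedEEG:
        """Synthesize this participant's feedback-locked epochs
        (deterministic per participant and study seed)."""
        tab = self.trial_tables[participant_id]
        labels = tab[["choice_correct", "phase_nonsocial", "phase_social"]].copy()
        return synthesize_epochs(
            self.eeg_config,
            labels,
            rng_seed=self._epoch_seeds[participant_id],
            participant_coef=float(self.cohort.loc[participant_id, "theta_coef"]),
        )

    def theta_table(
        self,
        freqs: np.ndarray | None = None,
        participants: list | None = None,
    ) -> pd.DataFrame:
        """Per-participant midfrontal theta summaries.

        Columns: per-electrode and midfrontal mean power over all trials,
        midfrontal power on correct / incorrect trials and in the four
        phase x source cells. ``freqs`` defaults to the full 1-40 Hz
        ladder; passing just the 4-8 Hz bins gives the same theta summary
        faster.
        """
        pids = participants or list(self.trial_tables)
        rows = {}
        for pid in pids:
            ep = self.epochs(pid)
            tfr = morlet_tfr(ep, freqs=freqs)
            ex = extract_theta(tfr, ep.labels)
            row = {e: ex.loc["all", e] for e in ("Fz", "FCz", "Cz")}
            row["midfrontal"] = ex.loc["all", "midfrontal"]
            for cond in ("correct", "incorrect", "stable_nonsocial",
                         "volatile_nonsocial", "stable_social", "volatile_social"):
                row[cond] = ex.loc[cond, "midfrontal"]
            rows[pid] = row
        return pd.DataFrame.from_dict(rows, orient="index")


def generate_study(
    cohort: pd.DataFrame,
    schedule: TaskSchedule | None = None,
    rng_seed: int = 0,
    eeg_config: EEGConfig | None = None,
) -> StudyData:
    """Simulate the full study for a generated cohort.

    All participants play the same trial-input realization (the task used
    one fixed trial order); behaviour comes from each participant's own
    HGF + response parameters; EEG epochs are synthesized lazily per
    participant with theta amplitude scaled by the participant coefficient
    and trial correctness.
    """
    from .recovery import PARAM_NAMES
    from .simulate import simulate_admissible_session

    schedule = schedule or build_default_schedule()
    ss = np.random.SeedSequence(rng_seed)
    inputs_seed, sessions_seed, eeg_root = (int(x % (2**31)) for x in ss.generate_state(3))
    trial_inputs = generate_trial_inputs(schedule, inputs_seed)

    sess_rng = np.random.default_rng(sessions_seed)
    cohort = cohort.copy()
    tables = {}
    for pid, row in cohort.iterrows():
        tables[pid], d = simulate_admissible_session(
            schedule, {k: row[k] for k in PARAM_NAMES}, sess_rng,
            trial_inputs=trial_inputs,
        )
        cohort.loc[pid, list(PARAM_NAMES)] = [d[k] for k in PARAM_NAMES]
    epoch_seeds = {
        pid: int(s % (2**31))
        for pid, s in zip(cohort.index, np.random.SeedSequence(eeg_root).generate_state(len(cohort)))
    }
    return StudyData(
        cohort=cohort,
        schedule=schedule,
        trial_inputs=trial_inputs,
        trial_tables=tables,
        eeg_config=eeg_config or EEGConfig(),
        _epoch_seeds=epoch_seeds,
    )
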