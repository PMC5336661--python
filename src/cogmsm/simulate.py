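"""Synthetic cohort generator for parameter-recovery experiments.

Emulates a four-wave ageing cohort: ~2000 subjects entering at ages 60-64,
interviewed every 4 years for 12 years, with four cognitive states
(CN, MCI, dementia, death) or three (CN, test-based MCI, death). Trajectories
are exact draws from a time-homogeneous continuous-time Markov chain
(competing exponential sojourns), observed only at the wave schedule except
for death, which is recorded at its exact age. Wave-level dropout is
non-informative by default.

Default ground truth: baseline intensities calibrated so the covariate-average
subject reproduces the published wave-to-wave transition frequencies; a risk
index distributed N(9.4, 5.9^2) truncated to [0, 32] acting on the CN->MCI
intensity with hazard ratio 1.07 per point, and a standard-normal genetic
score acting on CN->dementia with hazard ratio 4.19 per SD. Covariates enter
the intensities centred (risk index minus its mean), so the baseline rates are
those of an average subject; per-unit hazard ratios are unaffected by
centring.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .msm import TransitionStructure, four_state_structure, three_state_structure, build_q
from .panel import CohortPanel, DEATH, CENSORED

#: baseline log intensities (per year) calibrated so that P(4 years) matches
#: the published wave-to-wave transition frequencies for an average subject
THETA_4STATE = {
    ("CN", "MCI"): np.log(0.012386),
    ("MCI", "CN"): np.log(0.226227),
    ("CN", "DEMENTIA"): np.log(0.001327),
    ("MCI", "DEMENTIA"): np.log(0.038255),
    ("CN", "DEATH"): np.log(0.009670),
    ("MCI", "DEATH"): np.log(0.014974),
    ("DEMENTIA", "DEATH"): np.log(0.084118),
}

THETA_3STATE = {
    ("CN", "MCI_TB"): np.log(0.040442),
    ("MCI_TB", "CN"): np.log(0.129573),
    ("CN", "DEATH"): np.log(0.008669),
    ("MCI_TB", "DEATH"): np.log(0.016601),
}

#: published effect sizes used as default generative truth
HR_ADRI_CN_MCI = 1.07
HR_GRS_CN_DEMENTIA = 4.19

ADRI_MEAN, ADRI_SD = 9.4, 5.9

#: per-wave dropout probabilities at waves 2, 3, 4
DEFAULT_DROPOUT = (0.135, 0.093, 0.206)


@dataclass
class SimConfig:
    """Ground truth and observation design for a simulated cohort.

    ``theta`` maps allowed transitions to log baseline intensities (per year,
    at covariate value zero); ``beta`` maps transitions to
    ``{covariate: log hazard ratio}``. ``covariates`` maps covariate names to
    distribution specs: ``{"dist": "truncnorm", "mean":, "sd":, "lo":, "hi":,
    "center": bool}`` or ``{"dist": "normal"}``. Centred covariates are
    shifted by their distribution mean before entering the intensities.
    """

    n_subjects: int = 2000
    baseline_age_range: tuple[float, float] = (60.0, 64.0)
    wave_offsets: tuple[float, ...] = (0.0, 4.0, 8.0, 12.0)
    structure: TransitionStructure = field(default_factory=four_state_structure)
    theta: dict = field(default_factory=lambda: dict(THETA_4STATE))
    beta: dict = field(default_factory=lambda: {
        ("CN", "MCI"): {"adri_c": np.log(HR_ADRI_CN_MCI)},
        ("CN", "DEMENTIA"): {"grs_z": np.log(HR_GRS_CN_DEMENTIA)},
    })
    covariates: dict = field(default_factory=lambda: {
        "adri_c": {"dist": "truncnorm", "mean": ADRI_MEAN, "sd": ADRI_SD,
                   "lo": 0.0, "hi": 32.0, "center": True},
        "grs_z": {"dist": "normal"},
    })
    dropout: tuple[float, ...] = DEFAULT_DROPOUT
    dropout_state_multiplier: float = 1.0  # >1: impaired states drop out more
    wave_jitter: float = 0.0  # uniform +/- jitter (years) on waves 2+
    horizon: float = 12.0

    def __post_init__(self) -> None:
        if any(not 0 <= p <= 1 for p in self.dropout):
            raise ValueError("dropout probabilities must lie in [0, 1]")
        if list(self.wave_offsets) != sorted(self.wave_offsets):
            raise ValueError("wave offsets must increase")
        for t, th in self.theta.items():
            if not np.isfinite(th):
                raise ValueError(f"non-finite log intensity for {t}")

    def true_model(self) -> dict:
        """The (theta, beta, structure) triple stored with each dataset."""
        return {
            "states": list(self.structure.states),
            "transitions": [list(t) for t in self.structure.transitions],
            "theta": {f"{r}->{s}": float(v) for (r, s), v in self.theta.items()},
            "beta": {f"{r}->{s}": {c: float(b) for c, b in d.items()}
                     for (r, s), d in self.beta.items()},
        }


def three_state_config(**overrides) -> SimConfig:
    """Default generative truth for the test-based MCI (3-state) analyses."""
    base = dict(
        structure=three_state_structure(impaired_state="MCI_TB"),
        theta=dict(THETA_3STATE),
        beta={("CN", "MCI_TB"): {"adri_c": np.log(HR_ADRI_CN_MCI)}},
    )
    base.update(overrides)
    return SimConfig(**base)


def draw_covariates(config: SimConfig, n: int, rng: np.random.Generator) -> pd.DataFrame:
    cols = {}
    for name, spec in config.covariates.items():
        if spec["dist"] == "normal":
            x = rng.standard_normal(n)
        elif spec["dist"] == "truncnorm":
            a = (spec["lo"] - spec["mean"]) / spec["sd"]
            b = (spec["hi"] - spec["mean"]) / spec["sd"]
            x = truncnorm.rvs(a, b, loc=spec["mean"], scale=spec["sd"],
                              size=n, random_state=rng)
            cols[name.replace("_c", "_raw")] = x.copy()
            if spec.get("center", False):
                x = x - spec["mean"]
        else:
            raise ValueError(f"unknown covariate distribution {spec['dist']!r}")
        cols[name] = x
    return pd.DataFrame(cols, index=pd.RangeIndex(n))


def simulate_trajectory(z: dict, config: SimConfig, rng: np.random.Generator,
                        baseline_age: float) -> list[tuple[float, str]]:
    """Exact continuous-time path: list of (entry age, state), starting CN.

    Sojourn in state r is exponential with rate ``sum_s q_rs(z)``; the next
    state is drawn with probability proportional to ``q_rs(z)``. The path
    stops at an absorbing state or at the administrative horizon.
    """
    st = config.structure
    Q = build_q(st, config.theta, config.beta, z)
    state = st.states[0]
    age = baseline_age
    path = [(age, state)]
    end = baseline_age + config.horizon
    absorbing = set(st.absorbing_states)
    while state not in absorbing:
        i = st.index(state)
        rates = Q[i].copy()
        rates[i] = 0.0
        total = rates.sum()
        if total <= 0:
            break  # zero-intensity row: infinite sojourn
        sojourn = rng.exponential(1.0 / total)
        if age + sojourn > end:
            break
        age += sojourn
        state = st.states[rng.choice(len(rates), p=rates / total)]
        path.append((age, state))
    return path


def _state_at(path: list[tuple[float, str]], age: float) -> str:
    state = path[0][1]
    for t, s in path:
        if t <= age:
            state = s
        else:
            break
    return state


def observe_panel(paths: list, covariates: pd.DataFrame, config: SimConfig,
                  rng: np.random.Generator) -> CohortPanel:
    """Sample each trajectory at the wave schedule with dropout.

    Death is recorded at its exact age the first time a wave falls after it;
    after a dropout draw succeeds, no further waves are emitted for that
    subject (non-informative right censoring). With
    ``dropout_state_multiplier`` > 1, currently-impaired subjects drop out
    with proportionally higher probability.
    """
    st = config.structure
    death = st.death_state
    rows = []
    for sid, path in enumerate(paths):
        a0 = path[0][0]
        death_age = None
        for t, s in path:
            if s == death:
                death_age = t
        dropped = False
        for w, offset in enumerate(config.wave_offsets):
            if dropped:
                break
            obs_age = a0 + offset
            if w > 0 and config.wave_jitter > 0:
                obs_age += rng.uniform(-config.wave_jitter, config.wave_jitter)
            if death_age is not None and death_age <= obs_age:
                rows.append({"subject_id": sid, "wave": w + 1, "age": death_age,
                             "state": DEATH, "death_age": death_age})
                break
            if w > 0:
                p_drop = config.dropout[min(w - 1, len(config.dropout) - 1)]
                if config.dropout_state_multiplier != 1.0 and \
                        _state_at(path, obs_age) != st.states[0]:
                    p_drop = min(1.0, p_drop * config.dropout_state_multiplier)
                if rng.uniform() < p_drop:
                    dropped = True
                    break
            rows.append({"subject_id": sid, "wave": w + 1, "age": obs_age,
                         "state": _state_at(path, obs_age), "death_age": np.nan})
    df = pd.DataFrame(rows)
    df = df.merge(covariates.reset_index(names="subject_id"), on="subject_id")
    return CohortPanel(df)


def simulate_cohort(config: SimConfig | None = None, seed: int = 0
                    ) -> tuple[CohortPanel, dict]:
    """Generate a full synthetic cohort panel plus its ground-truth record."""
    config = config or SimConfig()
    rng = np.random.default_rng(seed)
    cov = draw_covariates(config, config.n_subjects, rng)
    cov_names = list(config.covariates)
    ages = rng.uniform(*config.baseline_age_range, size=config.n_subjects)
    paths = [
        simulate_trajectory({c: cov.iloc[i][c] for c in cov_names}, config, rng, ages[i])
        for i in range(config.n_subjects)
    ]
    panel = observe_panel(paths, cov, config, rng)
    truth = config.true_model()
    truth["seed"] = seed
    truth["n_subjects"] = config.n_subjects
    return panel, truth


#: per-test (mean, SD) roughly matching a 60+ cohort's baseline psychometrics
PSYCHOMETRIC_NORMS = {
    "perceptual_speed": (50.0, 9.7),
    "episodic_memory": (7.2, 2.3),
    "working_memory": (4.9, 2.2),
    "vocabulary": (52.0, 6.0),
}


def synthetic_psychometrics(panel: CohortPanel, seed: int = 0,
                            impaired_shift: float = 1.8,
                            impaired_states=("MCI", "MCI_TB", "DEMENTIA")
                            ) -> pd.DataFrame:
    """State-shifted normal test scores for classifier testing (extension hook).

    Living subject-waves get four normal test scores; waves in an impaired
    state are shifted down by ``impaired_shift`` SDs on every test. Education
    years are drawn once per subject (normal 14 +/- 2.8, clipped to [6, 20]).
    This emulates only the location shift the test-based classifier keys on —
    no claim of realism for correlation structure or practice effects.
    """
    rng = np.random.default_rng(seed)
    df = panel.data[~panel.data["state"].isin([DEATH, CENSORED])].copy()
    edu = {}
    for sid in df["subject_id"].unique():
        edu[sid] = float(np.clip(rng.normal(14.0, 2.8), 6.0, 20.0))
    df["education_years"] = df["subject_id"].map(edu)
    impaired = df["state"].isin(impaired_states).to_numpy()
    for test, (mu, sd) in PSYCHOMETRIC_NORMS.items():
        x = rng.normal(mu, sd, size=len(df))
        x[impaired] -= impaired_shift * sd
        df[test] = x
    return df


def simulate_survival(n: int = 2000, hr_per_unit: float = 1.06,
                      baseline_hazard: float = 0.011,
                      entry_age_range: tuple[float, float] = (60.0, 64.0),
                      followup: float = 12.0, seed: int = 0) -> pd.DataFrame:
    """Event ages under proportional hazards on the age time scale.

    A constant baseline hazard (per year, at the covariate mean) is scaled by
    ``hr_per_unit ** (covariate - mean)``; subjects enter at a uniform age in
    ``entry_age_range`` (left truncation) and are administratively censored
    ``followup`` years after entry. The covariate is drawn like the risk
    index: normal(9.4, 5.9) truncated to [0, 32]. Returns an
    (entry_age, exit_age, event, adri_score, adri_c) records table.
    """
    rng = np.random.default_rng(seed)
    a = (0.0 - ADRI_MEAN) / ADRI_SD
    b = (32.0 - ADRI_MEAN) / ADRI_SD
    adri = truncnorm.rvs(a, b, loc=ADRI_MEAN, scale=ADRI_SD, size=n, random_state=rng)
    zc = adri - ADRI_MEAN
    rate = baseline_hazard * hr_per_unit ** zc
    entry = rng.uniform(*entry_age_range, size=n)
    t_event = rng.exponential(1.0 / rate)
    event = t_event <= followup
    exit_age = entry + np.minimum(t_event, followup)
    return pd.DataFrame({"entry_age": entry, "exit_age": exit_age,
                         "event": event, "adri_score": adri, "adri_c": zc})


def empirical_transition_table(panel: CohortPanel) -> pd.DataFrame:
    """Counts and row percentages of consecutive-wave state pairs.

    Rows are living from-states; the ``CENSORED`` column counts subjects whose
    next wave is missing due to dropout (a living last record before the final
    wave); reaching the end of the study contributes no pair. Percentages are
    row counts over the row total (including censored), as in a published
    transition table.
    """
    df = panel.data
    final_wave = df["wave"].max()
    counts: dict[str, dict[str, int]] = {}

    def bump(frm, to):
        counts.setdefault(frm, {})
        counts[frm][to] = counts[frm].get(to, 0) + 1

    for _, grp in df.groupby("subject_id", sort=False):
        states = grp["state"].tolist()
        for s0, s1 in zip(states, states[1:]):
            bump(s0, s1)
        if states[-1] not in (DEATH, CENSORED) and grp["wave"].iloc[-1] < final_wave:
            bump(states[-1], CENSORED)
    if not counts:
        return pd.DataFrame()
    table = pd.DataFrame(counts).T.fillna(0).astype(int)
    table = table.sort_index()
    totals = table.sum(axis=1)
    pct = table.div(totals, axis=0) * 100.0
    out = table.copy().astype(object)
    for r in table.index:
        for c in table.columns:
            out.loc[r, c] = f"{table.loc[r, c]} ({pct.loc[r, c]:.1f}%)"
    out.insert(0, "n", totals)
    return out


def transition_percentages(counts: dict[str, list[float]] | pd.DataFrame
                           ) -> pd.DataFrame:
    """Row percentages from a plain table of transition counts.

    Accepts a mapping from from-state to a list of counts (ordered by the
    to-state columns) or a DataFrame of counts; returns percentages over each
    row total.
    """
    table = pd.DataFrame(counts).T if isinstance(counts, dict) else counts
    return table.div(table.sum(axis=1), axis=0) * 100.0
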