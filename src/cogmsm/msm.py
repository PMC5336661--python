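"""Continuous-time multi-state Markov models for interval-censored panel data.

States are observed only at discrete visits, so exact transition times are
unknown; the likelihood of an interval from state ``r`` at age ``t_k`` to
state ``s`` at ``t_{k+1}`` is the matrix-exponential transition probability
``P_rs(t_{k+1} - t_k) = [exp(dt * Q)]_rs``. Death is treated as an absorbing
state observed at its exact age: a death at ``t`` after a last living
observation in ``r`` contributes ``sum_s P_rs(dt) * q_{s,death}``. Subjects
lost to follow-up are right-censored and contribute nothing past their last
observation (optionally, an "alive, state unknown" term).

Transition intensities follow a proportional-intensity regression,
``q_rs(z) = q_rs0 * exp(beta_rs' z)``, with per-transition covariate effects;
``exp(beta)`` is the hazard ratio for that transition. Estimation is maximum
likelihood via BFGS on the per-subject-normalised log likelihood, with
Wald confidence intervals from the inverse observed information.

The public surface follows the statsmodels idiom: build a
:class:`MultiStateModel` from a panel, call :meth:`~MultiStateModel.fit`, and
read estimates off the returned :class:`MultiStateResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize

from ._linalg import expm_batch, numerical_hessian
from .panel import CohortPanel, DEATH, CENSORED

_OBS, _DEATH_EXACT, _ALIVE_UNKNOWN = 0, 1, 2


class StructureError(ValueError):
    pass


@dataclass(frozen=True)
class TransitionStructure:
    """Allowed directed transitions over an ordered state set.

    ``covariates`` maps each allowed transition to the covariate names whose
    effects are estimated on it; pass a flat sequence of names to attach them
    to every transition.
    """

    states: tuple[str, ...]
    transitions: tuple[tuple[str, str], ...]
    covariates: dict = field(default_factory=dict)
    death_state: str | None = "DEATH"

    def __post_init__(self) -> None:
        for r, s in self.transitions:
            if r not in self.states or s not in self.states:
                raise StructureError(f"transition {r}->{s} uses unknown state")
            if r == s:
                raise StructureError("self-transitions are not allowed")
        if not isinstance(self.covariates, dict):
            cov = {t: tuple(self.covariates) for t in self.transitions}
            object.__setattr__(self, "covariates", cov)
        else:
            cov = {t: tuple(self.covariates.get(t, ())) for t in self.transitions}
            unknown = set(self.covariates) - set(self.transitions)
            if unknown:
                raise StructureError(f"covariates attached to disallowed transition(s) {unknown}")
            object.__setattr__(self, "covariates", cov)
        out = {r for r, _ in self.transitions}
        for a in self.absorbing_states:
            assert a not in out
        # connectivity: every state reachable from the initial (first) state
        reach = {self.states[0]}
        frontier = [self.states[0]]
        while frontier:
            r = frontier.pop()
            for a, b in self.transitions:
                if a == r and b not in reach:
                    reach.add(b)
                    frontier.append(b)
        if reach != set(self.states):
            raise StructureError(
                f"state(s) {set(self.states) - reach} unreachable from {self.states[0]}")

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def absorbing_states(self) -> tuple[str, ...]:
        out = {r for r, _ in self.transitions}
        return tuple(s for s in self.states if s not in out)

    def index(self, state: str) -> int:
        return self.states.index(state)

    @property
    def covariate_names(self) -> tuple[str, ...]:
        seen: list[str] = []
        for t in self.transitions:
            for c in self.covariates[t]:
                if c not in seen:
                    seen.append(c)
        return tuple(seen)

    def parameter_names(self) -> list[str]:
        names = [f"theta[{r}->{s}]" for r, s in self.transitions]
        for r, s in self.transitions:
            for c in self.covariates[(r, s)]:
                names.append(f"beta[{r}->{s}:{c}]")
        return names


def four_state_structure(covariates=()) -> TransitionStructure:
    """CN <-> MCI, CN/MCI -> DEMENTIA, all living -> DEATH; DEATH absorbing.

    Dementia has no backward transitions and exits only to death.
    """
    return TransitionStructure(
        states=("CN", "MCI", "DEMENTIA", "DEATH"),
        transitions=(("CN", "MCI"), ("MCI", "CN"), ("CN", "DEMENTIA"),
                     ("MCI", "DEMENTIA"), ("CN", "DEATH"), ("MCI", "DEATH"),
                     ("DEMENTIA", "DEATH")),
        covariates=covariates,
    )


def three_state_structure(covariates=(), impaired_state: str = "MCI") -> TransitionStructure:
    """CN <-> impaired state, both -> DEATH (test-based MCI analyses)."""
    return TransitionStructure(
        states=("CN", impaired_state, "DEATH"),
        transitions=(("CN", impaired_state), (impaired_state, "CN"),
                     ("CN", "DEATH"), (impaired_state, "DEATH")),
        covariates=covariates,
    )


def build_q(structure: TransitionStructure, theta: dict, beta: dict | None = None,
            z: dict | None = None) -> np.ndarray:
    """Intensity matrix ``Q(z)`` with entries ``q_rs0 * exp(beta_rs' z)``.

    ``theta`` maps each allowed transition ``(r, s)`` to its log baseline
    intensity; ``beta`` maps transitions to ``{covariate: coefficient}``;
    ``z`` supplies covariate values. Disallowed entries are exactly zero and
    each row sums to zero.
    """
    beta = beta or {}
    z = z or {}
    d = structure.n_states
    Q = np.zeros((d, d))
    for (r, s) in structure.transitions:
        lin = float(theta[(r, s)])
        for c, b in beta.get((r, s), {}).items():
            if c not in z:
                raise KeyError(f"covariate {c!r} required by transition {r}->{s} not supplied")
            lin += b * z[c]
        Q[structure.index(r), structure.index(s)] = np.exp(lin)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def transition_probability(Q: np.ndarray, t: float) -> np.ndarray:
    """``P(t) = exp(t*Q)``; rows sum to one, entries lie in [0, 1]."""
    if t < 0:
        raise ValueError("elapsed time must be non-negative")
    return expm_batch(t * np.asarray(Q, dtype=float))


def subject_loglik(times, states, structure: TransitionStructure, theta: dict,
                   beta: dict | None = None, z: dict | None = None,
                   censored_policy: str = "drop") -> float:
    """Log-likelihood contribution of one subject's observation history.

    ``states`` may end in ``DEATH`` (exactly observed at its time) or
    ``CENSORED`` (dropped, or an alive-state-unknown sum under
    ``censored_policy='alive_unknown'``). Structurally impossible observed
    transitions yield ``-inf`` rather than raising.
    """
    Q = build_q(structure, theta, beta, z)
    death = structure.death_state
    total = 0.0
    for (t0, s0), (t1, s1) in zip(zip(times, states), zip(times[1:], states[1:])):
        dt = t1 - t0
        if dt < 0:
            raise ValueError("observation times must be increasing")
        P = transition_probability(Q, dt)
        i = structure.index(s0)
        if s1 == DEATH and death is not None:
            p = float(P[i] @ Q[:, structure.index(death)])
        elif s1 == CENSORED:
            if censored_policy == "drop":
                continue
            live = [structure.index(s) for s in structure.states if s != death]
            p = float(P[i, live].sum())
        else:
            p = float(P[i, structure.index(s1)])
        total += np.log(p) if p > 0 else -np.inf
    return total


def _invert_information(H: np.ndarray) -> tuple[np.ndarray | None, bool]:
    """Covariance from an observed-information matrix, tolerating flat directions.

    A baseline intensity whose transition saw no events drifts to -inf where
    the likelihood is flat, leaving a zero row/column in the information; the
    remaining parameters are still identified, so the well-curved submatrix is
    inverted and the flat parameters get NaN variances instead of poisoning
    every standard error.
    """
    p = H.shape[0]
    curved = np.diag(H) > 1e-6
    if not curved.any():
        return None, False
    Hs = H[np.ix_(curved, curved)]
    try:
        sub = np.linalg.inv(Hs)
    except np.linalg.LinAlgError:
        return None, False
    if not (np.all(np.isfinite(sub)) and np.all(np.diag(sub) > 0)):
        return None, False
    cov = np.full((p, p), np.nan)
    cov[np.ix_(curved, curved)] = sub
    return cov, True


class MultiStateModel:
    """Panel-data multi-state Markov model with per-transition covariates.

    Parameters
    ----------
    panel : CohortPanel
        Long-format observations; states must match ``structure.states``
        (plus ``DEATH``/``CENSORED`` terminals). Covariates named in the
        structure are read from the panel's covariate columns (baseline value
        = the subject's first record).
    structure : TransitionStructure
    censored_policy : {"drop", "alive_unknown"}
        How a terminal CENSORED record contributes: not at all
        (administrative right censoring, the default) or as a sum over living
        states at the censoring time.
    """

    def __init__(self, panel: CohortPanel, structure: TransitionStructure,
                 censored_policy: str = "drop") -> None:
        if censored_policy not in ("drop", "alive_unknown"):
            raise ValueError("censored_policy must be 'drop' or 'alive_unknown'")
        self.panel = panel
        self.structure = structure
        self.censored_policy = censored_policy
        self._prepare()

    # -- parameter bookkeeping ------------------------------------------
    @property
    def n_theta(self) -> int:
        return len(self.structure.transitions)

    @property
    def param_names(self) -> list[str]:
        return self.structure.parameter_names()

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def _prepare(self) -> None:
        st = self.structure
        cov_names = st.covariate_names
        df = self.panel.data
        for c in cov_names:
            if c not in df.columns:
                raise KeyError(f"covariate {c!r} not found in panel")

        sub_ids = self.panel.subject_ids
        sub_pos = {sid: k for k, sid in enumerate(sub_ids)}
        Z = np.zeros((len(sub_ids), len(cov_names)))
        rows_s, rows_dt, rows_from, rows_to, rows_kind = [], [], [], [], []
        n_trans_obs = np.zeros(self.n_theta)
        exposure = np.zeros(st.n_states)
        jumps = np.zeros((st.n_states, st.n_states))
        t_index = {t: k for k, t in enumerate(st.transitions)}
        death = st.death_state

        for sid, grp in df.groupby("subject_id", sort=False):
            k = sub_pos[sid]
            first = grp.iloc[0]
            for j, c in enumerate(cov_names):
                Z[k, j] = float(first[c])
            ages = grp["age"].to_numpy(dtype=float)
            states = grp["state"].tolist()
            if len(ages) < 2:
                raise ValueError(
                    f"subject {sid!r} has a single observation; apply exclusions first")
            for (t0, s0), (t1, s1) in zip(zip(ages, states), zip(ages[1:], states[1:])):
                if s0 in (DEATH, CENSORED):
                    continue
                i = st.index(s0)
                if s1 == DEATH and death is not None:
                    kind, j = _DEATH_EXACT, st.index(death)
                elif s1 == CENSORED:
                    if self.censored_policy == "drop":
                        continue
                    kind, j = _ALIVE_UNKNOWN, -1
                else:
                    if s1 not in st.states:
                        raise ValueError(f"state {s1!r} not in structure")
                    kind, j = _OBS, st.index(s1)
                rows_s.append(k)
                rows_dt.append(t1 - t0)
                rows_from.append(i)
                rows_to.append(j)
                rows_kind.append(kind)
                exposure[i] += t1 - t0
                if j >= 0 and (s0, s1) in t_index:
                    n_trans_obs[t_index[(s0, s1)]] += 1
                if j >= 0:
                    jumps[i, j] += 1

        self.n_subjects = len(sub_ids)
        self._Z = Z
        self._cov_names = cov_names
        self._iv_subj = np.asarray(rows_s, dtype=int)
        self._iv_dt = np.asarray(rows_dt, dtype=float)
        self._iv_from = np.asarray(rows_from, dtype=int)
        self._iv_to = np.asarray(rows_to, dtype=int)
        self._iv_kind = np.asarray(rows_kind, dtype=int)
        self._crude_counts = n_trans_obs
        self._exposure = exposure
        # beta layout: for each transition in order, its covariates in order
        self._beta_cov_idx = []
        self._beta_trans_idx = []
        for ti, t in enumerate(st.transitions):
            for c in st.covariates[t]:
                self._beta_trans_idx.append(ti)
                self._beta_cov_idx.append(cov_names.index(c))
        self._trans_from = np.array([st.index(r) for r, _ in st.transitions])
        self._trans_to = np.array([st.index(s) for _, s in st.transitions])
        if death is not None:
            self._death_idx = st.index(death)

    # -- likelihood ------------------------------------------------------
    def _q_batch(self, x: np.ndarray) -> np.ndarray:
        """Per-subject intensity matrices, shape (n_subjects, d, d)."""
        theta = x[: self.n_theta]
        beta = x[self.n_theta:]
        lin = np.tile(theta, (self.n_subjects, 1))
        for m, b in enumerate(beta):
            lin[:, self._beta_trans_idx[m]] += b * self._Z[:, self._beta_cov_idx[m]]
        q = np.exp(lin)
        d = self.structure.n_states
        Q = np.zeros((self.n_subjects, d, d))
        Q[:, self._trans_from, self._trans_to] = q
        idx = np.arange(d)
        Q[:, idx, idx] = -Q.sum(axis=2)
        return Q

    def loglik(self, x: np.ndarray) -> float:
        """Total log-likelihood at parameter vector ``x`` (theta then beta)."""
        x = np.asarray(x, dtype=float)
        Q = self._q_batch(x)
        Qi = Q[self._iv_subj]
        P = expm_batch(self._iv_dt[:, None, None] * Qi)
        n = len(self._iv_dt)
        rows = np.arange(n)
        p = np.empty(n)
        obs = self._iv_kind == _OBS
        p[obs] = P[rows[obs], self._iv_from[obs], self._iv_to[obs]]
        dth = self._iv_kind == _DEATH_EXACT
        if dth.any():
            frm = P[rows[dth], self._iv_from[dth], :]  # (m, d)
            qd = Qi[dth][:, :, self._death_idx]
            p[dth] = np.einsum("md,md->m", frm, qd)
        unk = self._iv_kind == _ALIVE_UNKNOWN
        if unk.any():
            frm = P[rows[unk], self._iv_from[unk], :]
            p[unk] = frm.sum(axis=1) - frm[:, self._death_idx]
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, np.log(np.maximum(p, 1e-300)), -np.inf)
        return float(terms.sum())

    def _objective(self, x: np.ndarray) -> float:
        # normalised (per-subject mean) negative log-likelihood for stability
        ll = self.loglik(x)
        if not np.isfinite(ll):
            return 1e10
        return -ll / self.n_subjects

    # -- initial values --------------------------------------------------
    def crude_start(self) -> np.ndarray:
        """Log crude rates (observed jumps / exposure in the source state).

        Interval-censored jump counts understate fast transitions but give a
        stable, data-driven starting point; covariate effects start at zero.
        """
        st = self.structure
        theta0 = np.empty(self.n_theta)
        for k, (r, s) in enumerate(st.transitions):
            i = st.index(r)
            count = max(self._crude_counts[k], 0.5)
            expo = max(self._exposure[i], 1e-8)
            theta0[k] = np.log(count / expo)
        return np.concatenate([theta0, np.zeros(self.n_params - self.n_theta)])

    def _starts(self, start, multistart, seed) -> list[np.ndarray]:
        base = self.crude_start() if start is None else np.asarray(start, dtype=float)
        starts = [base]
        rng = np.random.default_rng(seed)
        for _ in range(multistart):
            pert = base.copy()
            # perturb baseline intensities by up to +/-50% on the rate scale
            pert[: self.n_theta] += rng.uniform(
                np.log(0.5), np.log(1.5), size=self.n_theta)
            starts.append(pert)
        return starts

    # -- fitting ---------------------------------------------------------
    def fit(self, start=None, multistart: int = 0, seed: int = 0,
            gtol: float = 1e-6, maxiter: int = 500,
            compute_cov: bool = True) -> "MultiStateResults":
        """Maximum-likelihood fit by BFGS.

        ``multistart`` adds that many perturbed initial-value sets (baseline
        intensities jittered by up to +/-50%); the best final likelihood is
        retained. Standard errors come from the inverse observed information
        (central-difference Hessian of the total negative log-likelihood).
        """
        non_identifiable = [
            t for k, t in enumerate(self.structure.transitions)
            if self._crude_counts[k] == 0]
        best = None
        for x0 in self._starts(start, multistart, seed):
            res = scipy.optimize.minimize(
                self._objective, x0, method="BFGS",
                options={"gtol": gtol, "maxiter": maxiter})
            if best is None or res.fun < best.fun:
                best = res
        xhat = best.x
        ll = self.loglik(xhat)
        cov = None
        cov_ok = False
        if compute_cov:
            H = numerical_hessian(lambda v: -self.loglik(v), xhat)
            cov, cov_ok = _invert_information(H)
        return MultiStateResults(
            model=self, params=xhat, cov=cov if cov_ok else None,
            loglik=ll, converged=bool(best.success),
            n_obs=len(self._iv_dt),
            non_identifiable=tuple(non_identifiable))


@dataclass
class MultiStateResults:
    """Fitted multi-state model: estimates, covariance, hazard ratios.

    ``params`` stacks log baseline intensities (one per allowed transition)
    then per-transition covariate coefficients, in
    ``model.param_names`` order.
    """

    model: MultiStateModel
    params: np.ndarray
    cov: np.ndarray | None
    loglik: float
    converged: bool
    n_obs: int
    non_identifiable: tuple = ()

    @property
    def se(self) -> np.ndarray:
        if self.cov is None:
            return np.full(len(self.params), np.nan)
        return np.sqrt(np.diag(self.cov))

    def theta_dict(self) -> dict:
        return {t: float(self.params[k])
                for k, t in enumerate(self.model.structure.transitions)}

    def beta_dict(self) -> dict:
        st = self.model.structure
        out: dict = {t: {} for t in st.transitions}
        m = self.model.n_theta
        for t in st.transitions:
            for c in st.covariates[t]:
                out[t][c] = float(self.params[m])
                m += 1
        return out

    def hazard_ratios(self, alpha: float = 0.05) -> pd.DataFrame:
        """Per-transition covariate hazard ratios with Wald CIs on the log scale."""
        from scipy.stats import norm

        zcrit = norm.ppf(1 - alpha / 2)
        st = self.model.structure
        se = self.se
        rows = []
        m = self.model.n_theta
        for t in st.transitions:
            for c in st.covariates[t]:
                b, s = self.params[m], se[m]
                rows.append({
                    "transition": f"{t[0]}->{t[1]}", "covariate": c,
                    "hr": float(np.exp(b)),
                    "lo95": float(np.exp(b - zcrit * s)),
                    "hi95": float(np.exp(b + zcrit * s)),
                    "log_hr": float(b), "se": float(s),
                })
                m += 1
        return pd.DataFrame(rows)

    def intensity_matrix(self, z: dict | None = None) -> np.ndarray:
        return build_q(self.model.structure, self.theta_dict(),
                       self.beta_dict(), z or {})

    def transition_probability(self, t: float, z: dict | None = None) -> np.ndarray:
        return transition_probability(self.intensity_matrix(z), t)

    def state_probability_after(self, t: float, z: dict | None = None,
                                from_state: str = "CN") -> pd.Series:
        """State-occupancy probabilities ``t`` years after being in ``from_state``."""
        if not self.converged:
            raise RuntimeError("model did not converge; probabilities unavailable")
        P = self.transition_probability(t, z)
        row = P[self.model.structure.index(from_state)]
        return pd.Series(row, index=list(self.model.structure.states))

    def summary(self) -> str:
        st = self.model.structure
        lines = [
            "Multi-state Markov model (panel likelihood)",
            f"  states: {', '.join(st.states)}",
            f"  subjects: {self.model.n_subjects}   intervals: {self.n_obs}",
            f"  log-likelihood: {self.loglik:.3f}   converged: {self.converged}",
        ]
        if self.non_identifiable:
            lines.append(f"  WARNING no observed transitions for: {self.non_identifiable}")
        lines.append("  baseline intensities (per year):")
        se = self.se
        for k, t in enumerate(st.transitions):
            q = np.exp(self.params[k])
            lines.append(f"    {t[0]:>8} -> {t[1]:<8} q0 = {q:.5f}  (log {self.params[k]:+.3f} "
                         f"+/- {se[k]:.3f})")
        hr = self.hazard_ratios()
        if len(hr):
            lines.append("  hazard ratios:")
            for _, row in hr.iterrows():
                lines.append(
                    f"    {row['transition']:>20}  {row['covariate']:<12} "
                    f"HR {row['hr']:.3f} (95% CI {row['lo95']:.3f}-{row['hi95']:.3f})")
        return "\n".join(lines)
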