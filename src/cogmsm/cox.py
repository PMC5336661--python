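"""Cox proportional hazards on the age time scale with delayed entry.

Subjects enter the risk set at their baseline age (left truncation) and leave
at their event or censoring age, so the partial likelihood at an event age
``a`` compares the case against everyone with ``entry_age < a <= exit_age``.
Tied event ages — common when diagnosis ages are wave ages — are handled with
the Efron correction. Estimation is Newton–Raphson on the analytic gradient
and Hessian; predictive discrimination is summarised by Harrell's concordance
index restricted to pairs usable under delayed entry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm


class CoxError(ValueError):
    pass


class ConvergenceWarning(UserWarning):
    pass


def _partial_loglik_parts(beta, entry, exit_, event, X):
    """Efron partial log-likelihood, gradient and Hessian."""
    eta = X @ beta
    w = np.exp(eta)
    p = X.shape[1]
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    for a in np.unique(exit_[event]):
        tied = event & (exit_ == a)
        at_risk = (entry < a) & (exit_ >= a)
        m = int(tied.sum())
        Xd, wd = X[tied], w[tied]
        Xr, wr = X[at_risk], w[at_risk]
        S0r = wr.sum()
        S1r = Xr.T @ wr
        S2r = (Xr * wr[:, None]).T @ Xr
        S0d = wd.sum()
        S1d = Xd.T @ wd
        S2d = (Xd * wd[:, None]).T @ Xd
        ll += eta[tied].sum()
        grad += Xd.sum(axis=0)
        for l in range(m):
            f = l / m
            s0 = S0r - f * S0d
            s1 = S1r - f * S1d
            s2 = S2r - f * S2d
            ll -= np.log(s0)
            grad -= s1 / s0
            hess -= s2 / s0 - np.outer(s1, s1) / s0**2
    return ll, grad, hess


@dataclass
class SurvivalData:
    entry_age: np.ndarray
    exit_age: np.ndarray
    event: np.ndarray
    X: np.ndarray
    names: tuple[str, ...]


class CoxAgeScaleModel:
    """Left-truncated Cox model built from a records table.

    Parameters
    ----------
    records : pandas.DataFrame
        Columns ``entry_age``, ``exit_age``, ``event`` plus one column per
        covariate named in ``covariates``.
    covariates : sequence of str
        Covariate columns to include (e.g. the risk index and the genetic
        score jointly, matching the primary analysis).
    """

    def __init__(self, records: pd.DataFrame, covariates) -> None:
        covariates = list(covariates)
        entry = records["entry_age"].to_numpy(dtype=float)
        exit_ = records["exit_age"].to_numpy(dtype=float)
        event = records["event"].to_numpy(dtype=bool)
        if np.any(exit_ <= entry):
            raise CoxError("every record needs exit_age > entry_age")
        if event.sum() == 0:
            raise CoxError("no events in the data")
        X = records[covariates].to_numpy(dtype=float)
        keep = []
        for j, c in enumerate(covariates):
            if np.ptp(X[:, j]) == 0:
                warnings.warn(f"covariate {c!r} is constant; excluded (beta=0)",
                              ConvergenceWarning, stacklevel=2)
            else:
                keep.append(j)
        self.dropped = tuple(c for j, c in enumerate(covariates) if j not in keep)
        self.data = SurvivalData(entry, exit_, event, X[:, keep],
                                 tuple(covariates[j] for j in keep))

    def loglik(self, beta) -> float:
        d = self.data
        ll, _, _ = _partial_loglik_parts(np.asarray(beta, dtype=float),
                                         d.entry_age, d.exit_age, d.event, d.X)
        return float(ll)

    def fit(self, tol: float = 1e-8, maxiter: int = 50) -> "CoxResults":
        """Newton–Raphson to gradient norm < ``tol`` with step halving.

        A coefficient running away (monotone likelihood / perfect separation)
        triggers a diverging-beta warning and a ``converged=False`` result.
        """
        d = self.data
        p = d.X.shape[1]
        beta = np.zeros(p)
        converged = False
        ll, grad, hess = _partial_loglik_parts(beta, d.entry_age, d.exit_age,
                                               d.event, d.X)
        for _ in range(maxiter):
            if np.linalg.norm(grad) < tol:
                converged = True
                break
            try:
                step = np.linalg.solve(-hess, grad)
            except np.linalg.LinAlgError:
                break
            new_beta = beta + step
            new = _partial_loglik_parts(new_beta, d.entry_age, d.exit_age,
                                        d.event, d.X)
            halvings = 0
            while new[0] < ll and halvings < 20:
                step /= 2.0
                new_beta = beta + step
                new = _partial_loglik_parts(new_beta, d.entry_age, d.exit_age,
                                            d.event, d.X)
                halvings += 1
            beta = new_beta
            ll, grad, hess = new
        # a huge coefficient means the partial likelihood is monotone: the
        # gradient flattens out and "converges" while beta runs away
        if np.any(np.abs(beta) > 10):
            warnings.warn("diverging coefficient: monotone partial likelihood "
                          "(perfect separation?)", ConvergenceWarning, stacklevel=2)
            converged = False
        cov = np.linalg.inv(-hess) if p else np.zeros((0, 0))
        return CoxResults(model=self, params=beta, cov=cov, loglik=float(ll),
                          converged=converged)


@dataclass
class CoxResults:
    """Fitted Cox model: log hazard ratios, Wald CIs, concordance."""

    model: CoxAgeScaleModel
    params: np.ndarray
    cov: np.ndarray
    loglik: float
    converged: bool

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def hazard_ratios(self, alpha: float = 0.05) -> pd.DataFrame:
        zcrit = norm.ppf(1 - alpha / 2)
        rows = []
        for j, c in enumerate(self.model.data.names):
            b, s = self.params[j], self.se[j]
            rows.append({"covariate": c, "hr": float(np.exp(b)),
                         "lo95": float(np.exp(b - zcrit * s)),
                         "hi95": float(np.exp(b + zcrit * s)),
                         "log_hr": float(b), "se": float(s)})
        for c in self.model.dropped:
            rows.append({"covariate": c, "hr": 1.0, "lo95": np.nan,
                         "hi95": np.nan, "log_hr": 0.0, "se": np.nan})
        return pd.DataFrame(rows)

    def linear_predictor(self) -> np.ndarray:
        return self.model.data.X @ self.params

    def concordance(self) -> tuple[float, float]:
        """Harrell's C and its SE for the fitted linear predictor."""
        d = self.model.data
        return concordance_index(d.entry_age, d.exit_age, d.event,
                                 self.linear_predictor())

    def summary(self) -> str:
        c, c_se = self.concordance()
        lines = [
            "Cox proportional hazards (age time scale, left truncation, Efron ties)",
            f"  n: {len(self.model.data.event)}   events: {int(self.model.data.event.sum())}",
            f"  partial log-likelihood: {self.loglik:.3f}   converged: {self.converged}",
            f"  c-index: {c:.3f} (SE {c_se:.3f})",
        ]
        for _, row in self.hazard_ratios().iterrows():
            lines.append(f"    {row['covariate']:<12} HR {row['hr']:.3f} "
                         f"(95% CI {row['lo95']:.3f}-{row['hi95']:.3f})")
        return "\n".join(lines)


def concordance_index(entry, exit_, event, score) -> tuple[float, float]:
    """Harrell's C with delayed entry, and a U-statistic SE.

    Usable pairs: an event at age ``a`` versus any subject still under
    observation past ``a`` and already entered before ``a`` (including later
    events). Tied risk scores count 0.5. The SE comes from the asymptotic
    variance of the pair-mean kernel (Noether-style projection), which is the
    standard first-order estimator for a U-statistic.
    """
    entry = np.asarray(entry, float)
    exit_ = np.asarray(exit_, float)
    event = np.asarray(event, bool)
    score = np.asarray(score, float)
    n = len(score)
    conc_i = np.zeros(n)
    pairs_i = np.zeros(n)
    total_conc = 0.0
    total_pairs = 0
    for i in np.flatnonzero(event):
        a = exit_[i]
        comp = (exit_ > a) & (entry < a)
        comp[i] = False
        m = int(comp.sum())
        if m == 0:
            continue
        h = (score[i] > score[comp]) + 0.5 * (score[i] == score[comp])
        wins = float(h.sum())
        conc_i[i] += wins
        pairs_i[i] += m
        conc_i[comp] += h  # each comparator's own kernel value, for the projection
        pairs_i[comp] += 1
        total_conc += wins
        total_pairs += m
    if total_pairs == 0:
        raise CoxError("no usable pairs for the concordance index")
    c = total_conc / total_pairs
    with np.errstate(invalid="ignore", divide="ignore"):
        ci = np.where(pairs_i > 0, conc_i / pairs_i, np.nan)
    ok = pairs_i > 0
    k = int(ok.sum())
    sigma1 = np.nanstd(ci[ok], ddof=1) if k > 1 else 0.0
    se = 2.0 * sigma1 / np.sqrt(k) if k > 1 else np.nan
    return float(c), float(se)
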