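"""ERS-endpoint association models: linear (blood-pressure-like),
logistic (hypertension-like), and Cox with age as the time scale
(mortality-like), all reported per one SD of the (z-scored) ERS.

Age enters the mortality models only through the time scale — using
attained age as the time axis implies delayed entry with left truncation
at the enrollment age — while the linear/logistic endpoints adjust for age
as an ordinary covariate.  Models are unweighted maximum-likelihood fits;
Cox ties are handled by Efron's method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter

__all__ = ["AssociationResult", "fit_endpoint_model", "cox_age_timescale"]


@dataclass
class AssociationResult:
    endpoint: str
    family: str  # linear | logistic | cox
    estimate: float  # beta | log OR | log HR per 1 SD of ERS
    ci: tuple[float, float]  # on the estimate (log) scale
    covariates: list[str]

    @property
    def exp_estimate(self) -> float:
        return float(np.exp(self.estimate))

    @property
    def exp_ci(self) -> tuple[float, float]:
        return (float(np.exp(self.ci[0])), float(np.exp(self.ci[1])))

    def summary_row(self) -> dict:
        if self.family == "linear":
            return {
                "endpoint": self.endpoint,
                "family": self.family,
                "estimate": self.estimate,
                "ci_low": self.ci[0],
                "ci_high": self.ci[1],
            }
        return {
            "endpoint": self.endpoint,
            "family": self.family,
            "estimate": self.exp_estimate,
            "ci_low": self.exp_ci[0],
            "ci_high": self.exp_ci[1],
        }


def fit_endpoint_model(
    ers_z: np.ndarray,
    endpoint: np.ndarray,
    Z_design: np.ndarray | None,
    family: str,
    endpoint_name: str = "endpoint",
    z_names: list[str] | None = None,
) -> AssociationResult:
    """Maximum-likelihood linear or logistic fit with Wald 95% CI."""
    ers_z = np.asarray(ers_z, float)
    endpoint = np.asarray(endpoint, float)
    n = len(ers_z)
    cols = [np.ones(n), ers_z]
    if Z_design is not None and np.size(Z_design):
        cols.append(np.asarray(Z_design, float))
    X = np.column_stack(cols)

    if family == "linear":
        res = sm.OLS(endpoint, X).fit()
    elif family == "logistic":
        uniq = np.unique(endpoint)
        if not np.all(np.isin(uniq, [0.0, 1.0])):
            raise ValueError("logistic endpoint must be 0/1")
        try:
            res = sm.Logit(endpoint.astype(int), X).fit(disp=0, maxiter=200)
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"logistic fit failed (separation?): {exc}") from exc
        if not np.all(np.isfinite(res.bse)):
            raise RuntimeError("logistic fit unstable: non-finite SEs (separation?)")
    else:
        raise ValueError(f"unknown family: {family!r}")

    est = float(res.params[1])
    se = float(res.bse[1])
    return AssociationResult(
        endpoint=endpoint_name,
        family=family,
        estimate=est,
        ci=(est - 1.96 * se, est + 1.96 * se),
        covariates=list(z_names or []),
    )


def cox_age_timescale(
    ers_z: np.ndarray,
    entry_age: np.ndarray,
    exit_age: np.ndarray,
    event: np.ndarray,
    Z_design: np.ndarray | None = None,
    endpoint_name: str = "mortality",
    z_names: list[str] | None = None,
) -> AssociationResult:
    """Cox partial likelihood on the age scale with delayed entry.

    A subject is at risk at age t iff entry_age < t <= exit_age, so risk
    sets respect left truncation by construction.  Efron tie handling.
    """
    entry_age = np.asarray(entry_age, float)
    exit_age = np.asarray(exit_age, float)
    event = np.asarray(event).astype(int)
    if (entry_age >= exit_age).any():
        raise ValueError("entry_age must be strictly below exit_age")
    if event.sum() == 0:
        raise ValueError("no events")

    df = pd.DataFrame({"entry": entry_age, "exit": exit_age, "event": event, "ers": ers_z})
    covs = []
    if Z_design is not None and np.size(Z_design):
        Z_design = np.asarray(Z_design, float)
        covs = list(z_names or [f"z{j}" for j in range(Z_design.shape[1])])
        for j, nm in enumerate(covs):
            df[nm] = Z_design[:, j]

    cph = CoxPHFitter()
    cph.fit(
        df,
        duration_col="exit",
        event_col="event",
        entry_col="entry",
        show_progress=False,
        fit_options={"precision": 1e-12},  # tight Newton stop for oracle-level accuracy
    )
    est = float(cph.params_["ers"])
    se = float(cph.standard_errors_["ers"])
    return AssociationResult(
        endpoint=endpoint_name,
        family="cox",
        estimate=est,
        ci=(est - 1.96 * se, est + 1.96 * se),
        covariates=covs,
    )
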