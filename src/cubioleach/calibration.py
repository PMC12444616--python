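"""Rate-constant calibration against column outflow time series.

`ColumnLeachModel` wraps an observed outflow series (Cu2+, Fe3+, Fe2+ in
mol/L versus time) together with the forward column model; ``fit()`` estimates
the dissolution rate constant k by joint nonlinear least squares over the
three species with equal weight in concentration units, and ``score()``
evaluates goodness of fit at a fixed k (the no-fitting mode in which the
forward model is judged against data with parameters set a priori).

The search runs on log k, which keeps the optimizer scale-free and enforces
k > 0; the confidence half-width comes from the Gauss-Newton covariance at
the optimum.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace as dc_replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize

from .column import InflowProgram, simulate_column
from .core import ChemKinetics, ColumnGeometry, ColumnSolution

__all__ = ["r_squared", "ColumnLeachModel", "ColumnFitResult", "fit_rate_constant"]

_SPECIES_COLS = {
    "cu": "cu_out_mol_L",
    "fe3": "fe3_out_mol_L",
    "fe2": "fe2_out_mol_L",
}


def r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot; may be negative.

    Undefined (raises) for a constant observed series.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("observed and predicted must be 1-d of equal length")
    if obs.size < 2:
        raise ValueError("need at least 2 points")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R^2 undefined for a constant observed series")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


@dataclass
class ColumnFitResult:
    """Estimates and diagnostics from a rate-constant fit.

    Attributes
    ----------
    params : dict
        Fitted parameters, here ``{"k": ...}`` (L/(mol min)).
    conf_half_width : dict
        95% confidence half-widths from the Gauss-Newton covariance.
    rsquared : dict
        Per-species R^2 of the fitted forward model.
    residuals : pandas.DataFrame
        Observed-minus-predicted per species at the observation times.
    """

    params: dict
    conf_half_width: dict
    rsquared: dict
    residuals: pd.DataFrame
    cost_trace: list
    nfev: int
    success: bool
    message: str
    model: "ColumnLeachModel"

    @property
    def k(self) -> float:
        return self.params["k"]

    def summary(self) -> str:
        buf = io.StringIO()
        buf.write("Column leaching rate-constant fit\n")
        buf.write("=" * 45 + "\n")
        buf.write(f"observations: {len(self.residuals)} times x "
                  f"{len(_SPECIES_COLS)} species\n")
        buf.write(f"flow rate:    {self.model.q_ml_min} mL/min\n")
        buf.write(f"converged:    {self.success} ({self.nfev} evaluations)\n\n")
        hw = self.conf_half_width["k"]
        buf.write(f"k  = {self.k:.5g} +/- {hw:.2g} L/(mol min)  [95% CI]\n\n")
        for sp, r2 in self.rsquared.items():
            buf.write(f"R^2 ({sp:>3}) = {r2:8.4f}\n")
        return buf.getvalue()


class ColumnLeachModel:
    """Forward column model bound to an observed outflow series.

    Parameters
    ----------
    data : pandas.DataFrame
        Must have ``time_min`` plus ``cu_out_mol_L``, ``fe3_out_mol_L``,
        ``fe2_out_mol_L`` columns.
    geom, inflow, q_ml_min
        The known run conditions under which the data were collected.
    dt_min : float
        Forward-model integration step.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        geom: ColumnGeometry,
        inflow: InflowProgram,
        q_ml_min: float,
        dt_min: float = 0.1,
        initial: Optional[ColumnSolution] = None,
    ) -> None:
        missing = {"time_min", *_SPECIES_COLS.values()} - set(data.columns)
        if missing:
            raise ValueError(f"data is missing columns {sorted(missing)}")
        if len(data) <= 5:
            raise ValueError("need more than 5 time points to fit")
        self.data = data.sort_values("time_min").reset_index(drop=True)
        self.geom = geom
        self.inflow = inflow
        self.q_ml_min = q_ml_min
        self.dt_min = dt_min
        self.initial = initial
        self._times = self.data["time_min"].to_numpy(dtype=float)
        self._obs = np.concatenate(
            [self.data[col].to_numpy(dtype=float) for col in _SPECIES_COLS.values()]
        )

    @classmethod
    def from_csv(cls, path, geom, inflow, q_ml_min, **kwargs) -> "ColumnLeachModel":
        return cls(pd.read_csv(path), geom, inflow, q_ml_min, **kwargs)

    def predict(self, k: float) -> np.ndarray:
        """Forward-model outflow, stacked (cu, fe3, fe2), at the observed times."""
        kin = ChemKinetics(k_l_per_mol_min=k)
        run = simulate_column(
            self.geom,
            kin,
            self.inflow,
            self.q_ml_min,
            duration_min=float(self._times[-1]),
            dt_min=self.dt_min,
            initial=self.initial,
        )
        t = run.times_min
        return np.concatenate(
            [
                np.interp(self._times, t, run.cu2_out),
                np.interp(self._times, t, run.fe3_out),
                np.interp(self._times, t, run.fe2_out),
            ]
        )

    def _rsquared(self, pred: np.ndarray) -> dict:
        n = len(self._times)
        out = {}
        for i, sp in enumerate(_SPECIES_COLS):
            out[sp] = r_squared(
                self._obs[i * n : (i + 1) * n], pred[i * n : (i + 1) * n]
            )
        return out

    def score(self, k: float) -> dict:
        """Per-species R^2 of the forward model at a fixed rate constant."""
        return self._rsquared(self.predict(k))

    def fit(self, k0: float = 0.01, max_nfev: int = 200) -> ColumnFitResult:
        """Least-squares estimate of k (log-parameterized, k > 0)."""
        if k0 <= 0:
            raise ValueError("initial guess must be > 0")
        trace: list[float] = []

        def resid(theta: np.ndarray) -> np.ndarray:
            r = self.predict(float(np.exp(theta[0]))) - self._obs
            trace.append(0.5 * float(r @ r))
            return r

        sol = optimize.least_squares(
            resid, x0=[np.log(k0)], method="lm", max_nfev=max_nfev
        )
        if not sol.success:
            raise RuntimeError(
                f"rate-constant fit did not converge: {sol.message}; "
                f"cost trace {trace[-5:]}"
            )
        k_hat = float(np.exp(sol.x[0]))
        pred = self.predict(k_hat)

        # Gauss-Newton covariance on log k -> delta-method half-width on k
        n_obs = self._obs.size
        dof = max(n_obs - 1, 1)
        s2 = float(sol.fun @ sol.fun) / dof
        jtj = float(np.asarray(sol.jac.T @ sol.jac).item())
        var_logk = s2 / jtj if jtj > 0 else float("inf")
        half_width = 1.96 * k_hat * float(np.sqrt(var_logk))

        n = len(self._times)
        resid_df = pd.DataFrame({"time_min": self._times})
        for i, (sp, col) in enumerate(_SPECIES_COLS.items()):
            resid_df[f"resid_{sp}"] = (
                self._obs[i * n : (i + 1) * n] - pred[i * n : (i + 1) * n]
            )
        return ColumnFitResult(
            params={"k": k_hat},
            conf_half_width={"k": half_width},
            rsquared=self._rsquared(pred),
            residuals=resid_df,
            cost_trace=trace,
            nfev=sol.nfev,
            success=bool(sol.success),
            message=str(sol.message),
            model=self,
        )


def fit_rate_constant(
    series: pd.DataFrame,
    geom: ColumnGeometry,
    inflow: InflowProgram,
    q_ml_min: float,
    init_guess: float = 0.01,
    dt_min: float = 0.1,
) -> ColumnFitResult:
    """Convenience wrapper: build a :class:`ColumnLeachModel` and fit k."""
    return ColumnLeachModel(series, geom, inflow, q_ml_min, dt_min=dt_min).fit(
        k0=init_guess
    )
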