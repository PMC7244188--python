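"""Hill dose-response fitting, gas-to-aqueous calibration, fractional block.

The fractional block of the EPSC at anesthetic concentration X follows the
Hill form

    Y(X) = Max - Max / (1 + (X / EC50)^Hill)

which is 0 at X = 0 and exactly Max/2 at X = EC50 for any Hill coefficient.
Aqueous concentration is linearly proportional to the gaseous partial
concentration, so the calibration is a through-origin straight line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize
from sklearn.base import BaseEstimator


class FitFailureError(RuntimeError):
    """Nonlinear fit failed to converge from every start."""


@dataclass
class HillFit:
    EC50: float
    Max: float
    hill: float
    residual_ss: float

    def __post_init__(self) -> None:
        if self.EC50 <= 0 or not 0 < self.Max <= 100 or self.hill <= 0:
            raise ValueError("invalid Hill parameters")


def hill_eval(X, fit: HillFit):
    """Percent block at concentration(s) X (mM)."""
    X = np.asarray(X, float)
    val = fit.Max - fit.Max / (1.0 + (X / fit.EC50) ** fit.hill)
    return float(val) if val.ndim == 0 else val


class HillCurve(BaseEstimator):
    """Nonlinear least-squares Hill fit with a deterministic multi-start grid.

    Starts: EC50 in {0.1, 0.3, 1, 3} mM x hill in {0.5, 1, 2}, Max initialised
    at the maximum observed block. Bounds: EC50 > 0, 0 < Max <= 100, hill > 0.

    Attributes: ``ec50_`` (mM), ``max_`` (%), ``hill_``, ``residual_ss_``.
    """

    _EC50_STARTS = (0.1, 0.3, 1.0, 3.0)
    _HILL_STARTS = (0.5, 1.0, 2.0)

    @staticmethod
    def _model(X, ec50, mx, hill):
        return mx - mx / (1.0 + (X / ec50) ** hill)

    def fit(self, concs: np.ndarray, blocks: np.ndarray) -> "HillCurve":
        X = np.asarray(concs, float)
        y = np.asarray(blocks, float)
        if np.unique(X).size < 3:
            raise ValueError("Hill fit needs >= 3 distinct concentrations")
        if np.allclose(y, 0.0):
            raise FitFailureError("all blocks are zero: Max unidentifiable")
        max0 = float(np.clip(np.max(y), 1.0, 100.0))
        best = None
        diagnostics = []
        for ec50_0 in self._EC50_STARTS:
            for hill_0 in self._HILL_STARTS:
                try:
                    popt, _ = scipy.optimize.curve_fit(
                        self._model, X, y, p0=(ec50_0, max0, hill_0),
                        bounds=([1e-9, 1e-9, 1e-9], [np.inf, 100.0, np.inf]),
                        maxfev=20000,
                    )
                except (RuntimeError, ValueError) as exc:  # non-convergence
                    diagnostics.append(f"start ({ec50_0}, {hill_0}): {exc}")
                    continue
                ss = float(np.sum((y - self._model(X, *popt)) ** 2))
                if best is None or ss < best[0]:
                    best = (ss, popt)
        if best is None:
            raise FitFailureError(
                "Hill fit did not converge from any start:\n" + "\n".join(diagnostics)
            )
        ss, (ec50, mx, hill) = best
        self.ec50_, self.max_, self.hill_ = float(ec50), float(mx), float(hill)
        self.residual_ss_ = ss
        return self

    def predict(self, X):
        return self._model(np.asarray(X, float), self.ec50_, self.max_, self.hill_)

    def to_hill_fit(self) -> HillFit:
        return HillFit(self.ec50_, self.max_, self.hill_, self.residual_ss_)


def fit_hill(concs, blocks) -> HillFit:
    """Functional wrapper over :class:`HillCurve`."""
    return HillCurve().fit(concs, blocks).to_hill_fit()


@dataclass
class CalibrationFit:
    """Gas (%) to aqueous (mM) calibration line through the origin."""

    slope: float  # mM per gaseous %
    through_origin: bool = True

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")

    def convert(self, gas_pct):
        """Aqueous concentration (mM) for gaseous concentration(s) (%)."""
        return np.asarray(gas_pct, float) * self.slope if np.ndim(gas_pct) else gas_pct * self.slope


class LinearCalibration(BaseEstimator):
    """Through-origin least-squares calibration: aqueous_mM = slope * gas_pct."""

    def fit(self, gas_pct: np.ndarray, aqueous_mM: np.ndarray) -> "LinearCalibration":
        x = np.atleast_1d(np.asarray(gas_pct, float))
        y = np.atleast_1d(np.asarray(aqueous_mM, float))
        if x.size < 1:
            raise ValueError("calibration needs >= 1 point")
        self.slope_ = float(np.sum(x * y) / np.sum(x * x))
        self.residual_ss_ = float(np.sum((y - self.slope_ * x) ** 2))
        return self

    def predict(self, gas_pct):
        return np.asarray(gas_pct, float) * self.slope_


def fit_calibration(gas_pct, aqueous_mM) -> CalibrationFit:
    est = LinearCalibration().fit(gas_pct, aqueous_mM)
    return CalibrationFit(slope=est.slope_)


def fractional_block(ctrl_amp: float, drug_amp: float) -> float:
    """Percent reduction of amplitude by the drug: 100*(1 - drug/ctrl)."""
    if ctrl_amp <= 0:
        raise ValueError("control amplitude must be positive")
    return 100.0 * (1.0 - drug_amp / ctrl_amp)


def group_mean_blocks(df, conc_col: str = "conc_mM", block_col: str = "block_pct"):
    """Average per-cell blocks within each concentration (the quantity the
    dose-response curve is fit to). Returns (concs, mean_blocks) arrays.

    Note: the mean of per-cell fractional blocks generally differs from the
    fractional block of per-condition mean amplitudes; this package fits the
    former and exposes both routes (see tests).
    """
    g = df.groupby(conc_col)[block_col].mean()
    return g.index.to_numpy(float), g.to_numpy(float)
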