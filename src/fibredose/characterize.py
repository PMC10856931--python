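"""Laboratory figures of merit for counting-mode SiPM dosimeters.

A detector is characterised from an X-ray-tube current scan: at each tube
current the gross counting rate is recorded, followed by a paired dark run
(to cancel dark counts, scintillator afterglow and memory effects by
per-point subtraction).  Three figures of merit are extracted:

* **MDR** (minimum detectable rate): the rate equal to three times the
  Poisson fluctuation of the dark counts in a window,
  ``MDR = 3 sqrt(DCR / dt)``.
* **Linearity range**: the largest low-current prefix of the scan for which
  a weighted straight-line fit of PCR vs current keeps reduced chi^2 at or
  below a gate (2.7, ~90% CL at one residual degree of freedom); pile-up
  bends the response at high rates and trips the gate.
* **Sensitivity**: the slope m of the linear regime, PCR = m * I.

The linearity stage follows the statsmodels pattern: build a
:class:`LinearityModel` from data, call :meth:`~LinearityModel.fit`, read the
estimates off the returned :class:`LinearityResults`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import SiPMSpec
from .exceptions import DataError, InsufficientDataError

__all__ = [
    "CurrentScan",
    "DetectorFigures",
    "LinearityModel",
    "LinearityResults",
    "figures_of_merit",
    "fit_linearity",
    "mdr",
    "subtract_dcr",
]


@dataclass
class CurrentScan:
    """One irradiation series: per-current gross counts with paired dark runs.

    ``window_s`` is the per-point counting window; currents must be strictly
    increasing and all counts non-negative.
    """

    current_ma: np.ndarray
    gross_counts: np.ndarray
    dark_counts: np.ndarray
    window_s: np.ndarray
    threshold: float = 0.5
    detector: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        self.current_ma = np.asarray(self.current_ma, dtype=float)
        self.gross_counts = np.asarray(self.gross_counts, dtype=np.int64)
        self.dark_counts = np.asarray(self.dark_counts, dtype=np.int64)
        self.window_s = np.broadcast_to(
            np.asarray(self.window_s, dtype=float), self.current_ma.shape
        ).copy()
        n = self.current_ma.size
        if not (self.gross_counts.size == self.dark_counts.size == n):
            raise DataError("current, gross and dark columns must have equal length")
        if np.any(np.diff(self.current_ma) <= 0):
            raise DataError("tube currents must be strictly increasing")
        for name, col in (("gross_counts", self.gross_counts),
                          ("dark_counts", self.dark_counts)):
            bad = np.flatnonzero(col < 0)
            if bad.size:
                raise DataError(f"negative {name} at row {bad[0]}")
        if np.any(self.window_s <= 0):
            raise DataError("counting windows must be positive")

    def __len__(self) -> int:
        return self.current_ma.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "current_mA": self.current_ma,
                "gross_counts": self.gross_counts,
                "dark_counts": self.dark_counts,
                "window_s": self.window_s,
            }
        )

    @property
    def dark_rate_hz(self) -> float:
        """Pooled dark count rate estimate from the paired dark runs, Hz."""
        return float(self.dark_counts.sum() / self.window_s.sum())

    @property
    def dark_rate_err_hz(self) -> float:
        return float(math.sqrt(self.dark_counts.sum()) / self.window_s.sum())


def subtract_dcr(scan: CurrentScan) -> pd.DataFrame:
    """Per-point dark subtraction: PCR_i = (gross_i - dark_i) / dt, in kHz.

    The Poisson uncertainty is ``sqrt(gross + dark) / dt``.  Negative PCR
    values (downward dark fluctuations at zero signal) are kept and flagged
    in the ``negative`` column rather than clipped.
    """
    pcr_hz = (scan.gross_counts - scan.dark_counts) / scan.window_s
    sigma_hz = np.sqrt(scan.gross_counts + scan.dark_counts) / scan.window_s
    if np.any(sigma_hz <= 0):
        # both counts zero: no information at that point
        raise DataError("point with zero gross and dark counts has undefined error")
    return pd.DataFrame(
        {
            "current_mA": scan.current_ma,
            "pcr_khz": pcr_hz / 1e3,
            "sigma_khz": sigma_hz / 1e3,
            "negative": pcr_hz < 0,
        }
    )


def mdr(dcr: float, window: float) -> float:
    """Minimum detectable rate in Hz: 3 sqrt(DCR / dt).

    The smallest background-subtracted rate exceeding three Poisson standard
    deviations of the dark counts accumulated in a window ``dt``.
    """
    if dcr < 0:
        raise DataError("dark count rate must be >= 0")
    if window <= 0:
        raise DataError("counting window must be positive")
    return 3.0 * math.sqrt(dcr / window)


class LinearityModel:
    """Weighted straight-line model PCR = m * I + q over a growing prefix.

    Points are added in order of increasing current; the fit retained is the
    largest prefix whose reduced chi^2 stays at or below the gate, after
    which the response is declared nonlinear (pile-up regime).
    """

    def __init__(self, current_ma, pcr_khz, sigma_khz):
        self.current_ma = np.asarray(current_ma, dtype=float)
        self.pcr_khz = np.asarray(pcr_khz, dtype=float)
        self.sigma_khz = np.asarray(sigma_khz, dtype=float)
        if not (self.current_ma.size == self.pcr_khz.size == self.sigma_khz.size):
            raise DataError("current, PCR and sigma must have equal length")
        if np.any(np.diff(self.current_ma) <= 0):
            raise DataError("currents must be strictly increasing")
        if np.any(self.sigma_khz <= 0):
            raise DataError("PCR uncertainties must be positive")

    @classmethod
    def from_scan(cls, scan: CurrentScan) -> "LinearityModel":
        df = subtract_dcr(scan)
        return cls(df["current_mA"], df["pcr_khz"], df["sigma_khz"])

    @staticmethod
    def _wls(x, y, w):
        """Weighted LS of y = q + m x; returns (q, m), covariance, chi2."""
        X = np.column_stack([np.ones_like(x), x])
        xtw = X.T * w
        cov = np.linalg.inv(xtw @ X)
        beta = cov @ (xtw @ y)
        resid = y - X @ beta
        chi2 = float(np.sum(w * resid**2))
        return beta, cov, chi2

    def fit(self, chi2_max: float = 2.7, min_points: int = 3) -> "LinearityResults":
        n = self.current_ma.size
        if n < min_points:
            raise InsufficientDataError(
                f"linearity fit needs at least {min_points} points, got {n}"
            )
        w = 1.0 / self.sigma_khz**2
        # largest prefix whose fit passes the gate: scanning every prefix
        # (rather than stopping at the first failure) keeps a single noisy
        # short prefix from truncating an otherwise linear range
        best = None
        for m in range(min_points, n + 1):
            beta, cov, chi2 = self._wls(
                self.current_ma[:m], self.pcr_khz[:m], w[:m]
            )
            chi2_red = chi2 / (m - 2)
            if chi2_red <= chi2_max:
                best = (m, beta, cov, chi2_red)
        if best is None:
            return LinearityResults(self, n_included=0, params=np.full(2, np.nan),
                                    cov_params=np.full((2, 2), np.nan),
                                    chi2_reduced=np.nan, chi2_max=chi2_max)
        m, beta, cov, chi2_red = best
        return LinearityResults(self, n_included=m, params=beta, cov_params=cov,
                                chi2_reduced=chi2_red, chi2_max=chi2_max)


@dataclass
class LinearityResults:
    """Result of the prefix-gated weighted linear fit.

    ``params`` holds (intercept q, slope m) in (kHz, kHz/mA); ``bse`` their
    standard errors from the weighted-least-squares covariance.  An empty
    included set (``ok`` False) means no linear range was found even for the
    smallest prefix.
    """

    model: LinearityModel
    n_included: int
    params: np.ndarray
    cov_params: np.ndarray
    chi2_reduced: float
    chi2_max: float

    @property
    def ok(self) -> bool:
        return self.n_included > 0

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    @property
    def intercept_khz(self) -> float:
        return float(self.params[0])

    @property
    def slope_khz_ma(self) -> float:
        return float(self.params[1])

    @property
    def included_mask(self) -> np.ndarray:
        mask = np.zeros(self.model.current_ma.size, dtype=bool)
        mask[: self.n_included] = True
        return mask

    @property
    def dof(self) -> int:
        return max(self.n_included - 2, 0)

    @property
    def upper_limit_current_ma(self) -> float:
        if not self.ok:
            return float("nan")
        return float(self.model.current_ma[self.n_included - 1])

    @property
    def upper_limit_pcr_khz(self) -> float:
        """PCR at the last included current: the top of the linear range."""
        if not self.ok:
            return float("nan")
        return float(self.model.pcr_khz[self.n_included - 1])

    def predict(self, current_ma):
        x = np.asarray(current_ma, dtype=float)
        return self.params[0] + self.params[1] * x

    def summary(self) -> str:
        if not self.ok:
            return (
                "Linearity fit: no linear range "
                f"(reduced chi2 > {self.chi2_max} for every prefix)"
            )
        se = self.bse
        lines = [
            "Weighted linear fit PCR = q + m*I (prefix-gated)",
            f"  points included : {self.n_included}/{self.model.current_ma.size}",
            f"  slope m         : {self.params[1]:.6g} +/- {se[1]:.3g} kHz/mA",
            f"  intercept q     : {self.params[0]:.6g} +/- {se[0]:.3g} kHz",
            f"  reduced chi2    : {self.chi2_reduced:.3f} (gate {self.chi2_max}, "
            f"dof {self.dof})",
            f"  linear up to    : {self.upper_limit_current_ma:.3g} mA "
            f"({self.upper_limit_pcr_khz:.4g} kHz)",
        ]
        return "\n".join(lines)


def fit_linearity(scan_or_df, chi2_max: float = 2.7) -> LinearityResults:
    """Prefix-gated weighted linear fit of a current scan.

    Accepts a :class:`CurrentScan` (dark-subtracted internally) or a frame
    with columns ``current_mA, pcr_khz, sigma_khz``.
    """
    if isinstance(scan_or_df, CurrentScan):
        model = LinearityModel.from_scan(scan_or_df)
    else:
        df = scan_or_df
        model = LinearityModel(df["current_mA"], df["pcr_khz"], df["sigma_khz"])
    return model.fit(chi2_max=chi2_max)


@dataclass
class DetectorFigures:
    """Summary record of one detector characterisation.

    MDR is reported from the scan's measured dark rate (and, when a
    datasheet spec is supplied, from the datasheet DCR for comparison).
    """

    detector: str
    threshold: float
    dcr_measured_khz: float
    dcr_measured_err_khz: float
    mdr_khz: dict
    mdr_err_khz: dict
    mdr_datasheet_khz: dict
    sensitivity_khz_ma: float
    sensitivity_err_khz_ma: float
    linearity: LinearityResults

    def to_dict(self) -> dict:
        return {
            "detector": self.detector,
            "threshold_pe": self.threshold,
            "dcr_measured_khz": self.dcr_measured_khz,
            "dcr_measured_err_khz": self.dcr_measured_err_khz,
            "mdr_khz": {str(k): v for k, v in self.mdr_khz.items()},
            "mdr_err_khz": {str(k): v for k, v in self.mdr_err_khz.items()},
            "mdr_datasheet_khz": {str(k): v for k, v in self.mdr_datasheet_khz.items()},
            "sensitivity_khz_ma": self.sensitivity_khz_ma,
            "sensitivity_err_khz_ma": self.sensitivity_err_khz_ma,
            "linearity": {
                "ok": self.linearity.ok,
                "n_included": self.linearity.n_included,
                "chi2_reduced": None if not self.linearity.ok else self.linearity.chi2_reduced,
                "upper_limit_current_ma": self.linearity.upper_limit_current_ma,
                "upper_limit_pcr_khz": self.linearity.upper_limit_pcr_khz,
                "intercept_khz": self.linearity.intercept_khz,
                "intercept_err_khz": float(self.linearity.bse[0]) if self.linearity.ok else None,
            },
        }


def figures_of_merit(
    scan: CurrentScan,
    spec: SiPMSpec | None = None,
    windows: tuple = (0.1, 0.5),
    chi2_max: float = 2.7,
) -> DetectorFigures:
    """Assemble MDR, sensitivity and linearity limits for one scan.

    MDR uses the mean dark rate measured in the scan's paired dark runs;
    when a datasheet ``spec`` is given the datasheet-DCR MDR is reported
    alongside.  The MDR for a longer window is smaller by sqrt(ratio):
    halving noise by integrating longer.
    """
    dcr_hz = scan.dark_rate_hz
    dcr_err_hz = scan.dark_rate_err_hz
    results = fit_linearity(scan, chi2_max=chi2_max)
    mdr_map, mdr_err_map, mdr_sheet = {}, {}, {}
    for w in windows:
        value = mdr(dcr_hz, w)
        mdr_map[w] = value / 1e3
        # delta method on the pooled dark-rate estimate
        mdr_err_map[w] = (value * dcr_err_hz / (2 * dcr_hz) / 1e3) if dcr_hz > 0 else 0.0
        if spec is not None:
            mdr_sheet[w] = mdr(spec.dcr, w) / 1e3
    if results.ok:
        sens, sens_err = results.slope_khz_ma, float(results.bse[1])
    else:
        warnings.warn("no linear range found; sensitivity undefined", stacklevel=2)
        sens, sens_err = float("nan"), float("nan")
    return DetectorFigures(
        detector=scan.detector or (spec.name if spec else ""),
        threshold=scan.threshold,
        dcr_measured_khz=dcr_hz / 1e3,
        dcr_measured_err_khz=dcr_err_hz / 1e3,
        mdr_khz=mdr_map,
        mdr_err_khz=mdr_err_map,
        mdr_datasheet_khz=mdr_sheet,
        sensitivity_khz_ma=sens,
        sensitivity_err_khz_ma=sens_err,
        linearity=results,
    )
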