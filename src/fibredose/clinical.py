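"""Pre-clinical HDR/LDR analysis pipeline.

Takes photon-counting-rate (PCR) scans recorded around an actual
brachytherapy source in a phantom and assesses the dosimeter against its
design specifications:

1. **Calibration** at the reference geometry (r0 = 2 cm on the transverse
   plane): conversion factor k between predicted dose rate and PCR.
2. **Energy-correction curve**: ratio of measured PCR to k times the TG43
   prediction vs distance, with a weighted linear fit (a linear trend with
   small slope indicates protocol compliance; the scintillator is not
   water-equivalent at low photon energies).
3. **Angular symmetrisation**: measurements at arbitrary (r, theta) are
   mapped onto the transverse plane by dividing out the geometry-factor
   ratio and the anisotropy factor, yielding PCR_sym(r).
4. **Radial profile fit** of h(r) = (a/r^2 + b/r + c) exp(-d r), an
   inverse-square-dominated heuristic with exponential attenuation.
5. **Figures of merit** derived from the fitted profile: statistical
   precision SP(r; dt) = sqrt(N_PCR + N_DCR) / N_PCR, spatial resolution
   dR(r) = 3 sigma_PCR / |h'(r)|, and the distance at which the profile
   crosses the minimum detectable rate.

The radial fit follows the statsmodels pattern: a
:class:`RadialProfileModel` is built from data and :meth:`fit` returns a
:class:`RadialProfileResults` carrying estimates, covariance and the
derived performance quantities.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .catalog import DEFAULT_SPECS, ModeSpec, SpecTable
from .exceptions import (
    CalibrationError,
    ConfigurationError,
    DataError,
    FitError,
    InsufficientDataError,
    InvalidGeometryError,
)
from .tg43 import PolarPoint, SourceSpec, dose_rate, geometry_factor, anisotropy_factor, yz_to_polar

__all__ = [
    "Calibration",
    "CrossingResult",
    "EnergyCorrection",
    "PerformanceReport",
    "RadialProfileModel",
    "RadialProfileResults",
    "ScanSeries",
    "calibrate_at_reference",
    "compliance_report",
    "energy_correction_curve",
    "fit_h",
    "mdr_crossing_distance",
    "spatial_resolution",
    "statistical_precision",
    "symmetrise_pcr",
]


@dataclass
class ScanSeries:
    """Counting-rate measurements at a set of source-sensor geometries.

    ``data`` carries either bench columns ``y_cm, z_cm`` (sensor at lateral
    distance y, source moved along z; sensor axial position 0) or a radial
    column ``r_cm`` (transverse-plane geometry), plus ``pcr_khz``,
    ``sigma_khz`` and ``window_s``.
    """

    data: pd.DataFrame
    threshold: float = 1.5
    detector: str = ""
    source_name: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        cols = set(self.data.columns)
        has_yz = {"y_cm", "z_cm"} <= cols
        has_r = "r_cm" in cols
        if has_yz and has_r:
            raise DataError("series mixes (y, z) and radial geometry conventions")
        if not has_yz and not has_r:
            raise DataError("series needs either y_cm/z_cm or r_cm columns")
        for c in ("pcr_khz", "sigma_khz", "window_s"):
            if c not in cols:
                raise DataError(f"missing column {c!r}")
        if np.any(self.data["sigma_khz"].to_numpy() <= 0):
            raise DataError("PCR uncertainties must be positive")
        if np.any(self.data["window_s"].to_numpy() <= 0):
            raise DataError("counting windows must be positive")
        if has_yz and np.any(self.data["y_cm"].to_numpy() <= 0):
            raise InvalidGeometryError("lateral distances y must be positive")
        if has_r and np.any(self.data["r_cm"].to_numpy() <= 0):
            raise InvalidGeometryError("radial distances must be positive")
        self.mode = "yz" if has_yz else "radial"

    def __len__(self) -> int:
        return len(self.data)

    def polar(self) -> tuple[np.ndarray, np.ndarray]:
        """(r, theta) arrays for every row, converting bench coordinates."""
        if self.mode == "radial":
            r = self.data["r_cm"].to_numpy(dtype=float)
            theta = np.full_like(r, math.pi / 2)
            return r, theta
        pts = [
            yz_to_polar(y, z)
            for y, z in zip(self.data["y_cm"].to_numpy(), self.data["z_cm"].to_numpy())
        ]
        return (np.array([p.r for p in pts]), np.array([p.theta for p in pts]))


@dataclass(frozen=True)
class Calibration:
    """Conversion factor between model dose rate and counting rate."""

    k_khz_per_dose: float
    sigma_k: float
    r_cm: float
    theta_rad: float
    row: int


def calibrate_at_reference(
    series: ScanSeries,
    src: SourceSpec,
    tol_r_cm: float = 0.05,
    tol_theta_deg: float = 2.0,
) -> Calibration:
    """Gauge counts against the dose model at the reference geometry.

    Selects the measurement closest to (r0, theta0) within the positional
    tolerance and returns k = PCR / D(r0, theta0).  Two equidistant
    candidates are ambiguous and raise.
    """
    r, theta = series.polar()
    dr = np.abs(r - src.r0)
    dtheta = np.abs(theta - src.theta0)
    ok = (dr <= tol_r_cm) & (dtheta <= math.radians(tol_theta_deg))
    if not np.any(ok):
        raise CalibrationError(
            f"no measurement within {tol_r_cm} cm / {tol_theta_deg} deg of the "
            f"reference point (r0 = {src.r0} cm)"
        )
    # arc-length metric so radial and angular misses are commensurate
    dist = np.hypot(dr, src.r0 * dtheta)
    dist[~ok] = np.inf
    order = np.argsort(dist)
    if ok.sum() > 1 and math.isclose(dist[order[0]], dist[order[1]], rel_tol=0, abs_tol=1e-12):
        raise CalibrationError("two reference candidates at identical distance; ambiguous")
    i = int(order[0])
    pred = dose_rate(PolarPoint(r[i], theta[i]), src)
    pcr = float(series.data["pcr_khz"].iloc[i])
    sig = float(series.data["sigma_khz"].iloc[i])
    if pred <= 0:
        raise CalibrationError("model dose rate is non-positive at the reference point")
    return Calibration(k_khz_per_dose=pcr / pred, sigma_k=sig / pred,
                       r_cm=float(r[i]), theta_rad=float(theta[i]), row=i)


@dataclass
class EnergyCorrection:
    """Per-point data/model ratios with a weighted linear trend fit."""

    points: pd.DataFrame  # r_cm, ratio, sigma
    slope: float
    slope_err: float
    intercept: float
    intercept_err: float
    chi2_reduced: float


def energy_correction_curve(
    series: ScanSeries, src: SourceSpec, k: Calibration | float
) -> EnergyCorrection:
    """Ratio of measured PCR to the calibrated model prediction vs distance.

    A flat unit ratio means the dosimeter response tracks the water-dose
    model; a linear trend with distance is the signature of the energy
    dependence of a non-water-equivalent scintillator.
    """
    k_val = k.k_khz_per_dose if isinstance(k, Calibration) else float(k)
    r, theta = series.polar()
    pred = np.array([k_val * dose_rate(PolarPoint(ri, ti), src) for ri, ti in zip(r, theta)])
    if np.any(pred <= 0):
        raise DataError("model prediction non-positive at some scan point")
    ratio = series.data["pcr_khz"].to_numpy() / pred
    sigma = series.data["sigma_khz"].to_numpy() / pred
    pts = pd.DataFrame({"r_cm": r, "ratio": ratio, "sigma": sigma}).sort_values("r_cm")
    x = pts["r_cm"].to_numpy()
    y = pts["ratio"].to_numpy()
    w = 1.0 / pts["sigma"].to_numpy() ** 2
    X = np.column_stack([np.ones_like(x), x])
    cov = np.linalg.inv((X.T * w) @ X)
    beta = cov @ ((X.T * w) @ y)
    resid = y - X @ beta
    dof = max(x.size - 2, 1)
    chi2_red = float(np.sum(w * resid**2)) / dof
    return EnergyCorrection(
        points=pts.reset_index(drop=True),
        slope=float(beta[1]), slope_err=float(math.sqrt(cov[1, 1])),
        intercept=float(beta[0]), intercept_err=float(math.sqrt(cov[0, 0])),
        chi2_reduced=chi2_red,
    )


def symmetrise_pcr(
    series: ScanSeries, src: SourceSpec, y_min_cm: float | None = None
) -> ScanSeries:
    """Collapse off-transverse measurements onto the transverse profile.

    PCR_sym(r) = PCR(r, theta) * [G(r, theta0) / G(r, theta)] / F(r, theta):
    the geometry-factor ratio maps the line-source solid angle to the
    transverse plane and the anisotropy factor divides out the capsule
    shadowing, leaving a purely radial profile.  Identity on points already
    at theta0 with F = 1.

    ``y_min_cm`` drops bench rows with y below the cut before symmetrising
    (rows close to the source tunnel are contaminated by fibre-generated
    stem light and pile-up).
    """
    data = series.data
    if y_min_cm is not None:
        if series.mode != "yz":
            warnings.warn("y_min filter ignored for radial-mode series", stacklevel=2)
        else:
            data = data[data["y_cm"] >= y_min_cm].reset_index(drop=True)
            if data.empty:
                raise DataError(f"no rows left after the y >= {y_min_cm} cm cut")
    sub = ScanSeries(data, threshold=series.threshold, detector=series.detector,
                     source_name=series.source_name, seed=series.seed)
    r, theta = sub.polar()
    factor = np.empty_like(r)
    for i, (ri, ti) in enumerate(zip(r, theta)):
        p = PolarPoint(ri, ti)
        g_ratio = geometry_factor(PolarPoint(ri, src.theta0), src.capsule_length) / \
            geometry_factor(p, src.capsule_length)
        f = anisotropy_factor(p, src.anisotropy)
        factor[i] = g_ratio / f
    out = pd.DataFrame(
        {
            "r_cm": r,
            "pcr_khz": data["pcr_khz"].to_numpy() * factor,
            "sigma_khz": data["sigma_khz"].to_numpy() * factor,
            "window_s": data["window_s"].to_numpy(),
        }
    ).sort_values("r_cm").reset_index(drop=True)
    return ScanSeries(out, threshold=series.threshold, detector=series.detector,
                      source_name=series.source_name, seed=series.seed)


# ---------------------------------------------------------------------------
# radial profile model


def _h(r, a, b, c, d):
    return (a / r**2 + b / r + c) * np.exp(-d * r)


def _h_prime(r, a, b, c, d):
    return (-2 * a / r**3 - b / r**2) * np.exp(-d * r) - d * _h(r, a, b, c, d)


class RadialProfileModel:
    """Nonlinear model h(r) = (a/r^2 + b/r + c) exp(-d r) for a PCR profile.

    ``a`` (kHz cm^2) carries the inverse-square geometry, ``b``/``c`` soak
    up scatter build-up, ``d`` (1/cm) the effective attenuation; d is
    bounded non-negative so the profile decays.
    """

    def __init__(self, r_cm, pcr_khz, sigma_khz):
        r = np.asarray(r_cm, dtype=float)
        y = np.asarray(pcr_khz, dtype=float)
        s = np.asarray(sigma_khz, dtype=float)
        order = np.argsort(r)
        self.r = r[order]
        self.pcr = y[order]
        self.sigma = s[order]
        if np.any(self.r <= 0):
            raise InvalidGeometryError("distances must be positive")
        if np.any(self.sigma <= 0):
            raise DataError("uncertainties must be positive")
        if self.r.size < 5:
            raise InsufficientDataError("radial profile fit needs at least 5 points")
        if np.all(self.pcr <= 0):
            raise DataError("profile has no positive rates; nothing to fit")

    @classmethod
    def from_series(cls, series: ScanSeries) -> "RadialProfileModel":
        if series.mode != "radial":
            raise DataError("build the model from a radial series (symmetrise first)")
        d = series.data
        return cls(d["r_cm"], d["pcr_khz"], d["sigma_khz"])

    def _initial_guess(self) -> np.ndarray:
        # inverse-square amplitude from the innermost points, decay from the
        # log-slope of the outermost distinct pair after removing the 1/r^2
        # part; duplicate radii (symmetrised +-z points) are averaged
        a0 = float(np.mean(self.pcr[:2] * self.r[:2] ** 2))
        r_uniq = np.unique(self.r)
        d0 = 0.0
        if r_uniq.size >= 2:
            r1, r2 = r_uniq[-2], r_uniq[-1]
            y1 = float(np.mean(self.pcr[self.r == r1])) * r1**2
            y2 = float(np.mean(self.pcr[self.r == r2])) * r2**2
            if y1 > 0 and y2 > 0:
                d0 = max(0.0, math.log(y1 / y2) / (r2 - r1))
        return np.array([max(a0, 1e-9), 0.0, 0.0, d0])

    def fit(self, p0=None, maxfev: int = 20000) -> "RadialProfileResults":
        p0 = self._initial_guess() if p0 is None else np.asarray(p0, dtype=float)
        bounds = ([-np.inf, -np.inf, -np.inf, 0.0], [np.inf] * 4)
        p0 = np.clip(p0, bounds[0], bounds[1])
        try:
            popt, pcov = optimize.curve_fit(
                _h, self.r, self.pcr, p0=p0, sigma=self.sigma,
                absolute_sigma=True, bounds=bounds, maxfev=maxfev,
            )
        except RuntimeError as exc:
            raise FitError(f"radial profile fit did not converge: {exc}") from exc
        if not np.all(np.isfinite(pcov)):
            raise FitError("singular covariance; radial profile fit is degenerate")
        resid = (self.pcr - _h(self.r, *popt)) / self.sigma
        dof = self.r.size - 4
        chi2_red = float(np.sum(resid**2)) / max(dof, 1)
        res = RadialProfileResults(
            model=self, params=popt, cov_params=pcov,
            chi2_reduced=chi2_red, dof=max(dof, 0),
            r_min=float(self.r[0]), r_max=float(self.r[-1]),
        )
        h_fit = res.predict(self.r)
        if np.any(h_fit <= 0) or np.any(np.diff(h_fit) > 0):
            warnings.warn(
                "fitted radial profile is not positive and decreasing over the "
                "data range; derived figures may be unreliable",
                stacklevel=2,
            )
        return res


@dataclass
class RadialProfileResults:
    """Fitted radial profile with covariance and derived figures of merit.

    Parameter order is (a, b, c, d).  All derived uncertainties use the
    first-order delta method on the fit covariance.
    """

    model: RadialProfileModel
    params: np.ndarray
    cov_params: np.ndarray
    chi2_reduced: float
    dof: int
    r_min: float
    r_max: float

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    def predict(self, r):
        """h(r) in kHz."""
        return _h(np.asarray(r, dtype=float), *self.params)

    def derivative(self, r):
        """dh/dr in kHz/cm."""
        return _h_prime(np.asarray(r, dtype=float), *self.params)

    # -- delta-method machinery -------------------------------------------

    def _propagate(self, func) -> float:
        """1-sigma uncertainty of scalar func(params) via numerical gradient."""
        p = self.params
        grad = np.zeros_like(p)
        for i in range(p.size):
            step = 1e-6 * max(abs(p[i]), 1e-9)
            up, dn = p.copy(), p.copy()
            up[i] += step
            dn[i] -= step
            if dn[i] < 0 and i == 3:  # keep d within its bound
                dn[i] = max(dn[i], 0.0)
            grad[i] = (func(up) - func(dn)) / (up[i] - dn[i])
        var = float(grad @ self.cov_params @ grad)
        return math.sqrt(max(var, 0.0))

    def predict_err(self, r: float) -> float:
        return self._propagate(lambda p: _h(r, *p))

    # -- figures of merit --------------------------------------------------

    def statistical_precision(self, r: float, window: float, dcr_hz: float):
        """SP(r; dt) = sqrt(N_PCR + N_DCR) / N_PCR as a fraction, with error.

        N_PCR = h(r) dt signal counts, N_DCR = DCR dt dark counts in the
        same window; the dark contribution is distance-independent.
        """
        if window <= 0 or dcr_hz < 0:
            raise DataError("window must be positive and DCR >= 0")

        def sp_of(params):
            h_hz = _h(r, *params) * 1e3
            if h_hz <= 0:
                raise DataError(f"fitted profile non-positive at r = {r} cm")
            n_pcr = h_hz * window
            n_dcr = dcr_hz * window
            return math.sqrt(n_pcr + n_dcr) / n_pcr

        return sp_of(self.params), self._propagate(sp_of)

    def spatial_resolution(self, r: float, window: float, dcr_hz: float):
        """dR(r) = 3 sigma_PCR / |h'(r)| in mm, with error.

        sigma_PCR is the single-window Poisson rate uncertainty including
        dark counts, sqrt((h + DCR) dt) / dt; the displacement that moves
        the expected signal by three such deviations.
        """
        if window <= 0 or dcr_hz < 0:
            raise DataError("window must be positive and DCR >= 0")

        def dr_of(params):
            h_hz = _h(r, *params) * 1e3
            slope_hz = _h_prime(r, *params) * 1e3
            if h_hz <= 0:
                raise DataError(f"fitted profile non-positive at r = {r} cm")
            if abs(slope_hz) < 1e-12:
                raise DataError(f"flat profile at r = {r} cm; resolution undefined")
            sigma_pcr = math.sqrt((h_hz + dcr_hz) * window) / window
            return 10.0 * 3.0 * sigma_pcr / abs(slope_hz)  # cm -> mm

        return dr_of(self.params), self._propagate(dr_of)

    def mdr_crossing(self, mdr_khz: float, domain: tuple | None = None) -> "CrossingResult":
        """Distance at which the profile drops to the minimum detectable rate.

        Bracketing + Brent root of h(r) = MDR over ``domain`` (defaults to
        the fit range).  If the profile sits above the MDR over the whole
        domain the crossing is reported as beyond the far end; below it
        everywhere, beyond the near end.
        """
        lo, hi = domain if domain is not None else (self.r_min, self.r_max)
        if not 0 < lo < hi:
            raise DataError("invalid crossing domain")
        f = lambda r: float(self.predict(r)) - mdr_khz
        flo, fhi = f(lo), f(hi)
        if flo < 0:
            return CrossingResult(float("nan"), float("nan"), "below_mdr_everywhere")
        if fhi > 0:
            return CrossingResult(float("nan"), float("nan"), "beyond_domain")
        root = optimize.brentq(f, lo, hi, xtol=1e-9)

        def root_of(params):
            g = lambda r: _h(r, *params) - mdr_khz
            try:
                return optimize.brentq(g, lo, hi, xtol=1e-9)
            except ValueError:
                return root
        return CrossingResult(float(root), self._propagate(root_of), "ok")

    def summary(self) -> str:
        names = ["a [kHz cm^2]", "b [kHz cm]", "c [kHz]", "d [1/cm]"]
        lines = [
            "Radial profile fit h(r) = (a/r^2 + b/r + c) exp(-d r)",
            f"  n = {self.model.r.size} points, r in [{self.r_min:.3g}, "
            f"{self.r_max:.3g}] cm, reduced chi2 = {self.chi2_reduced:.3f} "
            f"(dof {self.dof})",
        ]
        for name, v, e in zip(names, self.params, self.bse):
            lines.append(f"  {name:<13s}: {v:.6g} +/- {e:.3g}")
        return "\n".join(lines)


@dataclass(frozen=True)
class CrossingResult:
    r_cm: float
    sigma_cm: float
    status: str  # "ok" | "beyond_domain" | "below_mdr_everywhere"

    @property
    def found(self) -> bool:
        return self.status == "ok"


# ---------------------------------------------------------------------------
# spec-style functional wrappers


def fit_h(series_or_arrays, **kwargs) -> RadialProfileResults:
    """Weighted nonlinear fit of the radial profile h(r)."""
    if isinstance(series_or_arrays, ScanSeries):
        model = RadialProfileModel.from_series(series_or_arrays)
    else:
        r, pcr, sigma = series_or_arrays
        model = RadialProfileModel(r, pcr, sigma)
    return model.fit(**kwargs)


def statistical_precision(r, window, fit: RadialProfileResults, dcr: float):
    """SP(r; dt) as a fraction; ``dcr`` in Hz."""
    return fit.statistical_precision(r, window, dcr)


def spatial_resolution(r, window, fit: RadialProfileResults, dcr: float):
    """dR(r) in mm; ``dcr`` in Hz."""
    return fit.spatial_resolution(r, window, dcr)


def mdr_crossing_distance(fit: RadialProfileResults, mdr_hz: float,
                          domain: tuple | None = None) -> CrossingResult:
    """Root of h(r) = MDR; ``mdr_hz`` in Hz."""
    return fit.mdr_crossing(mdr_hz / 1e3, domain=domain)


# ---------------------------------------------------------------------------
# compliance


@dataclass
class PerformanceReport:
    """Derived performance of one fitted system against its design targets."""

    mode: str
    pcr_at_target_khz: tuple
    mdr_khz: float
    mdr_crossing: CrossingResult
    sp_pct: tuple
    delta_r_mm: tuple
    checks: dict  # name -> {"value", "limit", "pass"}

    @property
    def all_pass(self) -> bool:
        return all(c["pass"] for c in self.checks.values())

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "pcr_at_target_khz": list(self.pcr_at_target_khz),
            "mdr_khz": self.mdr_khz,
            "mdr_crossing_cm": None if not self.mdr_crossing.found else self.mdr_crossing.r_cm,
            "mdr_crossing_err_cm": None if not self.mdr_crossing.found else self.mdr_crossing.sigma_cm,
            "mdr_crossing_status": self.mdr_crossing.status,
            "statistical_precision_pct": list(self.sp_pct),
            "spatial_resolution_mm": list(self.delta_r_mm),
            "checks": self.checks,
            "all_pass": self.all_pass,
        }

    def summary(self) -> str:
        lines = [f"Performance report ({self.mode.upper()})"]
        v, e = self.pcr_at_target_khz
        lines.append(f"  PCR at target distance : {v:.4g} +/- {e:.2g} kHz "
                     f"(MDR {self.mdr_khz:.4g} kHz)")
        if self.mdr_crossing.found:
            lines.append(f"  MDR crossing distance  : {self.mdr_crossing.r_cm:.3g} "
                         f"+/- {self.mdr_crossing.sigma_cm:.2g} cm")
        else:
            lines.append(f"  MDR crossing distance  : {self.mdr_crossing.status}")
        v, e = self.sp_pct
        lines.append(f"  statistical precision  : {v:.3g} +/- {e:.2g} %")
        v, e = self.delta_r_mm
        lines.append(f"  spatial resolution     : {v:.3g} +/- {e:.2g} mm")
        for name, c in self.checks.items():
            lines.append(f"  [{'PASS' if c['pass'] else 'FAIL'}] {name}: "
                         f"{c['value']:.4g} vs limit {c['limit']:.4g}")
        return "\n".join(lines)


def compliance_report(
    fit: RadialProfileResults,
    dcr_hz: float,
    specs: SpecTable = DEFAULT_SPECS,
    mode: str = "hdr",
) -> PerformanceReport:
    """Evaluate a fitted profile against the per-mode design targets.

    Sensitivity requires the fitted PCR at the mode's maximum sensing
    distance to exceed the MDR for the mode's counting window; statistical
    precision and spatial resolution are evaluated at their own target
    distances.  The MDR-crossing search extends to twice the target
    distance, since the crossing typically lies beyond the measured range.
    """
    from .characterize import mdr as _mdr

    spec = specs.for_mode(mode)
    window = spec.precision_window_s
    mdr_khz = _mdr(dcr_hz, window) / 1e3
    target_r = spec.max_distance_cm
    pcr_t = float(fit.predict(target_r))
    pcr_t_err = fit.predict_err(target_r)
    crossing = fit.mdr_crossing(
        mdr_khz, domain=(fit.r_min, max(fit.r_max, 2.0 * spec.max_distance_cm))
    )
    sp, sp_err = fit.statistical_precision(spec.precision_at_cm, window, dcr_hz)
    dr, dr_err = fit.spatial_resolution(spec.resolution_at_cm, window, dcr_hz)
    checks = {
        f"PCR above MDR at {target_r:g} cm": {
            "value": pcr_t, "limit": mdr_khz, "pass": bool(pcr_t > mdr_khz)},
        f"statistical precision at {spec.precision_at_cm:g} cm "
        f"< {spec.precision_pct:g}% in {window:g} s": {
            "value": sp * 100, "limit": spec.precision_pct,
            "pass": bool(sp * 100 < spec.precision_pct)},
        f"spatial resolution at {spec.resolution_at_cm:g} cm "
        f"< {spec.resolution_mm:g} mm": {
            "value": dr, "limit": spec.resolution_mm,
            "pass": bool(dr < spec.resolution_mm)},
    }
    return PerformanceReport(
        mode=mode, pcr_at_target_khz=(pcr_t, pcr_t_err), mdr_khz=mdr_khz,
        mdr_crossing=crossing, sp_pct=(sp * 100, sp_err * 100),
        delta_r_mm=(dr, dr_err), checks=checks,
    )
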