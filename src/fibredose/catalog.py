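"""Published device parameters and project design specifications.

Datasheet characteristics of the four candidate SiPMs (two KETEK WB-series
devices, two HAMAMATSU MPPCs) and the measured characterisation results at
both discriminator thresholds, plus the dosimeter design-specification
table used by the compliance report. These are inputs to the analysis, not
outputs of it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "DETECTORS",
    "MEASURED",
    "DEFAULT_SPECS",
    "SiPMSpec",
    "SpecTable",
    "ModeSpec",
    "MeasuredValue",
]


@dataclass(frozen=True)
class SiPMSpec:
    """Datasheet parameters of a SiPM driving simulation and MDR predictions.

    ``pde_620`` is the photon detection efficiency at 620 nm (the scintillator
    emission), ``dcr`` the dark count rate in Hz at the 0.5 p.e. threshold,
    ``oct_prob`` the optical cross-talk probability (one avalanche firing at
    least one neighbouring cell), ``sensitive_area`` in mm^2 and
    ``cell_pitch`` in um.
    """

    name: str
    pde_620: float
    dcr: float
    oct_prob: float
    sensitive_area: float
    cell_pitch: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pde_620 <= 1.0:
            raise ValueError("pde_620 must be a fraction in [0, 1]")
        if self.dcr < 0:
            raise ValueError("dcr must be >= 0")
        if not 0.0 <= self.oct_prob < 1.0:
            raise ValueError("oct_prob must be a fraction in [0, 1)")


#: Datasheet values at 25 C. DCR in Hz at 0.5 p.e.
DETECTORS: dict[str, SiPMSpec] = {
    "PM1125": SiPMSpec("PM1125", pde_620=0.17, dcr=125e3, oct_prob=0.26,
                       sensitive_area=1.0, cell_pitch=25.0),
    "PM3325": SiPMSpec("PM3325", pde_620=0.17, dcr=1125e3, oct_prob=0.26,
                       sensitive_area=9.0, cell_pitch=25.0),
    "S13360-1350": SiPMSpec("S13360-1350", pde_620=0.24, dcr=90e3, oct_prob=0.03,
                            sensitive_area=1.69, cell_pitch=50.0),
    "S13360-1375": SiPMSpec("S13360-1375", pde_620=0.30, dcr=90e3, oct_prob=0.07,
                            sensitive_area=1.69, cell_pitch=75.0),
}


@dataclass(frozen=True)
class MeasuredValue:
    value: float
    error: float

    def __iter__(self):
        return iter((self.value, self.error))


#: Measured characterisation figures per detector and threshold:
#: MDR in kHz for the 0.1 s and 0.5 s windows, sensitivity m in kHz/mA.
MEASURED: dict[str, dict[float, dict[str, MeasuredValue]]] = {
    "PM1125": {
        0.5: {"mdr_0.1s": MeasuredValue(3.1, 0.2), "mdr_0.5s": MeasuredValue(1.4, 0.05),
              "sensitivity": MeasuredValue(6710, 31)},
        1.5: {"mdr_0.1s": MeasuredValue(1.5, 0.1), "mdr_0.5s": MeasuredValue(0.68, 0.04),
              "sensitivity": MeasuredValue(1713, 22)},
    },
    "PM3325": {
        0.5: {"mdr_0.1s": MeasuredValue(10.5, 0.3), "mdr_0.5s": MeasuredValue(4.7, 0.1),
              "sensitivity": MeasuredValue(12438, 448)},
        1.5: {"mdr_0.1s": MeasuredValue(5.5, 0.2), "mdr_0.5s": MeasuredValue(2.5, 0.07),
              "sensitivity": MeasuredValue(3192, 31)},
    },
    "S13360-1350": {
        0.5: {"mdr_0.1s": MeasuredValue(3.0, 0.2), "mdr_0.5s": MeasuredValue(1.4, 0.05),
              "sensitivity": MeasuredValue(14203, 354)},
        1.5: {"mdr_0.1s": MeasuredValue(0.49, 0.07), "mdr_0.5s": MeasuredValue(0.22, 0.002),
              "sensitivity": MeasuredValue(354, 3)},
    },
    "S13360-1375": {
        0.5: {"mdr_0.1s": MeasuredValue(2.8, 0.2), "mdr_0.5s": MeasuredValue(1.2, 0.05),
              "sensitivity": MeasuredValue(18187, 378)},
        1.5: {"mdr_0.1s": MeasuredValue(0.47, 0.07), "mdr_0.5s": MeasuredValue(0.21, 0.002),
              "sensitivity": MeasuredValue(533, 4)},
    },
}


@dataclass(frozen=True)
class ModeSpec:
    """Design targets for one treatment mode.

    ``max_distance_cm``: farthest distance at which a dose signal must be
    resolvable above the dark-count floor; ``resolution_mm`` at
    ``resolution_at_cm``: spatial resolution target; ``precision_pct`` in a
    ``precision_window_s`` window at ``precision_at_cm``: statistical
    precision target.
    """

    max_distance_cm: float
    resolution_mm: float
    resolution_at_cm: float
    precision_pct: float
    precision_window_s: float
    precision_at_cm: float
    dose_rate_range: str = ""

    def __post_init__(self) -> None:
        for f in (self.max_distance_cm, self.resolution_mm, self.resolution_at_cm,
                  self.precision_pct, self.precision_window_s, self.precision_at_cm):
            if not f > 0:
                raise ValueError("specification entries must be positive")


@dataclass(frozen=True)
class SpecTable:
    hdr: ModeSpec
    ldr: ModeSpec

    def for_mode(self, mode: str) -> ModeSpec:
        mode = mode.lower()
        if mode not in ("hdr", "ldr"):
            raise ValueError(f"mode must be 'hdr' or 'ldr', got {mode!r}")
        return self.hdr if mode == "hdr" else self.ldr


#: Project design specifications: dose sensitivity up to 10 cm (HDR) / 3 cm
#: (LDR); spatial resolution 1 mm @ 5 cm (HDR) / 3 mm @ 3 cm (LDR);
#: statistical precision 5% in 0.1 s @ 10 cm (HDR) / 5% in 0.5 s @ 3 cm (LDR).
DEFAULT_SPECS = SpecTable(
    hdr=ModeSpec(max_distance_cm=10.0, resolution_mm=1.0, resolution_at_cm=5.0,
                 precision_pct=5.0, precision_window_s=0.1, precision_at_cm=10.0,
                 dose_rate_range=">12 Gy/h"),
    ldr=ModeSpec(max_distance_cm=3.0, resolution_mm=3.0, resolution_at_cm=3.0,
                 precision_pct=5.0, precision_window_s=0.5, precision_at_cm=3.0,
                 dose_rate_range="0.4-2 Gy/h"),
)


def positioning_uncertainty_mm(tunnel_diameter_mm: float = 2.1,
                               catheter_outer_mm: float = 2.0,
                               catheter_inner_mm: float = 1.5,
                               capsule_diameter_mm: float = 0.9) -> float:
    """Maximum source-sensor positioning play in the phantom, mm.

    Sum of the radial clearances of the catheter in its machined tunnel and
    of the source capsule inside the catheter lumen:
    (tunnel - catheter_outer)/2 + (catheter_inner - capsule)/2.
    """
    if capsule_diameter_mm > catheter_inner_mm or catheter_outer_mm > tunnel_diameter_mm:
        raise ValueError("nested diameters must decrease inwards")
    return ((tunnel_diameter_mm - catheter_outer_mm)
            + (catheter_inner_mm - capsule_diameter_mm)) / 2.0


def chi2_gate_confidence(chi2_reduced_max: float, dof: int = 1) -> float:
    """Confidence level of accepting a fit with reduced chi^2 <= threshold.

    P(chi^2_dof <= threshold * dof) for a correct linear model with Gaussian
    errors; the 2.7 gate at one residual degree of freedom is ~90%.
    """
    from scipy.stats import chi2 as _chi2

    if chi2_reduced_max <= 0 or dof < 1:
        raise ValueError("threshold must be positive and dof >= 1")
    return float(_chi2.cdf(chi2_reduced_max * dof, dof))


def mdr_scaling(mdr: float, window_from: float, window_to: float) -> float:
    """Rescale a minimum detectable rate between counting windows.

    MDR = 3 sqrt(DCR / dt) scales as 1/sqrt(dt), so the 0.5 s value is the
    0.1 s value divided by sqrt(5).
    """
    if window_from <= 0 or window_to <= 0:
        raise ValueError("windows must be positive")
    return mdr * math.sqrt(window_from / window_to)
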