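"""Gel-filtration calibration and hydrodynamic conformational-state calls.

Size-exclusion chromatography reports an *apparent* molecular mass from the
log-linear relation between the mass of globular standards and their
elution volume (or time). For a disordered or partially folded protein the
apparent mass exceeds the sequence-derived mass because the chain occupies
more hydrodynamic volume than a compact globule of the same mass.

The comparison is made on the hydrodynamic-radius scale using the published
log-linear calibrations log10(Rs/Å) = a·log10(M/Da) + b fitted separately
for native globular proteins, molten globules, pre-molten globules and
chemically unfolded chains. The relative radius increase over the native
expectation diagnoses the conformational state: a 15–20% increase marks the
native → molten-globule transition and a larger increase a pre-molten
globule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class HydroCalibration:
    """Log-linear mass-to-radius calibration for one conformational class."""

    state: str
    a: float  # slope of log10 Rs vs log10 M
    b: float  # intercept, log10 Å


#: Published conformational-class calibrations, log10 Rs = a·log10 M + b.
HYDRO_STATES: dict[str, HydroCalibration] = {
    "native": HydroCalibration("native", 0.369, -0.254),
    "molten_globule": HydroCalibration("molten_globule", 0.334, -0.053),
    "pre_molten_globule": HydroCalibration("pre_molten_globule", 0.392, -0.210),
    "unfolded_urea": HydroCalibration("unfolded_urea", 0.521, -0.649),
    "unfolded_gdmcl": HydroCalibration("unfolded_gdmcl", 0.543, -0.701),
}


@dataclass
class GFCalibration:
    """Least-squares fit of log10(mass/Da) on elution for column standards."""

    slope: float
    intercept: float
    r2: float
    standards: list[tuple[float, float]]  # (mass_da, elution)

    @property
    def elution_range(self) -> tuple[float, float]:
        elutions = [e for _, e in self.standards]
        return min(elutions), max(elutions)


@dataclass(frozen=True)
class MassEstimate:
    mass_da: float
    elution: float
    extrapolated: bool


@dataclass(frozen=True)
class ConformationCall:
    r_native: float
    r_apparent: float

    @property
    def increase_pct(self) -> float:
        return 100.0 * (self.r_apparent - self.r_native) / self.r_native

    @property
    def call(self) -> str:
        """Threshold rule: <15% native; 15–20% (inclusive) molten globule;
        >20% pre-molten globule."""
        inc = self.increase_pct
        if inc < 15.0:
            return "native"
        if inc <= 20.0:
            return "molten_globule"
        return "pre_molten_globule"


def fit_gf_calibration(standards: list[tuple[float, float]]) -> GFCalibration:
    """Fit log10(mass) vs elution by least squares over ≥2 standards."""
    if len(standards) < 2:
        raise ValueError("need at least two standards")
    masses = np.array([m for m, _ in standards], dtype=float)
    elutions = np.array([e for _, e in standards], dtype=float)
    if np.all(masses <= 0):
        raise ValueError("standard masses must be positive")
    if len(np.unique(elutions)) < 2:
        raise ValueError("singular fit: standards share a single elution value")
    res = stats.linregress(elutions, np.log10(masses))
    if res.slope >= 0:
        warnings.warn(
            "gel-filtration calibration slope is non-negative; larger species "
            "should elute earlier on a size-exclusion column",
            stacklevel=2,
        )
    return GFCalibration(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        standards=[(float(m), float(e)) for m, e in standards],
    )


def apparent_mass(cal: GFCalibration, elution: float) -> MassEstimate:
    """Apparent mass 10^(slope·elution + intercept); extrapolation flagged."""
    lo, hi = cal.elution_range
    return MassEstimate(
        mass_da=float(10.0 ** (cal.slope * elution + cal.intercept)),
        elution=float(elution),
        extrapolated=not (lo <= elution <= hi),
    )


def hydrodynamic_radius(mass_da: float, state: str | HydroCalibration = "native") -> float:
    """Stokes radius in Å from the log-linear calibration of one state."""
    if mass_da <= 0:
        raise ValueError("mass must be positive")
    cal = HYDRO_STATES[state] if isinstance(state, str) else state
    return float(10.0 ** (cal.a * np.log10(mass_da) + cal.b))


def classify_conformation(r_native: float, r_apparent: float) -> ConformationCall:
    """Conformational-state call from the relative radius increase."""
    if r_native <= 0 or r_apparent <= 0:
        raise ValueError("radii must be positive")
    return ConformationCall(r_native=float(r_native), r_apparent=float(r_apparent))
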