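"""Enzymatic-hydrolysis assay mathematics.

Implements the four assay statistics used to characterise protease
hydrolysates of plant proteins:

* **degree of hydrolysis (DH)** by the pH-stat method, including the
  temperature-dependent pKa of the liberated alpha-amino groups and their
  dissociation degree;
* **alcohol dehydrogenase (ADH) activation** from initial reaction rates
  estimated as the derivative at t = 0 of a curve fitted to an A340
  progress trace;
* **xanthine oxidase (XOD) inhibition** from a four-cuvette absorbance
  scheme (sample, no-enzyme, no-sample, blank);
* **DPPH radical scavenging** with a sample-colour blank correction.

All percentages are returned on the 0-100 scale and may be negative where
the defining formula admits it (a sample that slows the enzyme, say).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import DomainError, FitError

__all__ = [
    "TitrationRecord",
    "KineticTrace",
    "RateResult",
    "XodAbsorbanceQuad",
    "DpphTriple",
    "alpha_amino_pKa",
    "dissociation_degree",
    "degree_of_hydrolysis",
    "fit_initial_rate",
    "adh_activation_rate",
    "xod_inhibition_rate",
    "dpph_scavenging_rate",
]

PKA_VARIANTS = ("standard", "paper-literal")
CURVE_FAMILIES = ("quadratic", "linear", "exponential")


@dataclass(frozen=True)
class TitrationRecord:
    """One pH-stat titration: base consumed while hydrolysing a protein.

    ``naoh_concentration`` is in mol/L and ``naoh_volume`` in mL, so their
    product is millimoles of base -- dimensionally consistent with
    ``h_tot`` given in mmol of peptide bonds per g of protein.
    """

    naoh_concentration: float  # mol/L
    naoh_volume: float  # mL
    system_pH: float
    temperature: float  # K
    protein_mass: float  # g
    h_tot: float  # mmol peptide bonds / g protein

    def __post_init__(self) -> None:
        for name in ("naoh_concentration", "naoh_volume", "protein_mass", "h_tot"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be non-negative, got {getattr(self, name)}")
        if not 0.0 <= self.system_pH <= 14.0:
            raise DomainError(f"system_pH must lie in [0, 14], got {self.system_pH}")
        if self.temperature <= 0:
            raise DomainError(f"temperature must be positive, got {self.temperature}")


@dataclass(frozen=True)
class KineticTrace:
    """An absorbance progress curve (e.g. NADH formation at 340 nm)."""

    times: np.ndarray
    absorbances: np.ndarray
    time_unit: str = "s"  # "s" or "min"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.absorbances, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "absorbances", a)
        if t.ndim != 1 or t.shape != a.shape:
            raise DomainError("times and absorbances must be 1-D arrays of equal length")
        if t.size < 3:
            raise DomainError(f"a kinetic trace needs at least 3 points, got {t.size}")
        if np.any(np.diff(t) <= 0):
            raise DomainError("times must be strictly increasing (no duplicates)")
        if self.time_unit not in ("s", "min"):
            raise DomainError(f"time_unit must be 's' or 'min', got {self.time_unit!r}")

    @property
    def times_min(self) -> np.ndarray:
        """Times converted to minutes, the unit all rates are reported in."""
        return self.times / 60.0 if self.time_unit == "s" else self.times


@dataclass(frozen=True)
class RateResult:
    """Initial rate estimated from a fitted progress curve."""

    initial_rate: float  # AU/min
    fit_kind: str
    fit_residual: float  # sum of squared residuals, AU^2
    coefficients: tuple = field(default=())

    def __post_init__(self) -> None:
        if self.fit_residual < -1e-12:
            raise DomainError("fit_residual must be non-negative")


@dataclass(frozen=True)
class XodAbsorbanceQuad:
    """The four absorbance readings of the XOD inhibition scheme.

    ``a_sample``: peptide + enzyme; ``b_no_enzyme``: peptide without enzyme;
    ``c_no_sample``: enzyme without peptide; ``d_blank``: neither.
    """

    a_sample: float
    b_no_enzyme: float
    c_no_sample: float
    d_blank: float

    def __post_init__(self) -> None:
        if self.c_no_sample == self.d_blank:
            raise DomainError(
                "no-sample control equals blank: the uninhibited enzyme signal is zero "
                "and the inhibition ratio is undefined"
            )


@dataclass(frozen=True)
class DpphTriple:
    """Control, sample and colour-blank absorbances of a DPPH assay."""

    a_control: float
    a_sample: float
    a_blank: float

    def __post_init__(self) -> None:
        if self.a_control <= 0:
            raise DomainError(f"a_control must be positive, got {self.a_control}")


def alpha_amino_pKa(temperature: float, formula_variant: str = "standard") -> float:
    """Temperature-corrected pKa of peptide alpha-amino groups.

    The correction is anchored at 298 K, where both variants give 7.8.
    The default ``"standard"`` variant uses the van't-Hoff-style product
    denominator

        pKa(T) = 7.8 + (298 - T) / (298 * T) * 2400,

    which moves the pKa by a fraction of a unit over assay temperatures.
    The ``"paper-literal"`` variant replaces the product ``298 * T`` with
    the sum ``298 + T``; it is provided for comparison only, since away
    from 298 K it produces physically impossible values (pKa of -89 at
    323 K) and is therefore not the default.

    Parameters
    ----------
    temperature : float
        Absolute temperature in Kelvin; must lie in (250, 400).
    formula_variant : {"standard", "paper-literal"}
    """
    if not 250.0 < temperature < 400.0:
        raise DomainError(f"temperature {temperature} K outside the supported range (250, 400)")
    if formula_variant == "standard":
        return 7.8 + (298.0 - temperature) / (298.0 * temperature) * 2400.0
    if formula_variant == "paper-literal":
        return 7.8 + (298.0 - temperature) / (298.0 + temperature) * 2400.0
    raise DomainError(f"unknown pKa formula variant {formula_variant!r}; choose from {PKA_VARIANTS}")


def dissociation_degree(pH: float, pKa: float) -> float:
    """Fraction of alpha-amino groups deprotonated at the given pH.

    Henderson-Hasselbalch logistic form ``10**(pH-pKa) / (1 + 10**(pH-pKa))``;
    strictly increasing in pH and exactly 0.5 at pH == pKa.
    """
    x = 10.0 ** (pH - pKa)
    return x / (1.0 + x)


def degree_of_hydrolysis(record: TitrationRecord, formula_variant: str = "standard") -> float:
    """Degree of hydrolysis (percent) from a pH-stat titration.

    DH% = 100 * (C * V) / (a * m * h_tot), where C*V (mol/L * mL) is the
    millimoles of base consumed, ``a`` the dissociation degree of the
    alpha-amino groups at the system pH and temperature, ``m`` the protein
    mass (g) and ``h_tot`` the peptide-bond content (mmol/g).
    """
    if record.protein_mass == 0:
        raise DomainError("protein_mass must be positive to compute DH")
    if record.h_tot == 0:
        raise DomainError("h_tot must be positive to compute DH")
    pKa = alpha_amino_pKa(record.temperature, formula_variant)
    a = dissociation_degree(record.system_pH, pKa)
    if a <= 0:
        raise DomainError("dissociation degree is zero; DH undefined")
    mmol_base = record.naoh_concentration * record.naoh_volume
    return 100.0 * mmol_base / (a * record.protein_mass * record.h_tot)


def _fit_exponential(t: np.ndarray, y: np.ndarray):
    """A(t) = a0 + amp * (1 - exp(-k t)): saturating approach to a plateau."""

    def model(t, a0, amp, k):
        return a0 + amp * (1.0 - np.exp(-k * t))

    span = y[-1] - y[0]
    t_scale = max(t[-1], 1e-9)
    p0 = (y[0], span if span != 0 else 1e-3, 1.0 / t_scale)
    popt, _ = curve_fit(model, t, y, p0=p0, maxfev=20000)
    resid = y - model(t, *popt)
    # d/dt at 0 of amp*(1 - exp(-k t)) is amp*k
    return popt[1] * popt[2], float(resid @ resid), tuple(popt)


def fit_initial_rate(trace: KineticTrace, curve_family: str = "quadratic") -> RateResult:
    """Estimate the initial reaction rate as the derivative at t = 0 of a fitted curve.

    The trace is fitted by least squares with the chosen curve family and
    the analytic first derivative of the fitted curve is evaluated at
    t = 0.  The rate is always reported in AU/min regardless of the
    trace's time unit.

    Families: ``"quadratic"`` (default; captures early-time curvature of a
    saturating progress curve), ``"linear"``, and ``"exponential"``
    (single-exponential approach to a plateau).
    """
    t = trace.times_min
    y = trace.absorbances
    if np.ptp(t) == 0:
        raise FitError("all time points identical; design matrix is singular")
    if curve_family == "quadratic":
        if t.size < 3:
            raise FitError("quadratic family needs at least 3 points")
        coef = np.polynomial.polynomial.polyfit(t, y, 2)
        resid = y - np.polynomial.polynomial.polyval(t, coef)
        return RateResult(float(coef[1]), "quadratic", float(resid @ resid), tuple(coef))
    if curve_family == "linear":
        coef = np.polynomial.polynomial.polyfit(t, y, 1)
        resid = y - np.polynomial.polynomial.polyval(t, coef)
        return RateResult(float(coef[1]), "linear", float(resid @ resid), tuple(coef))
    if curve_family == "exponential":
        try:
            rate, rss, popt = _fit_exponential(t, y)
        except RuntimeError as exc:  # pragma: no cover - pathological traces
            raise FitError(f"exponential fit did not converge: {exc}") from exc
        return RateResult(float(rate), "exponential", rss, popt)
    raise DomainError(f"unknown curve family {curve_family!r}; choose from {CURVE_FAMILIES}")


def adh_activation_rate(v_sample: float, v_control: float) -> float:
    """ADH activation (percent): 100 * (Vs - Vo) / Vo.

    Negative when the sample slows the enzyme below the no-sample control.
    """
    if v_control <= 0:
        raise DomainError(f"control rate must be positive, got {v_control}")
    return 100.0 * (v_sample - v_control) / v_control


def xod_inhibition_rate(quad: XodAbsorbanceQuad) -> float:
    """XOD inhibition (percent): 100 * (1 - (A - B) / (C - D)).

    (A - B) is the enzyme-attributable signal in the presence of peptide,
    (C - D) without; the rate is 0 when they coincide and 100 when the
    sample suppresses the enzyme signal entirely.
    """
    ratio = (quad.a_sample - quad.b_no_enzyme) / (quad.c_no_sample - quad.d_blank)
    return 100.0 * (1.0 - ratio)


def dpph_scavenging_rate(triple: DpphTriple) -> float:
    """DPPH radical scavenging (percent): 100 * (Ac - As + Ab) / Ac.

    ``Ab`` corrects for the sample's own colour at 517 nm; the rate is 100
    when the sample absorbance equals its blank (all radical quenched).
    """
    return 100.0 * (triple.a_control - triple.a_sample + triple.a_blank) / triple.a_control
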