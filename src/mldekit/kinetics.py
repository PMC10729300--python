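"""Enzyme-kinetics computations: Michaelis–Menten fits and derived numbers.

Covers the small, exact calculations behind a biochemical characterization
table: nonlinear least-squares fitting of v = Vmax·S/(Km + S), conversion
of specific activity (nmol·min⁻¹·mg⁻¹) to a turnover number kcat (s⁻¹) via
the protomer molar mass, catalytic efficiency kcat/Km in s⁻¹·M⁻¹, the
ATP-per-carboxylation stoichiometry of a coupled NADPH-consumption assay,
and fold-change / percent-reduction reporting arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import floor, log10

import numpy as np
from scipy.optimize import curve_fit

#: Default protomer molar mass (g/mol) for the glycolyl-CoA carboxylase
#: holoenzyme used throughout: 1.30e5 is consistent with the published
#: (Vmax, kcat) pairs of both the parent enzyme and its G20R variant.
GCC_PROTOMER_MASS: float = 1.30e5

#: NADPH molar extinction coefficient at 340 nm, M^-1 cm^-1.
NADPH_EPSILON_340: float = 6220.0


class KineticsError(ValueError):
    """Raised for physically meaningless inputs or failed fits."""


@dataclass(frozen=True)
class KineticFit:
    """Michaelis–Menten parameters with asymptotic standard errors."""

    vmax: float  # nmol min^-1 mg^-1
    km: float  # mM
    vmax_se: float
    km_se: float
    n_points: int


def michaelis_menten(S: np.ndarray, vmax: float, km: float) -> np.ndarray:
    return vmax * S / (km + S)


def mm_fit(S: np.ndarray, v: np.ndarray) -> KineticFit:
    """Nonlinear least-squares Michaelis–Menten fit.

    Deterministic: initialized at Vmax0 = max(v), Km0 = median(S), with both
    parameters bounded below by zero. Needs at least three distinct
    substrate concentrations. A fitted Km collapsing to the zero boundary
    (rates flat in S, i.e. fully saturated data) is reported as an error.
    """
    S = np.asarray(S, dtype=float)
    v = np.asarray(v, dtype=float)
    if S.shape != v.shape or S.ndim != 1:
        raise KineticsError("S and v must be equal-length vectors")
    if len(np.unique(S)) < 3:
        raise KineticsError("need >= 3 distinct substrate concentrations")
    if np.any(S < 0) or np.any(v < 0):
        raise KineticsError("concentrations and rates must be nonnegative")
    p0 = (float(np.max(v)), float(np.median(S)))
    try:
        popt, pcov = curve_fit(
            michaelis_menten, S, v, p0=p0, bounds=(0.0, np.inf), maxfev=10000
        )
    except RuntimeError as exc:
        raise KineticsError(f"Michaelis-Menten fit did not converge: {exc}") from exc
    vmax, km = float(popt[0]), float(popt[1])
    if vmax <= 0:
        raise KineticsError("fitted Vmax is not positive")
    if km <= 1e-6 * float(np.max(S)):
        raise KineticsError(
            "fitted Km collapsed to the zero boundary (rates saturated at all S)"
        )
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    return KineticFit(
        vmax=vmax, km=km, vmax_se=float(se[0]), km_se=float(se[1]), n_points=len(S)
    )


def catalytic_efficiency(kcat: float, km_mM: float) -> float:
    """kcat/Km in s^-1 M^-1 from kcat (s^-1) and Km (mM)."""
    if kcat <= 0 or km_mM <= 0:
        raise KineticsError("kcat and Km must be positive")
    return kcat / (km_mM * 1e-3)


def kcat_from_vmax(vmax: float, protomer_mass: float = GCC_PROTOMER_MASS) -> float:
    """Turnover number (s^-1) from specific activity.

    ``vmax`` in nmol·min⁻¹·mg⁻¹, ``protomer_mass`` in g·mol⁻¹:
    kcat = vmax · 10⁻⁶ · M / 60 (the 10⁻⁶ collects nmol→mol and mg→g).
    """
    if vmax <= 0 or protomer_mass <= 0:
        raise KineticsError("vmax and protomer mass must be positive")
    return vmax * 1e-6 * protomer_mass / 60.0


def atp_per_carboxylation(
    atp_total: float, nadph_consumed: float, sanity_factor: float = 10.0
) -> float:
    """ATP molecules hydrolyzed per productive carboxylation.

    Under ATP-limited conditions the reaction consumes the full ATP pool
    while the coupled readout counts productive carboxylations as NADPH
    oxidation, so the ratio is (ATP supplied)/(NADPH consumed), both in the
    same concentration units. 1.0 is perfect coupling; larger values mean
    futile carboxybiotin decarboxylation. Consumption exceeding the ATP
    pool ``sanity_factor``-fold indicates mismatched units and is rejected.
    """
    if atp_total <= 0 or nadph_consumed <= 0:
        raise KineticsError("amounts must be positive")
    if nadph_consumed > atp_total * sanity_factor:
        raise KineticsError(
            "NADPH consumption exceeds the ATP pool by more than the sanity bound; "
            "check units"
        )
    return atp_total / nadph_consumed


def nadph_from_a340(
    delta_a340: float, epsilon: float = NADPH_EPSILON_340, pathlength_cm: float = 1.0
) -> float:
    """Convert an absorbance change at 340 nm to NADPH concentration (M).

    Beer-Lambert: ΔC = ΔA / (ε·l), with ε defaulting to NADPH's 6220
    M⁻¹cm⁻¹. A positive ``delta_a340`` is an absorbance *decrease*
    (consumption).
    """
    if epsilon <= 0 or pathlength_cm <= 0:
        raise KineticsError("extinction coefficient and pathlength must be positive")
    return delta_a340 / (epsilon * pathlength_cm)


def fold_change(a: float, b: float) -> float:
    """a/b — e.g. variant Vmax over parent Vmax."""
    if b <= 0:
        raise KineticsError("denominator must be positive")
    return a / b


def percent_reduction(new: float, old: float) -> float:
    """100·(1 − new/old): how much lower the new value is, in percent."""
    if old <= 0:
        raise KineticsError("reference value must be positive")
    return 100.0 * (1.0 - new / old)


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures for reporting."""
    if x == 0:
        return 0.0
    return round(x, -int(floor(log10(abs(x)))) + (sig - 1))
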