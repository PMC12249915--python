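"""Fast-exchange 1:1 host-guest binding analysis from diffusion NMR.

A guest exchanging rapidly (on the NMR timescale) between its free form and
an inclusion complex shows a single set of signals whose diffusion
coefficient is the population-weighted average of the free-guest and complex
values.  Because the host is much larger than the guest, the complex diffuses
essentially like the free host, so three measured diffusion coefficients —
free guest, observed guest in the host-containing sample, and host — fix the
bound molar fraction:

    f_bound = (D_free − D_obs) / (D_free − D_host)

Combining f_bound with the analytical concentrations gives the 1:1
association constant

    K = f / ((c_host − f·c_guest) · (1 − f))        [L/mol]

and inverting that relation (a quadratic in f) predicts the bound fraction
at any other composition.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

from .constants import (
    BOLTZMANN_K,
    D2O_VISCOSITY_PA_S,
    DEFAULT_D_BRACKET_TOL,
    DEFAULT_VISCOSITY_MATCH_TOL,
    ROOM_TEMPERATURE_K,
)

__all__ = [
    "DiffusionRecord",
    "HydrodynamicContext",
    "BindingMeasurement",
    "BindingResult",
    "ViscosityCheck",
    "NonIdentifiableError",
    "InconsistentDataError",
    "bound_fraction_from_diffusion",
    "association_constant",
    "fraction_from_K",
    "stokes_einstein_radius",
    "viscosity_match",
]


class NonIdentifiableError(ValueError):
    """Free-guest and host diffusion coefficients coincide: the bound
    fraction cannot be resolved from the weighted-average model."""


class InconsistentDataError(ValueError):
    """Observed guest D lies outside the [D_host, D_free] bracket by more
    than the allowed tolerance."""


@dataclass(frozen=True)
class DiffusionRecord:
    """One measured diffusion coefficient.

    Parameters
    ----------
    species_id : str
        Species label (e.g. ``"HDO"``, ``"guest"``).
    D : float
        Diffusion coefficient, m²/s.
    sample_id : str
        Sample the measurement belongs to.
    temperature : float
        Sample temperature, K.
    """

    species_id: str
    D: float
    sample_id: str = ""
    temperature: float = ROOM_TEMPERATURE_K

    def __post_init__(self) -> None:
        if not self.D > 0:
            raise ValueError(f"D must be positive, got {self.D!r}")
        if not self.temperature > 0:
            raise ValueError("temperature must be positive")


@dataclass(frozen=True)
class HydrodynamicContext:
    """Solvent conditions for Stokes-Einstein conversions."""

    temperature: float = ROOM_TEMPERATURE_K
    viscosity: float = D2O_VISCOSITY_PA_S
    boltzmann_k: float = BOLTZMANN_K

    def __post_init__(self) -> None:
        for name in ("temperature", "viscosity", "boltzmann_k"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class BindingMeasurement:
    """Diffusion coefficients and analytical concentrations for one
    host-guest binding determination.

    All diffusion coefficients in m²/s, concentrations in mol/L.
    ``D_guest_observed`` is the single averaged value seen for the guest in
    the host-containing sample; ``D_guest_free`` comes from a host-free
    reference sample of matched viscosity.
    """

    D_guest_free: float
    D_guest_observed: float
    D_host: float
    c_guest: float
    c_host: float

    def __post_init__(self) -> None:
        for name in ("D_guest_free", "D_guest_observed", "D_host", "c_guest", "c_host"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not self.D_host < self.D_guest_free:
            raise ValueError(
                "D_host must be smaller than D_guest_free "
                "(the host is the larger, slower species)"
            )


@dataclass(frozen=True)
class BindingResult:
    """Bound fraction, association constant and equilibrium speciation."""

    bound_fraction: float
    K: float  # L/mol
    conc_complex: float  # mol/L
    conc_free_guest: float  # mol/L
    conc_free_host: float  # mol/L
    c_guest: float = field(default=float("nan"))
    c_host: float = field(default=float("nan"))

    def as_dict(self) -> dict:
        return {
            "bound_fraction": self.bound_fraction,
            "K_per_molar": self.K,
            "conc_complex_M": self.conc_complex,
            "conc_free_guest_M": self.conc_free_guest,
            "conc_free_host_M": self.conc_free_host,
        }


@dataclass(frozen=True)
class ViscosityCheck:
    """Cross-sample comparison of D for one non-binding reference species."""

    species_id: str
    D_sample_a: float
    D_sample_b: float
    relative_difference: float
    tolerance: float
    passed: bool


def bound_fraction_from_diffusion(
    m: BindingMeasurement,
    bracket_tolerance: float = DEFAULT_D_BRACKET_TOL,
) -> float:
    """Bound molar fraction of the guest from the fast-exchange model.

    The observed guest diffusion coefficient is the population-weighted
    average of the free-guest and complex (≈ host) values, so

        f = (D_free − D_obs) / (D_free − D_host).

    Observed values overshooting the [D_host, D_free] bracket by up to
    ``bracket_tolerance`` (fractional, relative to the bracket width) are
    clamped to the boundary with a warning; larger excursions raise
    :class:`InconsistentDataError`.

    Raises
    ------
    NonIdentifiableError
        If D_free and D_host agree to within ``bracket_tolerance`` of
        D_free so the weighting is not identifiable.
    """

    span = m.D_guest_free - m.D_host
    if span <= bracket_tolerance * m.D_guest_free:
        raise NonIdentifiableError(
            "D_guest_free and D_host are too close: the bound fraction is "
            "not identifiable from the weighted-average model"
        )
    f = (m.D_guest_free - m.D_guest_observed) / span
    if f < 0 or f > 1:
        overshoot = max(-f, f - 1.0)
        if overshoot > bracket_tolerance:
            raise InconsistentDataError(
                f"observed D {m.D_guest_observed:g} lies outside "
                f"[{m.D_host:g}, {m.D_guest_free:g}] beyond the "
                f"{bracket_tolerance:.1%} tolerance"
            )
        clamped = min(max(f, 0.0), 1.0)
        warnings.warn(
            f"observed guest D slightly outside the [D_host, D_free] "
            f"bracket; bound fraction clamped from {f:.4f} to {clamped:.1f}",
            stacklevel=2,
        )
        f = clamped
    return f


def association_constant(
    bound_fraction: float, c_guest: float, c_host: float
) -> BindingResult:
    """1:1 association constant and equilibrium concentrations.

    Parameters
    ----------
    bound_fraction : float
        Fraction of guest molecules in the complex, in [0, 1).
    c_guest, c_host : float
        Analytical (total) concentrations, mol/L.

    Returns
    -------
    BindingResult
        With ``K = f / ((c_host − f·c_guest)(1 − f))`` in L/mol and the
        mass-balance-consistent equilibrium concentrations.
    """

    f = bound_fraction
    if not 0.0 <= f < 1.0:
        raise ValueError(
            "bound_fraction must lie in [0, 1); K diverges at full binding"
        )
    if c_guest <= 0 or c_host <= 0:
        raise ValueError("concentrations must be positive")
    free_host = c_host - f * c_guest
    if free_host <= 0:
        raise ValueError(
            "free host concentration would be non-positive: bound fraction "
            "exceeds what the host supply permits (impossible stoichiometry)"
        )
    K = f / (free_host * (1.0 - f))
    return BindingResult(
        bound_fraction=f,
        K=K,
        conc_complex=f * c_guest,
        conc_free_guest=(1.0 - f) * c_guest,
        conc_free_host=free_host,
        c_guest=c_guest,
        c_host=c_host,
    )


def fraction_from_K(K: float, c_guest: float, c_host: float) -> float:
    """Bound guest fraction at equilibrium for a 1:1 complex.

    Solves the mass-balance relation ``K·(c_host − f·c_guest)·(1 − f) = f``
    for the unique physically admissible root f ∈ [0, 1].  The relation is a
    quadratic in f; the smaller root is the physical branch (the larger one
    exceeds min(1, c_host/c_guest)).

    Parameters
    ----------
    K : float
        Association constant, L/mol (≥ 0).
    c_guest, c_host : float
        Analytical concentrations, mol/L (> 0).
    """

    if K < 0:
        raise ValueError("K must be non-negative")
    if c_guest <= 0 or c_host <= 0:
        raise ValueError("concentrations must be positive")
    if K == 0.0:
        return 0.0
    # K·c_guest·f² − (K·(c_guest + c_host) + 1)·f + K·c_host = 0
    a = K * c_guest
    b = -(K * (c_guest + c_host) + 1.0)
    c = K * c_host
    disc = b * b - 4.0 * a * c
    if disc < 0:
        raise ArithmeticError("negative discriminant: no real bound fraction")
    # b < 0 always; the smaller (physical) root via the Citardauq form
    # 2c / (-b + sqrt(disc)) avoids cancellation when K·c is small.
    f = 2.0 * c / (-b + math.sqrt(disc))
    if not -1e-12 <= f <= 1.0 + 1e-12:
        raise ArithmeticError(
            f"no root in [0, 1] (got {f!r}); numerical failure for "
            f"K={K}, c_guest={c_guest}, c_host={c_host}"
        )
    f = min(max(f, 0.0), 1.0)
    residual = K * (c_host - f * c_guest) * (1.0 - f) - f
    if abs(residual) > 1e-10 * max(1.0, K * c_host):
        raise ArithmeticError(
            f"mass-balance residual {residual:g} above tolerance"
        )
    return f


def stokes_einstein_radius(D: float, ctx: HydrodynamicContext | None = None) -> float:
    """Hydrodynamic radius r = k_B·T / (6π·η·D), in metres."""

    if ctx is None:
        ctx = HydrodynamicContext()
    if not D > 0:
        raise ValueError("D must be positive")
    return ctx.boltzmann_k * ctx.temperature / (6.0 * math.pi * ctx.viscosity * D)


def viscosity_match(
    records_a: Sequence[DiffusionRecord],
    records_b: Sequence[DiffusionRecord],
    reference_species: Sequence[str],
    tolerance: float = DEFAULT_VISCOSITY_MATCH_TOL,
) -> list[ViscosityCheck]:
    """Check that two samples have comparable viscosity.

    Diffusion coefficients of species not involved in complex formation
    (ideally the residual-water HDO signal) should agree between samples if
    the viscosities match; otherwise diffusion-based bound fractions are not
    comparable across the samples.

    Returns one :class:`ViscosityCheck` per reference species; overall
    agreement holds iff every check passes.

    Raises
    ------
    KeyError
        If a reference species is missing from either sample.
    """

    def lookup(records: Sequence[DiffusionRecord], species: str, label: str) -> float:
        for r in records:
            if r.species_id == species:
                return r.D
        raise KeyError(
            f"reference species {species!r} not found in sample {label}"
        )

    checks = []
    for species in reference_species:
        d_a = lookup(records_a, species, "a")
        d_b = lookup(records_b, species, "b")
        rel = abs(d_a - d_b) / max(d_a, d_b)
        checks.append(
            ViscosityCheck(
                species_id=species,
                D_sample_a=d_a,
                D_sample_b=d_b,
                relative_difference=rel,
                tolerance=tolerance,
                passed=rel <= tolerance,
            )
        )
    return checks
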