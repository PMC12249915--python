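"""Formulation arithmetic for lyophilised cyclodextrin systems.

Covers the bookkeeping around a freeze-dried host-guest formulation: the
average molar mass of a randomly substituted cyclodextrin lot (from degree
of substitution and water content), batch composition from molar ratios,
reconstitution concentrations, solubility-enhancement factors, stability
series summaries and first-order t90 shelf-life arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
__all__ = [
    "CDSpec",
    "CompoundSpec",
    "Recipe",
    "StabilitySeries",
    "StabilitySummary",
    "cd_molar_mass",
    "batch_composition",
    "mass_from_moles",
    "solution_concentration",
    "enhancement_factor",
    "stability_summary",
    "t90_first_order",
    "rate_constant_from_t90",
]


@dataclass(frozen=True)
class CDSpec:
    """A randomly substituted cyclodextrin lot.

    Parameters
    ----------
    parent_mass : float
        Anhydrous parent macrocycle molar mass, g/mol (β-CD: 1134.98).
    substituent_net_mass : float
        Net mass added per substitution, g/mol (sodium sulfobutyl ether
        replacing a hydroxyl hydrogen: +158.15).
    DS : float
        Average degree of substitution of the lot.
    water_fraction : float
        Mass fraction of water in the as-received material, in [0, 1).
    """

    parent_mass: float
    substituent_net_mass: float
    DS: float
    water_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.parent_mass <= 0:
            raise ValueError("parent_mass must be positive")
        if self.DS < 0:
            raise ValueError("DS must be non-negative")
        if not 0.0 <= self.water_fraction < 1.0:
            raise ValueError("water_fraction must lie in [0, 1)")


@dataclass(frozen=True)
class CompoundSpec:
    """A registry compound with at least a name and molar mass (g/mol)."""

    name: str
    molar_mass: float
    formula: str | None = None
    pKa_list: tuple[float, ...] = ()
    note: str = ""

    def __post_init__(self) -> None:
        if not self.molar_mass > 0:
            raise ValueError(f"{self.name}: molar_mass must be positive")


@dataclass(frozen=True)
class Recipe:
    """Molar-ratio recipe anchored to one reference component.

    ``components`` pairs each compound with its molar ratio; exactly one
    component name must equal ``reference_component``.  The batch is scaled
    so the reference component weighs ``target_reference_mass`` grams.
    """

    components: tuple[tuple[CompoundSpec, float], ...]
    reference_component: str
    target_reference_mass: float  # g
    solvent_volume: float | None = None  # L

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple(self.components))
        names = [c.name for c, _ in self.components]
        if names.count(self.reference_component) != 1:
            raise ValueError(
                f"recipe must contain exactly one reference component "
                f"{self.reference_component!r}; found {names}"
            )
        if any(r <= 0 for _, r in self.components):
            raise ValueError("molar ratios must be positive")
        if self.target_reference_mass <= 0:
            raise ValueError("target_reference_mass must be positive")


@dataclass(frozen=True)
class StabilitySeries:
    """Reconstitution-concentration time series for one stored formulation."""

    timestamps: tuple[float, ...]  # months
    concentration: tuple[float, ...]  # mg/mL
    sum_degradation_products: tuple[float, ...] | None = None  # percent

    def __post_init__(self) -> None:
        object.__setattr__(self, "timestamps", tuple(self.timestamps))
        object.__setattr__(self, "concentration", tuple(self.concentration))
        if len(self.timestamps) != len(self.concentration):
            raise ValueError("timestamps and concentration differ in length")
        if any(b <= a for a, b in zip(self.timestamps, self.timestamps[1:])):
            raise ValueError("timestamps must be strictly increasing")
        if any(c < 0 for c in self.concentration):
            raise ValueError("concentrations must be non-negative")
        if self.sum_degradation_products is not None:
            dp = tuple(self.sum_degradation_products)
            if len(dp) != len(self.timestamps):
                raise ValueError("sum_degradation_products length mismatch")
            object.__setattr__(self, "sum_degradation_products", dp)


@dataclass(frozen=True)
class StabilitySummary:
    """Percent changes of a stability series."""

    interval_percent_change: tuple[float, ...]
    total_drift_percent: float
    dp_delta_percent: float | None


def cd_molar_mass(spec: CDSpec) -> float:
    """As-is (hydrated basis) average molar mass of a substituted CD lot.

    (parent + DS × net substituent mass) / (1 − water fraction), g/mol.
    Dividing by the dry-mass fraction converts the anhydrous average to the
    mass one actually weighs out per mole of macrocycle.
    """

    anhydrous = spec.parent_mass + spec.DS * spec.substituent_net_mass
    return anhydrous / (1.0 - spec.water_fraction)


def batch_composition(recipe: Recipe) -> dict[str, float]:
    """Per-component masses (g) for a molar-ratio batch, plus ``"total"``.

    mass_i = (ratio_i / ratio_ref) · (m_ref / M_ref) · M_i — i.e. all
    components share the mole scale set by the reference component.
    """

    ref = next(
        (c, r) for c, r in recipe.components if c.name == recipe.reference_component
    )
    ref_moles = recipe.target_reference_mass / ref[0].molar_mass
    masses: dict[str, float] = {}
    for compound, ratio in recipe.components:
        moles = ratio / ref[1] * ref_moles
        masses[compound.name] = moles * compound.molar_mass
    masses["total"] = sum(masses.values())
    return masses


def mass_from_moles(compound: CompoundSpec, moles: float) -> float:
    """Mass in grams of ``moles`` mol of a compound."""

    if moles < 0:
        raise ValueError("moles must be non-negative")
    return moles * compound.molar_mass


def solution_concentration(mass_g: float, volume_l: float) -> float:
    """Concentration in mg/mL of ``mass_g`` grams dissolved in ``volume_l``
    litres (numerically equal to g/L)."""

    if volume_l <= 0:
        raise ValueError("volume must be positive")
    if mass_g < 0:
        raise ValueError("mass must be non-negative")
    return mass_g / volume_l


def enhancement_factor(s_new: float, s_ref: float) -> float:
    """Fold-change in solubility (same units for both arguments)."""

    if s_ref <= 0:
        raise ValueError("reference solubility must be positive")
    return s_new / s_ref


def stability_summary(series: StabilitySeries) -> StabilitySummary:
    """Percent drift of a stability series.

    Returns per-interval percent changes between consecutive time points,
    total first-to-last drift, and (when degradation-product data are
    present) the last-minus-first change in summed degradation products.
    """

    conc = series.concentration
    if len(conc) < 2:
        raise ValueError("stability series needs at least two time points")
    if conc[0] == 0:
        raise ValueError("initial concentration must be non-zero")
    intervals = tuple(
        (b - a) / a * 100.0 for a, b in zip(conc, conc[1:])
    )
    total = (conc[-1] - conc[0]) / conc[0] * 100.0
    dp_delta = None
    if series.sum_degradation_products is not None:
        dp = series.sum_degradation_products
        dp_delta = dp[-1] - dp[0]
    return StabilitySummary(
        interval_percent_change=intervals,
        total_drift_percent=total,
        dp_delta_percent=dp_delta,
    )


def t90_first_order(k: float) -> float:
    """Time for a 10% concentration drop under first-order kinetics.

    t90 = ln(10/9) / k, in the time unit of 1/k.
    """

    if k <= 0:
        raise ValueError("rate constant must be positive")
    return math.log(10.0 / 9.0) / k


def rate_constant_from_t90(t90: float) -> float:
    """First-order rate constant from a t90 value (inverse of
    :func:`t90_first_order`)."""

    if t90 <= 0:
        raise ValueError("t90 must be positive")
    return math.log(10.0 / 9.0) / t90
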