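"""Acid-base speciation and pH under the ideal-solution approximation.

Protonation fractions follow the Henderson-Hasselbalch relation; polyprotic
acids are treated with the standard cumulative-Ka partition over their
protonation microstates.  Solution pH comes from the charge balance

    [H+] + c_Na − [OH−] − Σ_i C_i · q̄_i(pH) = 0

where q̄_i is the average number of protons lost by acid i at the given pH
and c_Na collects inert counter-cations (e.g. Na⁺ introduced by base
addition).  Activity coefficients are taken as unity throughout, so computed
pH values for concentrated, high-ionic-strength samples are approximate.

Neutralisation with sodium hydrogencarbonate is modelled as
H⁺ + HCO₃⁻ → H₂O + CO₂↑ with the CO₂ escaping the open system: each mole of
NaHCO₃ leaves one mole of inert Na⁺ behind and no conjugate base, which is
what makes the dosing arithmetic a pure counter-ion addition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .constants import KW

__all__ = [
    "AcidSpec",
    "IonisationProfile",
    "MixtureComponent",
    "MixtureSpec",
    "fraction_protonated",
    "microstate_fractions",
    "speciation",
    "solve_pH",
    "bicarbonate_dose",
]


@dataclass(frozen=True)
class AcidSpec:
    """An n-protic acid.

    Parameters
    ----------
    name : str
    pKa_list : tuple of float
        Successive pKa values, strictly increasing.
    molar_mass : float
        g/mol.
    volatile : bool
        Whether the acid sublimates from a frozen solution during
        freeze-drying (liquid acids) or stays in the solid (solid acids,
        which then form ternary systems).
    physical_state : str
        ``"liquid"``, ``"solid"`` or ``"gas"`` at room temperature.
    """

    name: str
    pKa_list: tuple[float, ...]
    molar_mass: float
    volatile: bool = False
    physical_state: str = "solid"

    def __post_init__(self) -> None:
        object.__setattr__(self, "pKa_list", tuple(float(p) for p in self.pKa_list))
        if len(self.pKa_list) == 0:
            raise ValueError(f"{self.name}: pKa_list must not be empty")
        if any(b <= a for a, b in zip(self.pKa_list, self.pKa_list[1:])):
            raise ValueError(f"{self.name}: pKa_list must be strictly increasing")
        if not self.molar_mass > 0:
            raise ValueError(f"{self.name}: molar_mass must be positive")
        if self.physical_state not in ("liquid", "solid", "gas"):
            raise ValueError(f"{self.name}: unknown physical_state")

    @property
    def n_protons(self) -> int:
        return len(self.pKa_list)


@dataclass(frozen=True)
class IonisationProfile:
    """Speciation of one acid over a pH grid.

    ``species_fractions[i, j]`` is the fraction of microstate j (j protons
    removed; j = 0 is the fully protonated form) at ``pH_grid[i]``.
    ``net_charge`` is the average charge per acid molecule (0 … −n).
    """

    acid: AcidSpec
    pH_grid: np.ndarray
    species_fractions: np.ndarray
    net_charge: np.ndarray

    def to_frame(self):
        """Long-format pandas DataFrame (pH, species, fraction)."""
        import pandas as pd

        n = self.acid.n_protons
        cols = {f"H{n - j}A" if n - j > 0 else "A": self.species_fractions[:, j]
                for j in range(n + 1)}
        frame = pd.DataFrame({"pH": self.pH_grid, **cols})
        frame["net_charge"] = self.net_charge
        return frame


@dataclass(frozen=True)
class MixtureComponent:
    """One mixture constituent: an acid, or an inert strong-base cation.

    ``kind="acid"`` requires ``acid``; ``kind="strong_base"`` models fully
    dissociated inert counter-cations (Na⁺) at the given concentration.
    """

    concentration: float  # mol/L
    acid: AcidSpec | None = None
    kind: str = "acid"

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be non-negative")
        if self.kind == "acid" and self.acid is None:
            raise ValueError("acid component requires an AcidSpec")
        if self.kind not in ("acid", "strong_base"):
            raise ValueError(f"unknown component kind {self.kind!r}")


@dataclass(frozen=True)
class MixtureSpec:
    """Aqueous mixture of acids and inert counter-cations."""

    components: tuple[MixtureComponent, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple(self.components))

    @classmethod
    def of_acids(cls, *pairs: tuple[AcidSpec, float]) -> "MixtureSpec":
        return cls(tuple(MixtureComponent(conc, acid=a) for a, conc in pairs))

    def with_counter_ion(self, concentration: float) -> "MixtureSpec":
        """Mixture with additional inert cation (e.g. Na⁺ from dosing)."""
        extra = MixtureComponent(concentration, kind="strong_base")
        return MixtureSpec(self.components + (extra,))


def fraction_protonated(pH: float, pKa: float) -> float:
    """Fraction of a single ionisable group carrying its proton.

    Henderson-Hasselbalch: 1 / (1 + 10^(pH − pKa)).  Total function of
    finite inputs; 0.5 at pH = pKa.
    """

    return 1.0 / (1.0 + 10.0 ** (np.asarray(pH, dtype=float) - pKa))


def microstate_fractions(acid: AcidSpec, pH) -> np.ndarray:
    """Fractions of the n+1 protonation microstates of ``acid``.

    Column j is the species with j protons removed.  Computed from the
    cumulative-Ka partition in log10 space for numerical stability:
    log w_j = j·pH − Σ_{k≤j} pKa_k, normalised so fractions sum to 1.
    """

    pH = np.atleast_1d(np.asarray(pH, dtype=float))
    cum_pKa = np.concatenate(([0.0], np.cumsum(acid.pKa_list)))
    j = np.arange(acid.n_protons + 1)
    logw = np.outer(pH, j) - cum_pKa  # shape (n_pH, n+1)
    logw -= logw.max(axis=1, keepdims=True)
    w = 10.0 ** logw
    return w / w.sum(axis=1, keepdims=True)


def speciation(acid: AcidSpec, pH_grid) -> IonisationProfile:
    """Full speciation profile of a polyprotic acid over a pH grid."""

    pH_grid = np.atleast_1d(np.asarray(pH_grid, dtype=float))
    fractions = microstate_fractions(acid, pH_grid)
    j = np.arange(acid.n_protons + 1)
    net_charge = -(fractions * j).sum(axis=1)
    return IonisationProfile(
        acid=acid, pH_grid=pH_grid, species_fractions=fractions, net_charge=net_charge
    )


def _charge_balance(pH: float, mixture: MixtureSpec) -> float:
    h = 10.0 ** (-pH)
    resid = h - KW / h
    for comp in mixture.components:
        if comp.concentration == 0:
            continue
        if comp.kind == "strong_base":
            resid += comp.concentration
        else:
            fr = microstate_fractions(comp.acid, pH)[0]
            avg_deprotonated = float(
                (fr * np.arange(comp.acid.n_protons + 1)).sum()
            )
            resid -= comp.concentration * avg_deprotonated
    return resid


def solve_pH(mixture: MixtureSpec) -> float:
    """Ideal-solution pH by safeguarded root-finding on the charge balance.

    Brackets the root on pH ∈ [0, 14]; raises if the charge balance has no
    sign change there (e.g. an excess of inert cations with no acid to
    neutralise would need pH > 14).
    """

    if len(mixture.components) == 0:
        return -0.5 * np.log10(KW)  # pure water
    lo, hi = 0.0, 14.0
    f_lo, f_hi = _charge_balance(lo, mixture), _charge_balance(hi, mixture)
    if f_lo * f_hi > 0:
        raise ValueError(
            "charge balance has no root in pH [0, 14] for this mixture"
        )
    return float(brentq(_charge_balance, lo, hi, args=(mixture,), xtol=1e-12))


def bicarbonate_dose(mixture: MixtureSpec, target_pH: float) -> float:
    """Moles of NaHCO₃ per litre needed to raise the mixture to ``target_pH``.

    The hydrogencarbonate anion consumes one proton and leaves as CO₂, so a
    dose b is equivalent to adding b mol/L of inert Na⁺ to the charge
    balance.  The pH is strictly increasing in the dose; the dose solving
    pH(mixture + b) = target is found by bracketing + Brent.

    Raises
    ------
    ValueError
        If ``target_pH`` is below the mixture's current pH.
    """

    current = solve_pH(mixture)
    if target_pH < current - 1e-9:
        raise ValueError(
            f"target pH {target_pH:.3f} is below the current pH {current:.3f}"
        )
    if abs(target_pH - current) <= 1e-9:
        return 0.0

    def excess(b: float) -> float:
        return solve_pH(mixture.with_counter_ion(b)) - target_pH

    hi = 1e-6
    while excess(hi) < 0:
        hi *= 2.0
        if hi > 1e3:
            raise ValueError("target pH unreachable by bicarbonate dosing")
    return float(brentq(excess, 0.0, hi, xtol=1e-15, rtol=1e-12))
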