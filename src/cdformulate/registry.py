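"""Compound, acid and cyclodextrin registry.

Loads the packaged YAML registry (``data/compounds.yaml``) or a user-supplied
override file of the same shape, and materialises the typed specs the other
modules consume.  The substituted-cyclodextrin molar mass is always computed
from its structural description (parent mass, degree of substitution, water
fraction) rather than stored.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .formulation import CDSpec, CompoundSpec, cd_molar_mass
from .ionisation import AcidSpec

__all__ = [
    "load_registry",
    "get_compound",
    "get_acid",
    "get_cd",
    "cd_compound",
]


def load_registry(path: str | Path | None = None) -> dict:
    """Parsed registry dictionary (packaged default unless ``path`` given)."""

    if path is None:
        text = (
            resources.files("cdformulate").joinpath("data/compounds.yaml").read_text()
        )
    else:
        text = Path(path).read_text()
    reg = yaml.safe_load(text)
    if not isinstance(reg, dict) or "compounds" not in reg:
        raise ValueError("registry must be a mapping with a 'compounds' section")
    return reg


def get_compound(name: str, registry: dict | None = None) -> CompoundSpec:
    """CompoundSpec for a registry entry (``KeyError`` names the compound)."""

    reg = registry if registry is not None else load_registry()
    try:
        entry = reg["compounds"][name]
    except KeyError:
        raise KeyError(f"compound {name!r} not in registry") from None
    pKa = tuple(entry.get("acid", {}).get("pKa", ()))
    return CompoundSpec(
        name=name,
        molar_mass=float(entry["molar_mass"]),
        formula=entry.get("formula"),
        pKa_list=pKa,
        note=entry.get("note", ""),
    )


def get_acid(name: str, registry: dict | None = None) -> AcidSpec:
    """AcidSpec for a registry compound that has an ``acid`` section."""

    reg = registry if registry is not None else load_registry()
    try:
        entry = reg["compounds"][name]
    except KeyError:
        raise KeyError(f"compound {name!r} not in registry") from None
    if "acid" not in entry:
        raise KeyError(f"compound {name!r} has no acid parameters in the registry")
    return AcidSpec(
        name=name,
        pKa_list=tuple(entry["acid"]["pKa"]),
        molar_mass=float(entry["molar_mass"]),
        volatile=bool(entry.get("volatile", False)),
        physical_state=entry.get("physical_state", "solid"),
    )


def get_cd(name: str = "sbe_beta_cd", registry: dict | None = None) -> CDSpec:
    """CDSpec for a registry cyclodextrin lot."""

    reg = registry if registry is not None else load_registry()
    try:
        entry = reg["cyclodextrins"][name]
    except KeyError:
        raise KeyError(f"cyclodextrin {name!r} not in registry") from None
    return CDSpec(
        parent_mass=float(entry["parent_mass"]),
        substituent_net_mass=float(entry["substituent_net_mass"]),
        DS=float(entry["DS"]),
        water_fraction=float(entry.get("water_fraction", 0.0)),
    )


def cd_compound(name: str = "sbe_beta_cd", registry: dict | None = None) -> CompoundSpec:
    """Substituted CD as a CompoundSpec with its computed as-is molar mass."""

    spec = get_cd(name, registry)
    return CompoundSpec(
        name=name,
        molar_mass=cd_molar_mass(spec),
        note="as-is molar mass computed from DS and water content",
    )
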