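"""Readers, writers and unit handling for the tabular interfaces.

Every numeric table carries explicit unit strings (``D_unit`` columns,
quantity suffixes such as ``"1.917mM"``); values are normalised to SI
(m²/s, mol/L) on ingest.  Mandatory units guard against the magnitude
mix-ups that scaled diffusion coefficients (1e-10 m²/s) and millimolar
concentrations invite.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from . import __version__
from .binding import DiffusionRecord
from .formulation import Recipe, StabilitySeries
from .ionisation import MixtureComponent, MixtureSpec
from . import registry as _registry

__all__ = [
    "SchemaError",
    "RunConfig",
    "parse_concentration",
    "parse_mass",
    "parse_diffusion_unit",
    "load_diffusion_table",
    "write_diffusion_table",
    "load_concentrations",
    "load_recipe",
    "load_mixture",
    "load_stability_series",
    "make_report",
    "write_report",
]


class SchemaError(ValueError):
    """A table or config file violates the expected schema."""


@dataclass(frozen=True)
class RunConfig:
    """Run-level configuration: seeds, tolerances, output location."""

    seed: int = 0
    output_dir: Path = Path(".")
    viscosity_match_tolerance: float = 0.02
    d_bracket_tolerance: float = 0.01
    registry_path: Path | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.viscosity_match_tolerance <= 0 or self.d_bracket_tolerance <= 0:
            raise ValueError("tolerances must be positive")
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer")


_CONC_UNITS = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6, "nM": 1e-9}
_MASS_UNITS = {"kg": 1e3, "g": 1.0, "mg": 1e-3, "ug": 1e-6, "µg": 1e-6}


def parse_mass(text: str) -> float:
    """Mass string with mandatory unit -> grams (e.g. ``"1mg"``, ``"53.5 mg"``)."""

    m = re.fullmatch(r"\s*([0-9.eE+-]+)\s*([a-zA-Zµ]+)\s*", str(text))
    if not m or m.group(2) not in _MASS_UNITS:
        raise SchemaError(
            f"cannot parse mass {text!r}; expected a number with unit "
            f"{sorted(_MASS_UNITS)}"
        )
    return float(m.group(1)) * _MASS_UNITS[m.group(2)]


def parse_concentration(text: str | float) -> float:
    """Concentration string with mandatory unit -> mol/L.

    Accepts e.g. ``"1.917mM"``, ``"22.5 mM"``, ``"0.01 M"``.  Bare numbers
    are rejected: the unit must be explicit.
    """

    if isinstance(text, (int, float)):
        raise SchemaError(
            f"concentration {text!r} lacks a unit; write e.g. '{text}mM'"
        )
    m = re.fullmatch(r"\s*([0-9.eE+-]+)\s*([a-zA-Zµ]+)\s*", text)
    if not m:
        raise SchemaError(f"cannot parse concentration {text!r}")
    value, unit = m.groups()
    if unit not in _CONC_UNITS:
        raise SchemaError(
            f"unknown concentration unit {unit!r}; expected one of "
            f"{sorted(_CONC_UNITS)}"
        )
    return float(value) * _CONC_UNITS[unit]


def parse_diffusion_unit(unit: str) -> float:
    """Diffusion-coefficient unit string -> multiplier to m²/s.

    Accepts ``"m2/s"`` optionally preceded by a power-of-ten factor, e.g.
    ``"1e-10 m2/s"`` (the conventional DOSY reporting scale) or ``"um2/s"``.
    """

    unit = unit.strip()
    if unit in ("m2/s", "m^2/s", "m**2/s"):
        return 1.0
    if unit in ("um2/s", "µm2/s"):
        return 1e-12
    m = re.fullmatch(r"([0-9.eE+-]+)\s*m\^?2/s", unit)
    if m:
        return float(m.group(1))
    raise SchemaError(f"cannot parse diffusion unit {unit!r}")


_DIFFUSION_COLUMNS = ("sample_id", "species_id", "D_value", "D_unit")


def load_diffusion_table(path: str | Path) -> list[DiffusionRecord]:
    """Read a diffusion CSV (sample_id, species_id, D_value, D_unit) into
    SI-normalised :class:`~cdformulate.binding.DiffusionRecord` objects.

    Lines starting with ``#`` are comments.  A missing column raises
    :class:`SchemaError` naming it; a bad value names its row.
    """

    frame = pd.read_csv(path, comment="#", skipinitialspace=True)
    for col in _DIFFUSION_COLUMNS:
        if col not in frame.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    records = []
    for idx, row in frame.iterrows():
        try:
            records.append(
                DiffusionRecord(
                    species_id=str(row["species_id"]),
                    D=float(row["D_value"]) * parse_diffusion_unit(str(row["D_unit"])),
                    sample_id=str(row["sample_id"]),
                )
            )
        except (ValueError, SchemaError) as exc:
            raise SchemaError(f"{path}: row {idx}: {exc}") from exc
    return records


def write_diffusion_table(
    records: Iterable[DiffusionRecord],
    path: str | Path,
    unit: str = "1e-10 m2/s",
    header_comment: str | None = None,
) -> Path:
    """Write diffusion records as CSV on the given reporting scale."""

    factor = parse_diffusion_unit(unit)
    frame = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "species_id": [r.species_id for r in records],
            "D_value": [r.D / factor for r in records],
            "D_unit": unit,
        }
    )
    path = Path(path)
    with path.open("w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        frame.to_csv(fh, index=False)
    return path


def load_concentrations(path: str | Path) -> dict[str, dict[str, float]]:
    """YAML/JSON sidecar of analytical concentrations -> mol/L.

    Shape: ``{sample_id: {species_id: "1.917mM", ...}, ...}``.
    """

    path = Path(path)
    data = (
        json.loads(path.read_text())
        if path.suffix == ".json"
        else yaml.safe_load(path.read_text())
    )
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: expected a mapping of samples")
    out: dict[str, dict[str, float]] = {}
    for sample, species in data.items():
        if not isinstance(species, dict):
            raise SchemaError(f"{path}: sample {sample!r} must map species to values")
        out[sample] = {s: parse_concentration(v) for s, v in species.items()}
    return out


def load_recipe(
    path: str | Path,
    name: str | None = None,
    target_reference_mass: float | None = None,
    reg: dict | None = None,
) -> Recipe:
    """Load a molar-ratio recipe from YAML, resolving molar masses through
    the compound registry.

    The file holds either one recipe mapping or a ``recipes:`` collection
    (then ``name`` selects one).  Recipe shape::

        components:
          - {compound: ceftobiprole, ratio: 1}
          - {compound: maleic_acid, ratio: 25}
          - {compound: sbe_beta_cd, ratio: 4}
        reference: ceftobiprole
        reference_mass_mg: 1.0       # overridable via target_reference_mass (g)
    """

    data = yaml.safe_load(Path(path).read_text())
    if "recipes" in data:
        try:
            data = data["recipes"][name]
        except KeyError:
            raise SchemaError(f"{path}: no recipe named {name!r}") from None
    if reg is None:
        reg = _registry.load_registry()
    components = []
    for comp in data["components"]:
        cname = comp["compound"]
        if cname in reg.get("cyclodextrins", {}):
            spec = _registry.cd_compound(cname, reg)
        else:
            try:
                spec = _registry.get_compound(cname, reg)
            except KeyError:
                raise SchemaError(
                    f"{path}: no molar mass available for component {cname!r}"
                ) from None
        components.append((spec, float(comp["ratio"])))
    if target_reference_mass is None:
        target_reference_mass = float(data.get("reference_mass_mg", 1.0)) * 1e-3
    return Recipe(
        components=tuple(components),
        reference_component=data["reference"],
        target_reference_mass=target_reference_mass,
        solvent_volume=data.get("solvent_volume_l"),
    )


def load_mixture(path: str | Path, reg: dict | None = None) -> MixtureSpec:
    """Load an aqueous mixture description from YAML.

    Shape::

        components:
          - {acid: citric_acid, conc: "16.8 mM"}
          - {strong_base: true, conc: "5 mM"}     # inert counter-cation
    """

    data = yaml.safe_load(Path(path).read_text())
    if reg is None:
        reg = _registry.load_registry()
    components = []
    for comp in data["components"]:
        conc = parse_concentration(comp["conc"])
        if comp.get("strong_base"):
            components.append(MixtureComponent(conc, kind="strong_base"))
        else:
            components.append(
                MixtureComponent(conc, acid=_registry.get_acid(comp["acid"], reg))
            )
    return MixtureSpec(tuple(components))


def load_stability_series(path: str | Path) -> StabilitySeries:
    """CSV (time_months, conc_mg_per_ml[, sum_dp_percent]) -> series."""

    frame = pd.read_csv(path, comment="#", skipinitialspace=True)
    for col in ("time_months", "conc_mg_per_ml"):
        if col not in frame.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    dp = (
        tuple(frame["sum_dp_percent"].astype(float))
        if "sum_dp_percent" in frame.columns
        else None
    )
    return StabilitySeries(
        timestamps=tuple(frame["time_months"].astype(float)),
        concentration=tuple(frame["conc_mg_per_ml"].astype(float)),
        sum_degradation_products=dp,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def make_report(
    results: dict,
    inputs: Sequence[str | Path] = (),
    config: dict | None = None,
    timestamp: str | None = None,
) -> dict:
    """Machine-readable run report: results, input hashes, config echo.

    Deterministic for identical inputs apart from the optional timestamp.
    """

    return {
        "package": "cdformulate",
        "version": __version__,
        "inputs": {str(p): _sha256(Path(p)) for p in inputs},
        "config": config or {},
        "results": results,
        **({"timestamp": timestamp} if timestamp is not None else {}),
    }


def write_report(report: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return path
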