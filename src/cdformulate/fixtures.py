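"""Deterministic scenario fixtures.

Writes the study's reported measurement scenarios as plain-text data files
(no RNG involved): the DOSY diffusion table for the dilute maleate samples
with and without cyclodextrin, the analytical concentrations, the molar-ratio
recipes of every prepared system, reconstitution-solubility bookkeeping, and
the solid-state stability series.  Each file carries a provenance comment
describing what the numbers are; regeneration is byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .binding import DiffusionRecord
from .io import write_diffusion_table

__all__ = ["make_fixtures"]

_D_SCALE = 1e-10  # reporting convention: diffusion in 1e-10 m2/s

#: Reported diffusion coefficients (1e-10 m²/s) of the two dilute DOSY
#: samples: the ternary drug/maleic acid/SBE-β-CD system (1:25:4) at 1.9 mM
#: drug, and its CD-free 1:25 counterpart at matched viscosity.
_DOSY_TABLE = [
    # (sample_id, species_id, D / 1e-10 m2/s)
    ("maleate_1to25to4_dilute", "guest_observed", 2.68),
    ("maleate_1to25to4_dilute", "host", 1.79),
    ("maleate_1to25to4_dilute", "HDO", 18.47),
    ("maleate_1to25to4_dilute", "maleic_acid", 7.19),
    ("maleate_1to25_dilute", "guest", 3.16),
    ("maleate_1to25_dilute", "HDO", 18.42),
    ("maleate_1to25_dilute", "maleic_acid", 7.11),
]

_CONCENTRATIONS = {
    "maleate_1to25to4_dilute": {"guest": "1.917mM", "host": "7.667mM"},
    "maleate_1to25_dilute": {"guest": "7.5mM"},
}

_RECIPES = {
    "formic_1to2": {
        "components": [
            {"compound": "ceftobiprole", "ratio": 1},
            {"compound": "sbe_beta_cd", "ratio": 2},
        ],
        "reference": "ceftobiprole",
        "solvent": "0.1 M formic acid",
        "note": "binary system freeze-dried from a volatile-acid solution",
    },
    "hcl_1to2": {
        "components": [
            {"compound": "ceftobiprole", "ratio": 1},
            {"compound": "sbe_beta_cd", "ratio": 2},
        ],
        "reference": "ceftobiprole",
        "solvent": "0.01 M hydrochloric acid",
        "note": "volatile strong acid; abandoned after solid-state degradation",
    },
    "citrate_1to100to1": {
        "components": [
            {"compound": "ceftobiprole", "ratio": 1},
            {"compound": "citric_acid", "ratio": 100},
            {"compound": "sbe_beta_cd", "ratio": 1},
        ],
        "reference": "ceftobiprole",
        "note": "weak solid acid; 100-fold excess needed to reach pH 2.5",
    },
    "tosylate_1to25to2": {
        "components": [
            {"compound": "ceftobiprole", "ratio": 1},
            {"compound": "tosylic_acid", "ratio": 25},
            {"compound": "sbe_beta_cd", "ratio": 2},
        ],
        "reference": "ceftobiprole",
        "note": "strong solid acid; rapid solid-state degradation",
    },
    "maleate_1to25to4": {
        "components": [
            {"compound": "ceftobiprole", "ratio": 1},
            {"compound": "maleic_acid", "ratio": 25},
            {"compound": "sbe_beta_cd", "ratio": 4},
        ],
        "reference": "ceftobiprole",
        "reference_mass_mg": 1.0,
        "note": "lead ternary system; 23.6 mg of solid carries 1 mg of drug",
    },
    "maleate_1to25": {
        "components": [
            {"compound": "ceftobiprole", "ratio": 1},
            {"compound": "maleic_acid", "ratio": 25},
        ],
        "reference": "ceftobiprole",
        "note": "CD-free counterpart of the lead system",
    },
}

#: Reported reconstitution solubilities (mg/mL) and pH bookkeeping per
#: scenario.  These are measured values kept for qualitative comparison;
#: the package does not model them.
_SOLUBILITY_ROWS = [
    # scenario, solubility, pH before lyophilisation, pH after reconstitution
    ("water_untreated", 0.05, "", "", "untreated drug in pure water"),
    ("formic_no_cd_unprocessed", 0.14, "", "", "unprocessed drug in 0.1 M formic acid"),
    ("formic_no_cd", 2.1, 2.3, 4.0, "freeze-dried from 0.1 M formic acid, no CD"),
    ("formic_1to2", 3.4, 2.3, 4.0, "freeze-dried 1:2 with CD from 0.1 M formic acid"),
    ("hcl_1to2", 1.0, 2.0, 1.0, "freeze-dried from 0.01 M HCl; heavy degradation"),
    ("citrate_1to100to1", 8.6, 2.5, "", "weak solid acid, initial test"),
    ("tosylate_1to25to2", 21.3, 2.4, "", "strong solid acid, initial test"),
    ("maleate_1to25to4", 14.0, 2.5, 1.5, "lead ternary system, initial test"),
    ("maleate_1to25", 0.7, "", "", "physical mixture, drug + maleic acid only"),
    ("maleate_1to25to4_physical_mix", 1.3, "", "", "unlyophilised physical mixture"),
    ("water_freeze_dried", 0.12, "", "", "freeze-dried from pure water, no acid"),
    ("water_1to4_freeze_dried", 0.15, "", "", "freeze-dried 1:4 with CD from pure water"),
]

#: Solid-state stability series (freezer storage), mg/mL on reconstitution.
#: Degradation-product sums are reported relative to the initial time point
#: (only the 8-month delta of +0.5 % is known for the maleate system).
_STABILITY = {
    "maleate_1to25to4": {
        "time_months": [0, 8],
        "conc_mg_per_ml": [14.0, 11.3],
        "sum_dp_percent": [0.0, 0.5],
        "note": "lead ternary system; drift attributed to moisture uptake",
    },
    "tosylate_1to25to2": {
        "time_months": [0, 9],
        "conc_mg_per_ml": [21.3, 4.5],
        "note": "strong-acid system; rapid solid-state degradation",
    },
    "citrate_1to100to1": {
        "time_months": [0, 6, 9],
        "conc_mg_per_ml": [8.6, 7.3, 5.1],
        "note": "hygroscopic citrate system",
    },
}


def make_fixtures(output_dir: str | Path) -> list[Path]:
    """Write the scenario fixture set into ``output_dir`` (created if
    needed); returns the written paths.  Fully deterministic."""

    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    records = [
        DiffusionRecord(species_id=s, D=v * _D_SCALE, sample_id=sample)
        for sample, s, v in _DOSY_TABLE
    ]
    written.append(
        write_diffusion_table(
            records,
            out / "dosy_diffusion.csv",
            header_comment=(
                "Reported DOSY diffusion coefficients of the dilute maleate "
                "samples with and without SBE-beta-CD.\n"
                "HDO and maleic acid are viscosity-matching references."
            ),
        )
    )

    conc_path = out / "dosy_concentrations.yaml"
    conc_path.write_text(
        "# Analytical concentrations of the dilute DOSY samples.\n"
        + yaml.safe_dump(_CONCENTRATIONS, sort_keys=True)
    )
    written.append(conc_path)

    recipes_path = out / "recipes.yaml"
    recipes_path.write_text(
        "# Molar-ratio recipes of the prepared freeze-dried systems.\n"
        + yaml.safe_dump({"recipes": _RECIPES}, sort_keys=True)
    )
    written.append(recipes_path)

    sol_path = out / "solubility.csv"
    with sol_path.open("w") as fh:
        fh.write(
            "# Reported reconstitution solubility (mg/mL) and pH bookkeeping "
            "per scenario.\n"
            "# Measured fixture values for qualitative comparison; "
            "not modelled outputs.\n"
            "scenario,solubility_mg_per_ml,ph_initial,ph_reconstituted,note\n"
        )
        for row in _SOLUBILITY_ROWS:
            fh.write(",".join(str(x) for x in row[:4]) + f',"{row[4]}"\n')
    written.append(sol_path)

    for name, series in _STABILITY.items():
        path = out / f"stability_{name}.csv"
        cols = ["time_months", "conc_mg_per_ml"]
        if "sum_dp_percent" in series:
            cols.append("sum_dp_percent")
        with path.open("w") as fh:
            fh.write(f"# {series['note']}\n")
            fh.write(",".join(cols) + "\n")
            for i in range(len(series["time_months"])):
                fh.write(",".join(str(series[c][i]) for c in cols) + "\n")
        written.append(path)

    return written
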