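"""Trait catalogue for the wheat yield / protein-quality analysis.

Ten traits are tracked throughout the pipeline:

========  ===============================  ========  =================
code      trait                            unit      group
========  ===============================  ========  =================
GY        grain yield                      dt/ha     agronomic
PC        protein content                  %         agronomic
PY        protein yield (= GY*PC/100)      dt/ha     agronomic
WU        farinograph water uptake         %         standalone
DEV       dough development time           min       gluten viscosity
STAB      dough stability                  min       gluten strength
SOFT      dough softening                  FU        gluten strength
EXT       extensibility                    mm        gluten viscosity
RES       resistance to extension          EU        gluten strength
ENG       dough energy                     cm^2      gluten strength
========  ===============================  ========  =================

Dough softening is recorded on a lower-is-better scale; it is inverted
(multiplied by -1) before any statistical analysis so that all rheology
traits point in the favourable direction.  Protein yield is the product
of grain yield and protein content and is never modelled as an
independent genetic trait.
"""

from __future__ import annotations

from dataclasses import dataclass

ALL_TRAITS: tuple[str, ...] = (
    "GY", "PC", "PY", "WU", "DEV", "STAB", "SOFT", "EXT", "RES", "ENG",
)

#: traits with an independently drawn genetic value (PY is derived)
DRAWN_TRAITS: tuple[str, ...] = (
    "GY", "PC", "WU", "DEV", "STAB", "SOFT", "EXT", "RES", "ENG",
)

AGRONOMIC_TRAITS: tuple[str, ...] = ("GY", "PC", "PY")
RHEOLOGY_TRAITS: tuple[str, ...] = ("WU", "DEV", "STAB", "SOFT", "EXT", "RES", "ENG")

#: gluten strength group (SOFT enters after inversion)
STRENGTH_TRAITS: tuple[str, ...] = ("RES", "ENG", "STAB", "SOFT")
#: gluten viscosity group; water uptake stands alone in every index
VISCOSITY_TRAITS: tuple[str, ...] = ("EXT", "DEV")


@dataclass(frozen=True)
class TraitInfo:
    code: str
    name: str
    unit: str
    mean: float        # population mean on the measured scale
    genetic_sd: float  # additive genetic standard deviation, trait units
    lower_is_better: bool = False


TRAIT_CATALOGUE: dict[str, TraitInfo] = {
    "GY": TraitInfo("GY", "grain yield", "dt/ha", 80.0, 5.0),
    "PC": TraitInfo("PC", "protein content", "%", 14.5, 0.8),
    "PY": TraitInfo("PY", "protein yield", "dt/ha", 11.6, 0.9),
    "WU": TraitInfo("WU", "water uptake", "%", 60.0, 2.0),
    "DEV": TraitInfo("DEV", "dough development time", "min", 3.5, 1.0),
    "STAB": TraitInfo("STAB", "dough stability", "min", 8.0, 3.0),
    "SOFT": TraitInfo("SOFT", "dough softening", "FU", 60.0, 20.0, lower_is_better=True),
    "EXT": TraitInfo("EXT", "extensibility", "mm", 160.0, 15.0),
    "RES": TraitInfo("RES", "resistance to extension", "EU", 350.0, 80.0),
    "ENG": TraitInfo("ENG", "dough energy", "cm^2", 100.0, 25.0),
}

GLU_LOCI: tuple[str, ...] = ("Glu-A1", "Glu-B1", "Glu-D1")
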