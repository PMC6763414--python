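"""Desired-gain genomic selection indices.

An index assigns each line the score Index_i = sum_t x_it b_t over
centred and standardized GEBV (or sub-index) columns, with weights
solved from

    b = G^{-1} a,

where G is the sample covariance matrix of the standardized components
and a the vector of desired gains in standardized-trait units.  Under
this construction the expected standardized gain pattern of truncation
selection on the index is proportional to a, so zeros in a act as
restrictions (hold the trait) and positive entries as targeted gains.

Named indices:

* STRH — gluten strength: a = (1,1,1,1) over (RES, ENG, STAB, SOFT)
  (SOFT on the inverted scale), equal weight on the four strength
  traits.
* VISC — gluten viscosity: a = (1,1) over (EXT, DEV).
* GPD  — grain protein deviation: a = (PC=1, GY=0, STRH=lambda,
  VISC=gamma): raise protein content, hold grain yield.
* GYD  — grain yield deviation: the mirror image (GY=1, PC=0, ...).
* HY   — high yield: a = (PY=1, PC=0, STRH=lambda, VISC=gamma):
  raise protein yield via yield potential, hold protein content.
* HP   — high protein: a = (PY=1, GY=0, STRH=lambda, VISC=gamma).

Water uptake never enters any index; the strength and viscosity
sub-indices are themselves centred and standardized before joining the
four-component indices.  lambda and gamma vary in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .traits import STRENGTH_TRAITS, VISCOSITY_TRAITS

NAMED_INDEX_COMPONENTS = {
    "GPD": ("PC", "GY"), "GYD": ("GY", "PC"),
    "HY": ("PY", "PC"), "HP": ("PY", "GY"),
}

CONDITION_LIMIT = 1e8


@dataclass
class IndexSpec:
    name: str
    components: list[str]
    a: np.ndarray
    G: np.ndarray
    b: np.ndarray
    lam: float | None = None
    gamma: float | None = None

    def to_dict(self) -> dict:
        return {"name": self.name, "components": list(self.components),
                "a": list(map(float, self.a)),
                "G": [list(map(float, row)) for row in self.G],
                "b": list(map(float, self.b)),
                "lambda": self.lam, "gamma": self.gamma}


def standardize_gebvs(
    gebvs: pd.DataFrame, reference_lines: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Centre and scale each trait column to mean 0, sd 1 (sample sd).

    Moments are computed over ``reference_lines`` (default: all rows)
    and applied to every row, so held-out lines are expressed on the
    reference scale.  Returns the transformed frame and a (mean, sd)
    table for reuse.
    """
    ref = gebvs if reference_lines is None else gebvs.loc[list(reference_lines)]
    mean = ref.mean()
    sd = ref.std(ddof=1)
    zero = sd[sd <= 0]
    if len(zero):
        raise ValueError(f"zero variance in traits {list(zero.index)}")
    params = pd.DataFrame({"mean": mean, "sd": sd})
    return (gebvs - mean) / sd, params


def gebv_covariance(std_gebvs: pd.DataFrame, components: list[str]) -> np.ndarray:
    """Sample covariance matrix of the standardized component columns."""
    if len(components) < 2:
        raise ValueError("an index needs at least 2 components")
    if len(std_gebvs) < 10:
        raise ValueError("need at least 10 lines to estimate G")
    missing = [c for c in components if c not in std_gebvs.columns]
    if missing:
        raise ValueError(f"components missing from GEBV table: {missing}")
    G = np.cov(std_gebvs[list(components)].to_numpy(float), rowvar=False, ddof=1)
    return (G + G.T) / 2.0


def index_weights(G: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Solve G b = a; refuses ill-conditioned G rather than regularize."""
    G = np.asarray(G, dtype=float)
    a = np.asarray(a, dtype=float)
    cond = np.linalg.cond(G)
    if not np.isfinite(cond) or cond > CONDITION_LIMIT:
        raise ValueError(
            f"G is singular or ill-conditioned (cond={cond:.3g}); "
            "components are collinear — drop one or add an explicit ridge")
    b = np.linalg.solve(G, a)
    resid = np.max(np.abs(G @ b - a))
    if resid > 1e-10:  # polish with one refinement step
        b = b + np.linalg.solve(G, a - G @ b)
    return b


def composite_index(std_gebvs: pd.DataFrame, spec: IndexSpec) -> pd.Series:
    """Per-line index values: the weighted sum of component columns."""
    missing = [c for c in spec.components if c not in std_gebvs.columns]
    if missing:
        raise ValueError(f"components missing from GEBV table: {missing}")
    vals = std_gebvs[list(spec.components)].to_numpy(float) @ spec.b
    return pd.Series(vals, index=std_gebvs.index, name=spec.name)


def build_subindex(name: str, std_gebvs: pd.DataFrame) -> tuple[IndexSpec, pd.Series]:
    """STRH or VISC sub-index with equal desired gains on its traits."""
    if name == "STRH":
        comps = list(STRENGTH_TRAITS)
    elif name == "VISC":
        comps = list(VISCOSITY_TRAITS)
    else:
        raise ValueError(f"unknown sub-index {name!r}")
    a = np.ones(len(comps))
    G = gebv_covariance(std_gebvs, comps)
    b = index_weights(G, a)
    spec = IndexSpec(name, comps, a, G, b)
    return spec, composite_index(std_gebvs, spec)


def build_named_index(
    name: str, std_gebvs: pd.DataFrame,
    lam: float = 0.0, gamma: float = 0.0,
) -> tuple[IndexSpec, pd.Series]:
    """Combined four-component index (GPD, GYD, HY or HP).

    Builds the STRH and VISC sub-indices first, standardizes their
    values, forms the 4 x 4 covariance of (primary, restricted, STRH,
    VISC), sets the desired gains a = (1, 0, lambda, gamma) and solves
    for the weights.
    """
    if name not in NAMED_INDEX_COMPONENTS:
        raise ValueError(f"unknown index {name!r}; choose from "
                         f"{sorted(NAMED_INDEX_COMPONENTS)}")
    if not (0.0 <= lam <= 1.0 and 0.0 <= gamma <= 1.0):
        raise ValueError("lambda and gamma must lie in [0, 1]")
    primary, restricted = NAMED_INDEX_COMPONENTS[name]
    for t in (primary, restricted):
        if t not in std_gebvs.columns:
            raise ValueError(f"{name} needs a GEBV column for {t}")

    _, strh = build_subindex("STRH", std_gebvs)
    _, visc = build_subindex("VISC", std_gebvs)
    table = pd.DataFrame({
        primary: std_gebvs[primary],
        restricted: std_gebvs[restricted],
        "STRH": (strh - strh.mean()) / strh.std(ddof=1),
        "VISC": (visc - visc.mean()) / visc.std(ddof=1),
    })
    comps = [primary, restricted, "STRH", "VISC"]
    a = np.array([1.0, 0.0, lam, gamma])
    G = gebv_covariance(table, comps)
    b = index_weights(G, a)
    spec = IndexSpec(name, comps, a, G, b, lam=lam, gamma=gamma)
    return spec, composite_index(table, spec)
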