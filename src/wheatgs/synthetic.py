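"""Synthetic wheat breeding-programme generator.

Emulates the statistical structure of a winter-wheat line population
evaluated for grain yield, protein content and dough rheology:

* a few hundred inbred/doubled-haploid lines from many biparental
  families, genotyped at several thousand SNPs with realistic linkage
  disequilibrium and family structure (gene dropping through a founder
  haplotype pool),
* three major glutenin loci (Glu-A1, Glu-B1, Glu-D1) with additive
  effects on the gluten-strength traits,
* correlated polygenic trait values with a built-in negative genetic
  correlation between grain yield and protein content, protein yield
  derived multiplicatively from the two,
* unbalanced multi-environment trials with AR1 x AR1 spatial error and
  replicated checks; rheology traits measured only on a subset of lines
  per trial.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence.spawn``: child streams are created in a
fixed order (genotypes, glutenin alleles, genetic values, phenotypes),
so components stay reproducible individually and jointly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cholesky

from .containers import GenotypeMatrix
from .traits import (
    ALL_TRAITS, DRAWN_TRAITS, RHEOLOGY_TRAITS, GLU_LOCI, TRAIT_CATALOGUE,
)

# ---------------------------------------------------------------------------
# architecture


def default_sigma_g() -> pd.DataFrame:
    """Default genetic correlation matrix over the drawn traits.

    Encodes the yield/protein trade-off (cor(GY,PC) = -0.6), a tightly
    correlated gluten strength group {RES, ENG, STAB, SOFT}, a viscosity
    pair {EXT, DEV}, a weakly attached water uptake, and slightly
    negative correlations of grain yield with the rheology traits
    (more negative with the viscosity pair).  SOFT is on the inverted
    (higher-is-better) analysis scale.
    """
    order = list(DRAWN_TRAITS)
    C = pd.DataFrame(np.eye(len(order)), index=order, columns=order)
    pairs = {
        ("GY", "PC"): -0.6, ("GY", "WU"): 0.0, ("GY", "DEV"): -0.25,
        ("GY", "STAB"): -0.15, ("GY", "SOFT"): -0.15, ("GY", "EXT"): -0.25,
        ("GY", "RES"): -0.15, ("GY", "ENG"): -0.15,
        ("PC", "WU"): 0.1, ("PC", "DEV"): 0.25, ("PC", "STAB"): 0.3,
        ("PC", "SOFT"): 0.3, ("PC", "EXT"): 0.25, ("PC", "RES"): 0.3,
        ("PC", "ENG"): 0.3,
        ("WU", "DEV"): 0.15, ("WU", "STAB"): 0.15, ("WU", "SOFT"): 0.15,
        ("WU", "EXT"): 0.1, ("WU", "RES"): 0.15, ("WU", "ENG"): 0.15,
        ("DEV", "STAB"): 0.35, ("DEV", "SOFT"): 0.35, ("DEV", "EXT"): 0.6,
        ("DEV", "RES"): 0.35, ("DEV", "ENG"): 0.35,
        ("STAB", "SOFT"): 0.6, ("STAB", "EXT"): 0.3, ("STAB", "RES"): 0.6,
        ("STAB", "ENG"): 0.6,
        ("SOFT", "EXT"): 0.3, ("SOFT", "RES"): 0.6, ("SOFT", "ENG"): 0.6,
        ("EXT", "RES"): 0.3, ("EXT", "ENG"): 0.35,
        ("RES", "ENG"): 0.6,
    }
    for (a, b), v in pairs.items():
        C.loc[a, b] = C.loc[b, a] = v
    return C


def default_glu_effects() -> pd.DataFrame:
    """Glutenin locus effects (genetic-SD units per allele substitution).

    Nonzero only on rheology traits; Glu-D1 is the strongest locus and
    acts mainly on the gluten-strength group.
    """
    eff = pd.DataFrame(0.0, index=list(GLU_LOCI), columns=list(DRAWN_TRAITS))
    eff.loc["Glu-D1", ["RES", "ENG", "STAB", "SOFT", "DEV", "EXT"]] = (
        0.50, 0.45, 0.40, 0.30, 0.15, 0.10)
    eff.loc["Glu-B1", ["RES", "ENG", "STAB", "SOFT"]] = (0.25, 0.25, 0.20, 0.15)
    eff.loc["Glu-A1", ["RES", "ENG", "STAB"]] = (0.15, 0.15, 0.10)
    return eff


def _default_h2() -> dict[str, float]:
    h2 = {"GY": 0.6, "PC": 0.6, "PY": 0.55, "WU": 0.5}
    h2.update({t: 0.4 for t in ("DEV", "STAB", "SOFT", "EXT", "RES", "ENG")})
    return h2


@dataclass
class GeneticArchitecture:
    """Trait catalogue dimensions, genetic correlations and major loci."""

    sigma_g: pd.DataFrame = field(default_factory=default_sigma_g)
    trait_h2: dict[str, float] = field(default_factory=_default_h2)
    glu_effects: pd.DataFrame = field(default_factory=default_glu_effects)
    n_qtl_background: int = 300

    def __post_init__(self) -> None:
        C = self.sigma_g.to_numpy(float)
        if not np.allclose(C, C.T):
            raise ValueError("sigma_g must be symmetric")
        if not np.allclose(np.diag(C), 1.0):
            raise ValueError("sigma_g must have unit diagonal")
        if np.linalg.eigvalsh(C).min() < -1e-10:
            raise ValueError("sigma_g must be positive semi-definite")
        for t, h in self.trait_h2.items():
            if not 0.0 < h <= 1.0:
                raise ValueError(f"trait_h2[{t}] outside (0, 1]")


@dataclass
class TrueGeneticValues:
    """Line x trait additive genetic values on the analysis scale.

    ``values`` are in trait units; SOFT is stored inverted (higher is
    better), matching the orientation of all downstream analysis.  PY is
    derived as GY * PC / 100, never drawn.  ``background`` and
    ``glu_part`` decompose the standardized drawn values.
    """

    lines: list[str]
    values: pd.DataFrame                  # columns = ALL_TRAITS, trait units
    std_values: pd.DataFrame              # per-trait standardized values
    background: pd.DataFrame              # standardized polygenic part
    glu_part: pd.DataFrame                # standardized Glu-1 part

    def to_csv(self, path) -> None:
        out = self.values.copy()
        out.index.name = "line"
        out.to_csv(path)


# ---------------------------------------------------------------------------
# genotypes


def simulate_genotypes(
    n_families: int = 394,
    lines_per_family: int | None = None,
    n_lines: int | None = 480,
    n_chromosomes: int = 21,
    markers_per_chromosome: int = 350,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
    n_founder_lines: int = 25,
    n_ancestral: int = 4,
    switch_prob: float = 0.08,
    crossover_prob: float = 0.08,
    het_rate: float = 0.02,
) -> tuple[GenotypeMatrix, list[str]]:
    """Gene-drop inbred/DH lines through a founder pool.

    A small pool of ``n_founder_lines`` elite founders (two haplotypes
    each, mosaics of a handful of ancestral haplotypes — block-wise LD
    decaying with map distance) is reused across families, as parents
    are in a practical breeding programme; this reuse is what creates
    the kinship gradients downstream models rely on.  Each family
    crosses two founders; a line is a doubled recombinant gamete of the
    F1, with residual heterozygosity at rate ``het_rate``.  Either
    ``lines_per_family`` or a total ``n_lines`` (spread as evenly as
    possible over families) must be given.

    Returns the genotype matrix and the per-line family labels.
    """
    if n_families <= 0 or n_chromosomes <= 0 or markers_per_chromosome <= 0:
        raise ValueError("counts must be positive")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must be a non-empty subinterval of (0, 0.5]")
    if lines_per_family is None:
        if n_lines is None:
            raise ValueError("give lines_per_family or n_lines")
        base, extra = divmod(n_lines, n_families)
        fam_sizes = [base + (1 if i < extra else 0) for i in range(n_families)]
    else:
        fam_sizes = [lines_per_family] * n_families
    total = sum(fam_sizes)
    if total < 2:
        raise ValueError("need at least 2 lines in total")

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    m = n_chromosomes * markers_per_chromosome
    p = rng.uniform(lo, hi, size=m)

    # ancestral haplotypes: Bernoulli(p) alleles
    anc = (rng.random((n_ancestral, m)) < p).astype(np.int8)

    chrom = np.repeat(np.arange(1, n_chromosomes + 1), markers_per_chromosome)
    position = np.tile(np.arange(markers_per_chromosome, dtype=float), n_chromosomes)

    chrom_starts = np.arange(n_chromosomes) * markers_per_chromosome
    marker_idx = np.arange(m)

    def _mosaic(source: np.ndarray, switch: float) -> np.ndarray:
        """Recombinant mosaic of the rows of `source`, chromosome-wise."""
        n_src = source.shape[0]
        new_segment = rng.random(m) < switch
        new_segment[chrom_starts] = True  # chromosomes recombine freely
        seg_id = np.cumsum(new_segment) - 1
        states = rng.integers(n_src, size=seg_id[-1] + 1)
        return source[states[seg_id], marker_idx]

    # founder lines: two mosaic haplotypes each, reused across families
    founders = np.stack([
        np.stack([_mosaic(anc, switch_prob), _mosaic(anc, switch_prob)])
        for _ in range(n_founder_lines)
    ])

    lines: list[str] = []
    families: list[str] = []
    dosages = np.empty((total, m), dtype=float)
    row = 0
    for f, size in enumerate(fam_sizes):
        par = rng.choice(n_founder_lines, size=2, replace=False)
        p1, p2 = founders[par[0]], founders[par[1]]
        for s in range(size):
            gam1 = _mosaic(p1, crossover_prob)
            gam2 = _mosaic(p2, crossover_prob)
            dh = _mosaic(np.stack([gam1, gam2]), crossover_prob)
            dos = (2 * dh - 1).astype(float)
            if het_rate > 0:
                het = rng.random(m) < het_rate
                dos[het] = 0.0
            dosages[row] = dos
            lines.append(f"L{row + 1:04d}")
            families.append(f"F{f + 1:04d}")
            row += 1

    markers = [f"chr{c:02d}_m{k + 1:04d}"
               for c in range(1, n_chromosomes + 1)
               for k in range(markers_per_chromosome)]
    geno = GenotypeMatrix(lines, markers, chrom, position, dosages)
    return geno, families


def simulate_glu_alleles(
    lines: list[str],
    allele_freqs: dict[str, float] | None = None,
    seed: int = 0,
    missing_fraction: float = 0.0,
    het_rate: float = 0.02,
) -> pd.DataFrame:
    """Draw raw glutenin allele strings for each line.

    ``allele_freqs`` gives the frequency of the favourable (+1-coded)
    allele per locus.  Allele universe: Glu-A1 {0 | 1, 2*}, Glu-B1
    {6+8 | 7+8, 7+9}, Glu-D1 {5+10 | 2+12} (unfavourable | favourable
    under the -1/+1 coding).  Heterozygous calls are emitted as
    "x/y" strings; a ``missing_fraction`` of lines is left unscreened
    (NaN at all three loci).
    """
    freqs = {"Glu-A1": 0.6, "Glu-B1": 0.6, "Glu-D1": 0.5}
    if allele_freqs:
        freqs.update(allele_freqs)
    for loc, f in freqs.items():
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"allele frequency for {loc} outside [0, 1]")
    if not 0.0 <= missing_fraction < 1.0:
        raise ValueError("missing_fraction outside [0, 1)")

    unfav = {"Glu-A1": ["0"], "Glu-B1": ["6+8"], "Glu-D1": ["5+10"]}
    fav = {"Glu-A1": ["1", "2*"], "Glu-B1": ["7+8", "7+9"], "Glu-D1": ["2+12"]}

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    n = len(lines)
    calls = pd.DataFrame(index=list(lines), columns=list(GLU_LOCI), dtype=object)
    for loc in GLU_LOCI:
        f = freqs[loc]
        for i in range(n):
            if rng.random() < het_rate:
                calls.iloc[i, calls.columns.get_loc(loc)] = (
                    f"{rng.choice(unfav[loc])}/{rng.choice(fav[loc])}")
            elif rng.random() < f:
                calls.iloc[i, calls.columns.get_loc(loc)] = str(rng.choice(fav[loc]))
            else:
                calls.iloc[i, calls.columns.get_loc(loc)] = str(rng.choice(unfav[loc]))
    if missing_fraction > 0:
        mask = rng.random(n) < missing_fraction
        calls.loc[mask, :] = np.nan
    return calls


# ---------------------------------------------------------------------------
# genetic values


def simulate_genetic_values(
    genotypes: GenotypeMatrix,
    glu: pd.DataFrame | None,
    arch: GeneticArchitecture | None = None,
    seed: int = 0,
) -> TrueGeneticValues:
    """Draw correlated polygenic values and add glutenin-locus effects.

    Background effects sit on ``arch.n_qtl_background`` random markers
    with across-trait covariance proportional to ``arch.sigma_g``; the
    realized polygenic part is standardized to unit variance per trait,
    then the Glu-1 contributions (SD units per allele code) are added on
    top.  Trait values are returned on the measured scale (catalogue
    mean + genetic SD x standardized value), with SOFT on the inverted
    analysis scale.  PY = GY * PC / 100.
    """
    arch = arch or GeneticArchitecture()
    traits = list(DRAWN_TRAITS)
    C = arch.sigma_g.loc[traits, traits].to_numpy(float)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])

    n, m = genotypes.n_lines, genotypes.n_markers
    n_qtl = min(arch.n_qtl_background, m)
    causal = rng.choice(m, size=n_qtl, replace=False)
    Z = genotypes.dosages[:, causal]
    if np.isnan(Z).any():
        raise ValueError("genotypes must be complete (impute first)")

    # effect matrix with rows ~ N(0, C): correlations across traits
    L = cholesky(C + 1e-12 * np.eye(len(traits)), lower=True)
    B = rng.standard_normal((n_qtl, len(traits))) @ L.T
    g = Z @ B
    g -= g.mean(axis=0)
    sd = g.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    background = pd.DataFrame(g / sd, index=genotypes.lines, columns=traits)

    glu_part = pd.DataFrame(0.0, index=genotypes.lines, columns=traits)
    if glu is not None:
        from .genotypes import recode_glu
        codes = recode_glu(glu).fillna(0.0)
        codes = codes.reindex(genotypes.lines).fillna(0.0)
        eff = arch.glu_effects.loc[list(GLU_LOCI), traits].to_numpy(float)
        glu_part.loc[:, :] = codes.to_numpy(float) @ eff

    std = background + glu_part

    values = pd.DataFrame(index=genotypes.lines, columns=list(ALL_TRAITS), dtype=float)
    for t in traits:
        info = TRAIT_CATALOGUE[t]
        mean = -info.mean if info.lower_is_better else info.mean
        values[t] = mean + info.genetic_sd * std[t].to_numpy()
    values["PY"] = values["GY"] * values["PC"] / 100.0

    std_all = (values - values.mean()) / values.std(ddof=1)
    return TrueGeneticValues(list(genotypes.lines), values, std_all,
                             background, glu_part)


# ---------------------------------------------------------------------------
# trials


@dataclass
class TrialDesign:
    """Layout and noise structure of the multi-environment trial series.

    Noise scales are per-trait dicts in trait units; use
    :meth:`from_architecture` to derive them from target plot-level
    heritabilities.  Agronomic trials measure GY and PC on every plot
    (PY is their product); rheology trials measure the seven dough
    traits on a ``rheology_coverage`` fraction of lines, mostly
    unreplicated apart from the checks.
    """

    n_agronomic_trials: int = 6
    n_rheology_trials: int = 5
    lines_per_agronomic_trial: float = 0.5   # fraction of all lines per trial
    rheology_coverage: float = 0.6
    n_checks: int = 3
    check_reps: int = 4
    reps_per_line: int = 1
    ar1_rho_row: float = 0.4
    ar1_rho_col: float = 0.4
    trial_effect_sd: dict[str, float] = field(default_factory=dict)
    spatial_sd: dict[str, float] = field(default_factory=dict)
    error_sd: dict[str, float] = field(default_factory=dict)
    n_years: int = 2

    def __post_init__(self) -> None:
        if not (0.0 <= self.ar1_rho_row < 1.0 and 0.0 <= self.ar1_rho_col < 1.0):
            raise ValueError("AR1 correlations must lie in [0, 1)")

    @classmethod
    def from_architecture(
        cls,
        arch: GeneticArchitecture | None = None,
        spatial_fraction: float = 0.3,
        **kwargs,
    ) -> "TrialDesign":
        """Choose noise scales so plot-level h2 matches ``arch.trait_h2``.

        Total non-genetic plot variance is sigma_g^2 (1/h2 - 1), split
        ``spatial_fraction`` : (1 - spatial_fraction) between the AR1
        field and iid error.  Trial main effects get one genetic SD.
        """
        arch = arch or GeneticArchitecture()
        spatial, error, trial_eff = {}, {}, {}
        for t in ALL_TRAITS:
            sg = TRAIT_CATALOGUE[t].genetic_sd
            h2 = arch.trait_h2.get(t, 0.5)
            noise_var = sg * sg * (1.0 / h2 - 1.0)
            spatial[t] = float(np.sqrt(spatial_fraction * noise_var))
            error[t] = float(np.sqrt((1.0 - spatial_fraction) * noise_var))
            trial_eff[t] = sg
        kwargs.setdefault("spatial_sd", spatial)
        kwargs.setdefault("error_sd", error)
        kwargs.setdefault("trial_effect_sd", trial_eff)
        return cls(**kwargs)


def _ar1_field(n_rows: int, n_cols: int, rho_r: float, rho_c: float,
               rng: np.random.Generator) -> np.ndarray:
    """Unit-variance AR1(rho_r) x AR1(rho_c) Gaussian field on a grid."""
    def chol_ar1(n: int, rho: float) -> np.ndarray:
        idx = np.arange(n)
        R = rho ** np.abs(idx[:, None] - idx[None, :])
        return cholesky(R + 1e-10 * np.eye(n), lower=True)

    E = rng.standard_normal((n_rows, n_cols))
    return chol_ar1(n_rows, rho_r) @ E @ chol_ar1(n_cols, rho_c).T


def _grid_for(n_plots: int) -> tuple[int, int]:
    n_cols = int(np.ceil(np.sqrt(n_plots)))
    n_rows = int(np.ceil(n_plots / n_cols))
    return n_rows, n_cols


def simulate_plot_phenotypes(
    gvalues: TrueGeneticValues,
    design: TrialDesign | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Lay out trials and emit plot-level phenotypes.

    plot value = trial effect + genetic value + AR1 spatial field + iid
    error, per trait.  PY is the product GY x PC / 100 at plot level.
    SOFT is emitted on its raw lower-is-better scale (the analysis-scale
    value negated); run ``preprocess_softening`` before analysis.
    """
    design = design or TrialDesign.from_architecture()
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    lines = np.array(gvalues.lines)
    n = len(lines)

    checks = list(lines[:design.n_checks])
    non_checks = [l for l in lines if l not in checks]

    records: list[dict] = []

    def _add_trial(trial_id: str, year: int, entries: list[str],
                   reps: dict[str, int], trait_list: list[str]) -> None:
        plot_lines: list[str] = []
        for l in entries:
            plot_lines.extend([l] * reps.get(l, 1))
        n_plots = len(plot_lines)
        n_rows, n_cols = _grid_for(n_plots)
        order = rng.permutation(n_plots)
        plot_lines = [plot_lines[i] for i in order]

        fields = {t: design.spatial_sd.get(t, 0.0)
                  * _ar1_field(n_rows, n_cols, design.ar1_rho_row,
                               design.ar1_rho_col, rng)
                  for t in trait_list if t != "PY"}
        trial_eff = {t: rng.normal(0.0, design.trial_effect_sd.get(t, 0.0))
                     for t in trait_list if t != "PY"}

        for i, line in enumerate(plot_lines):
            r, c = divmod(i, n_cols)
            rec = {"line": line, "trial": trial_id, "year": year,
                   "row": r + 1, "col": c + 1, "is_check": line in checks}
            for t in trait_list:
                if t == "PY":
                    continue
                gv = gvalues.values.loc[line, t]
                val = (trial_eff[t] + gv + fields[t][r, c]
                       + rng.normal(0.0, design.error_sd.get(t, 0.0)))
                rec[t] = -val if t == "SOFT" else val
            if "PY" in trait_list:
                rec["PY"] = rec["GY"] * rec["PC"] / 100.0
            records.append(rec)

    # trial series: staggered windows over a shuffled line order, so the
    # line sets of consecutive trials interleave and every line appears in
    # several trials (losing any one trial never orphans a line)
    def _series(prefix, n_trials, coverage, rep_count, trait_list):
        perm = rng.permutation(non_checks)
        per_trial = max(2, int(round(coverage * n)))
        for j in range(n_trials):
            start = int(round(j * len(perm) / max(n_trials, 1)))
            entries = [perm[(start + k) % len(perm)] for k in range(per_trial)]
            entries = list(dict.fromkeys(entries))
            reps = {l: rep_count for l in entries}
            reps.update({c: design.check_reps for c in checks})
            _add_trial(f"{prefix}{j + 1:02d}", 2015 + j % design.n_years,
                       entries + checks, reps, trait_list)

    _series("AGR", design.n_agronomic_trials,
            design.lines_per_agronomic_trial, design.reps_per_line,
            ["GY", "PC", "PY"])
    _series("RHE", design.n_rheology_trials, design.rheology_coverage, 1,
            list(RHEOLOGY_TRAITS))

    plots = pd.DataFrame.from_records(records)
    for t in ALL_TRAITS:
        if t not in plots.columns:
            plots[t] = np.nan
    meta = ["line", "trial", "year", "row", "col", "is_check"]
    return plots[meta + list(ALL_TRAITS)]


def inject_marker_missingness(
    genotypes: GenotypeMatrix,
    missing_rate: float = 0.02,
    n_bad_markers: int = 0,
    bad_marker_rate: float = 0.15,
    seed: int = 0,
) -> GenotypeMatrix:
    """Blank out entries: a background rate everywhere plus a set of
    'bad' markers whose missingness exceeds the 10% QC threshold."""
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate outside [0, 1)")
    if n_bad_markers > genotypes.n_markers:
        raise ValueError("n_bad_markers exceeds marker count")
    out = genotypes.copy()
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    n, m = out.dosages.shape
    if missing_rate > 0:
        out.dosages[rng.random((n, m)) < missing_rate] = np.nan
    if n_bad_markers > 0:
        bad = rng.choice(m, size=n_bad_markers, replace=False)
        for k in bad:
            n_miss = int(np.ceil(bad_marker_rate * n))
            rows = rng.choice(n, size=n_miss, replace=False)
            out.dosages[rows, k] = np.nan
    return out


def simulate_line_blues(
    gvalues: TrueGeneticValues,
    entry_h2: dict[str, float] | float = 0.7,
    seed: int = 0,
) -> pd.DataFrame:
    """Entry-mean phenotypes: true value + noise at a target entry-mean h2.

    Convenience shortcut that skips the plot/spatial layer; useful when
    only the prediction and index stages are exercised.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    out = gvalues.values.copy()
    for t in out.columns:
        h2 = entry_h2.get(t, 0.7) if isinstance(entry_h2, dict) else entry_h2
        if not 0.0 < h2 <= 1.0:
            raise ValueError("entry-mean h2 outside (0, 1]")
        sg = gvalues.values[t].std(ddof=1)
        noise_sd = sg * np.sqrt(1.0 / h2 - 1.0)
        out[t] = out[t] + rng.normal(0.0, noise_sd, size=len(out))
    return out
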