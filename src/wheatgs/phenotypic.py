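"""Two-stage analysis of multi-environment trial data.

Stage one fits, per trial and trait, a linear mixed model with fixed
genotype effects and one of 16 spatial structures — every combination
of random row / random column effects with an IID, AR1-in-row,
AR1-in-column or AR1 x AR1 residual — and picks the structure by AIC
(REML log-likelihoods are comparable because all candidates share the
same fixed effects; the AIC penalty counts variance parameters only).
Line BLUEs come from the genotype-fixed fit; the genetic variance for
heritability comes from a parallel genotype-random fit under the same
structure.  Heritability uses the Piepho-Moehring form

    h2 = s2_G / (s2_G + MVD / 2)

with MVD the mean variance of a difference between line BLUEs.  Trials
are filtered on h2 (> 0.3 for agronomic traits; rheology trials are
only dropped below 0.1, and trials whose quality cannot be assessed are
kept).  Stage two combines the per-trial BLUEs in a model with fixed
genotype and trial effects and iid residuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._mixed import reml_general, reml_kernel
from .containers import validate_plot_table

RESIDUAL_STRUCTURES = ("IID", "AR1_ROW", "AR1_COL", "AR1_BOTH")


@dataclass(frozen=True)
class SpatialModelSpec:
    row_effect: bool
    col_effect: bool
    residual: str

    def __post_init__(self):
        if self.residual not in RESIDUAL_STRUCTURES:
            raise ValueError(f"unknown residual structure {self.residual!r}")

    @property
    def label(self) -> str:
        parts = []
        if self.row_effect:
            parts.append("row")
        if self.col_effect:
            parts.append("col")
        parts.append(self.residual)
        return "+".join(parts)


def all_spatial_specs() -> list[SpatialModelSpec]:
    """The 16 candidate structures; the all-off IID baseline is first."""
    specs = []
    for res in RESIDUAL_STRUCTURES:
        for row in (False, True):
            for col in (False, True):
                specs.append(SpatialModelSpec(row, col, res))
    specs.sort(key=lambda s: (s.residual != "IID", s.row_effect + s.col_effect,
                              s.row_effect, s.col_effect,
                              RESIDUAL_STRUCTURES.index(s.residual)))
    return specs


@dataclass
class TrialFit:
    trial: str
    trait: str
    spec: SpatialModelSpec
    reml_loglik: float
    aic: float
    n_var_params: int
    variance_components: dict[str, float]
    blues: pd.Series
    mvd: float
    h2: float | None = None
    unassessable: bool = False
    boundary: list[str] = field(default_factory=list)
    _plots: pd.DataFrame | None = field(default=None, repr=False)

    def h2_from_components(self) -> float:
        s2g = self.variance_components["genotype"]
        return s2g / (s2g + self.mvd / 2.0)


def preprocess_softening(plot_table: pd.DataFrame) -> pd.DataFrame:
    """Invert dough softening (multiply by -1) so higher is better.

    Raises if the table was already processed (tracked via a flag in
    ``DataFrame.attrs``); missing values stay missing.
    """
    if "SOFT" not in plot_table.columns:
        raise ValueError("plot table has no SOFT column")
    if plot_table.attrs.get("soft_inverted", False):
        raise ValueError("softening already inverted; refusing to invert twice")
    out = plot_table.copy()
    out["SOFT"] = -out["SOFT"]
    out.attrs = dict(plot_table.attrs)
    out.attrs["soft_inverted"] = True
    return out


# ---------------------------------------------------------------------------
# stage one


def _design(trial_plots: pd.DataFrame, trait: str):
    data = trial_plots[trial_plots[trait].notna()].copy()
    if data.empty:
        raise ValueError(f"no data for trait {trait}")
    lines = sorted(data["line"].unique())
    if len(lines) < 2:
        raise ValueError("need at least 2 lines with data")
    y = data[trait].to_numpy(float)
    line_idx = pd.Categorical(data["line"], categories=lines).codes
    Xg = np.zeros((len(data), len(lines)))
    Xg[np.arange(len(data)), line_idx] = 1.0
    rows = data["row"].to_numpy(int)
    cols = data["col"].to_numpy(int)
    drow = np.abs(rows[:, None] - rows[None, :])
    dcol = np.abs(cols[:, None] - cols[None, :])
    return data, y, lines, Xg, rows, cols, drow, dcol


def _incidence(values: np.ndarray) -> np.ndarray:
    levels = np.unique(values)
    Z = np.zeros((len(values), len(levels)))
    Z[np.arange(len(values)), np.searchsorted(levels, values)] = 1.0
    return Z @ Z.T


def _make_residual_builder(drow: np.ndarray, dcol: np.ndarray):
    """AR1 x AR1 residual correlation via power lookup tables.

    rho = 0 in a direction collapses to an indicator of zero distance,
    so the same formula covers IID, AR1_ROW, AR1_COL and AR1_BOTH.
    """
    max_r, max_c = int(drow.max()), int(dcol.max())

    def build(rhos: dict) -> np.ndarray:
        rr = rhos.get("rho_row", 0.0)
        rc = rhos.get("rho_col", 0.0)
        pr = np.power(rr, np.arange(max_r + 1))
        pc = np.power(rc, np.arange(max_c + 1))
        return pr[drow] * pc[dcol]

    return build


def _fit_one_spec(spec, y, X, rows, cols, drow, dcol):
    structures = {}
    if spec.row_effect and len(np.unique(rows)) > 1:
        structures["row"] = _incidence(rows)
    if spec.col_effect and len(np.unique(cols)) > 1:
        structures["col"] = _incidence(cols)

    rho_names = []
    if spec.residual in ("AR1_ROW", "AR1_BOTH") and len(np.unique(rows)) > 1:
        rho_names.append("rho_row")
    if spec.residual in ("AR1_COL", "AR1_BOTH") and len(np.unique(cols)) > 1:
        rho_names.append("rho_col")

    builder = _make_residual_builder(drow, dcol) if rho_names else None
    return reml_general(y, X, structures, builder, rho_names=tuple(rho_names))


def fit_spatial_models(
    trial_plots: pd.DataFrame, trait: str,
    specs: list[SpatialModelSpec] | None = None,
) -> list[TrialFit]:
    """Fit the 16 candidate spatial models (genotype fixed) to one trial.

    Returns one :class:`TrialFit` per candidate, each carrying BLUEs,
    MVD, REML log-likelihood and AIC.  Variance parameters that a
    degenerate geometry (single row or column) makes unidentifiable are
    pinned at zero and not counted in the AIC penalty.
    """
    data, y, lines, Xg, rows, cols, drow, dcol = _design(trial_plots, trait)
    trial_id = str(data["trial"].iloc[0])
    if len(lines) == len(data):
        # no replication at all: the genotype-fixed model is saturated.
        # BLUEs are the raw plot values; quality cannot be assessed.
        blues = pd.Series(y, index=data["line"].to_numpy(), name=trait)
        blues = blues.groupby(level=0).mean().reindex(lines)
        return [TrialFit(
            trial=trial_id, trait=trait,
            spec=SpatialModelSpec(False, False, "IID"),
            reml_loglik=float("nan"), aic=float("nan"), n_var_params=1,
            variance_components={"residual": float("nan"), "row": 0.0,
                                 "col": 0.0, "rho_row": 0.0, "rho_col": 0.0},
            blues=blues, mvd=float("nan"), unassessable=True, _plots=data)]
    fits = []
    for spec in specs or all_spatial_specs():
        res = _fit_one_spec(spec, y, Xg, rows, cols, drow, dcol)
        vc = {"residual": res.sigma2_e,
              "row": res.variance("row") if "row" in res.gammas else 0.0,
              "col": res.variance("col") if "col" in res.gammas else 0.0,
              "rho_row": res.rhos.get("rho_row", 0.0),
              "rho_col": res.rhos.get("rho_col", 0.0)}
        blues = pd.Series(res.beta, index=lines, name=trait)
        C = res.beta_cov
        n = len(lines)
        T, S = float(np.trace(C)), float(C.sum())
        mvd = (n * T - S) * 2.0 / (n * (n - 1))
        aic = -2.0 * res.reml_loglik + 2.0 * res.n_var_params
        fits.append(TrialFit(
            trial=trial_id, trait=trait, spec=spec,
            reml_loglik=res.reml_loglik, aic=aic,
            n_var_params=res.n_var_params, variance_components=vc,
            blues=blues, mvd=mvd, boundary=list(res.boundary),
            _plots=data,
        ))
    return fits


def select_model_aic(fits: list[TrialFit]) -> TrialFit:
    """Minimum-AIC fit; ties go to fewer variance parameters, then to
    the earlier candidate (baseline first)."""
    if not fits:
        raise ValueError("empty candidate list")
    best_aic = min(f.aic for f in fits)
    tied = [(f.n_var_params, i, f) for i, f in enumerate(fits)
            if f.aic <= best_aic + 1e-9]
    tied.sort(key=lambda t: (t[0], t[1]))
    return tied[0][2]


def trial_heritability(
    fit: TrialFit, error_source: str = "all_lines",
) -> float | None:
    """Piepho-Moehring heritability for one trial.

    ``all_lines`` refits the trial with genotype random (same spatial
    structure) to obtain s2_G and combines it with the stored MVD.
    ``checks_only`` estimates the error variance from the replicated
    checks alone (assuming other lines share it), for trials where most
    entries are unreplicated.  Returns None — and flags the fit
    un-assessable — when no replication supports the estimate.
    """
    if error_source not in ("all_lines", "checks_only"):
        raise ValueError(f"unknown error source {error_source!r}")
    data = fit._plots
    if data is None:
        raise ValueError("fit carries no plot data")
    trait = fit.trait
    counts = data["line"].value_counts()

    if error_source == "checks_only":
        checks = data[data["is_check"]]
        rep_checks = [l for l, c in checks["line"].value_counts().items() if c >= 2]
        if not rep_checks:
            fit.unassessable = True
            fit.h2 = None
            return None
        sub = checks[checks["line"].isin(rep_checks)]
        dev = sub[trait] - sub.groupby("line")[trait].transform("mean")
        dof = len(sub) - len(rep_checks)
        s2e = float((dev ** 2).sum() / dof)
        # moment estimator: the spread of line means carries genetic plus
        # error variance; the check replicates estimate the error part,
        # assuming the unreplicated lines share it
        line_means = data.groupby("line")[trait].mean()
        rbar = float(counts.mean())
        s2g = max(float(line_means.var(ddof=1)) - s2e / rbar, 0.0)
        mvd = 2.0 * s2e / rbar
        fit.variance_components["genotype"] = s2g
        fit.variance_components["residual_checks"] = s2e
        fit.mvd = mvd
        fit.h2 = s2g / (s2g + mvd / 2.0) if (s2g + mvd) > 0 else 0.0
        return fit.h2

    if (counts < 2).all() or not np.isfinite(fit.mvd):
        fit.unassessable = True
        fit.h2 = None
        return None

    s2g = _genetic_variance_reml(fit)
    fit.variance_components["genotype"] = s2g
    fit.h2 = s2g / (s2g + fit.mvd / 2.0)
    return fit.h2


def _genetic_variance_reml(fit: TrialFit) -> float:
    """s2_G from the genotype-random parallel fit under ``fit.spec``."""
    data, y, lines, Xg, rows, cols, drow, dcol = _design(fit._plots, fit.trait)
    structures = {"genotype": Xg @ Xg.T}
    if fit.spec.row_effect and len(np.unique(rows)) > 1:
        structures["row"] = _incidence(rows)
    if fit.spec.col_effect and len(np.unique(cols)) > 1:
        structures["col"] = _incidence(cols)
    rho_names = []
    if fit.spec.residual in ("AR1_ROW", "AR1_BOTH") and len(np.unique(rows)) > 1:
        rho_names.append("rho_row")
    if fit.spec.residual in ("AR1_COL", "AR1_BOTH") and len(np.unique(cols)) > 1:
        rho_names.append("rho_col")
    builder = _make_residual_builder(drow, dcol) if rho_names else None
    res = reml_general(y, np.ones((len(y), 1)), structures,
                       builder, rho_names=tuple(rho_names))
    return res.variance("genotype")


def filter_trials(fits: list[TrialFit], trait_class: str) -> list[str]:
    """Stage-one quality filter.

    Agronomic traits keep trials with h2 strictly above 0.3; rheology
    traits drop trials with h2 strictly below 0.1 and keep trials whose
    h2 could not be assessed.
    """
    if trait_class not in ("agronomic", "rheology"):
        raise ValueError(f"unknown trait class {trait_class!r}")
    kept = []
    for f in fits:
        if f.h2 is None or f.unassessable:
            if trait_class == "rheology":
                kept.append(f.trial)
            continue
        if trait_class == "agronomic":
            if f.h2 > 0.3:
                kept.append(f.trial)
        else:
            if not f.h2 < 0.1:
                kept.append(f.trial)
    return kept


# ---------------------------------------------------------------------------
# stage two


@dataclass
class AcrossTrialResult:
    trait: str
    blues: pd.Series
    h2: float | None
    included_trials: list[str]
    grand_mean: float
    mvd: float
    connected_groups: list[set[str]] = field(default_factory=list)


def _trial_contrasts(trials: list[str], trial_codes: np.ndarray) -> np.ndarray:
    """Sum-to-zero coding for the trial factor (T-1 columns)."""
    T = len(trials)
    C = np.zeros((len(trial_codes), T - 1))
    for j in range(T - 1):
        C[trial_codes == j, j] = 1.0
    C[trial_codes == T - 1, :] = -1.0
    return C


def across_trial_analysis(
    stage1_blues: pd.DataFrame, trait: str,
) -> AcrossTrialResult:
    """Combine per-trial BLUEs: y_ij = mu + g_i + t_j + r_ij.

    Genotype and trial are fixed (sum-to-zero trial coding), the
    residual absorbs line-by-trial interaction and is iid.  BLUEs are
    ordinary least squares; the across-trial heritability comes from a
    parallel genotype-random fit combined with the MVD of the fixed-
    genotype fit.  ``stage1_blues`` is a long table with columns
    (line, trial, blue).
    """
    df = stage1_blues.dropna(subset=["blue"]).copy()
    if df.empty:
        raise ValueError("no stage-one BLUEs supplied")
    lines = sorted(df["line"].astype(str).unique())
    trials = sorted(df["trial"].astype(str).unique())

    # connectivity of the trial graph through shared lines
    groups: list[set[str]] = []
    line_trials = df.groupby(df["line"].astype(str))["trial"].apply(
        lambda s: set(s.astype(str)))
    parent = {t: t for t in trials}

    def find(t):
        while parent[t] != t:
            parent[t] = parent[parent[t]]
            t = parent[t]
        return t

    for ts in line_trials:
        ts = sorted(ts)
        for other in ts[1:]:
            parent[find(other)] = find(ts[0])
    comp: dict[str, set[str]] = {}
    for t in trials:
        comp.setdefault(find(t), set()).add(t)
    groups = list(comp.values())
    if len(trials) > 1 and len(groups) == len(trials):
        raise ValueError("trial graph fully disconnected: no shared lines")

    y = df["blue"].to_numpy(float)
    line_codes = pd.Categorical(df["line"].astype(str), categories=lines).codes
    trial_codes = pd.Categorical(df["trial"].astype(str), categories=trials).codes
    Xg = np.zeros((len(df), len(lines)))
    Xg[np.arange(len(df)), line_codes] = 1.0

    if len(trials) == 1:
        X = Xg
    else:
        X = np.hstack([Xg, _trial_contrasts(trials, trial_codes)])

    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    blues = pd.Series(beta[: len(lines)], index=lines, name=trait)
    resid = y - X @ beta
    dof = len(y) - rank
    q = len(lines)

    h2 = None
    mvd = float("nan")
    if dof > 0 and (np.bincount(line_codes) >= 2).any():
        s2 = float(resid @ resid) / dof
        XtX_inv = np.linalg.pinv(X.T @ X)
        C = s2 * XtX_inv[:q, :q]
        T_, S_ = float(np.trace(C)), float(C.sum())
        mvd = (q * T_ - S_) * 2.0 / (q * (q - 1))
        X2 = (np.ones((len(y), 1)) if len(trials) == 1 else
              np.hstack([np.ones((len(y), 1)), _trial_contrasts(trials, trial_codes)]))
        res = reml_kernel(y, X2, Z=Xg)
        s2g = res.sigma2_u
        h2 = s2g / (s2g + mvd / 2.0) if (s2g + mvd) > 0 else 0.0

    return AcrossTrialResult(
        trait=trait, blues=blues, h2=h2, included_trials=trials,
        grand_mean=float(blues.mean()), mvd=mvd, connected_groups=groups,
    )


# ---------------------------------------------------------------------------
# full stage-one + stage-two chain


def analyse_trait(
    plots: pd.DataFrame, trait: str, trait_class: str,
    error_source: str | None = None,
) -> tuple[AcrossTrialResult, pd.DataFrame]:
    """Run the full two-stage chain for one trait.

    Per trial: fit the 16 spatial candidates, select by AIC, compute
    heritability (checks-only error for rheology traits by default),
    filter, then combine the surviving trials' BLUEs across trials.
    Returns the across-trial result and a per-trial report table.
    """
    validate_plot_table(plots)
    if error_source is None:
        error_source = "checks_only" if trait_class == "rheology" else "all_lines"
    selected: list[TrialFit] = []
    for trial_id, tp in plots.groupby("trial"):
        if tp[trait].notna().sum() == 0 or tp.loc[tp[trait].notna(), "line"].nunique() < 2:
            continue
        fits = fit_spatial_models(tp, trait)
        best = select_model_aic(fits)
        trial_heritability(best, error_source=error_source)
        selected.append(best)

    kept = set(filter_trials(selected, trait_class))
    report = pd.DataFrame([{
        "trial": f.trial, "trait": f.trait, "spec": f.spec.label,
        "aic": f.aic, "h2": f.h2, "mvd": f.mvd,
        "kept": f.trial in kept,
        **{f"vc_{k}": v for k, v in f.variance_components.items()},
    } for f in selected])

    long = pd.concat([
        pd.DataFrame({"line": f.blues.index, "trial": f.trial, "blue": f.blues.values})
        for f in selected if f.trial in kept
    ], ignore_index=True)
    result = across_trial_analysis(long, trait)
    return result, report
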