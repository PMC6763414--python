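"""Single-trait genomic prediction.

GBLUP fits y = 1 mu + u + e with u ~ N(0, K s2u) on the training lines
and predicts breeding values for untested lines through the genomic
relationship matrix; the variance components come from an exact 1-D
profile REML (one eigendecomposition of the projected kernel, then a
scalar search over the variance ratio).  WBLUP adds the three glutenin
loci as separate effects, either fixed (absorbed into the GLS fixed
effects) or random with one variance per locus (differential shrinkage,
fitted by the general dense REML).  Marker-only prediction drops the
genomic kernel.  Every predicted value decomposes exactly as

    GEBV_i = mu + g_i (+ sum_j m_ij beta_j).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from ._mixed import reml_general, reml_kernel
from .containers import Kinship

MODEL_TAGS = ("GBLUP", "WBLUP_fixed", "WBLUP_random",
              "MARKER_fixed", "MARKER_random")


@dataclass
class VarianceComponents:
    sigma2_u: float
    sigma2_e: float
    reml_loglik: float
    sigma2_m: dict[str, float] = field(default_factory=dict)
    boundary: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.sigma2_u < 0 or self.sigma2_e < 0:
            raise ValueError("variances must be non-negative")


@dataclass
class GebvResult:
    """Per-line GEBVs with their exact decomposition."""

    values: pd.DataFrame          # columns: gebv, mu, genomic, glu
    model: str
    varcomp: VarianceComponents
    dropped_glu: list[str] = field(default_factory=list)

    @property
    def gebv(self) -> pd.Series:
        return self.values["gebv"]


def reml_single_kernel(y: pd.Series, K: Kinship) -> VarianceComponents:
    """Variance components of the intercept-only single-kernel model."""
    y = y.dropna()
    if len(y) < 10:
        raise ValueError("need at least 10 phenotyped lines")
    Ksub = K.subset(list(y.index.astype(str)))
    if float(y.var(ddof=1)) < 1e-12:
        warnings.warn("constant phenotype: variance components at zero")
        return VarianceComponents(0.0, 0.0, float("nan"),
                                  boundary=["sigma2_u", "sigma2_e"])
    res = reml_kernel(y.to_numpy(float), np.ones((len(y), 1)), K=Ksub.K)
    return VarianceComponents(res.sigma2_u, res.sigma2_e, res.reml_loglik,
                              boundary=[res.boundary] if res.boundary else [])


def _check_partition(train_y: pd.Series, K: Kinship, test_lines) -> None:
    train = set(train_y.index.astype(str))
    test = set(map(str, test_lines))
    known = set(K.lines)
    if not train <= known or not test <= known:
        raise ValueError("train/test lines missing from the kinship matrix")
    if train & test:
        raise ValueError("test lines overlap the training set")


def _assemble(lines, mu, genomic, glu, model, vc, dropped=()) -> GebvResult:
    df = pd.DataFrame({"mu": mu, "genomic": genomic, "glu": glu},
                      index=list(lines))
    df["gebv"] = df["mu"] + df["genomic"] + df["glu"]
    return GebvResult(df[["gebv", "mu", "genomic", "glu"]], model, vc,
                      list(dropped))


def gblup_predict(
    train_y: pd.Series, K: Kinship, test_lines: list[str],
) -> GebvResult:
    """GBLUP breeding values GEBV_i = mu + g_i for train and test lines."""
    train_y = train_y.dropna()
    _check_partition(train_y, K, test_lines)
    train = list(train_y.index.astype(str))
    lines = train + [l for l in map(str, test_lines) if l not in train]
    Ksub = K.subset(lines)
    n_tr = len(train)
    y = train_y.to_numpy(float)

    res = reml_kernel(y, np.ones((n_tr, 1)), K=Ksub.K[:n_tr, :n_tr])
    mu = float(res.beta[0])
    if res.sigma2_u == 0.0:
        g = np.zeros(len(lines))
    else:
        c = cho_factor(res.V + 1e-10 * np.eye(n_tr), lower=True)
        g = res.sigma2_u * Ksub.K[:, :n_tr] @ cho_solve(c, y - mu)
    vc = VarianceComponents(res.sigma2_u, res.sigma2_e, res.reml_loglik,
                            boundary=[res.boundary] if res.boundary else [])
    return _assemble(lines, mu, g, np.zeros(len(lines)), "GBLUP", vc)


def _glu_design(glu: pd.DataFrame, lines: list[str]):
    M = glu.reindex(lines).fillna(0.0).to_numpy(float)
    return M, list(glu.columns)


def wblup_predict(
    train_y: pd.Series, K: Kinship, glu: pd.DataFrame,
    mode: str = "random", test_lines: list[str] = (),
) -> GebvResult:
    """Weighted GBLUP: glutenin loci as separate fixed or random effects.

    Fixed mode absorbs the -1/0/+1 locus columns into the GLS fixed
    effects (columns constant in training are dropped with a warning);
    random mode estimates one variance per locus by dense REML, giving
    locus-specific shrinkage.  GEBV_i = mu + g_i + sum_j m_ij beta_j.
    """
    if mode not in ("fixed", "random"):
        raise ValueError(f"unknown WBLUP mode {mode!r}")
    train_y = train_y.dropna()
    _check_partition(train_y, K, test_lines)
    train = list(train_y.index.astype(str))
    lines = train + [l for l in map(str, test_lines) if l not in train]
    Ksub = K.subset(lines)
    n_tr = len(train)
    y = train_y.to_numpy(float)
    M_all, loci = _glu_design(glu, lines)
    M_tr = M_all[:n_tr]

    keep = [j for j in range(M_tr.shape[1]) if np.ptp(M_tr[:, j]) > 0]
    dropped = [loci[j] for j in range(len(loci)) if j not in keep]
    if dropped:
        warnings.warn(f"glutenin effects inestimable (constant in training): {dropped}")
    loci_kept = [loci[j] for j in keep]

    if mode == "fixed":
        X = np.hstack([np.ones((n_tr, 1)), M_tr[:, keep]])
        res = reml_kernel(y, X, K=Ksub.K[:n_tr, :n_tr])
        mu = float(res.beta[0])
        beta = res.beta[1:]
        if res.sigma2_u == 0.0:
            g = np.zeros(len(lines))
        else:
            c = cho_factor(res.V + 1e-10 * np.eye(n_tr), lower=True)
            g = res.sigma2_u * Ksub.K[:, :n_tr] @ cho_solve(c, y - X @ res.beta)
        vc = VarianceComponents(res.sigma2_u, res.sigma2_e, res.reml_loglik,
                                boundary=[res.boundary] if res.boundary else [])
        glu_part = M_all[:, keep] @ beta
        return _assemble(lines, mu, g, glu_part, "WBLUP_fixed", vc, dropped)

    structures = {"genomic": Ksub.K[:n_tr, :n_tr]}
    for j, name in zip(keep, loci_kept):
        m = M_tr[:, j:j + 1]
        structures[name] = m @ m.T
    res = reml_general(y, np.ones((n_tr, 1)), structures)
    mu = float(res.beta[0])
    s2u = res.variance("genomic")
    s2m = {name: res.variance(name) for name in loci_kept}
    V = res.sigma2_e * np.eye(n_tr) + s2u * Ksub.K[:n_tr, :n_tr]
    for j, name in zip(keep, loci_kept):
        m = M_tr[:, j:j + 1]
        V += s2m[name] * (m @ m.T)
    c = cho_factor(V + 1e-10 * np.eye(n_tr), lower=True)
    r = cho_solve(c, y - mu)
    g = s2u * Ksub.K[:, :n_tr] @ r if s2u > 0 else np.zeros(len(lines))
    beta = np.array([s2m[name] * float(M_tr[:, j] @ r)
                     for j, name in zip(keep, loci_kept)])
    glu_part = M_all[:, keep] @ beta
    vc = VarianceComponents(s2u, res.sigma2_e, res.reml_loglik,
                            sigma2_m=s2m, boundary=list(res.boundary))
    return _assemble(lines, mu, g, glu_part, "WBLUP_random", vc, dropped)


def marker_only_predict(
    train_y: pd.Series, glu: pd.DataFrame,
    mode: str = "fixed", test_lines: list[str] = (),
) -> GebvResult:
    """Marker-assisted prediction from the three glutenin loci alone."""
    if mode not in ("fixed", "random"):
        raise ValueError(f"unknown marker-only mode {mode!r}")
    train_y = train_y.dropna()
    train = list(train_y.index.astype(str))
    overlap = set(train) & set(map(str, test_lines))
    if overlap:
        raise ValueError("test lines overlap the training set")
    lines = train + [l for l in map(str, test_lines) if l not in train]
    n_tr = len(train)
    y = train_y.to_numpy(float)
    M_all, loci = _glu_design(glu, lines)
    M_tr = M_all[:n_tr]
    keep = [j for j in range(M_tr.shape[1]) if np.ptp(M_tr[:, j]) > 0]
    dropped = [loci[j] for j in range(len(loci)) if j not in keep]
    if dropped:
        warnings.warn(f"glutenin effects inestimable (constant in training): {dropped}")
    loci_kept = [loci[j] for j in keep]

    if mode == "fixed":
        X = np.hstack([np.ones((n_tr, 1)), M_tr[:, keep]])
        beta_full, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        mu, beta = float(beta_full[0]), beta_full[1:]
        resid = y - X @ beta_full
        s2e = float(resid @ resid) / max(n_tr - X.shape[1], 1)
        vc = VarianceComponents(0.0, s2e, float("nan"))
    else:
        structures = {}
        for j, name in zip(keep, loci_kept):
            m = M_tr[:, j:j + 1]
            structures[name] = m @ m.T
        res = reml_general(y, np.ones((n_tr, 1)), structures)
        mu = float(res.beta[0])
        s2m = {name: res.variance(name) for name in loci_kept}
        V = res.sigma2_e * np.eye(n_tr)
        for j, name in zip(keep, loci_kept):
            m = M_tr[:, j:j + 1]
            V += s2m[name] * (m @ m.T)
        c = cho_factor(V + 1e-10 * np.eye(n_tr), lower=True)
        r = cho_solve(c, y - mu)
        beta = np.array([s2m[name] * float(M_tr[:, j] @ r)
                         for j, name in zip(keep, loci_kept)])
        vc = VarianceComponents(0.0, res.sigma2_e, res.reml_loglik,
                                sigma2_m=s2m, boundary=list(res.boundary))
    glu_part = M_all[:, keep] @ np.asarray(beta)
    tag = "MARKER_fixed" if mode == "fixed" else "MARKER_random"
    return _assemble(lines, mu, np.zeros(len(lines)), glu_part, tag, vc, dropped)


def genomic_heritability(
    validation_y: pd.Series, K_val: Kinship,
    clamp: tuple[float, float] = (0.01, 1.0),
) -> tuple[float, bool]:
    """Genomic heritability h2 = (s2_P - s2_e) / s2_P in a validation set.

    s2_P is the sample phenotypic variance, s2_e the residual variance
    of a GBLUP fit on the validation data only.  The estimate is
    clamped to ``clamp``; the second return value flags clamping.
    """
    y = validation_y.dropna()
    if len(y) < 20:
        raise ValueError("validation set must have at least 20 lines")
    s2p = float(y.var(ddof=1))
    if s2p <= 0:
        raise ValueError("zero phenotypic variance in validation set")
    vc = reml_single_kernel(y, K_val)
    h2 = (s2p - vc.sigma2_e) / s2p
    lo, hi = clamp
    if h2 < lo:
        return lo, True
    if h2 > hi:
        return hi, True
    return float(h2), False
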