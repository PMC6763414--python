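"""Marker QC, imputation, glutenin recoding, kinship and structure.

The genomic relationship matrix follows the Endelman & Jannink /
VanRaden form

    K = W W' / (2 Sum_k p_k (1 - p_k)),    W_ik = Z_ik + 1 - 2 p_k,

with dosages Z in {-1, 0, +1} and p_k the frequency of the +1-coded
allele computed from the (imputed) matrix itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, Kinship
from .traits import GLU_LOCI

# ---------------------------------------------------------------------------
# QC

QC_MIN_CALL_RATE = 0.90
QC_MIN_MAF = 0.05
QC_MAX_MISSING = 0.10


@dataclass
class QCReport:
    n_input: int
    n_kept: int
    removed_call_rate: list[str] = field(default_factory=list)
    removed_maf: list[str] = field(default_factory=list)
    removed_missing: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input, "n_kept": self.n_kept,
            "removed_call_rate": self.removed_call_rate,
            "removed_maf": self.removed_maf,
            "removed_missing": self.removed_missing,
        }


def qc_markers(
    raw: GenotypeMatrix,
    min_call_rate: float = QC_MIN_CALL_RATE,
    min_maf: float = QC_MIN_MAF,
    max_missing: float = QC_MAX_MISSING,
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop markers by call rate, minor allele frequency and missingness.

    A marker fails when its call rate is below ``min_call_rate``, its
    MAF is below ``min_maf`` (strict), or its missing fraction exceeds
    ``max_missing`` (strict).  Lines are never removed.
    """
    miss = raw.missing_rate()
    call_rate = 1.0 - miss
    p = raw.allele_frequency()
    maf = np.minimum(p, 1.0 - p)

    fail_cr = call_rate < min_call_rate
    fail_maf = maf < min_maf
    fail_miss = miss > max_missing
    keep = ~(fail_cr | fail_maf | fail_miss)
    if not keep.any():
        raise ValueError("QC removed every marker")

    mk = np.asarray(raw.markers)
    report = QCReport(
        n_input=raw.n_markers, n_kept=int(keep.sum()),
        removed_call_rate=list(mk[fail_cr]),
        removed_maf=list(mk[fail_maf & ~fail_cr]),
        removed_missing=list(mk[fail_miss & ~fail_cr & ~fail_maf]),
    )
    return raw.subset_markers(keep), report


# ---------------------------------------------------------------------------
# imputation


def _mode_impute_column(col: np.ndarray) -> np.ndarray:
    vals, counts = np.unique(col[~np.isnan(col)], return_counts=True)
    mode = vals[np.argmax(counts)]
    out = col.copy()
    out[np.isnan(out)] = mode
    return out


def impute_missing(
    qc: GenotypeMatrix,
    method: str = "iterative_forest_like",
    seed: int = 0,
    k_neighbours: int = 5,
    min_corr: float = 0.25,
    max_iter: int = 5,
) -> GenotypeMatrix:
    """Chromosome-wise imputation of missing dosages.

    ``column_mode`` fills each marker with its most frequent dosage.
    ``iterative_forest_like`` is an iterative nearest-marker classifier:
    after a mode initialization, each originally missing entry is
    re-predicted as the per-line majority vote over the ``k_neighbours``
    most correlated markers on the same chromosome, looped until the
    imputed entries stabilize.  Only markers on the same chromosome
    inform each other in either mode.
    """
    if method not in ("iterative_forest_like", "column_mode"):
        raise ValueError(f"unknown imputation method {method!r}")
    out = qc.copy()
    X = out.dosages
    miss_mask = np.isnan(X)
    if not miss_mask.any():
        return out
    if miss_mask.all(axis=0).any():
        raise ValueError("a marker is entirely missing; run QC first")

    for k in range(X.shape[1]):
        if miss_mask[:, k].any():
            X[:, k] = _mode_impute_column(X[:, k])
    if method == "column_mode":
        return out

    for chrom in np.unique(out.chromosome):
        cols = np.flatnonzero(out.chromosome == chrom)
        sub_mask = miss_mask[:, cols]
        if not sub_mask.any() or len(cols) < 2:
            continue
        sub = X[:, cols]
        for _ in range(max_iter):
            with np.errstate(invalid="ignore", divide="ignore"):
                C = np.nan_to_num(np.corrcoef(sub.T))
            np.fill_diagonal(C, 0.0)
            absC = np.abs(C)
            changed = False
            for j in np.flatnonzero(sub_mask.any(axis=0)):
                kk = min(k_neighbours, len(cols) - 1)
                nb = np.argpartition(absC[j], -kk)[-kk:]
                nb = nb[absC[j, nb] >= min_corr]
                if nb.size == 0:
                    continue  # no informative neighbour: keep column mode
                w = absC[j, nb] ** 2
                sgn = np.sign(C[j, nb])
                vals, counts = np.unique(sub[~sub_mask[:, j], j],
                                         return_counts=True)
                mode_j = vals[np.argmax(counts)]
                prior = float(w.sum()) * 0.25
                rows = np.flatnonzero(sub_mask[:, j])
                for i in rows:
                    # a negatively correlated neighbour votes for the
                    # opposite dosage; the column mode casts a prior vote
                    votes: dict[float, float] = {mode_j: prior}
                    for v, s, wt in zip(sub[i, nb], sgn, w):
                        votes[s * v] = votes.get(s * v, 0.0) + wt
                    best = max(sorted(votes), key=lambda v: votes[v])
                    if best != sub[i, j]:
                        sub[i, j] = best
                        changed = True
            if not changed:
                break
        X[:, cols] = sub
    return out


# ---------------------------------------------------------------------------
# glutenin recoding

#: raw allele string -> -1/+1 code, per locus ("x/y" strings are heterozygous)
GLU_CODING: dict[str, dict[str, float]] = {
    "Glu-A1": {"0": -1.0, "1": 1.0, "2*": 1.0},
    "Glu-B1": {"6+8": -1.0, "7+8": 1.0, "7+9": 1.0},
    "Glu-D1": {"5+10": -1.0, "2+12": 1.0},
}


def recode_glu(raw_calls: pd.DataFrame) -> pd.DataFrame:
    """Recode raw glutenin allele strings to the -1/0/+1 scheme.

    Glu-A1: 0 -> -1; 1, 2* -> +1.  Glu-B1: 6+8 -> -1; 7+8, 7+9 -> +1.
    Glu-D1: 5+10 -> -1; 2+12 -> +1.  Heterozygous calls ("x/y") map to
    0; missing stays missing; any other string raises.
    """
    missing_cols = [l for l in GLU_LOCI if l not in raw_calls.columns]
    if missing_cols:
        raise ValueError(f"glutenin table misses loci {missing_cols}")
    out = pd.DataFrame(index=raw_calls.index, columns=list(GLU_LOCI), dtype=float)
    for loc in GLU_LOCI:
        table = GLU_CODING[loc]
        for idx, call in raw_calls[loc].items():
            if call is None or (isinstance(call, float) and np.isnan(call)):
                out.loc[idx, loc] = np.nan
                continue
            call = str(call)
            if "/" in call:
                a, b = call.split("/", 1)
                if a not in table or b not in table:
                    raise ValueError(f"unknown {loc} allele in {call!r}")
                out.loc[idx, loc] = 0.0
            elif call in table:
                out.loc[idx, loc] = table[call]
            else:
                raise ValueError(f"unknown {loc} allele {call!r}")
    return out


def glu_model_matrix(coded: pd.DataFrame, missing_policy: str = "neutral") -> pd.DataFrame:
    """Model matrix for the three glutenin loci.

    ``neutral`` codes unscreened lines 0 (no information); ``drop``
    removes them.
    """
    if missing_policy == "neutral":
        return coded.fillna(0.0)
    if missing_policy == "drop":
        return coded.dropna()
    raise ValueError(f"unknown missing policy {missing_policy!r}")


# ---------------------------------------------------------------------------
# kinship and diversity


def compute_grm(geno: GenotypeMatrix) -> Kinship:
    """Genomic relationship matrix K = WW' / (2 Sum p_k(1-p_k))."""
    Z = geno.dosages
    if np.isnan(Z).any():
        raise ValueError("GRM requires a complete matrix; impute first")
    p = (Z.mean(axis=0) + 1.0) / 2.0
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0:
        raise ValueError("all markers monomorphic: zero GRM denominator")
    W = Z + 1.0 - 2.0 * p
    K = (W @ W.T) / denom
    K = (K + K.T) / 2.0
    return Kinship(list(geno.lines), K, denom)


def modified_rogers_distance(geno: GenotypeMatrix) -> tuple[pd.DataFrame, float]:
    """Pairwise modified Rogers' distances and their population mean.

    For biallelic loci with inbred-style dosages z in {-1, 0, +1} the
    allele-frequency form reduces to

        D_ij = sqrt( Sum_k (z_ik - z_jk)^2 / (4 m) ),

    which is 0 for identical lines and 1 for opposite homozygotes at
    every locus.  The mean is over unordered pairs.
    """
    Z = geno.dosages
    if np.isnan(Z).any():
        raise ValueError("distances require a complete matrix")
    n, m = Z.shape
    sq = np.sum(Z * Z, axis=1)
    D2 = (sq[:, None] + sq[None, :] - 2.0 * Z @ Z.T) / (4.0 * m)
    D = np.sqrt(np.clip(D2, 0.0, None))
    np.fill_diagonal(D, 0.0)
    dist = pd.DataFrame(D, index=geno.lines, columns=geno.lines)
    iu = np.triu_indices(n, k=1)
    mean_d = float(D[iu].mean()) if n > 1 else 0.0
    return dist, mean_d


def structure_pca(K: Kinship, n_components: int = 10) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal components of the kinship matrix.

    Returns per-line scores (eigenvector * sqrt(eigenvalue)) ordered by
    decreasing eigenvalue, and the explained-variance fractions.
    """
    M = np.asarray(K.K, dtype=float)
    if not np.allclose(M, M.T, atol=1e-8):
        raise ValueError("kinship must be symmetric")
    vals, vecs = np.linalg.eigh(M)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    vals_c = np.clip(vals, 0.0, None)
    k = min(n_components, len(vals))
    scores = vecs[:, :k] * np.sqrt(vals_c[:k])
    explained = vals_c / vals_c.sum() if vals_c.sum() > 0 else vals_c
    cols = [f"PC{i + 1}" for i in range(k)]
    return pd.DataFrame(scores, index=K.lines, columns=cols), explained[:k]


# ---------------------------------------------------------------------------
# VCF import


def genotypes_from_vcf(path: str) -> GenotypeMatrix:
    """Import diploid biallelic GT calls from an (uncompressed) VCF.

    0/0 -> -1, 0/1 or 1/0 -> 0, 1/1 -> +1, missing -> NaN.
    """
    lines: list[str] = []
    markers, chroms, poss, rows = [], [], [], []
    with open(path) as fh:
        for raw in fh:
            if raw.startswith("##"):
                continue
            parts = raw.rstrip("\n").split("\t")
            if raw.startswith("#CHROM"):
                lines = parts[9:]
                continue
            chrom, pos, vid, ref, alt = parts[0], parts[1], parts[2], parts[3], parts[4]
            if "," in alt:
                warnings.warn(f"skipping multi-allelic site {vid}")
                continue
            fmt = parts[8].split(":")
            gt_i = fmt.index("GT")
            row = []
            for samp in parts[9:]:
                gt = samp.split(":")[gt_i].replace("|", "/")
                if gt in ("./.", "."):
                    row.append(np.nan)
                else:
                    a = sorted(gt.split("/"))
                    row.append({"00": -1.0, "01": 0.0, "11": 1.0}["".join(a)])
            markers.append(vid if vid != "." else f"{chrom}:{pos}")
            chroms.append(chrom)
            poss.append(float(pos))
            rows.append(row)
    return GenotypeMatrix(lines, markers, np.array(chroms),
                          np.array(poss), np.array(rows, dtype=float).T)
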