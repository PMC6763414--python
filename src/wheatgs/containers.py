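"""Shared data containers and their plain-text readers/writers."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .traits import ALL_TRAITS

#: columns every plot table carries in addition to trait columns
PLOT_META_COLUMNS = ["line", "trial", "year", "row", "col", "is_check"]


@dataclass
class GenotypeMatrix:
    """Line x marker dosage matrix with a marker map.

    Dosages are coded -1 / 0 / +1 (homozygous reference, heterozygous,
    homozygous alternative); missing calls are ``NaN``.
    """

    lines: list[str]
    markers: list[str]
    chromosome: np.ndarray
    position: np.ndarray
    dosages: np.ndarray  # float, shape (n_lines, n_markers), NaN = missing

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.chromosome = np.asarray(self.chromosome)
        self.position = np.asarray(self.position, dtype=float)
        n, m = self.dosages.shape
        if n != len(self.lines) or m != len(self.markers):
            raise ValueError("dosage shape does not match line/marker labels")
        legal = np.isnan(self.dosages) | np.isin(self.dosages, (-1.0, 0.0, 1.0))
        if not legal.all():
            raise ValueError("dosages must be -1, 0, +1 or missing")

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.dosages).any())

    def missing_rate(self) -> np.ndarray:
        """Per-marker fraction of missing calls."""
        return np.isnan(self.dosages).mean(axis=0)

    def allele_frequency(self) -> np.ndarray:
        """Per-marker frequency of the +1-coded allele, ignoring missing."""
        with np.errstate(invalid="ignore"):
            return (np.nanmean(self.dosages, axis=0) + 1.0) / 2.0

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.lines), list(self.markers),
            self.chromosome.copy(), self.position.copy(), self.dosages.copy(),
        )

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return GenotypeMatrix(
            list(self.lines),
            [self.markers[i] for i in np.flatnonzero(keep)] if keep.dtype == bool
            else [self.markers[i] for i in keep],
            self.chromosome[keep], self.position[keep], self.dosages[:, keep],
        )

    def subset_lines(self, line_ids: list[str]) -> "GenotypeMatrix":
        idx = [self.lines.index(l) for l in line_ids]
        return GenotypeMatrix(
            list(line_ids), list(self.markers),
            self.chromosome.copy(), self.position.copy(), self.dosages[idx],
        )

    # -- plain-text round trip ------------------------------------------------

    def to_tsv(self, geno_path: str | Path, map_path: str | Path) -> None:
        df = pd.DataFrame(self.dosages, index=self.lines, columns=self.markers)
        df.index.name = "line"
        df.to_csv(geno_path, sep="\t", na_rep="")
        pd.DataFrame(
            {"marker": self.markers, "chromosome": self.chromosome,
             "position": self.position}
        ).to_csv(map_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, geno_path: str | Path, map_path: str | Path) -> "GenotypeMatrix":
        df = pd.read_csv(geno_path, sep="\t", index_col=0)
        mp = pd.read_csv(map_path, sep="\t").set_index("marker").loc[df.columns]
        return cls(
            [str(l) for l in df.index], [str(m) for m in df.columns],
            mp["chromosome"].to_numpy(), mp["position"].to_numpy(float),
            df.to_numpy(float),
        )


@dataclass
class Kinship:
    """Genomic relationship matrix K = W W' / (2 Σ p_k (1-p_k))."""

    lines: list[str]
    K: np.ndarray
    denominator: float = float("nan")

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        if self.K.shape != (len(self.lines), len(self.lines)):
            raise ValueError("kinship shape does not match line labels")

    def subset(self, line_ids: list[str]) -> "Kinship":
        idx = np.array([self.lines.index(l) for l in line_ids])
        return Kinship(list(line_ids), self.K[np.ix_(idx, idx)], self.denominator)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.K, index=self.lines, columns=self.lines)
        df.index.name = "line"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Kinship":
        df = pd.read_csv(path, index_col=0)
        return cls([str(l) for l in df.index], df.to_numpy(float))


@dataclass
class BlueSet:
    """Line-level BLUEs per trait with heritability metadata.

    ``blues`` is a line x trait DataFrame (NaN where a line has no data for a
    trait); ``h2`` maps trait -> across-trial heritability; ``trial_reports``
    optionally keeps the per-trial stage-one summaries.
    """

    blues: pd.DataFrame
    h2: dict[str, float] = field(default_factory=dict)
    trial_reports: pd.DataFrame | None = None

    @property
    def lines(self) -> list[str]:
        return [str(l) for l in self.blues.index]

    def to_csv(self, path: str | Path) -> None:
        out = self.blues.copy()
        out.index.name = "line"
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "BlueSet":
        df = pd.read_csv(path, index_col=0)
        df.index = df.index.astype(str)
        return cls(df)


def validate_plot_table(plots: pd.DataFrame) -> None:
    """Check plot-table schema: metadata columns plus at least one trait."""
    missing = [c for c in PLOT_META_COLUMNS if c not in plots.columns]
    if missing:
        raise ValueError(f"plot table misses columns {missing}")
    if not any(t in plots.columns for t in ALL_TRAITS):
        raise ValueError("plot table has no trait columns")
    dup = plots.duplicated(subset=["trial", "row", "col"])
    if dup.any():
        raise ValueError("duplicate (trial, row, col) plot coordinates")
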