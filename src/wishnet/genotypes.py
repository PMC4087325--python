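"""Core genotype containers: genetic map and dosage matrix.

Dosages are stored as a float array counting copies of the line-A (reference)
allele, 0/1/2, with ``NaN`` marking missing calls.  All downstream statistics
(correlation, regression) are invariant to affine recoding, so external
dialects that code genotypes 1/2/3 or 1/2-with-0-missing are translated to
this representation at the I/O boundary, never inside the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GeneticMap", "GenotypeMatrix"]


@dataclass(frozen=True)
class GeneticMap:
    """Marker map: chromosome, physical (bp) and genetic (cM) positions.

    Positions must be strictly increasing within each chromosome on both
    scales; chromosome ids must be non-empty strings.
    """

    chrom: np.ndarray
    marker: np.ndarray
    bp: np.ndarray
    cm: np.ndarray

    def __post_init__(self) -> None:
        chrom = np.asarray(self.chrom, dtype=object)
        marker = np.asarray(self.marker, dtype=object)
        bp = np.asarray(self.bp, dtype=np.int64)
        cm = np.asarray(self.cm, dtype=float)
        if not (len(chrom) == len(marker) == len(bp) == len(cm)):
            raise ValueError("map columns have inconsistent lengths")
        if any(not str(c) for c in chrom):
            raise ValueError("empty chromosome id in map")
        if np.any(cm < 0):
            raise ValueError("negative genetic position in map")
        for c in pd.unique(chrom):
            sel = chrom == c
            if np.any(np.diff(bp[sel]) <= 0):
                raise ValueError(f"bp positions not strictly increasing on chromosome {c}")
            if np.any(np.diff(cm[sel]) <= 0):
                raise ValueError(f"cM positions not strictly increasing on chromosome {c}")
        object.__setattr__(self, "chrom", chrom)
        object.__setattr__(self, "marker", marker)
        object.__setattr__(self, "bp", bp)
        object.__setattr__(self, "cm", cm)

    def __len__(self) -> int:
        return len(self.marker)

    @property
    def chromosomes(self) -> list:
        return list(pd.unique(self.chrom))

    def chrom_indices(self, c) -> np.ndarray:
        return np.flatnonzero(self.chrom == c)

    def subset(self, idx: np.ndarray) -> "GeneticMap":
        idx = np.asarray(idx)
        return GeneticMap(self.chrom[idx], self.marker[idx], self.bp[idx], self.cm[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chrom, "marker": self.marker, "cm": self.cm, "bp": self.bp}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GeneticMap":
        return cls(
            df["chrom"].to_numpy(dtype=object),
            df["marker"].to_numpy(dtype=object),
            df["bp"].to_numpy(),
            df["cm"].to_numpy(dtype=float),
        )


@dataclass
class GenotypeMatrix:
    """Animals x markers allele-dosage matrix with missing-data mask.

    ``dosages[i, j]`` counts the line-A allele of animal ``i`` at marker
    ``j`` (0, 1 or 2); missing entries are ``NaN``.
    """

    animal_ids: list = field(default_factory=list)
    dosages: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    gmap: GeneticMap | None = None
    marker_names: np.ndarray | None = None  # used when no map is attached

    def __post_init__(self) -> None:
        self.animal_ids = [str(a) for a in self.animal_ids]
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosage matrix must be 2-D")
        n, m = self.dosages.shape
        if n != len(self.animal_ids):
            raise ValueError("number of animal ids does not match dosage rows")
        if self.gmap is not None and m != len(self.gmap):
            raise ValueError("map does not cover all markers")
        if self.marker_names is not None:
            self.marker_names = np.asarray(self.marker_names, dtype=object)
            if len(self.marker_names) != m:
                raise ValueError("marker names do not match dosage columns")
        if len(set(self.animal_ids)) != n:
            raise ValueError("duplicate animal ids")
        obs = self.dosages[~np.isnan(self.dosages)]
        if obs.size and not np.isin(obs, (0.0, 1.0, 2.0)).all():
            raise ValueError("non-missing dosages must be 0, 1 or 2")

    # -- basic shape/accessors -------------------------------------------
    @property
    def n_animals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def marker_ids(self) -> np.ndarray:
        if self.gmap is not None:
            return self.gmap.marker
        if self.marker_names is not None:
            return self.marker_names
        return np.array([f"m{j}" for j in range(self.n_markers)], dtype=object)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosages)

    # -- summary statistics ----------------------------------------------
    def sample_missing_rate(self) -> np.ndarray:
        return self.missing_mask.mean(axis=1)

    def marker_missing_rate(self) -> np.ndarray:
        return self.missing_mask.mean(axis=0)

    def allele_freq(self) -> np.ndarray:
        """Frequency of the line-A allele per marker (NaN if fully missing)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def genotype_counts(self) -> np.ndarray:
        """(markers, 3) counts of genotypes 0/1/2 ignoring missing."""
        out = np.empty((self.n_markers, 3), dtype=np.int64)
        for g in (0, 1, 2):
            out[:, g] = np.nansum(self.dosages == g, axis=0)
        return out

    # -- subsetting ------------------------------------------------------
    def take_animals(self, ids) -> "GenotypeMatrix":
        pos = {a: i for i, a in enumerate(self.animal_ids)}
        missing = [a for a in ids if str(a) not in pos]
        if missing:
            raise KeyError(f"unknown animal ids: {missing[:5]}")
        idx = [pos[str(a)] for a in ids]
        return GenotypeMatrix([self.animal_ids[i] for i in idx],
                              self.dosages[idx], self.gmap, self.marker_names)

    def take_markers(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        gmap = self.gmap.subset(idx) if self.gmap is not None else None
        names = self.marker_ids[idx] if gmap is None else None
        return GenotypeMatrix(list(self.animal_ids), self.dosages[:, idx],
                              gmap, names)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.animal_ids, columns=self.marker_ids)
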