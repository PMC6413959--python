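"""Core in-memory containers: genotype matrices, genetic maps, kinship matrices.

Genotypes are stored as reference-allele dosages in {0, 1, 2} with NaN for
missing calls, one row per line (inbred variety) and one column per biallelic
marker.  Genetic maps hold per-marker chromosome and centimorgan position,
ordered along each chromosome.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError


class GenotypeMatrix:
    """Lines x markers matrix of reference-allele dosages.

    Parameters
    ----------
    dosage:
        2-D array-like, shape ``(n_lines, n_markers)``; values in {0, 1, 2}
        or NaN for missing.
    lines, markers:
        Unique identifiers for rows and columns.
    """

    def __init__(self, dosage, lines: Sequence[str], markers: Sequence[str]):
        dosage = np.asarray(dosage, dtype=float)
        if dosage.ndim != 2:
            raise ValidationError("dosage must be a 2-D array")
        lines = [str(x) for x in lines]
        markers = [str(x) for x in markers]
        if dosage.shape != (len(lines), len(markers)):
            raise ValidationError(
                f"dosage shape {dosage.shape} does not match "
                f"{len(lines)} lines x {len(markers)} markers"
            )
        if len(set(lines)) != len(lines):
            raise ValidationError("line ids are not unique")
        if len(set(markers)) != len(markers):
            raise ValidationError("marker ids are not unique")
        finite = dosage[np.isfinite(dosage)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValidationError("dosages must lie in [0, 2]")
        self.dosage = dosage
        self.lines = lines
        self.markers = markers
        self._line_idx = {x: i for i, x in enumerate(lines)}
        self._marker_idx = {x: i for i, x in enumerate(markers)}

    # -- basic protocol ----------------------------------------------------
    @property
    def n_lines(self) -> int:
        return len(self.lines)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GenotypeMatrix({self.n_lines} lines x {self.n_markers} markers)"

    def line_index(self, line: str) -> int:
        try:
            return self._line_idx[line]
        except KeyError:
            raise KeyError(f"unknown line id: {line!r}") from None

    def row(self, line: str) -> np.ndarray:
        return self.dosage[self.line_index(line)]

    # -- construction / IO -------------------------------------------------
    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GenotypeMatrix":
        """Build from a DataFrame with line ids as index and marker ids as columns."""
        return cls(frame.to_numpy(dtype=float), list(frame.index), list(frame.columns))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosage, index=self.lines, columns=self.markers)

    @classmethod
    def read_tsv(cls, path, missing: Iterable[str] = ("NA", "")) -> "GenotypeMatrix":
        frame = pd.read_csv(
            path, sep="\t", index_col=0, na_values=list(missing), keep_default_na=False
        )
        frame.index = frame.index.astype(str)
        return cls.from_frame(frame)

    def write_tsv(self, path, missing: str = "NA") -> None:
        self.to_frame().to_csv(path, sep="\t", na_rep=missing)

    # -- views -------------------------------------------------------------
    def subset_lines(self, lines: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.line_index(x) for x in lines]
        return GenotypeMatrix(self.dosage[idx], list(lines), self.markers)

    def subset_markers(self, markers: Sequence[str]) -> "GenotypeMatrix":
        idx = [self._marker_idx[m] for m in markers]
        return GenotypeMatrix(self.dosage[:, idx], self.lines, list(markers))

    # -- summaries ----------------------------------------------------------
    def allele_freq(self) -> np.ndarray:
        """Per-marker frequency of the reference allele among non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Per-marker minor-allele frequency."""
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)


class GeneticMap:
    """Ordered marker positions in centimorgans across chromosomes.

    Holds a DataFrame with columns ``marker``, ``chrom``, ``pos`` (cM).
    Markers are kept in the given order; positions must be non-decreasing
    within each chromosome.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"marker", "chrom", "pos"}
        if not required.issubset(frame.columns):
            raise ValidationError(f"map frame needs columns {sorted(required)}")
        frame = frame.loc[:, ["marker", "chrom", "pos"]].reset_index(drop=True)
        frame["marker"] = frame["marker"].astype(str)
        frame["chrom"] = frame["chrom"].astype(str)
        frame["pos"] = frame["pos"].astype(float)
        if frame["marker"].duplicated().any():
            dups = frame.loc[frame["marker"].duplicated(), "marker"].tolist()
            raise ValidationError(f"duplicate marker ids in map: {dups[:5]}")
        if (frame["pos"] < 0).any():
            raise ValidationError("map positions must be >= 0")
        for chrom, grp in frame.groupby("chrom", sort=False):
            if (np.diff(grp["pos"].to_numpy()) < 0).any():
                raise ValidationError(f"positions decrease within chromosome {chrom}")
        self.frame = frame
        self.markers = frame["marker"].tolist()
        self.chrom = frame["chrom"].to_numpy()
        self.pos = frame["pos"].to_numpy()
        self._marker_idx = {m: i for i, m in enumerate(self.markers)}
        self._switch_probs: np.ndarray | None = None

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GeneticMap({self.n_markers} markers, {len(self.chromosomes)} chromosomes)"

    def marker_index(self, marker: str) -> int:
        return self._marker_idx[marker]

    # -- recombination geometry --------------------------------------------
    def switch_probs(self) -> np.ndarray:
        """Per-marker probability that a gamete switches parental strand.

        Entry ``i`` is the Haldane recombination fraction between markers
        ``i-1`` and ``i`` on the same chromosome, r = (1 - exp(-2d/100)) / 2,
        and 0.5 at the first marker of every chromosome (uniform strand
        choice, chromosomes independent).  Cached; the map is immutable.
        """
        if self._switch_probs is not None:
            return self._switch_probs
        probs = np.empty(self.n_markers)
        if self.n_markers == 0:
            return probs
        d = np.diff(self.pos, prepend=self.pos[0])
        probs[:] = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
        new_chrom = np.ones(self.n_markers, dtype=bool)
        new_chrom[1:] = self.chrom[1:] != self.chrom[:-1]
        probs[new_chrom] = 0.5
        self._switch_probs = probs
        return probs

    def pairwise_distance(self) -> np.ndarray:
        """Marker x marker genetic distance in cM; inf between chromosomes."""
        d = np.abs(self.pos[:, None] - self.pos[None, :])
        same = self.chrom[:, None] == self.chrom[None, :]
        d[~same] = np.inf
        return d

    def subset(self, markers: Sequence[str]) -> "GeneticMap":
        idx = sorted(self._marker_idx[m] for m in markers)
        return GeneticMap(self.frame.iloc[idx])

    @classmethod
    def read_tsv(cls, path) -> "GeneticMap":
        frame = pd.read_csv(path, sep="\t")
        frame.columns = [c.lower() for c in frame.columns]
        return cls(frame)

    def write_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


class KinshipMatrix:
    """Symmetric matrix of kinship coefficients in [0, 1].

    ``source`` records whether values came from the pedigree recursion
    (expected-IBD) or from marker identity-by-state sharing.
    """

    def __init__(self, values, ids: Sequence[str], source: str = "pedigree"):
        values = np.asarray(values, dtype=float)
        ids = [str(x) for x in ids]
        if values.shape != (len(ids), len(ids)):
            raise ValidationError("kinship matrix shape does not match ids")
        if len(set(ids)) != len(ids):
            raise ValidationError("kinship ids are not unique")
        if not np.allclose(values, values.T, atol=1e-10, equal_nan=True):
            raise ValidationError("kinship matrix is not symmetric")
        self.values = values
        self.ids = ids
        self.source = source
        self._idx = {x: i for i, x in enumerate(ids)}

    @property
    def n(self) -> int:
        return len(self.ids)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"KinshipMatrix({self.n} ids, source={self.source!r})"

    def get(self, a: str, b: str) -> float:
        return float(self.values[self._idx[a], self._idx[b]])

    def subset(self, ids: Sequence[str]) -> "KinshipMatrix":
        idx = [self._idx[x] for x in ids]
        return KinshipMatrix(self.values[np.ix_(idx, idx)], list(ids), self.source)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    @classmethod
    def read_tsv(cls, path, source: str = "pedigree") -> "KinshipMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls(frame.to_numpy(dtype=float), [str(x) for x in frame.index], source)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")
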