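"""Binned genomic signal containers shared by all pipeline stages.

A :class:`BinnedTrack` stores one value per fixed-width, non-overlapping
genomic bin, chromosome by chromosome, with ``NaN`` marking excluded
("missing") bins.  Bin ``i`` covers ``[i*bin_size, (i+1)*bin_size)`` in
0-based half-open coordinates; the terminal bin of each chromosome may be
partial and is flagged as such.  A :class:`TitrationSeries` aligns k >= 2
normalized tracks, one per MNase concentration, on an identical bin grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Genome",
    "BinnedTrack",
    "MACCTrack",
    "TitrationSeries",
    "read_chrom_sizes",
    "read_bedgraph",
]


@dataclass(frozen=True)
class Genome:
    """Chromosome name -> length (bp) table defining the analyzed genome."""

    sizes: Mapping[str, int]

    def __post_init__(self) -> None:
        for chrom, size in self.sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive size {size}")

    @property
    def chroms(self) -> list[str]:
        return list(self.sizes)

    @property
    def total_size(self) -> int:
        """Total length of the analyzed chromosomes (the genome-size factor)."""
        return int(sum(self.sizes.values()))

    def n_bins(self, chrom: str, bin_size: int) -> int:
        return -(-self.sizes[chrom] // bin_size)  # ceil division

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sizes


def read_chrom_sizes(path: str | Path) -> Genome:
    """Read a two-column TSV of chromosome sizes (``chrom<TAB>length``)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"], dtype={"chrom": str})
    return Genome(dict(zip(df["chrom"], df["size"].astype(int))))


class BinnedTrack:
    """Per-bin values over a genome, ``NaN`` = missing/excluded bin."""

    def __init__(
        self,
        bin_size: int,
        data: Dict[str, np.ndarray],
        *,
        normalized: bool = False,
        units: str = "raw",
        genome: Genome | None = None,
    ) -> None:
        if bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        self.bin_size = int(bin_size)
        self.data = {c: np.asarray(v, dtype=float) for c, v in data.items()}
        self.normalized = normalized
        self.units = units
        self.genome = genome

    # -- grid --------------------------------------------------------------

    @property
    def chroms(self) -> list[str]:
        return list(self.data)

    @property
    def n_bins(self) -> int:
        return int(sum(v.size for v in self.data.values()))

    def same_grid(self, other: "BinnedTrack") -> bool:
        return (
            self.bin_size == other.bin_size
            and self.chroms == other.chroms
            and all(self.data[c].size == other.data[c].size for c in self.data)
        )

    def require_same_grid(self, other: "BinnedTrack") -> None:
        if not self.same_grid(other):
            raise ValueError("tracks are on different bin grids (bin_size/chromosomes/lengths differ)")

    def partial_terminal_bin(self, chrom: str) -> bool:
        """True if the last bin of *chrom* does not span a full ``bin_size``."""
        if self.genome is None:
            return False
        return self.genome.sizes[chrom] % self.bin_size != 0

    # -- values ------------------------------------------------------------

    def values(self) -> np.ndarray:
        """All per-bin values concatenated in chromosome order (NaN included)."""
        if not self.data:
            return np.empty(0)
        return np.concatenate([self.data[c] for c in self.chroms])

    def defined_values(self) -> np.ndarray:
        v = self.values()
        return v[np.isfinite(v)]

    def defined_mask(self) -> Dict[str, np.ndarray]:
        return {c: np.isfinite(v) for c, v in self.data.items()}

    def copy(self) -> "BinnedTrack":
        return BinnedTrack(
            self.bin_size,
            {c: v.copy() for c, v in self.data.items()},
            normalized=self.normalized,
            units=self.units,
            genome=self.genome,
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"{type(self).__name__}(bin_size={self.bin_size}, "
            f"chroms={len(self.data)}, bins={self.n_bins}, units={self.units!r})"
        )

    # -- IO ----------------------------------------------------------------

    def iter_intervals(self) -> Iterator[tuple[str, int, int, float]]:
        for chrom in self.chroms:
            vals = self.data[chrom]
            size = self.genome.sizes[chrom] if self.genome is not None else vals.size * self.bin_size
            for i, v in enumerate(vals):
                if not np.isfinite(v):
                    continue
                start = i * self.bin_size
                end = min(start + self.bin_size, size)
                yield chrom, start, end, float(v)

    def to_bedgraph(self, path: str | Path, *, precision: int = 6) -> None:
        """Write defined bins as a 4-column bedGraph (0-based half-open)."""
        with open(path, "w") as fh:
            for chrom, start, end, v in self.iter_intervals():
                fh.write(f"{chrom}\t{start}\t{end}\t{v:.{precision}g}\n")

    def to_bigwig(self, path: str | Path) -> None:
        """Write a bigWig file (requires pyBigWig and a genome table)."""
        import pyBigWig  # deferred: optional dependency

        if self.genome is None:
            raise ValueError("bigWig output requires a genome (chromosome sizes)")
        bw = pyBigWig.open(str(path), "w")
        bw.addHeader([(c, int(self.genome.sizes[c])) for c in self.chroms])
        for chrom in self.chroms:
            ivals = [(s, e, v) for c, s, e, v in self.iter_intervals() if c == chrom]
            if ivals:
                bw.addEntries(
                    [chrom] * len(ivals),
                    [s for s, _, _ in ivals],
                    ends=[e for _, e, _ in ivals],
                    values=[v for _, _, v in ivals],
                )
        bw.close()


def _empty_grid(genome: Genome, bin_size: int, fill: float = np.nan) -> Dict[str, np.ndarray]:
    return {c: np.full(genome.n_bins(c, bin_size), fill) for c in genome.chroms}


def read_bedgraph(path: str | Path, genome: Genome, bin_size: int) -> BinnedTrack:
    """Read a bedGraph written by :meth:`BinnedTrack.to_bedgraph` back onto a grid.

    Intervals must coincide with the bin grid; bins absent from the file are
    missing (NaN).
    """
    data = _empty_grid(genome, bin_size)
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"], dtype={"chrom": str}
    )
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in genome:
            raise ValueError(f"bedGraph chromosome {chrom!r} absent from genome table")
        idx = sub["start"].to_numpy() // bin_size
        if np.any(sub["start"].to_numpy() % bin_size):
            raise ValueError(f"bedGraph intervals do not align to a {bin_size}-bp grid")
        data[chrom][idx] = sub["value"].to_numpy()
    return BinnedTrack(bin_size, data, normalized=True, units="per_million_scaled", genome=genome)


class MACCTrack(BinnedTrack):
    """Per-bin MACC scores (regression slopes) with fit P values and state flags.

    ``provenance`` records whether the score derives from whole-chromatin
    digests ("c-MACC") or histone-ChIP digests ("h-MACC").
    """

    def __init__(
        self,
        bin_size: int,
        data: Dict[str, np.ndarray],
        *,
        pvalues: Dict[str, np.ndarray] | None = None,
        provenance: str = "c-MACC",
        gc_corrected: bool = False,
        median_shifted: bool = False,
        significance_weighted: bool = False,
        genome: Genome | None = None,
    ) -> None:
        super().__init__(bin_size, data, normalized=True, units="macc", genome=genome)
        self.pvalues = (
            {c: np.asarray(v, dtype=float) for c, v in pvalues.items()} if pvalues else None
        )
        self.provenance = provenance
        self.gc_corrected = gc_corrected
        self.median_shifted = median_shifted
        self.significance_weighted = significance_weighted

    def copy(self) -> "MACCTrack":
        return MACCTrack(
            self.bin_size,
            {c: v.copy() for c, v in self.data.items()},
            pvalues={c: v.copy() for c, v in self.pvalues.items()} if self.pvalues else None,
            provenance=self.provenance,
            gc_corrected=self.gc_corrected,
            median_shifted=self.median_shifted,
            significance_weighted=self.significance_weighted,
            genome=self.genome,
        )

    def pvalue_values(self) -> np.ndarray:
        if self.pvalues is None:
            raise ValueError("track carries no fit P values")
        return np.concatenate([self.pvalues[c] for c in self.chroms])


@dataclass
class TitrationSeries:
    """k >= 2 normalized tracks on one bin grid, ordered by MNase amount."""

    tracks: Sequence[BinnedTrack]
    concentrations: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if len(self.tracks) < 2:
            raise ValueError("a titration series needs at least two points (k >= 2)")
        if len(self.tracks) != self.concentrations.size:
            raise ValueError("number of tracks must match number of concentrations")
        if np.any(self.concentrations <= 0):
            raise ValueError("MNase concentrations must be positive")
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("MNase concentrations must be strictly increasing")
        first = self.tracks[0]
        for t in self.tracks[1:]:
            first.require_same_grid(t)
        for t in self.tracks:
            if not t.normalized:
                raise ValueError("titration tracks must be normalized before assembly")

    @property
    def k(self) -> int:
        return len(self.tracks)

    @property
    def bin_size(self) -> int:
        return self.tracks[0].bin_size

    @property
    def chroms(self) -> list[str]:
        return self.tracks[0].chroms

    @property
    def genome(self) -> Genome | None:
        return self.tracks[0].genome

    def stacked(self, chrom: str) -> np.ndarray:
        """(k, n_bins) matrix of normalized frequencies for one chromosome."""
        return np.vstack([t.data[chrom] for t in self.tracks])
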