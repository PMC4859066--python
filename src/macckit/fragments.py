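"""Paired-end fragment input, filtering, binning and normalization.

One sequencing library (one MNase titration point, one pool) is held as a
:class:`FragmentSet`: a table of digestion fragments in 0-based half-open
coordinates plus library metadata.  Fragments come from a coordinate-sorted
indexed BAM (proper pairs), a BEDPE file, or a 3-column fragment BED.

Processing follows the standard MNase-seq conventions: insert-size
filtering (default 50-500 bp, the mononucleosome-compatible window),
removal of fragments touching anomalously high-count tag positions
(Z-score threshold, default 7), midpoint assignment to fixed-width bins,
and per-million library-size normalization with a genome-size/100-Mb
scaling factor so profiles are comparable across organisms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .tracks import BinnedTrack, Genome, TitrationSeries

logger = logging.getLogger(__name__)

__all__ = [
    "Fragment",
    "FragmentSet",
    "read_fragments",
    "filter_anomalous_positions",
    "bin_counts",
    "normalize_track",
    "pool_occupancy",
    "fragment_length_distribution",
    "LengthDistribution",
]

POOLS = ("chromatin", "histone_chip", "chip_input")


class Fragment(NamedTuple):
    """One sequenced digestion product (0-based half-open)."""

    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class FragmentSet:
    """Fragments of one library with its titration/pool metadata.

    ``fragments`` is a DataFrame with columns ``chrom`` (str), ``start``,
    ``end`` (int, 0-based half-open).
    """

    fragments: pd.DataFrame
    concentration: float
    label: str = ""
    pool: str = "chromatin"

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValueError("MNase concentration must be > 0")
        if self.pool not in POOLS:
            raise ValueError(f"pool must be one of {POOLS}, got {self.pool!r}")
        need = {"chrom", "start", "end"}
        if not need.issubset(self.fragments.columns):
            raise ValueError(f"fragment table must have columns {sorted(need)}")
        if len(self.fragments) and (self.fragments["end"] <= self.fragments["start"]).any():
            raise ValueError("fragments must satisfy start < end")

    @property
    def library_size(self) -> int:
        return len(self.fragments)

    @property
    def lengths(self) -> np.ndarray:
        return (self.fragments["end"] - self.fragments["start"]).to_numpy()

    def __iter__(self):
        for row in self.fragments.itertuples(index=False):
            yield Fragment(row.chrom, int(row.start), int(row.end))

    def to_bedpe(self, path: str | Path) -> None:
        """Write as BEDPE with two abutting half-fragment 'mates'."""
        df = self.fragments
        mid = (df["start"].to_numpy() + df["end"].to_numpy()) // 2
        out = pd.DataFrame(
            {
                "chrom1": df["chrom"],
                "start1": df["start"],
                "end1": mid,
                "chrom2": df["chrom"],
                "start2": mid,
                "end2": df["end"],
                "name": self.label or ".",
                "score": 0,
                "strand1": "+",
                "strand2": "-",
            }
        )
        out.to_csv(path, sep="\t", header=False, index=False)


def _fragments_from_bam(path: Path, min_mapq: int) -> pd.DataFrame:
    import pysam

    af = pysam.AlignmentFile(str(path), "rb")
    header_sort = (af.header.to_dict().get("HD") or {}).get("SO", "unknown")
    if header_sort != "coordinate":
        raise ValueError(
            f"{path}: BAM must be coordinate-sorted (header SO={header_sort!r}); run samtools sort"
        )
    if not af.has_index():
        raise ValueError(f"{path}: BAM must be indexed; run samtools index")
    chroms, starts, ends = [], [], []
    dropped_mapq = 0
    for read in af.fetch():
        if not read.is_proper_pair or not read.is_read1:
            continue
        if read.is_secondary or read.is_supplementary:
            continue
        if read.mapping_quality < min_mapq:
            dropped_mapq += 1
            continue
        tlen = read.template_length
        if tlen > 0:
            start, end = read.reference_start, read.reference_start + tlen
        else:
            end = read.reference_end
            start = end + tlen
        chroms.append(read.reference_name)
        starts.append(start)
        ends.append(end)
    af.close()
    if dropped_mapq:
        logger.info("dropped %d pairs below mapping quality %d", dropped_mapq, min_mapq)
    return pd.DataFrame({"chrom": chroms, "start": starts, "end": ends})


def _fragments_from_table(path: Path) -> pd.DataFrame:
    first = open(path).readline().rstrip("\n").split("\t")
    ncol = len(first)
    if ncol >= 6:  # BEDPE: mate intervals, fragment spans leftmost..rightmost
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            usecols=range(6),
            names=["chrom1", "start1", "end1", "chrom2", "start2", "end2"],
            dtype={"chrom1": str, "chrom2": str},
        )
        if (df["chrom1"] != df["chrom2"]).any():
            raise ValueError(f"{path}: inter-chromosomal BEDPE records are not fragments")
        return pd.DataFrame(
            {
                "chrom": df["chrom1"],
                "start": np.minimum(df["start1"], df["start2"]),
                "end": np.maximum(df["end1"], df["end2"]),
            }
        )
    if ncol >= 3:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            usecols=range(3),
            names=["chrom", "start", "end"],
            dtype={"chrom": str},
        )
        return df
    raise ValueError(f"{path}: expected BAM, BEDPE (>=6 columns) or BED (>=3 columns)")


def read_fragments(
    source: str | Path,
    min_len: int = 50,
    max_len: int = 500,
    *,
    concentration: float = 1.0,
    label: str = "",
    pool: str = "chromatin",
    min_mapq: int = 1,
) -> FragmentSet:
    """Read one library and apply the insert-size filter.

    Fragments with length outside ``[min_len, max_len]`` (inclusive) are
    discarded.  For BAM input, non-uniquely-mapped pairs are removed via the
    mapping-quality threshold; interval input carries no mapping information,
    so uniqueness filtering is skipped with a warning.
    """
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    source = Path(source)
    if source.suffix.lower() == ".bam":
        df = _fragments_from_bam(source, min_mapq)
    else:
        logger.warning(
            "%s: interval input carries no mapping-quality information; uniqueness filter skipped",
            source,
        )
        df = _fragments_from_table(source)
    lengths = df["end"] - df["start"]
    df = df[(lengths >= min_len) & (lengths <= max_len)].reset_index(drop=True)
    if len(df) == 0:
        raise ValueError(f"{source}: zero fragments retained after the [{min_len}, {max_len}] bp filter")
    return FragmentSet(df, concentration=concentration, label=label or source.stem, pool=pool)


def filter_anomalous_positions(fs: FragmentSet, z_threshold: float = 7.0) -> FragmentSet:
    """Drop fragments whose sequenced-tag endpoints hit anomalous positions.

    Each fragment contributes two tag positions: ``start`` and ``end - 1``
    (the first sequenced base of either mate).  Positions whose tag count
    exceeds ``mean + z_threshold * sd`` -- statistics taken over positions
    with at least one tag -- are flagged, and every fragment with a flagged
    endpoint is removed.  Such pile-ups typically mark collapsed repeats or
    PCR artifacts.
    """
    if z_threshold <= 0:
        raise ValueError("z_threshold must be positive")
    if fs.library_size == 0:
        raise ValueError("cannot filter an empty FragmentSet")
    if not np.isfinite(z_threshold):
        return fs

    keep_parts = []
    n_flagged = 0
    for chrom, sub in fs.fragments.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends_tag = sub["end"].to_numpy() - 1
        tags = np.concatenate([starts, ends_tag])
        positions, counts = np.unique(tags, return_counts=True)
        mean = counts.mean()
        sd = counts.std()
        if sd == 0:
            keep_parts.append(sub)
            continue
        flagged = positions[(counts - mean) / sd > z_threshold]
        n_flagged += flagged.size
        bad = np.isin(starts, flagged) | np.isin(ends_tag, flagged)
        keep_parts.append(sub[~bad])
    logger.info("anomalous-position filter: %d positions flagged (Z > %g)", n_flagged, z_threshold)
    out = pd.concat(keep_parts, ignore_index=True) if keep_parts else fs.fragments.iloc[0:0]
    return replace(fs, fragments=out)


def bin_counts(fs: FragmentSet, genome: Genome, bin_size: int) -> BinnedTrack:
    """Count fragments per bin by midpoint assignment.

    Each fragment falls in exactly one bin, the one containing
    ``floor((start + end) / 2)``, so the binned counts conserve the library
    size exactly.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    data = {c: np.zeros(genome.n_bins(c, bin_size)) for c in genome.chroms}
    for chrom, sub in fs.fragments.groupby("chrom", sort=False):
        if chrom not in genome:
            raise ValueError(f"fragments on chromosome {chrom!r} absent from the genome table")
        mids = (sub["start"].to_numpy() + sub["end"].to_numpy()) // 2
        idx = mids // bin_size
        if idx.size and idx.max() >= data[chrom].size:
            raise ValueError(f"fragment midpoint beyond declared length of chromosome {chrom!r}")
        np.add.at(data[chrom], idx, 1.0)
    return BinnedTrack(bin_size, data, normalized=False, units="raw", genome=genome)


def normalize_track(t: BinnedTrack, library_size: int, genome_size: int) -> BinnedTrack:
    """Scale raw counts to per-million-mapped-reads, per 100 Mb of genome.

    value' = value * 1e6 / library_size * genome_size / 1e8.  The genome-size
    factor makes bin frequencies comparable between genomes of different
    sizes.
    """
    if t.normalized:
        raise ValueError("track is already normalized")
    if library_size <= 0 or genome_size <= 0:
        raise ValueError("library_size and genome_size must be positive")
    factor = 1e6 / library_size * genome_size / 1e8
    data = {c: v * factor for c, v in t.data.items()}
    return BinnedTrack(t.bin_size, data, normalized=True, units="per_million_scaled", genome=t.genome)


def pool_occupancy(series: TitrationSeries) -> BinnedTrack:
    """Average normalized frequency over all titration points.

    This approximates the occupancy map a single pooled digest would give;
    a bin is missing only if it is missing in every track.
    """
    import warnings

    data = {}
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Mean of empty slice")
        for chrom in series.chroms:
            stack = series.stacked(chrom)
            data[chrom] = np.nanmean(stack, axis=0)
    return BinnedTrack(
        series.bin_size, data, normalized=True, units="per_million_scaled", genome=series.genome
    )


class LengthDistribution(NamedTuple):
    counts: pd.Series  # index: fragment length (bp), value: count
    mean: float
    median: float


def fragment_length_distribution(
    fs: FragmentSet,
    sites: Iterable[tuple[str, int, int]] | None = None,
    *,
    min_len: int = 50,
    max_len: int = 500,
) -> LengthDistribution:
    """Histogram of fragment lengths at 1-bp resolution over [min_len, max_len].

    When *sites* (intervals) are given, only fragments whose midpoint falls
    inside a site are counted; short site-restricted fragments at deep
    digestion are the hallmark of non-histone protection.
    """
    if fs.library_size == 0:
        raise ValueError("cannot profile an empty FragmentSet")
    df = fs.fragments
    if sites is not None:
        site_list = list(sites)
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in site_list:
            by_chrom.setdefault(chrom, []).append((int(start), int(end)))
        keep = np.zeros(len(df), dtype=bool)
        mids = (df["start"].to_numpy() + df["end"].to_numpy()) // 2
        chrom_arr = df["chrom"].to_numpy()
        for chrom, ivals in by_chrom.items():
            ivals.sort()
            starts = np.array([s for s, _ in ivals])
            ends = np.array([e for _, e in ivals])
            sel = chrom_arr == chrom
            pos = mids[sel]
            j = np.searchsorted(starts, pos, side="right") - 1
            inside = (j >= 0) & (pos < ends[np.clip(j, 0, len(ends) - 1)])
            keep[np.flatnonzero(sel)[inside]] = True
        df = df[keep]
        if len(df) == 0:
            logger.warning("no fragments overlap the given sites; empty length histogram")
            empty = pd.Series(0, index=pd.RangeIndex(min_len, max_len + 1, name="length"))
            return LengthDistribution(empty, float("nan"), float("nan"))
    lengths = (df["end"] - df["start"]).to_numpy()
    edges = np.arange(min_len, max_len + 2)
    hist, _ = np.histogram(lengths, bins=edges)
    counts = pd.Series(hist, index=pd.RangeIndex(min_len, max_len + 1, name="length"))
    return LengthDistribution(counts, float(lengths.mean()), float(np.median(lengths)))
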