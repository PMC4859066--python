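"""Site-centred average profiles, masked track correlation, UPGMA clustering.

Average profiles around anchor sets (TSS, peaks, enhancers) are computed
by linear interpolation of bin-centre values at 1-bp offsets, orienting
minus-strand anchors, averaging over sites, and smoothing with a short
running-mean window.  Sample-by-site signal matrices (e.g. enhancer
c-MACC across cell lines) are clustered by UPGMA with distance
1 - Pearson r.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from .fragments import pool_occupancy
from .tracks import BinnedTrack, TitrationSeries

logger = logging.getLogger(__name__)

__all__ = [
    "SiteProfile",
    "site_profile",
    "titration_tss_profiles",
    "split_genes_by_expression",
    "track_correlation",
    "cluster_profiles",
    "ClusterResult",
]


@dataclass
class SiteProfile:
    """Mean signal vs strand-oriented offset from the site anchor."""

    offsets: np.ndarray  # bp, symmetric about 0
    mean: np.ndarray  # smoothed mean signal per offset
    raw_mean: np.ndarray  # pre-smoothing mean
    n_sites: int
    n_dropped: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, "mean": self.mean, "raw_mean": self.raw_mean})


def _running_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Centred running mean, truncated (not padded) at the edges."""
    if window <= 1:
        return values.copy()
    kernel = np.ones(window)
    num = np.convolve(values, kernel, mode="same")
    den = np.convolve(np.ones_like(values), kernel, mode="same")
    return num / den


def site_profile(
    track: BinnedTrack,
    sites: Iterable[tuple],
    flank: int,
    smooth_window: int = 40,
) -> SiteProfile:
    """Average signal around anchors.

    ``sites`` yields ``(chrom, position)`` or ``(chrom, position, strand)``
    tuples; minus-strand profiles are reversed so offsets run 5'->3'.
    Values are sampled at every bp by linear interpolation between the
    centres of defined bins; sites whose flank leaves the chromosome are
    dropped (counted in ``n_dropped``).
    """
    if flank < track.bin_size:
        raise ValueError("flank must be at least one bin")
    offsets = np.arange(-flank, flank + 1)
    total = np.zeros(offsets.size)
    used = dropped = 0
    centers_cache: Dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for site in sites:
        chrom, pos = site[0], int(site[1])
        strand = site[2] if len(site) > 2 else "+"
        if chrom not in track.data:
            dropped += 1
            continue
        v = track.data[chrom]
        size = track.genome.sizes[chrom] if track.genome is not None else v.size * track.bin_size
        if pos - flank < 0 or pos + flank > size:
            dropped += 1
            continue
        if chrom not in centers_cache:
            centers = (np.arange(v.size) + 0.5) * track.bin_size
            finite = np.isfinite(v)
            centers_cache[chrom] = (centers[finite], v[finite])
        cx, cy = centers_cache[chrom]
        if cx.size == 0:
            dropped += 1
            continue
        sampled = np.interp(pos + offsets, cx, cy)
        if strand == "-":
            sampled = sampled[::-1]
        total += sampled
        used += 1
    if used == 0:
        raise ValueError("no usable sites (all dropped or off-chromosome)")
    if dropped:
        logger.info("site_profile: dropped %d site(s) whose flank exits the chromosome", dropped)
    raw = total / used
    return SiteProfile(offsets, _running_mean(raw, smooth_window), raw, used, dropped)


def split_genes_by_expression(
    genes: pd.DataFrame,
    expression: Mapping[str, float],
    lower_q: float = 1 / 3,
    upper_q: float = 2 / 3,
) -> tuple[list[tuple], list[tuple]]:
    """Split gene TSS anchors into expressed (upper) and silent (lower) sets.

    Returns ``(expressed, silent)`` lists of ``(chrom, tss, strand)``; the
    default split keeps the upper and lower expression thirds.
    """
    expr = np.array([expression.get(n, np.nan) for n in genes["name"]])
    defined = np.isfinite(expr)
    if defined.sum() == 0:
        raise ValueError("no genes with expression values")
    lo = np.quantile(expr[defined], lower_q)
    hi = np.quantile(expr[defined], upper_q)
    expressed, silent = [], []
    for (row, e, d) in zip(genes.itertuples(index=False), expr, defined):
        if not d:
            continue
        tss = row.start if row.strand == "+" else row.end
        anchor = (row.chrom, int(tss), row.strand)
        if e >= hi:
            expressed.append(anchor)
        elif e <= lo:
            silent.append(anchor)
    return expressed, silent


def titration_tss_profiles(
    series: TitrationSeries,
    tss_sets: Mapping[str, Sequence[tuple]],
    flank: int = 1000,
    smooth_window: int = 40,
) -> Dict[str, Dict[str, object]]:
    """Per-concentration and pooled average profiles around TSS sets.

    ``tss_sets`` maps a set name (e.g. ``"expressed"``, ``"silent"``) to
    its anchors.  Returns, per set, the list of per-titration-point
    profiles (in concentration order) and the profile of the pooled
    occupancy track.
    """
    out: Dict[str, Dict[str, object]] = {}
    pooled_track = pool_occupancy(series)
    for name, anchors in tss_sets.items():
        anchors = list(anchors)
        if not anchors:
            raise ValueError(f"empty gene set {name!r}")
        per_point = [
            site_profile(t, anchors, flank, smooth_window) for t in series.tracks
        ]
        pooled = site_profile(pooled_track, anchors, flank, smooth_window)
        out[name] = {"per_point": per_point, "pooled": pooled}
    return out


def track_correlation(
    a: BinnedTrack, b: BinnedTrack, mask: Mapping[str, np.ndarray] | None = None
) -> float:
    """Pearson r between two tracks over jointly defined (optionally masked) bins.

    Returns NaN when fewer than 3 joint bins remain; heatmap exports
    multiply by 100 and round.
    """
    a.require_same_grid(b)
    xs, ys = [], []
    for chrom in a.chroms:
        av, bv = a.data[chrom], b.data[chrom]
        joint = np.isfinite(av) & np.isfinite(bv)
        if mask is not None:
            sel = mask.get(chrom)
            joint &= np.zeros(av.size, bool) if sel is None else np.asarray(sel, bool)
        xs.append(av[joint])
        ys.append(bv[joint])
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if x.size < 3:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class ClusterResult:
    linkage: np.ndarray  # scipy linkage matrix (UPGMA)
    labels: list[str]
    leaf_order: list[str]


def cluster_profiles(matrix: pd.DataFrame) -> ClusterResult:
    """UPGMA clustering of sample signal vectors with distance 1 - Pearson r.

    ``matrix`` is samples x sites; rows are sorted by label first so the
    result does not depend on input order beyond label ties.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 samples to cluster")
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 sites to correlate profiles")
    matrix = matrix.loc[sorted(matrix.index, key=str)]
    values = matrix.to_numpy(dtype=float)
    sds = values.std(axis=1)
    for label, sd in zip(matrix.index, sds):
        if sd == 0:
            raise ValueError(f"sample {label!r} has zero-variance signal; correlation undefined")
    corr = np.corrcoef(values)
    dist = 1.0 - corr
    iu = np.triu_indices(len(matrix), k=1)
    condensed = np.maximum(dist[iu], 0.0)
    Z = linkage(condensed, method="average")
    order = [str(matrix.index[i]) for i in leaves_list(Z)]
    return ClusterResult(Z, [str(i) for i in matrix.index], order)
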