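"""MACC peaks, group-1/group-2 classification and site-overlap statistics.

A MACC peak is a bin whose score strictly exceeds both neighbours
(value[i-1] < value[i] > value[i+1]).  Comparing whole-chromatin scores
(c-MACC) with histone-ChIP scores (h-MACC) splits the high-accessibility
bins into group 1 -- high c-MACC with near-zero h-MACC, the signature of
non-histone-protein (NHP) protection -- and group 2 -- high c-MACC and
high h-MACC, accessible ("fragile") nucleosomes.  NHP-binding sites are
derived from ChIP/input enrichment via a Z-score threshold, and observed
peak/site overlap is compared against uniform re-placement of the peaks
over the defined bins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .tracks import BinnedTrack, MACCTrack

logger = logging.getLogger(__name__)

__all__ = [
    "PeakSet",
    "GroupAssignment",
    "call_local_peaks",
    "assign_groups",
    "chip_zscore_sites",
    "select_representative_profile",
    "overlap_with_sites",
    "OverlapResult",
]

NONE, GROUP1, GROUP2 = 0, 1, 2
GROUP_NAMES = {GROUP1: "group1", GROUP2: "group2", NONE: "none"}


@dataclass
class PeakSet:
    """Strict local maxima of a MACC track, on the bin grid."""

    bin_size: int
    peaks: List[Tuple[str, int, float]]  # (chrom, bin index, value)
    group: str | None = None

    def __len__(self) -> int:
        return len(self.peaks)

    def bins(self) -> Dict[str, np.ndarray]:
        out: Dict[str, list] = {}
        for chrom, i, _ in self.peaks:
            out.setdefault(chrom, []).append(i)
        return {c: np.array(v, dtype=int) for c, v in out.items()}

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, i, v in self.peaks:
                fh.write(
                    f"{chrom}\t{i * self.bin_size}\t{(i + 1) * self.bin_size}\t"
                    f"{self.group or 'peak'}\t{v:.4g}\t.\n"
                )


def call_local_peaks(m: MACCTrack) -> PeakSet:
    """Strict local maxima: value[i-1] < value[i] > value[i+1].

    Both neighbours must be defined bins, so bins at chromosome ends or
    adjacent to missing bins are ineligible; plateaus yield no peak.
    """
    peaks: List[Tuple[str, int, float]] = []
    for chrom in m.chroms:
        v = m.data[chrom]
        if v.size < 3:
            continue
        mid = v[1:-1]
        ok = (
            np.isfinite(mid)
            & np.isfinite(v[:-2])
            & np.isfinite(v[2:])
            & (v[:-2] < mid)
            & (mid > v[2:])
        )
        for i in np.flatnonzero(ok) + 1:
            peaks.append((chrom, int(i), float(v[i])))
    return PeakSet(m.bin_size, peaks)


@dataclass
class GroupAssignment:
    """Per-bin group labels (0 none / 1 group1 / 2 group2 / -1 missing)."""

    labels: Dict[str, np.ndarray]
    c_threshold: float  # 80th percentile of positive c-MACC
    h_low_threshold: float  # 10th percentile of positive h-MACC
    h_high_threshold: float  # 90th percentile of positive h-MACC

    def mask(self, group: int) -> Dict[str, np.ndarray]:
        return {c: v == group for c, v in self.labels.items()}

    def counts(self) -> Dict[str, int]:
        out = {}
        for code, name in GROUP_NAMES.items():
            out[name] = sum(int((v == code).sum()) for v in self.labels.values())
        return out

    def to_bed(self, path, track: MACCTrack, bin_size: int) -> None:
        with open(path, "w") as fh:
            for chrom, lab in self.labels.items():
                for i in np.flatnonzero(lab > 0):
                    fh.write(
                        f"{chrom}\t{i * bin_size}\t{(i + 1) * bin_size}\t"
                        f"{GROUP_NAMES[lab[i]]}\t{track.data[chrom][i]:.4g}\t.\n"
                    )


def assign_groups(
    c: MACCTrack,
    h: MACCTrack,
    c_top: float = 0.80,
    h_low: float = 0.10,
    h_high: float = 0.90,
) -> GroupAssignment:
    """Classify bins into group 1 / group 2 from c-MACC and h-MACC.

    Thresholds are quantiles of the *positive* score sub-distributions
    (inclusive linear interpolation), and comparisons are strict:
    group 1 = c-MACC above the ``c_top`` quantile of positive c scores and
    h-MACC below the ``h_low`` quantile of positive h scores;
    group 2 = same c condition and h-MACC above the ``h_high`` quantile.
    Both tracks must be median-shifted and share the bin grid.
    """
    c.require_same_grid(h)
    if not (c.median_shifted and h.median_shifted):
        raise ValueError("both tracks must be median-shifted before group assignment")
    c_vals = c.defined_values()
    h_vals = h.defined_values()
    c_pos = c_vals[c_vals > 0]
    h_pos = h_vals[h_vals > 0]
    if c_pos.size == 0 or h_pos.size == 0:
        raise ValueError("no positive scores in one of the tracks; thresholds undefined")
    c_thr = float(np.quantile(c_pos, c_top))
    h_lo = float(np.quantile(h_pos, h_low))
    h_hi = float(np.quantile(h_pos, h_high))
    labels: Dict[str, np.ndarray] = {}
    for chrom in c.chroms:
        cv, hv = c.data[chrom], h.data[chrom]
        lab = np.zeros(cv.size, dtype=int)
        joint = np.isfinite(cv) & np.isfinite(hv)
        lab[~joint] = -1
        high_c = joint & (cv > c_thr)
        lab[high_c & (hv < h_lo)] = GROUP1
        lab[high_c & (hv > h_hi)] = GROUP2
        labels[chrom] = lab
    logger.info(
        "group thresholds: c>%.4g, h<%.4g (group1) / h>%.4g (group2)", c_thr, h_lo, h_hi
    )
    return GroupAssignment(labels, c_thr, h_lo, h_hi)


def chip_zscore_sites(
    enrichment: BinnedTrack, z_threshold: float
) -> Dict[str, np.ndarray]:
    """Bins whose ChIP/input enrichment Z-score exceeds the threshold.

    Z is computed over all defined bins genome-wide; returns per-chromosome
    boolean masks on the bin grid.
    """
    vals = enrichment.defined_values()
    mean = vals.mean()
    sd = vals.std()
    if sd == 0:
        logger.warning("zero-variance enrichment track: no sites called")
        return {c: np.zeros(v.size, dtype=bool) for c, v in enrichment.data.items()}
    out = {}
    for chrom, v in enrichment.data.items():
        with np.errstate(invalid="ignore"):
            out[chrom] = np.isfinite(v) & ((v - mean) / sd > z_threshold)
    return out


def select_representative_profile(
    profiles: Sequence[BinnedTrack], z_values: Sequence[float] = (2, 3, 4, 5)
) -> BinnedTrack:
    """Pick, among replicate enrichment profiles of one protein, the one whose
    site counts vary least over Z thresholds.

    For each profile the number of site bins is computed at each Z in
    ``z_values``; the profile with the smallest coefficient of variation
    of those counts is returned (ties broken by input order).
    """
    if len(profiles) == 0:
        raise ValueError("need at least one profile")
    best_idx, best_cv = 0, np.inf
    for idx, prof in enumerate(profiles):
        counts = np.array(
            [sum(int(m.sum()) for m in chip_zscore_sites(prof, z).values()) for z in z_values],
            dtype=float,
        )
        mean = counts.mean()
        cv = counts.std() / mean if mean > 0 else np.inf
        if cv < best_cv:
            best_idx, best_cv = idx, cv
    return profiles[best_idx]


@dataclass
class OverlapResult:
    observed: float
    expected: float
    n_peaks: int
    n_site_bins: int


def overlap_with_sites(
    peaks: PeakSet,
    sites: Dict[str, np.ndarray],
    track: MACCTrack,
    n_rand: int = 10,
    seed: int = 0,
) -> OverlapResult:
    """Observed vs randomized fraction of peaks falling in site bins.

    The expected fraction is the mean over ``n_rand`` re-placements of the
    same number of peaks, drawn uniformly without replacement from the
    defined bins of *track* (missing bins are never eligible).
    """
    chroms = track.chroms
    site_flat = np.concatenate(
        [np.asarray(sites.get(c, np.zeros(track.data[c].size, bool)), dtype=bool) for c in chroms]
    )
    eligible = np.concatenate([np.isfinite(track.data[c]) for c in chroms])
    n_sites = int(site_flat.sum())
    n_peaks = len(peaks)
    if n_sites == 0 or n_peaks == 0:
        return OverlapResult(0.0, 0.0, n_peaks, n_sites)

    offsets = {}
    off = 0
    for c in chroms:
        offsets[c] = off
        off += track.data[c].size
    peak_idx = np.array([offsets[c] + i for c, i, _ in peaks.peaks], dtype=int)
    observed = float(site_flat[peak_idx].mean())

    rng = np.random.default_rng(seed)
    eligible_idx = np.flatnonzero(eligible)
    draws = np.empty(n_rand)
    for r in range(n_rand):
        placed = rng.choice(eligible_idx, size=n_peaks, replace=False)
        draws[r] = site_flat[placed].mean()
    return OverlapResult(observed, float(draws.mean()), n_peaks, n_sites)
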