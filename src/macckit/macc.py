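"""MACC scoring: per-bin regression of fragment frequency on log MNase amount.

The MACC score of a genomic bin is the ordinary-least-squares slope of its
normalized fragment frequencies against ``x = -log(c)`` over the titration
points ``c_1 < ... < c_k``.  With the negated-log abscissa, bins whose
yield rises as MNase decreases -- accessible chromatin, preferentially
released and then over-digested -- obtain positive scores, and bins
requiring deep digestion to release mononucleosomes obtain negative
scores.  Downstream adjustments implemented here: significance weighting
by ``(1 - P)``, LOWESS correction of the GC-content trend (optionally
stratified by CpG-island membership), median shifting, pooled-occupancy
quadrant classification and ChIP/input enrichment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Dict, Iterable

import numpy as np
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

from .tracks import BinnedTrack, Genome, MACCTrack, TitrationSeries

logger = logging.getLogger(__name__)

__all__ = [
    "fit_macc",
    "mann_kendall_p",
    "significance_weight",
    "GCTrack",
    "gc_content",
    "flag_cpg_islands",
    "gc_correct",
    "median_shift",
    "h3_enrichment",
    "classify_occupancy_accessibility",
    "QuadrantClassification",
]


# ---------------------------------------------------------------------------
# slope fitting


def fit_macc(
    series: TitrationSeries,
    *,
    log_base: float = math.e,
    provenance: str = "c-MACC",
    exclude: str = "all_zero",
) -> MACCTrack:
    """Fit the per-bin MACC slope and its Pearson-correlation P value.

    Parameters
    ----------
    series
        Normalized titration series (k >= 2 points).
    log_base
        Base of the concentration logarithm.  Changing the base rescales
        every slope by a constant and changes no sign and no P value.
    exclude
        ``"all_zero"`` (default): a bin is missing only when it has no
        signal at every titration point.  ``"any_zero"``: stricter rule,
        missing when any point has no signal.
    """
    if exclude not in ("all_zero", "any_zero"):
        raise ValueError("exclude must be 'all_zero' or 'any_zero'")
    c = series.concentrations
    if np.unique(c).size != c.size:
        raise ValueError("titration concentrations must be distinct")
    x = -np.log(c) / math.log(log_base)
    xc = x - x.mean()
    sxx = float(xc @ xc)
    k = series.k

    data: Dict[str, np.ndarray] = {}
    pvals: Dict[str, np.ndarray] = {}
    for chrom in series.chroms:
        y = series.stacked(chrom)  # (k, n)
        finite = np.isfinite(y)
        yz = np.where(finite, y, 0.0)
        absent = ~finite | (yz == 0)  # no mapped reads at this point
        missing = np.all(absent, axis=0) if exclude == "all_zero" else np.any(absent, axis=0)
        ybar = yz.mean(axis=0)
        dev = yz - ybar
        sxy = xc @ dev
        syy = np.einsum("ij,ij->j", dev, dev)
        slope = sxy / sxx
        with np.errstate(invalid="ignore", divide="ignore"):
            r = sxy / np.sqrt(sxx * syy)
        r = np.clip(r, -1.0, 1.0)
        if k > 2:
            with np.errstate(invalid="ignore", divide="ignore"):
                t = r * np.sqrt((k - 2) / (1.0 - r * r))
            p = 2.0 * stats.t.sf(np.abs(t), df=k - 2)
            p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
        else:
            p = np.ones_like(r)  # two points determine the line; no test
        zero_var = syy == 0
        slope[zero_var] = 0.0  # flat response: no trend, by convention
        p[zero_var] = 1.0
        slope[missing] = np.nan
        p[missing] = np.nan
        data[chrom] = slope
        pvals[chrom] = p
    return MACCTrack(
        series.bin_size, data, pvalues=pvals, provenance=provenance, genome=series.genome
    )


# ---------------------------------------------------------------------------
# Mann-Kendall trend test


@lru_cache(maxsize=32)
def _mahonian(n: int) -> np.ndarray:
    """Counts of permutations of 1..n by number of inversions."""
    counts = np.array([1], dtype=float)
    for m in range(2, n + 1):
        # convolve with a length-m box: new element can add 0..m-1 inversions
        counts = np.convolve(counts, np.ones(m))
    return counts


def _kendall_s(values: np.ndarray) -> int:
    diff = np.sign(values[None, :] - values[:, None])
    return int(np.triu(diff, k=1).sum())


def mann_kendall_p(values: Iterable[float]) -> float:
    """Two-sided P value of the Mann-Kendall trend test.

    For k <= 10 without ties the P value is exact, computed from the full
    permutation distribution of the Kendall S statistic (via the
    inversion-count recursion, equivalent to enumerating all k!
    orderings).  Otherwise the normal approximation with continuity
    correction and the standard tie-corrected variance is used.
    """
    v = np.asarray(list(values), dtype=float)
    k = v.size
    if k < 3:
        raise ValueError("Mann-Kendall test requires at least 3 observations")
    if np.any(~np.isfinite(v)):
        raise ValueError("Mann-Kendall test requires complete observations")
    s = _kendall_s(v)
    has_ties = np.unique(v).size != k
    npairs = k * (k - 1) // 2
    if k <= 10 and not has_ties:
        counts = _mahonian(k)  # index = number of inversions d; S = npairs - 2d
        s_vals = npairs - 2 * np.arange(counts.size)
        p = counts[np.abs(s_vals) >= abs(s)].sum() / counts.sum()
        return float(p)
    # tie-corrected variance of S under the null
    _, tie_counts = np.unique(v, return_counts=True)
    var_s = (
        k * (k - 1) * (2 * k + 5) - np.sum(tie_counts * (tie_counts - 1) * (2 * tie_counts + 5))
    ) / 18.0
    if var_s <= 0:
        return 1.0
    if s > 0:
        z = (s - 1) / math.sqrt(var_s)
    elif s < 0:
        z = (s + 1) / math.sqrt(var_s)
    else:
        z = 0.0
    return float(2.0 * stats.norm.sf(abs(z)))


def significance_weight(
    m: MACCTrack, method: str = "pearson", *, series: TitrationSeries | None = None
) -> MACCTrack:
    """Down-weight insignificant slopes: value' = value * (1 - P).

    ``method="pearson"`` uses the P values stored at fit time;
    ``method="mann_kendall"`` recomputes per-bin trend-test P values from
    the titration *series* (required).
    """
    if m.significance_weighted:
        raise ValueError("track is already significance-weighted")
    out = m.copy()
    if method == "pearson":
        if m.pvalues is None:
            raise ValueError("track carries no Pearson P values")
        pmap = m.pvalues
    elif method == "mann_kendall":
        if series is None:
            raise ValueError("mann_kendall weighting needs the titration series to recompute P")
        pmap = {}
        for chrom in m.chroms:
            y = series.stacked(chrom)
            p = np.full(y.shape[1], np.nan)
            for j in range(y.shape[1]):
                if np.isfinite(m.data[chrom][j]):
                    p[j] = mann_kendall_p(y[:, j])
            pmap[chrom] = p
        out.pvalues = pmap
    else:
        raise ValueError("method must be 'pearson' or 'mann_kendall'")
    for chrom in out.chroms:
        out.data[chrom] = out.data[chrom] * (1.0 - pmap[chrom])
    out.significance_weighted = True
    return out


# ---------------------------------------------------------------------------
# GC content and LOWESS correction


class GCTrack(BinnedTrack):
    """Per-bin G+C fraction in [0, 1], with optional CpG-island flags."""

    def __init__(self, bin_size: int, data: Dict[str, np.ndarray], *, genome: Genome | None = None):
        super().__init__(bin_size, data, normalized=True, units="gc_fraction", genome=genome)
        vals = self.defined_values()
        if vals.size and (vals.min() < 0 or vals.max() > 1):
            raise ValueError("GC fractions must lie in [0, 1]")
        self.cpg: Dict[str, np.ndarray] | None = None


def gc_content(reference: str | Path | "object", genome: Genome, bin_size: int) -> GCTrack:
    """Compute per-bin G+C fraction from a FASTA reference.

    The fraction is taken over non-N bases; all-N bins are missing.
    """
    if isinstance(reference, (str, Path)):
        from pyfaidx import Fasta

        fasta = Fasta(str(reference))
    else:
        fasta = reference  # mapping chrom -> sequence-like
    data: Dict[str, np.ndarray] = {}
    for chrom in genome.chroms:
        if chrom not in fasta:
            raise ValueError(f"chromosome {chrom!r} absent from the reference FASTA")
        seq = np.frombuffer(str(fasta[chrom][:]).upper().encode(), dtype="S1")
        n_bins = genome.n_bins(chrom, bin_size)
        is_gc = (seq == b"G") | (seq == b"C")
        is_base = is_gc | (seq == b"A") | (seq == b"T")
        pad = n_bins * bin_size - seq.size
        gc_counts = np.pad(is_gc.astype(float), (0, pad)).reshape(n_bins, bin_size).sum(axis=1)
        base_counts = np.pad(is_base.astype(float), (0, pad)).reshape(n_bins, bin_size).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            data[chrom] = np.where(base_counts > 0, gc_counts / base_counts, np.nan)
    return GCTrack(bin_size, data, genome=genome)


def flag_cpg_islands(gc: GCTrack, islands: Iterable[tuple[str, int, int]]) -> GCTrack:
    """Mark bins overlapping any CpG-island interval (0-based half-open)."""
    flags = {c: np.zeros(v.size, dtype=bool) for c, v in gc.data.items()}
    for chrom, start, end in islands:
        if chrom not in flags:
            continue
        lo = start // gc.bin_size
        hi = -(-end // gc.bin_size)
        flags[chrom][lo:hi] = True
    gc.cpg = flags
    return gc


def _lowess_fit(
    x: np.ndarray, y: np.ndarray, frac: float, it: int, subsample: int, rng: np.random.Generator
) -> np.ndarray:
    """LOWESS trend of y on x evaluated at every x, via a fitted subsample."""
    n = x.size
    if n > subsample:
        idx = rng.choice(n, size=subsample, replace=False)
    else:
        idx = np.arange(n)
    fitted = sm_lowess(y[idx], x[idx], frac=frac, it=it, return_sorted=True)
    # collapse duplicate abscissae, then interpolate to all bins
    fx, inv = np.unique(fitted[:, 0], return_index=True)
    fy = fitted[inv, 1]
    return np.interp(x, fx, fy)


def gc_correct(
    m: MACCTrack,
    gc: GCTrack,
    *,
    stratify_cpg: bool = False,
    frac: float = 0.3,
    iterations: int = 0,
    subsample: int = 10_000,
    min_stratum_bins: int = 100,
    seed: int = 0,
) -> MACCTrack:
    """Remove the LOWESS trend of MACC on GC content.

    Within each stratum (all bins, or CpG-island / non-island bins when
    ``stratify_cpg``), the corrected value is the raw value minus the
    LOWESS-fitted trend, plus the stratum's pre-correction mean so the
    global level is preserved.  MNase prefers AT-rich substrates, which
    otherwise leaves a GC-dependent trend in the slopes.

    ``iterations`` defaults to 0 (no robustifying reweighting): genuinely
    accessible/inaccessible bins carry large |MACC| and would be treated
    as outliers by robust iterations, biasing the fitted trend toward the
    neutral bins and leaving a residual GC correlation.
    """
    m.require_same_grid(gc)
    if stratify_cpg and gc.cpg is None:
        raise ValueError("stratify_cpg requires CpG-island flags on the GC track")
    rng = np.random.default_rng(seed)
    out = m.copy()
    chroms = m.chroms
    macc_all = np.concatenate([m.data[c] for c in chroms])
    gc_all = np.concatenate([gc.data[c] for c in chroms])
    defined = np.isfinite(macc_all) & np.isfinite(gc_all)

    if stratify_cpg:
        cpg_all = np.concatenate([gc.cpg[c] for c in chroms])
        strata = [defined & cpg_all, defined & ~cpg_all]
    else:
        strata = [defined]

    corrected = macc_all.copy()
    for mask in strata:
        n = int(mask.sum())
        if n < min_stratum_bins:
            logger.warning(
                "GC correction skipped for a stratum with %d < %d defined bins", n, min_stratum_bins
            )
            continue
        xs = gc_all[mask]
        ys = macc_all[mask]
        trend = _lowess_fit(xs, ys, frac, iterations, subsample, rng)
        # subtracting the *centred* trend preserves the stratum mean exactly
        corrected[mask] = ys - trend + trend.mean()

    offset = 0
    for chrom in chroms:
        size = m.data[chrom].size
        out.data[chrom] = corrected[offset : offset + size]
        offset += size
    out.gc_corrected = True
    return out


# ---------------------------------------------------------------------------
# shifting, enrichment, quadrants


def median_shift(m: MACCTrack) -> MACCTrack:
    """Subtract the genome-wide median so the score distribution is centred at 0."""
    vals = m.defined_values()
    if vals.size == 0:
        raise ValueError("cannot median-shift a track with no defined bins")
    med = float(np.median(vals))
    out = m.copy()
    for chrom in out.chroms:
        out.data[chrom] = out.data[chrom] - med
    out.median_shifted = True
    return out


def h3_enrichment(
    chip_pooled: BinnedTrack, input_pooled: BinnedTrack, pseudocount: float = 0.5
) -> BinnedTrack:
    """ChIP/input ratio of pooled fragment frequencies, per bin.

    The ratio is (chip + pseudocount) / (input + pseudocount); outputs
    report it on a log2 scale.
    """
    chip_pooled.require_same_grid(input_pooled)
    data = {}
    for chrom in chip_pooled.chroms:
        data[chrom] = (chip_pooled.data[chrom] + pseudocount) / (
            input_pooled.data[chrom] + pseudocount
        )
    return BinnedTrack(
        chip_pooled.bin_size,
        data,
        normalized=True,
        units="enrichment_ratio",
        genome=chip_pooled.genome,
    )


@dataclass
class QuadrantClassification:
    """Occupancy-vs-accessibility quadrant labels on the bin grid.

    Labels: 1 = high occupancy & high MACC, 2 = high occupancy & low MACC,
    0 = other, -1 = missing.
    """

    labels: Dict[str, np.ndarray]
    occ_threshold: float
    macc_low_threshold: float
    macc_high_threshold: float
    counts: Dict[str, int]

    LABEL_NAMES = {1: "high_occ_high_macc", 2: "high_occ_low_macc", 0: "other", -1: "missing"}


def classify_occupancy_accessibility(
    occupancy: BinnedTrack,
    m: MACCTrack,
    occ_top: float = 0.80,
    macc_low: float = 0.05,
    macc_high: float = 0.95,
) -> QuadrantClassification:
    """Classify bins by pooled occupancy vs MACC.

    High occupancy means above the ``occ_top`` quantile (top 20% by
    default); high/low MACC means above the ``macc_high`` / below the
    ``macc_low`` quantile.  Quantiles use inclusive linear interpolation
    over jointly defined bins, excluding partial terminal bins.
    """
    occupancy.require_same_grid(m)
    for q in (occ_top, macc_low, macc_high):
        if not 0 < q < 1:
            raise ValueError("quantiles must lie in (0, 1)")
    occ_vals, macc_vals = [], []
    for chrom in m.chroms:
        o, v = occupancy.data[chrom], m.data[chrom]
        joint = np.isfinite(o) & np.isfinite(v)
        if m.partial_terminal_bin(chrom) and joint.size:
            joint = joint.copy()
            joint[-1] = False  # partial bins are excluded from quantiles
        occ_vals.append(o[joint])
        macc_vals.append(v[joint])
    occ_pool = np.concatenate(occ_vals)
    macc_pool = np.concatenate(macc_vals)
    if occ_pool.size == 0:
        raise ValueError("no jointly defined bins")
    occ_q = float(np.quantile(occ_pool, occ_top))
    lo_q = float(np.quantile(macc_pool, macc_low))
    hi_q = float(np.quantile(macc_pool, macc_high))
    for name, pool, q in (("occupancy", occ_pool, occ_q), ("MACC", macc_pool, hi_q)):
        if np.mean(pool == q) > 0.5:
            logger.warning("degenerate %s distribution: quantile ties span >50%% of bins", name)

    labels: Dict[str, np.ndarray] = {}
    counts = {name: 0 for name in QuadrantClassification.LABEL_NAMES.values()}
    for chrom in m.chroms:
        o, v = occupancy.data[chrom], m.data[chrom]
        lab = np.zeros(o.size, dtype=int)
        joint = np.isfinite(o) & np.isfinite(v)
        lab[~joint] = -1
        high_occ = joint & (o > occ_q)
        lab[high_occ & (v > hi_q)] = 1
        lab[high_occ & (v < lo_q)] = 2
        labels[chrom] = lab
        for code, name in QuadrantClassification.LABEL_NAMES.items():
            counts[name] += int(np.sum(lab == code))
    logger.info(
        "quadrant thresholds: occupancy>%.4g, MACC<%.4g / >%.4g; counts=%s",
        occ_q,
        lo_q,
        hi_q,
        counts,
    )
    return QuadrantClassification(labels, occ_q, lo_q, hi_q, counts)
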