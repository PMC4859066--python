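"""End-to-end pipeline wiring: fragments -> tracks -> MACC -> downstream.

Stages run in dependency order; every run writes a provenance record
(config hash, seed, package version) next to its outputs and is
reproducible given the same configuration and seed.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np
import yaml

from . import __version__
from .config import RunConfig
from .fragments import (
    FragmentSet,
    bin_counts,
    filter_anomalous_positions,
    normalize_track,
    pool_occupancy,
    read_fragments,
)
from .hmm import fit_two_state_hmm, segment_stats, shuffle_track, viterbi_segment
from .macc import (
    classify_occupancy_accessibility,
    fit_macc,
    flag_cpg_islands,
    gc_content,
    gc_correct,
    h3_enrichment,
    median_shift,
)
from .peaks import assign_groups, call_local_peaks
from .tracks import Genome, MACCTrack, TitrationSeries, read_chrom_sizes

logger = logging.getLogger(__name__)

__all__ = ["series_from_fragment_sets", "macc_for_pool", "run_pipeline"]

STAGES = ("tracks", "macc", "segment", "peaks", "groups")


def series_from_fragment_sets(
    fragment_sets: Sequence[FragmentSet],
    genome: Genome,
    bin_size: int,
    z_threshold: float | None = 7.0,
) -> TitrationSeries:
    """Filter, bin and normalize one pool's libraries into a titration series.

    Libraries sharing a concentration (replicates) are pooled by
    concatenating their fragments before normalization; per-point
    normalization uses the post-filter retained library size.
    """
    by_conc: Dict[float, List[FragmentSet]] = {}
    for fs in fragment_sets:
        by_conc.setdefault(fs.concentration, []).append(fs)
    tracks, concs = [], []
    for conc in sorted(by_conc):
        group = by_conc[conc]
        if len(group) > 1:
            import pandas as pd

            merged = FragmentSet(
                pd.concat([g.fragments for g in group], ignore_index=True),
                concentration=conc,
                label="+".join(g.label for g in group),
                pool=group[0].pool,
            )
        else:
            merged = group[0]
        if z_threshold is not None:
            merged = filter_anomalous_positions(merged, z_threshold)
        raw = bin_counts(merged, genome, bin_size)
        tracks.append(normalize_track(raw, merged.library_size, genome.total_size))
        concs.append(conc)
    return TitrationSeries(tracks, np.array(concs))


def macc_for_pool(
    series: TitrationSeries,
    *,
    provenance: str,
    log_base: float,
    gc_track=None,
    stratify_cpg: bool = False,
    lowess_frac: float = 0.3,
    lowess_iterations: int = 0,
    seed: int = 0,
) -> MACCTrack:
    """MACC for one pool: fit, optional GC correction, median shift."""
    m = fit_macc(series, log_base=log_base, provenance=provenance)
    if gc_track is not None:
        m = gc_correct(
            m,
            gc_track,
            stratify_cpg=stratify_cpg,
            frac=lowess_frac,
            iterations=lowess_iterations,
            seed=seed,
        )
    return median_shift(m)


def run_pipeline(config: RunConfig, stages: Sequence[str] | None = None) -> Dict[str, object]:
    """Execute the requested stages and write artifacts under ``config.outdir``.

    Returns a dict of in-memory results keyed by artifact name.  Stage
    dependencies are implicit: requesting a late stage runs what it needs.
    """
    config.validate()
    stages = list(stages or STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}; available: {STAGES}")
    p = config.params
    outdir = Path(config.resolve(config.outdir))
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    genome = read_chrom_sizes(config.resolve(config.chrom_sizes))
    results: Dict[str, object] = {"genome": genome}

    # ---- fragments -> normalized titration series per pool ---------------
    by_pool: Dict[str, List[FragmentSet]] = {}
    for s in config.samples:
        fs = read_fragments(
            config.resolve(s.path),
            p.min_fragment_length,
            p.max_fragment_length,
            concentration=s.concentration,
            label=s.label,
            pool=s.pool,
        )
        by_pool.setdefault(s.pool, []).append(fs)
    series: Dict[str, TitrationSeries] = {
        pool: series_from_fragment_sets(sets, genome, p.bin_size, p.z_threshold)
        for pool, sets in by_pool.items()
    }
    results["series"] = series

    if "tracks" in stages:
        for pool, ser in series.items():
            for track, conc in zip(ser.tracks, ser.concentrations):
                track.to_bedgraph(outdir / f"{pool}_{conc:g}U.norm.bedgraph")
            pool_occupancy(ser).to_bedgraph(outdir / f"{pool}_pooled.bedgraph")

    # ---- MACC ------------------------------------------------------------
    need_macc = bool({"macc", "segment", "peaks", "groups"} & set(stages))
    if need_macc:
        gc_track = None
        if config.fasta:
            gc_track = gc_content(config.resolve(config.fasta), genome, p.bin_size)
            if config.cpg_islands:
                islands = _read_bed_intervals(config.resolve(config.cpg_islands))
                gc_track = flag_cpg_islands(gc_track, islands)
        macc_tracks: Dict[str, MACCTrack] = {}
        for pool, prov in (("chromatin", "c-MACC"), ("histone_chip", "h-MACC")):
            if pool not in series:
                continue
            macc_tracks[prov] = macc_for_pool(
                series[pool],
                provenance=prov,
                log_base=p.log_base,
                gc_track=gc_track,
                stratify_cpg=p.stratify_cpg,
                lowess_frac=p.lowess_frac,
                lowess_iterations=p.lowess_iterations,
                seed=p.seed,
            )
            macc_tracks[prov].to_bedgraph(outdir / f"{prov}.bedgraph")
        if "c-MACC" not in macc_tracks:
            raise ValueError("MACC stage requires a 'chromatin' pool in the sample table")
        results["macc"] = macc_tracks
        occupancy = pool_occupancy(series["chromatin"])
        results["occupancy"] = occupancy
        if "histone_chip" in series and "chip_input" in series:
            enrich = h3_enrichment(
                pool_occupancy(series["histone_chip"]),
                pool_occupancy(series["chip_input"]),
                p.pseudocount,
            )
            results["h3_enrichment"] = enrich
        quad = classify_occupancy_accessibility(
            occupancy,
            macc_tracks["c-MACC"],
            p.occ_top_quantile,
            p.macc_low_quantile,
            p.macc_high_quantile,
        )
        results["quadrants"] = quad
        _write_tsv_summary(outdir / "summary.tsv", quad)

    if "segment" in stages:
        c_macc = results["macc"]["c-MACC"]
        model = fit_two_state_hmm(
            c_macc, p.hmm_restarts, p.seed, min_defined_bins=p.hmm_min_defined_bins
        )
        seg = viterbi_segment(model, c_macc)
        shuffled = shuffle_track(c_macc, p.seed)
        null_model = fit_two_state_hmm(
            shuffled, p.hmm_restarts, p.seed + 1, min_defined_bins=p.hmm_min_defined_bins
        )
        null_seg = viterbi_segment(null_model, shuffled)
        stats = segment_stats(seg, null_seg)
        results["hmm_model"] = model
        results["segmentation"] = seg
        results["segment_stats"] = stats
        seg.to_bed(outdir / "hmm_states.bed", c_macc)
        with open(outdir / "hmm_model.yaml", "w") as fh:
            yaml.safe_dump(model.to_dict(), fh)
        logger.info("segmentation: %s", stats.summary().replace("\n", "; "))

    if "peaks" in stages or "groups" in stages:
        c_macc = results["macc"]["c-MACC"]
        peaks = call_local_peaks(c_macc)
        results["peaks"] = peaks
        peaks.to_bed(outdir / "peaks.bed")

    if "groups" in stages:
        if "h-MACC" not in results["macc"]:
            raise ValueError("group assignment requires a 'histone_chip' pool (h-MACC)")
        groups = assign_groups(
            results["macc"]["c-MACC"],
            results["macc"]["h-MACC"],
            p.c_top_quantile,
            p.h_low_quantile,
            p.h_high_quantile,
        )
        results["groups"] = groups
        groups.to_bed(outdir / "groups.bed", results["macc"]["c-MACC"], p.bin_size)

    with open(outdir / "run_info.json", "w") as fh:
        json.dump(
            {
                "config_hash": config.digest(),
                "seed": p.seed,
                "version": __version__,
                "stages": stages,
                "elapsed_s": round(time.time() - t0, 2),
            },
            fh,
            indent=2,
        )
    return results


def _read_bed_intervals(path: Path) -> List[tuple]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]), int(f[2])))
    return out


def _write_tsv_summary(path: Path, quad) -> None:
    with open(path, "w") as fh:
        fh.write("metric\tvalue\n")
        fh.write(f"occupancy_threshold\t{quad.occ_threshold:.6g}\n")
        fh.write(f"macc_low_threshold\t{quad.macc_low_threshold:.6g}\n")
        fh.write(f"macc_high_threshold\t{quad.macc_high_threshold:.6g}\n")
        for name, n in quad.counts.items():
            fh.write(f"count_{name}\t{n}\n")
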