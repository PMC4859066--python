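"""Genome annotation on the bin grid: region classes with priority resolution.

Each bin receives exactly one class among enhancer, promoter (upstream of
the TSS), 5'-gene (downstream of the TSS), TES-proximal, gene body and
unannotated, resolved by the priority order
enhancer > promoter > 5'-gene > TES-prox > gene body.  Windows are
organism-dependent (1 kb for fly, 2 kb for mouse/human annotations).
TSS-proximal bins that overlap a different gene are excluded from the
TSS classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping

import numpy as np
import pandas as pd

from .tracks import Genome

__all__ = ["GenomeAnnotation", "build_annotation", "region_enrichment"]

UNANNOTATED, GENE_BODY, TES_PROX, FIVE_PRIME, PROMOTER, ENHANCER = range(6)
CLASS_NAMES = {
    ENHANCER: "enhancer",
    PROMOTER: "promoter",
    FIVE_PRIME: "five_prime_gene",
    TES_PROX: "tes_proximal",
    GENE_BODY: "gene_body",
    UNANNOTATED: "unannotated",
}
# descending priority for assignment
PRIORITY = (ENHANCER, PROMOTER, FIVE_PRIME, TES_PROX, GENE_BODY)


@dataclass
class GenomeAnnotation:
    """Per-bin region-class codes (see ``CLASS_NAMES``)."""

    bin_size: int
    classes: Dict[str, np.ndarray]
    window: int

    def class_fractions(self) -> Dict[str, float]:
        total = sum(v.size for v in self.classes.values())
        out = {}
        for code, name in CLASS_NAMES.items():
            out[name] = sum(int((v == code).sum()) for v in self.classes.values()) / total
        return out

    def class_mask(self, code: int) -> Dict[str, np.ndarray]:
        return {c: v == code for c, v in self.classes.items()}


def _bin_range(start: int, end: int, bin_size: int, n_bins: int) -> slice:
    """Bins overlapping [start, end), clipped to the chromosome."""
    lo = max(start, 0) // bin_size
    hi = -(-min(end, n_bins * bin_size) // bin_size)
    return slice(max(lo, 0), max(hi, max(lo, 0)))


def build_annotation(
    genes: pd.DataFrame,
    enhancers: Iterable[tuple[str, int, int]],
    genome: Genome,
    bin_size: int,
    window: int = 1000,
) -> GenomeAnnotation:
    """Build the per-bin class map from gene models and enhancer intervals.

    ``genes`` needs columns chrom, start, end, strand ('+'/'-'); TSS is
    ``start`` on the plus strand and ``end`` on the minus strand, TES the
    opposite end.  Promoter = ``window`` bp upstream of the TSS, 5'-gene
    = ``window`` bp downstream, TES-proximal = +/-``window`` around the TES.
    """
    need = {"chrom", "start", "end", "strand"}
    if not need.issubset(genes.columns):
        raise ValueError(f"gene table must have columns {sorted(need)}")
    if genes["strand"].isin(["+", "-"]).all() is False or (~genes["strand"].isin(["+", "-"])).any():
        raise ValueError("every gene record must have strand '+' or '-'")

    nb = {c: genome.n_bins(c, bin_size) for c in genome.chroms}
    classes = {c: np.full(n, UNANNOTATED, dtype=int) for c, n in nb.items()}

    # per-bin count of overlapping genes, used for the other-gene exclusion
    gene_count = {c: np.zeros(n, dtype=int) for c, n in nb.items()}
    gene_rows = []
    for row in genes.itertuples(index=False):
        if row.chrom not in nb:
            continue
        gene_count[row.chrom][_bin_range(row.start, row.end, bin_size, nb[row.chrom])] += 1
        gene_rows.append(row)

    masks = {code: {c: np.zeros(n, dtype=bool) for c, n in nb.items()} for code in PRIORITY}
    for chrom, start, end in enhancers:
        if chrom in nb:
            masks[ENHANCER][chrom][_bin_range(start, end, bin_size, nb[chrom])] = True

    for row in gene_rows:
        chrom, n = row.chrom, nb[row.chrom]
        if row.strand == "+":
            tss, tes = row.start, row.end
            promoter = (tss - window, tss)
            five_prime = (tss, tss + window)
        else:
            tss, tes = row.end, row.start
            promoter = (tss, tss + window)
            five_prime = (tss - window, tss)
        own = np.zeros(n, dtype=bool)
        own[_bin_range(row.start, row.end, bin_size, n)] = True
        for code, (s, e) in ((PROMOTER, promoter), (FIVE_PRIME, five_prime)):
            sl = _bin_range(s, e, bin_size, n)
            sel = np.zeros(n, dtype=bool)
            sel[sl] = True
            # exclude TSS-proximal bins that overlap a *different* gene
            other = gene_count[chrom] - own.astype(int) > 0
            masks[code][chrom] |= sel & ~other
        masks[TES_PROX][chrom][_bin_range(tes - window, tes + window, bin_size, n)] = True
        masks[GENE_BODY][chrom][_bin_range(row.start, row.end, bin_size, n)] = True

    for chrom in classes:
        assigned = np.zeros(nb[chrom], dtype=bool)
        for code in PRIORITY:
            sel = masks[code][chrom] & ~assigned
            classes[chrom][sel] = code
            assigned |= sel
    return GenomeAnnotation(bin_size, classes, window)


def region_enrichment(
    bins: Mapping[str, np.ndarray], ann: GenomeAnnotation
) -> Dict[str, float]:
    """Enrichment of a bin set in each region class.

    ratio = (fraction of query bins in the class) /
            (fraction of the genome covered by the class); classes with
    zero genome coverage are reported as NaN.
    """
    total_bins = sum(v.size for v in ann.classes.values())
    n_query = sum(int(np.asarray(bins.get(c, np.zeros(0, bool))).sum()) for c in ann.classes)
    if n_query == 0:
        raise ValueError("empty query bin set")
    out: Dict[str, float] = {}
    for code, name in CLASS_NAMES.items():
        genome_frac = (
            sum(int((v == code).sum()) for v in ann.classes.values()) / total_bins
        )
        if genome_frac == 0:
            out[name] = float("nan")
            continue
        in_class = 0
        for chrom, v in ann.classes.items():
            q = bins.get(chrom)
            if q is not None:
                in_class += int(np.sum(np.asarray(q, dtype=bool) & (v == code)))
        out[name] = (in_class / n_query) / genome_frac
    return out
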