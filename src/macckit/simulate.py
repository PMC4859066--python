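"""Synthetic MNase titration data with known per-bin ground truth.

The generator emulates the two opposing modes of chromatin response to an
MNase titration: accessible loci are preferentially released under light
digestion and lost to over-digestion at high enzyme levels (yield falls
with concentration), while inaccessible loci require deep digestion to
release mononucleosomes (yield rises with concentration).  Per-bin
expected yield follows a log-linear response,

    lambda_ij = background + depth * exp(beta_i * (x_j - x_bar)),
    x_j = -ln(concentration_j),

so the MACC regression slope is the matched estimator of the planted
response.  Accessibility classes are organized into geometric-length
domains (domain-scale clustering of chromatin states), GC content is a
smooth random field that can bias the response, non-histone-protein (NHP)
loci yield short sub-nucleosomal fragments and are absent from the
histone-ChIP pool apart from non-specific background, and "fragile
nucleosome" loci respond strongly in both chromatin and ChIP pools.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Sequence

import numpy as np
import pandas as pd

from .fragments import POOLS, FragmentSet
from .tracks import Genome

__all__ = [
    "SyntheticTruth",
    "TitrationSimulation",
    "simulate_genome",
    "simulate_titration",
    "expected_macc",
    "write_fixture",
    "DEFAULT_CONCENTRATIONS",
    "DEFAULT_CLASS_FRACTIONS",
]

NEUTRAL, ACCESSIBLE_CLASS, INACCESSIBLE_CLASS = 0, 1, 2
CLASS_CODES = {"neutral": NEUTRAL, "accessible": ACCESSIBLE_CLASS, "inaccessible": INACCESSIBLE_CLASS}

# The study conditions: four-point exponential titration (units of MNase)
DEFAULT_CONCENTRATIONS = (1.5, 6.25, 25.0, 100.0)
# Accessible-state genome share ~20%, balanced by an equal inaccessible
# share (material over-digested at one end of the titration reappears as
# released mononucleosomes at the other, so the two scenarios trade yield);
# NHP/fragile loci each 15% of the accessible bins, i.e. ~3% of all bins.
DEFAULT_CLASS_FRACTIONS = {"accessible": 0.20, "inaccessible": 0.20, "neutral": 0.60}

# response-exponent magnitudes (see docs/methods.md for the error budget)
BETA_ACCESSIBLE = (0.25, 0.05)  # mean, sd of |beta| for generic accessible bins
BETA_INACCESSIBLE = (0.25, 0.05)
BETA_NEUTRAL_SD = 0.15  # continuous biological spread around zero (signal >> noise)
BETA_SPECIAL = (0.50, 0.05)  # NHP and fragile loci: strongest responders

FRAGMENT_LENGTH = (150.0, 20.0)  # bulk mononucleosomal fragments
NHP_FRAGMENT_LENGTH = (110.0, 15.0)  # sub-nucleosomal NHP footprints
LENGTH_BOUNDS = (50, 500)


@dataclass
class SyntheticTruth:
    """Planted per-bin ground truth of a simulated genome."""

    genome: Genome
    bin_size: int
    class_codes: Dict[str, np.ndarray]  # 0 neutral / 1 accessible / 2 inaccessible
    beta: Dict[str, np.ndarray]  # signed response exponents
    gc: Dict[str, np.ndarray]  # G+C fraction in [0.25, 0.75]
    nhp: Dict[str, np.ndarray]  # bool: non-histone-protection locus
    fragile: Dict[str, np.ndarray]  # bool: fragile-nucleosome locus
    domain_id: Dict[str, np.ndarray]
    seed: int

    @property
    def chroms(self) -> list[str]:
        return list(self.class_codes)

    @property
    def n_bins(self) -> int:
        return sum(v.size for v in self.class_codes.values())

    def concat(self, name: str) -> np.ndarray:
        return np.concatenate([getattr(self, name)[c] for c in self.chroms])

    def class_mask(self, cls: str) -> Dict[str, np.ndarray]:
        code = CLASS_CODES[cls]
        return {c: v == code for c, v in self.class_codes.items()}

    def to_bed(self, path: str | Path) -> None:
        """Truth as BED: name=class, score=beta, extra flag columns."""
        names = {v: k for k, v in CLASS_CODES.items()}
        with open(path, "w") as fh:
            for chrom in self.chroms:
                for i, code in enumerate(self.class_codes[chrom]):
                    flags = []
                    if self.nhp[chrom][i]:
                        flags.append("nhp")
                    if self.fragile[chrom][i]:
                        flags.append("fragile")
                    fh.write(
                        f"{chrom}\t{i * self.bin_size}\t{(i + 1) * self.bin_size}\t"
                        f"{names[int(code)]}\t{self.beta[chrom][i]:.4f}\t.\t"
                        f"{','.join(flags) or '.'}\t{self.gc[chrom][i]:.4f}\n"
                    )


def _smooth_gc_field(n: int, rng: np.random.Generator, corr_bins: float = 10.0) -> np.ndarray:
    """Smooth random GC field mapped into [0.25, 0.75]."""
    noise = rng.normal(size=n + 1)
    width = int(6 * corr_bins) | 1
    t = np.arange(width) - width // 2
    kernel = np.exp(-0.5 * (t / corr_bins) ** 2)
    kernel /= kernel.sum()
    smooth = np.convolve(noise, kernel, mode="same")[:n]
    z = (smooth - smooth.mean()) / (smooth.std() or 1.0)
    return 0.5 + 0.25 * np.tanh(z)


def simulate_genome(
    n_bins: int = 10_000,
    bin_size: int = 300,
    mean_domain_len: float = 20.0,
    class_fractions: Mapping[str, float] | None = None,
    nhp_fraction: float = 0.15,
    fragile_fraction: float = 0.15,
    seed: int = 0,
    n_chroms: int = 1,
) -> SyntheticTruth:
    """Plant a genome of accessibility domains with GC field and special loci.

    Domains have geometric lengths with the given mean (in bins) and each
    domain draws its class independently from ``class_fractions``.
    ``nhp_fraction`` and ``fragile_fraction`` are fractions *of the
    accessible bins* flagged (disjointly) as NHP-protected and
    fragile-nucleosome loci; both carry the boosted response magnitude.
    """
    fractions = dict(class_fractions or DEFAULT_CLASS_FRACTIONS)
    if any(f < 0 for f in fractions.values()) or sum(fractions.values()) > 1 + 1e-9:
        raise ValueError("class fractions must be non-negative and sum to <= 1")
    if nhp_fraction + fragile_fraction > 1:
        raise ValueError("nhp_fraction + fragile_fraction must not exceed 1")
    fractions.setdefault("neutral", 0.0)
    fractions["neutral"] += max(0.0, 1.0 - sum(fractions.values()))

    rng = np.random.default_rng(seed)
    per_chrom = [n_bins // n_chroms] * n_chroms
    per_chrom[-1] += n_bins - sum(per_chrom)
    sizes = {f"chrS{i + 1}": n * bin_size for i, n in enumerate(per_chrom)}
    genome = Genome(sizes)

    class_names = ["neutral", "accessible", "inaccessible"]
    probs = np.array([fractions.get(n, 0.0) for n in class_names])
    probs = probs / probs.sum()

    class_codes, beta, gc, nhp, fragile, domain_id = {}, {}, {}, {}, {}, {}
    next_domain = 0
    for chrom, nb in zip(sizes, per_chrom):
        codes = np.empty(nb, dtype=int)
        dom = np.empty(nb, dtype=int)
        pos = 0
        while pos < nb:
            length = rng.geometric(1.0 / mean_domain_len) if mean_domain_len > 1 else 1
            cls = rng.choice(3, p=probs)
            end = min(pos + length, nb)
            codes[pos:end] = cls
            dom[pos:end] = next_domain
            next_domain += 1
            pos = end
        b = np.zeros(nb)
        neutral = codes == NEUTRAL
        acc = codes == ACCESSIBLE_CLASS
        inacc = codes == INACCESSIBLE_CLASS
        b[neutral] = rng.normal(0.0, BETA_NEUTRAL_SD, neutral.sum())
        b[acc] = np.abs(rng.normal(*BETA_ACCESSIBLE, acc.sum()))
        b[inacc] = -np.abs(rng.normal(*BETA_INACCESSIBLE, inacc.sum()))

        nhp_mask = np.zeros(nb, dtype=bool)
        fragile_mask = np.zeros(nb, dtype=bool)
        acc_idx = np.flatnonzero(acc)
        n_special = int(round(len(acc_idx) * (nhp_fraction + fragile_fraction)))
        n_nhp = int(round(len(acc_idx) * nhp_fraction))
        if n_special:
            special = rng.choice(acc_idx, size=min(n_special, len(acc_idx)), replace=False)
            nhp_idx, fragile_idx = special[:n_nhp], special[n_nhp:]
            nhp_mask[nhp_idx] = True
            fragile_mask[fragile_idx] = True
            boost = np.abs(rng.normal(*BETA_SPECIAL, special.size))
            b[special] = boost  # strongest (positive) responders

        class_codes[chrom] = codes
        beta[chrom] = b
        gc[chrom] = _smooth_gc_field(nb, rng)
        nhp[chrom] = nhp_mask
        fragile[chrom] = fragile_mask
        domain_id[chrom] = dom
    return SyntheticTruth(
        genome, bin_size, class_codes, beta, gc, nhp, fragile, domain_id, seed
    )


@dataclass
class TitrationSimulation:
    """Simulated fragment libraries for every pool and titration point."""

    truth: SyntheticTruth
    concentrations: np.ndarray
    fragment_sets: Dict[str, List[FragmentSet]]  # pool -> one set per point
    depth: float
    gc_bias_strength: float
    background: float
    seed: int


def _expected_yield(
    truth: SyntheticTruth,
    concentrations: np.ndarray,
    depth: float,
    gc_bias_strength: float,
    background: float,
    pool: str,
) -> Dict[str, np.ndarray]:
    """(n_bins, k) expected fragment counts per chromosome for one pool."""
    x = -np.log(concentrations)
    u = x - x.mean()
    out = {}
    for chrom in truth.chroms:
        beta = truth.beta[chrom][:, None]
        gc_term = gc_bias_strength * (truth.gc[chrom][:, None] - 0.5)
        lam = background * depth + depth * np.exp((beta + gc_term) * u[None, :])
        if pool == "histone_chip":
            lam = np.where(truth.nhp[chrom][:, None], background * depth, lam)
        out[chrom] = lam
    return out


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    vals = rng.normal(mean, sd, size)
    bad = (vals < lo) | (vals > hi)
    while bad.any():  # redraw: cheap, tails are light
        vals[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (vals < lo) | (vals > hi)
    return vals


def simulate_titration(
    truth: SyntheticTruth,
    concentrations: Sequence[float] = DEFAULT_CONCENTRATIONS,
    depth: float = 50.0,
    gc_bias_strength: float = 0.0,
    seed: int = 0,
    *,
    background: float = 0.04,
    pools: Sequence[str] = POOLS,
) -> TitrationSimulation:
    """Draw Poisson fragment counts and fragment coordinates for every pool.

    ``depth`` is the expected specific yield (fragments per bin per point)
    at the titration midpoint; ``background`` adds a uniform non-specific
    floor of ``background * depth`` to every bin (and is all that remains
    of NHP loci in the histone-ChIP pool).  Fragment lengths are
    mononucleosomal, Normal(150, 20) truncated to [50, 500], except at NHP
    loci in the chromatin-derived pools where the protected footprint is
    sub-nucleosomal, Normal(110, 15).
    """
    conc = np.asarray(concentrations, dtype=float)
    if conc.size < 2 or np.any(np.diff(conc) <= 0):
        raise ValueError("need >= 2 strictly increasing concentrations")
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    fragment_sets: Dict[str, List[FragmentSet]] = {}
    for pool in pools:
        lam = _expected_yield(truth, conc, depth, gc_bias_strength, background, pool)
        sets = []
        for j, c in enumerate(conc):
            chroms_out, starts_out, ends_out = [], [], []
            for chrom in truth.chroms:
                counts = rng.poisson(lam[chrom][:, j])
                bin_idx = np.repeat(np.arange(counts.size), counts)
                n = bin_idx.size
                if n == 0:
                    continue
                mids = bin_idx * truth.bin_size + rng.uniform(0, truth.bin_size, n)
                nhp_here = truth.nhp[chrom][bin_idx] & (pool != "histone_chip")
                lengths = np.empty(n)
                n_nhp = int(nhp_here.sum())
                if n_nhp:
                    lengths[nhp_here] = _truncated_normal(
                        rng, *NHP_FRAGMENT_LENGTH, *LENGTH_BOUNDS, n_nhp
                    )
                lengths[~nhp_here] = _truncated_normal(
                    rng, *FRAGMENT_LENGTH, *LENGTH_BOUNDS, n - n_nhp
                )
                lengths = np.round(lengths).astype(int)
                starts = np.round(mids - lengths / 2).astype(int)
                size = truth.genome.sizes[chrom]
                starts = np.clip(starts, 0, np.maximum(size - lengths, 0))
                ends = starts + lengths
                chroms_out.append(np.full(n, chrom, dtype=object))
                starts_out.append(starts)
                ends_out.append(ends)
            df = pd.DataFrame(
                {
                    "chrom": np.concatenate(chroms_out) if chroms_out else [],
                    "start": np.concatenate(starts_out) if starts_out else [],
                    "end": np.concatenate(ends_out) if ends_out else [],
                }
            )
            sets.append(
                FragmentSet(df, concentration=float(c), label=f"{pool}_{c:g}U", pool=pool)
            )
        fragment_sets[pool] = sets
    return TitrationSimulation(
        truth, conc, fragment_sets, depth, gc_bias_strength, background, seed
    )


def expected_macc(
    truth: SyntheticTruth,
    concentrations: Sequence[float] = DEFAULT_CONCENTRATIONS,
    depth: float = 50.0,
    gc_bias_strength: float = 0.0,
    *,
    background: float = 0.04,
    pool: str = "chromatin",
    log_base: float = math.e,
) -> Dict[str, np.ndarray]:
    """Noise-free MACC slope implied by the planted truth.

    Computes the expected normalized frequency per bin and point (expected
    counts, expected library size, the per-million and genome-size/100-Mb
    factors) and returns the closed-form OLS slope on ``x = -log(c)``.
    This is the quantity ``fit_macc`` estimates; regression of fitted on
    expected slopes has unit slope under the model.
    """
    conc = np.asarray(concentrations, dtype=float)
    lam = _expected_yield(truth, conc, depth, gc_bias_strength, background, pool)
    lib = np.sum([lam[c].sum(axis=0) for c in truth.chroms], axis=0)  # per point
    factor = 1e6 / lib * truth.genome.total_size / 1e8
    x = -np.log(conc) / math.log(log_base)
    xc = x - x.mean()
    sxx = float(xc @ xc)
    out = {}
    for chrom in truth.chroms:
        y = lam[chrom] * factor[None, :]
        dev = y - y.mean(axis=1, keepdims=True)
        out[chrom] = (dev @ xc) / sxx
    return out


def write_fixture(sim: TitrationSimulation, directory: str | Path) -> Dict[str, object]:
    """Write the simulation to disk as plain-text files.

    Layout: ``fragments/<pool>_<conc>U.bedpe``, ``chrom.sizes`` (TSV),
    ``truth.bed``, ``genome.fa`` (random sequence matching the per-bin GC
    fractions) and ``samples.tsv`` (path, concentration, pool, label).
    Fixtures are losslessly re-readable by :func:`macckit.read_fragments`.
    """
    directory = Path(directory)
    frag_dir = directory / "fragments"
    frag_dir.mkdir(parents=True, exist_ok=True)
    truth = sim.truth

    sizes_path = directory / "chrom.sizes"
    with open(sizes_path, "w") as fh:
        for chrom, size in truth.genome.sizes.items():
            fh.write(f"{chrom}\t{size}\n")

    truth_path = directory / "truth.bed"
    truth.to_bed(truth_path)

    rng = np.random.default_rng(truth.seed + 1_000_003)
    fasta_path = directory / "genome.fa"
    with open(fasta_path, "w") as fh:
        for chrom in truth.chroms:
            fh.write(f">{chrom}\n")
            for i, gc in enumerate(truth.gc[chrom]):
                p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
                seq = rng.choice(list("ACGT"), size=truth.bin_size, p=p)
                fh.write("".join(seq) + "\n")

    rows = []
    for pool, sets in sim.fragment_sets.items():
        for fs in sets:
            path = frag_dir / f"{fs.label}.bedpe"
            fs.to_bedpe(path)
            rows.append(
                {
                    "path": str(path.relative_to(directory)),
                    "concentration": fs.concentration,
                    "pool": pool,
                    "label": fs.label,
                    "library_size": fs.library_size,
                }
            )
    samples = pd.DataFrame(rows)
    samples_path = directory / "samples.tsv"
    samples.to_csv(samples_path, sep="\t", index=False)
    return {
        "chrom_sizes": sizes_path,
        "truth": truth_path,
        "fasta": fasta_path,
        "samples": samples_path,
        "fragments": frag_dir,
    }
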