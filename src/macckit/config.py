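"""Declarative run configuration.

One YAML file drives a whole analysis: the sample table (fragment file,
MNase amount, pool, replicate, label), genome resources (chromosome
sizes, FASTA, annotations, CpG islands) and every tunable parameter.
Defaults follow the published protocol: 300-bp bins, 50-500 bp insert
window, Z=7 anomalous-position threshold, 80/10/90 positive-score
percentiles for group calling, 10 overlap randomizations, 40-bp profile
smoothing and a 1-kb TSS window (2 kb for mammalian annotations).
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import List, Optional

import yaml

__all__ = ["SampleSpec", "Parameters", "RunConfig"]


@dataclass
class SampleSpec:
    path: str
    concentration: float
    pool: str = "chromatin"
    label: str = ""
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValueError(f"sample {self.label or self.path}: concentration must be > 0")


@dataclass
class Parameters:
    bin_size: int = 300
    min_fragment_length: int = 50
    max_fragment_length: int = 500
    z_threshold: float = 7.0
    log_base: float = math.e
    lowess_frac: float = 0.3
    lowess_iterations: int = 0
    stratify_cpg: bool = False
    pseudocount: float = 0.5
    c_top_quantile: float = 0.80
    h_low_quantile: float = 0.10
    h_high_quantile: float = 0.90
    occ_top_quantile: float = 0.80
    macc_low_quantile: float = 0.05
    macc_high_quantile: float = 0.95
    n_randomizations: int = 10
    smooth_window: int = 40
    tss_window: int = 1000
    hmm_restarts: int = 10
    hmm_min_defined_bins: int = 100
    seed: int = 0


@dataclass
class RunConfig:
    chrom_sizes: str
    samples: List[SampleSpec]
    fasta: Optional[str] = None
    cpg_islands: Optional[str] = None
    genes: Optional[str] = None
    enhancers: Optional[str] = None
    outdir: str = "macckit_out"
    params: Parameters = field(default_factory=Parameters)
    base_dir: Optional[str] = None  # resolved against at load time; not serialized

    # -- IO ----------------------------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw, base_dir=str(path.parent))

    @classmethod
    def from_dict(cls, raw: dict, base_dir: str | None = None) -> "RunConfig":
        samples = [SampleSpec(**s) for s in raw.get("samples", [])]
        params = Parameters(**(raw.get("params") or {}))
        keys = {f.name for f in fields(cls)} - {"samples", "params", "base_dir"}
        rest = {k: v for k, v in raw.items() if k in keys}
        return cls(samples=samples, params=params, base_dir=base_dir, **rest)

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("base_dir")
        return d

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def resolve(self, p: str) -> Path:
        path = Path(p)
        if not path.is_absolute() and self.base_dir:
            path = Path(self.base_dir) / path
        return path

    def digest(self) -> str:
        """Stable hash of the configuration, for provenance headers."""
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    # -- validation --------------------------------------------------------

    def validate(self, *, check_files: bool = True) -> None:
        if not self.samples:
            raise ValueError("configuration lists no samples")
        by_pool: dict[str, set[float]] = {}
        for s in self.samples:
            by_pool.setdefault(s.pool, set()).add(s.concentration)
        for pool, concs in by_pool.items():
            if len(concs) < 2:
                raise ValueError(
                    f"pool {pool!r} has {len(concs)} distinct MNase concentration(s); "
                    "a titration needs at least 2"
                )
        if check_files:
            missing = [
                str(self.resolve(p))
                for p in [self.chrom_sizes, self.fasta, self.cpg_islands, self.genes, self.enhancers]
                + [s.path for s in self.samples]
                if p is not None and not self.resolve(p).exists()
            ]
            if missing:
                raise FileNotFoundError("missing input files: " + ", ".join(missing))
        p = self.params
        if p.min_fragment_length > p.max_fragment_length:
            raise ValueError("min_fragment_length must be <= max_fragment_length")
        for name in (
            "c_top_quantile",
            "h_low_quantile",
            "h_high_quantile",
            "occ_top_quantile",
            "macc_low_quantile",
            "macc_high_quantile",
        ):
            q = getattr(p, name)
            if not 0 < q < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {q}")
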