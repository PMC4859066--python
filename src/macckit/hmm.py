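"""Two-state Gaussian-HMM segmentation of MACC profiles.

The genome is modelled as alternating domains of "accessible" (mostly
positive MACC) and "inaccessible" (mostly negative MACC) chromatin.  A
two-state HMM with one Gaussian emission per state is fitted genome-wide
by Baum-Welch over the maximal gap-free runs of defined bins (missing
bins break the observation sequences rather than being imputed), and the
most probable state path is decoded per run with the Viterbi algorithm.
A within-chromosome shuffle of the score profile provides the null
against which the observed run lengths are compared.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

from .tracks import MACCTrack

logger = logging.getLogger(__name__)

__all__ = [
    "HMMModel",
    "StateSegmentation",
    "fit_two_state_hmm",
    "viterbi_segment",
    "shuffle_track",
    "segment_stats",
    "SegmentStats",
]

INACCESSIBLE, ACCESSIBLE, MISSING = 0, 1, -1
STATE_NAMES = {INACCESSIBLE: "inaccessible", ACCESSIBLE: "accessible", MISSING: "missing"}


@dataclass
class HMMModel:
    """2-state Gaussian HMM; state 1 ("accessible") has the larger emission mean."""

    startprob: np.ndarray  # (2,)
    transmat: np.ndarray  # (2, 2), rows sum to 1
    means: np.ndarray  # (2,)
    sds: np.ndarray  # (2,)
    log_likelihood: float = float("nan")

    def __post_init__(self) -> None:
        self.startprob = np.asarray(self.startprob, dtype=float)
        self.transmat = np.asarray(self.transmat, dtype=float)
        self.means = np.asarray(self.means, dtype=float).ravel()
        self.sds = np.asarray(self.sds, dtype=float).ravel()
        if not np.allclose(self.transmat.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition-matrix rows must sum to 1")
        if np.any(self.sds <= 0):
            raise ValueError("emission standard deviations must be positive")
        if np.any((self.startprob < 0) | (self.startprob > 1)):
            raise ValueError("initial probabilities must lie in [0, 1]")
        if self.means[ACCESSIBLE] < self.means[INACCESSIBLE]:
            raise ValueError("state 1 (accessible) must have the larger emission mean")

    def log_emission(self, values: np.ndarray) -> np.ndarray:
        """(n, 2) matrix of per-state Gaussian log densities."""
        v = np.asarray(values, dtype=float)[:, None]
        return (
            -0.5 * ((v - self.means[None, :]) / self.sds[None, :]) ** 2
            - np.log(self.sds[None, :])
            - 0.5 * np.log(2 * np.pi)
        )

    def to_dict(self) -> dict:
        return {
            "startprob": self.startprob.tolist(),
            "transmat": self.transmat.tolist(),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "log_likelihood": float(self.log_likelihood),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HMMModel":
        return cls(
            np.array(d["startprob"]),
            np.array(d["transmat"]),
            np.array(d["means"]),
            np.array(d["sds"]),
            float(d.get("log_likelihood", float("nan"))),
        )


@dataclass
class StateSegmentation:
    """Per-bin accessible/inaccessible labels plus the derived run list."""

    bin_size: int
    labels: Dict[str, np.ndarray]  # int arrays: 1/0/-1
    runs: List[Tuple[str, int, int, int]] = field(default_factory=list)
    # (chrom, first bin, last bin exclusive, state)

    def __post_init__(self) -> None:
        if not self.runs:
            self.runs = self._derive_runs()

    def _derive_runs(self) -> List[Tuple[str, int, int, int]]:
        runs = []
        for chrom, lab in self.labels.items():
            i = 0
            while i < lab.size:
                if lab[i] == MISSING:
                    i += 1
                    continue
                j = i
                while j < lab.size and lab[j] == lab[i]:
                    j += 1
                runs.append((chrom, i, j, int(lab[i])))
                i = j
        return runs

    def coverage(self) -> Dict[str, float]:
        """Fraction of defined bins per state."""
        total = acc = 0
        for lab in self.labels.values():
            defined = lab != MISSING
            total += int(defined.sum())
            acc += int((lab == ACCESSIBLE).sum())
        if total == 0:
            return {"accessible": float("nan"), "inaccessible": float("nan")}
        return {"accessible": acc / total, "inaccessible": (total - acc) / total}

    def run_lengths(self, state: int | None = None) -> np.ndarray:
        return np.array(
            [j - i for _, i, j, s in self.runs if state is None or s == state], dtype=int
        )

    def to_bed(self, path, track: MACCTrack | None = None) -> None:
        """Write runs as BED; score = mean MACC of the run when a track is given."""
        with open(path, "w") as fh:
            for chrom, i, j, s in self.runs:
                score = 0.0
                if track is not None:
                    vals = track.data[chrom][i:j]
                    vals = vals[np.isfinite(vals)]
                    score = float(vals.mean()) if vals.size else 0.0
                fh.write(
                    f"{chrom}\t{i * self.bin_size}\t{j * self.bin_size}\t"
                    f"{STATE_NAMES[s]}\t{score:.4g}\t.\n"
                )


def _defined_runs(m: MACCTrack) -> List[Tuple[str, int, int]]:
    """Maximal gap-free runs of defined bins: (chrom, start bin, end bin)."""
    runs = []
    for chrom in m.chroms:
        finite = np.isfinite(m.data[chrom])
        if not finite.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate([[0], finite.view(np.int8), [0]])))
        for s, e in zip(edges[::2], edges[1::2]):
            runs.append((chrom, int(s), int(e)))
    return runs


def fit_two_state_hmm(
    m: MACCTrack,
    n_restarts: int = 10,
    seed: int = 0,
    *,
    min_defined_bins: int = 100,
    n_iter: int = 200,
    tol: float = 1e-6,
) -> HMMModel:
    """Fit the 2-state Gaussian HMM by EM, best of ``n_restarts`` by likelihood.

    The defined-bin runs of all chromosomes are treated as independent
    observation sequences of one genome-wide model.  States are relabelled
    so that "accessible" is the state with the larger emission mean.
    Deterministic for a given seed.
    """
    from hmmlearn.hmm import GaussianHMM

    runs = _defined_runs(m)
    values = np.concatenate([m.data[c][i:j] for c, i, j in runs]) if runs else np.empty(0)
    if values.size < min_defined_bins:
        raise ValueError(f"need >= {min_defined_bins} defined bins to fit the HMM, got {values.size}")
    if np.ptp(values) == 0:
        raise ValueError("degenerate input: all MACC values identical; emissions not identifiable")
    X = values[:, None]
    lengths = [j - i for _, i, j in runs]

    best = None
    failures: list[str] = []
    rng = np.random.default_rng(seed)
    for restart in range(n_restarts):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        model = GaussianHMM(
            n_components=2,
            covariance_type="diag",
            n_iter=n_iter,
            tol=tol,
            random_state=sub_seed,
            min_covar=1e-6,
        )
        try:
            model.fit(X, lengths)
            score = model.score(X, lengths)
        except Exception as exc:  # pragma: no cover - hmmlearn numeric failure
            failures.append(f"restart {restart}: {exc}")
            continue
        if not np.isfinite(score):
            failures.append(f"restart {restart}: non-finite log-likelihood")
            continue
        if best is None or score > best[0]:
            best = (score, model)
    if best is None:
        raise RuntimeError("EM failed in all restarts: " + "; ".join(failures))
    score, model = best
    means = model.means_.ravel()
    sds = np.sqrt(model.covars_.ravel())
    order = np.argsort(means)  # state 0 = lower mean (inaccessible)
    return HMMModel(
        startprob=model.startprob_[order],
        transmat=model.transmat_[np.ix_(order, order)],
        means=means[order],
        sds=sds[order],
        log_likelihood=float(score),
    )


def viterbi_path(model: HMMModel, values: np.ndarray) -> np.ndarray:
    """Most probable state path for one gap-free observation sequence."""
    log_b = model.log_emission(values)
    n = values.size
    with np.errstate(divide="ignore"):
        log_start = np.log(model.startprob)
        log_trans = np.log(model.transmat)
    delta = log_start + log_b[0]
    back = np.zeros((n, 2), dtype=int)
    for t in range(1, n):
        cand = delta[:, None] + log_trans  # (from, to)
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], [0, 1]] + log_b[t]
    path = np.zeros(n, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(n - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


def viterbi_segment(model: HMMModel, m: MACCTrack) -> StateSegmentation:
    """Decode accessibility states; missing bins stay missing and break runs."""
    labels = {c: np.full(v.size, MISSING, dtype=int) for c, v in m.data.items()}
    for chrom, i, j in _defined_runs(m):
        labels[chrom][i:j] = viterbi_path(model, m.data[chrom][i:j])
    return StateSegmentation(m.bin_size, labels)


def shuffle_track(m: MACCTrack, seed: int = 0) -> MACCTrack:
    """Permute defined values uniformly within each chromosome (missing stay put)."""
    rng = np.random.default_rng(seed)
    out = m.copy()
    for chrom in out.chroms:
        v = out.data[chrom]
        idx = np.flatnonzero(np.isfinite(v))
        v[idx] = v[rng.permutation(idx)]
    return out


@dataclass
class SegmentStats:
    coverage: Dict[str, float]
    median_run_length: Dict[str, float]  # bins, per state
    run_lengths: Dict[str, np.ndarray]
    shuffled_median_run_length: Dict[str, float] | None = None

    def summary(self) -> str:
        lines = [
            f"accessible coverage: {self.coverage['accessible']:.4f}",
            f"inaccessible coverage: {self.coverage['inaccessible']:.4f}",
        ]
        for state in ("accessible", "inaccessible"):
            line = f"{state} median run length: {self.median_run_length[state]:.1f} bins"
            if self.shuffled_median_run_length is not None:
                line += f" (shuffled: {self.shuffled_median_run_length[state]:.1f})"
            lines.append(line)
        return "\n".join(lines)


def segment_stats(
    seg: StateSegmentation, shuffled_seg: StateSegmentation | None = None
) -> SegmentStats:
    """Per-state coverage and run-length statistics, optionally vs a shuffled null."""
    if not seg.runs:
        raise ValueError("empty segmentation")
    coverage = seg.coverage()
    run_lengths = {
        name: seg.run_lengths(state) for state, name in STATE_NAMES.items() if state != MISSING
    }
    medians = {
        name: float(np.median(v)) if v.size else float("nan") for name, v in run_lengths.items()
    }
    shuffled_medians = None
    if shuffled_seg is not None:
        shuffled_medians = {
            name: float(np.median(shuffled_seg.run_lengths(state)))
            if shuffled_seg.run_lengths(state).size
            else float("nan")
            for state, name in STATE_NAMES.items()
            if state != MISSING
        }
    return SegmentStats(coverage, medians, run_lengths, shuffled_medians)
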