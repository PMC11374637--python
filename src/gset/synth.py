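"""Synthetic spectra and read sets with known ground truth.

Two generators at different levels of realism:

* :func:`simulate_histogram` works directly in spectrum space.  Genomic
  k-mers are split into a homozygous component with Poisson (or negative
  binomial, when overdispersed) depth at coverage C, an optional
  heterozygous component at C/2, and an optional repeat component at 2C.
  Error k-mers are added as a geometrically distributed low-frequency limb
  (success probability 0.7, so most error k-mers are singletons) scaled to
  carry a chosen fraction of all k-mer instances.  In ``expected`` mode the
  exact expected per-frequency counts are emitted — deterministic,
  seed-free, and convenient as a noise-free oracle.

* :func:`simulate_reads` is mechanistic: it draws a uniform-random genome,
  tiles it with reads at uniform random start positions, and applies
  independent per-base substitution errors.  The error limb of the resulting
  spectrum then arises from actual erroneous windows rather than from a
  parametric stand-in.  Note the edge effect: a read of length rl yields
  rl - k + 1 windows, so the mean k-mer depth is C * (rl - k + 1) / rl for
  read coverage C, before any loss to errors.

All randomness flows from a single explicit seed; no global state is used.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .histio import KmerHistogram, ReadSet

__all__ = [
    "TruthRecord",
    "simulate_histogram",
    "simulate_reads",
    "expected_kmer_coverage",
]

#: geometric success probability of the error limb: mean error-k-mer
#: frequency 1/0.7 ≈ 1.43, i.e. roughly 70% of error k-mers are singletons
ERROR_LIMB_GEOM_P = 0.7

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth of a simulation, serialised next to its outputs.

    ``coverage`` is the mean k-mer depth for spectrum-space simulation and
    the read (base) coverage for read simulation; ``error_instance_weight``
    is the fraction of all k-mer instances sitting in the error limb (only
    meaningful for spectrum-space simulation — in read simulation the limb
    emerges from ``per_base_error_rate``).
    """

    true_genome_size: int
    coverage: float
    error_instance_weight: float = 0.0
    het_weight: float = 0.0
    repeat_weight: float = 0.0
    dispersion: float = 0.0
    seed: int | None = None
    mode: str = "sampled"
    read_length: int | None = None
    per_base_error_rate: float | None = None

    def __post_init__(self) -> None:
        if self.true_genome_size < 1:
            raise ValueError("genome size must be >= 1")
        for name in ("error_instance_weight", "het_weight", "repeat_weight"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if self.het_weight + self.repeat_weight >= 1.0:
            raise ValueError("het_weight + repeat_weight must be < 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.mode not in ("sampled", "expected"):
            raise ValueError(f"mode must be 'sampled' or 'expected', got {self.mode!r}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def _depth_dist(mean: float, dispersion: float):
    """Poisson(mean), or negative binomial with Var = mean + dispersion*mean^2."""
    if dispersion == 0.0:
        return stats.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return stats.nbinom(r, p)


def _sample_depths(rng: np.random.Generator, mean: float, dispersion: float,
                   n: int) -> np.ndarray:
    if dispersion == 0.0:
        return rng.poisson(mean, size=n)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=n)


def simulate_histogram(truth: TruthRecord, k: int | None = 21) -> KmerHistogram:
    """Generate a unique-k-mer spectrum directly from component parameters.

    Components (G = ``true_genome_size`` distinct genomic k-mers):

    * homozygous: ``(1 - het - repeat) * G`` k-mers at depth ~ C,
    * heterozygous: ``het * G`` k-mers at depth ~ C/2,
    * repeat: ``repeat * G`` k-mers at depth ~ 2C,
    * error limb: geometric frequencies, scaled so the limb carries
      ``error_instance_weight`` of all k-mer instances.

    Zero-depth draws are discarded (an unobserved k-mer leaves no trace in a
    spectrum).  ``expected`` mode emits the rounded expected count per
    frequency instead of sampling and ignores the seed entirely.
    """
    C = truth.coverage
    if C < 4:
        raise ValueError(
            f"coverage {C} < 4: error limb and homozygous peak would be "
            "unresolvable"
        )
    G = truth.true_genome_size
    comp = [
        (round((1.0 - truth.het_weight - truth.repeat_weight) * G), C),
        (round(truth.het_weight * G), C / 2.0),
        (round(truth.repeat_weight * G), 2.0 * C),
    ]
    w = truth.error_instance_weight

    counts: dict[int, int] = {}

    def _add(x: int, y: int) -> None:
        if y > 0:
            counts[x] = counts.get(x, 0) + y

    if truth.mode == "expected":
        genomic_instances = sum(n * mu for n, mu in comp)
        for n, mu in comp:
            if n == 0:
                continue
            dist = _depth_dist(mu, truth.dispersion)
            xmax = int(math.ceil(mu + 10.0 * math.sqrt(dist.var()))) + 1
            xs = np.arange(1, xmax + 1)
            ys = np.rint(n * dist.pmf(xs)).astype(np.int64)
            for x, y in zip(xs, ys):
                _add(int(x), int(y))
        if w > 0.0:
            err_instances = w / (1.0 - w) * genomic_instances
            n_err = err_instances * ERROR_LIMB_GEOM_P
            geom = stats.geom(ERROR_LIMB_GEOM_P)
            x = 1
            while True:
                y = int(round(n_err * geom.pmf(x)))
                if y == 0 and x > 1:
                    break
                _add(x, y)
                x += 1
    else:
        rng = np.random.default_rng(truth.seed)
        genomic_instances = 0
        for n, mu in comp:
            if n == 0:
                continue
            depths = _sample_depths(rng, mu, truth.dispersion, n)
            depths = depths[depths > 0]
            genomic_instances += int(depths.sum())
            binned = np.bincount(depths)
            for x in np.nonzero(binned)[0]:
                _add(int(x), int(binned[x]))
        if w > 0.0:
            err_instances = w / (1.0 - w) * genomic_instances
            n_err = int(round(err_instances * ERROR_LIMB_GEOM_P))
            freqs = rng.geometric(ERROR_LIMB_GEOM_P, size=n_err)
            binned = np.bincount(freqs)
            for x in np.nonzero(binned)[0]:
                _add(int(x), int(binned[x]))

    entries = tuple(sorted(counts.items()))
    if not entries:
        raise ValueError("simulation produced an empty spectrum")
    return KmerHistogram(entries=entries, k=k)


def expected_kmer_coverage(coverage: float, read_length: int, k: int) -> float:
    """Mean k-mer depth implied by read coverage: C * (rl - k + 1) / rl."""
    if not (1 <= k <= read_length):
        raise ValueError("need 1 <= k <= read_length")
    return coverage * (read_length - k + 1) / read_length


def simulate_reads(genome_size: int, read_length: int, coverage: float,
                   error_rate: float, seed: int | None = None,
                   fmt: str = "fasta") -> tuple[ReadSet, TruthRecord]:
    """Simulate single-end reads from a uniform-random genome.

    Draws a random A/C/G/T genome of ``genome_size`` bp, emits
    ``ceil(genome_size * coverage / read_length)`` reads at uniform random
    start positions, and substitutes each base independently with probability
    ``error_rate`` (always to a different base).  Deterministic for a given
    seed.
    """
    if read_length > genome_size:
        raise ValueError("read length exceeds genome size")
    if read_length < 1:
        raise ValueError("read length must be >= 1")
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    if not (0.0 <= error_rate <= 0.25):
        raise ValueError(f"error rate must be in [0, 0.25], got {error_rate}")

    rng = np.random.default_rng(seed)
    genome = rng.integers(0, 4, size=genome_size, dtype=np.int8)
    n_reads = math.ceil(genome_size * coverage / read_length)
    starts = rng.integers(0, genome_size - read_length + 1, size=n_reads)

    offsets = np.arange(read_length, dtype=np.int64)
    reads = genome[starts[:, None] + offsets[None, :]]
    if error_rate > 0.0:
        mask = rng.random(size=reads.shape) < error_rate
        # shift by 1..3 mod 4: guaranteed substitution to a different base
        shifts = rng.integers(1, 4, size=int(mask.sum()), dtype=np.int8)
        flat = reads.reshape(-1)
        idx = np.nonzero(mask.reshape(-1))[0]
        flat[idx] = (flat[idx] + shifts) % 4
        reads = flat.reshape(reads.shape)

    ascii_reads = _BASES[reads]
    records = tuple(
        (f"read_{i}", ascii_reads[i].tobytes().decode("ascii"))
        for i in range(n_reads)
    )
    truth = TruthRecord(
        true_genome_size=genome_size,
        coverage=coverage,
        seed=seed,
        mode="sampled",
        read_length=read_length,
        per_base_error_rate=error_rate,
    )
    return ReadSet(records=records, source_format=fmt), truth
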