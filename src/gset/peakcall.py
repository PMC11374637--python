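"""Peak and valley calling on unique-k-mer spectra.

A usable spectrum has three regions: a steeply decaying low-frequency limb of
error k-mers, a valley, and a homozygous coverage peak (optionally followed by
a repeat tail, and preceded by a heterozygous peak near half coverage in
diploid heterozygous samples).  The genome-size correction needs the
coordinates of the valley V(xv, yv) and the homozygous peak M(xm, ym).

The procedure:

1. Error cutoff ``L``: accumulate the area under the spectrum from the lowest
   frequency upward until the running total reaches the error share
   ``e * S`` of the total area ``S``; the frequency reached is ``L``.  The
   cutoff only needs to land left of the homozygous peak — sequencing errors
   have little effect on where that peak is — so the default area basis is
   the literal area under the plotted unique-k-mer curve (sum of y).  An
   instance-weighted basis (sum of x*y) is available for sensitivity
   analysis.
2. Windowed local maxima: points that are maximal within +/- max(L, 1)
   frequencies of themselves.
3. Homozygous peak M: the highest local maximum right of ``L``.
4. Valley V: the minimum of the spectrum between the cutoff and the peak.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .histio import KmerHistogram

logger = logging.getLogger(__name__)

__all__ = [
    "CutoffResult",
    "PeakCall",
    "total_instances",
    "curve_area",
    "error_cutoff",
    "smooth_counts",
    "local_maxima",
    "homozygous_peak",
    "find_valley",
    "call_peaks",
]


@dataclass(frozen=True)
class CutoffResult:
    """Outcome of the error-cutoff accumulation.

    ``S`` is the total area under the spectrum on the chosen basis,
    ``S_prime = error_rate * S`` the share attributed to sequencing error,
    and ``L`` the frequency at which the accumulated area first reaches
    ``S_prime`` (0 when the error rate is 0).
    """

    S: float
    S_prime: float
    L: int
    error_rate: float
    area_basis: str = "distinct"


@dataclass(frozen=True)
class PeakCall:
    """Called landmarks of a spectrum: cutoff, maxima, valley, peak."""

    L: int
    maxima: tuple[tuple[int, int], ...]
    valley: tuple[int, int]
    peak: tuple[int, int]
    cutoff: CutoffResult | None = None
    het_rule_fired: bool = False

    @property
    def xv(self) -> int:
        return self.valley[0]

    @property
    def yv(self) -> int:
        return self.valley[1]

    @property
    def xm(self) -> int:
        return self.peak[0]

    @property
    def ym(self) -> int:
        return self.peak[1]


def total_instances(hist: KmerHistogram) -> int:
    """Total number of k-mer instances, N = sum over entries of x*y."""
    return hist.n_instances


def curve_area(hist: KmerHistogram) -> int:
    """Area under the plotted spectrum: the number of distinct k-mers, sum(y)."""
    return hist.n_distinct


def error_cutoff(hist: KmerHistogram, error_rate: float,
                 area_basis: str = "distinct") -> CutoffResult:
    """Locate the error-cutoff frequency L for a given sequencing error rate.

    With ``area_basis="distinct"`` the area is sum(y); with ``"instances"``
    it is sum(x*y).  ``L`` is the smallest frequency at which the accumulated
    area reaches ``error_rate * S``; an ``error_rate`` of 0 yields ``L = 0``.

    Raises if the error share swallows the whole spectrum (the accumulated
    area would only reach the target at or beyond the maximum frequency),
    which signals an error rate inconsistent with the histogram.
    """
    if not (0.0 <= error_rate < 1.0):
        raise ValueError(f"error rate must be in [0, 1), got {error_rate}")
    if len(hist) == 0:
        raise ValueError("empty histogram")
    if area_basis == "distinct":
        weights = hist.y
    elif area_basis == "instances":
        weights = hist.x * hist.y
    else:
        raise ValueError(f"unknown area basis {area_basis!r}")
    S = float(weights.sum())
    S_prime = error_rate * S
    if error_rate == 0.0:
        return CutoffResult(S=S, S_prime=0.0, L=0,
                            error_rate=0.0, area_basis=area_basis)
    acc = np.cumsum(weights)
    idx = int(np.searchsorted(acc, S_prime, side="left"))
    if idx >= len(hist) - 1:
        raise ValueError(
            "error rate inconsistent with histogram: the error share reaches "
            "the maximum frequency"
        )
    L = int(hist.x[idx])
    if L >= hist.max_frequency:
        raise ValueError(
            "error rate inconsistent with histogram: cutoff at the maximum "
            "frequency"
        )
    return CutoffResult(S=S, S_prime=S_prime, L=L,
                        error_rate=error_rate, area_basis=area_basis)


def smooth_counts(hist: KmerHistogram, width: int = 3) -> KmerHistogram:
    """Moving-average smoothing of the counts (odd ``width``), for noisy
    empirical spectra.  Edge windows are truncated means.  Applied only to
    peak detection, never to the instance total N.
    """
    if width < 1 or width % 2 == 0:
        raise ValueError("smoothing width must be a positive odd integer")
    y = hist.y.astype(float)
    half = width // 2
    out = np.empty_like(y)
    for i in range(len(y)):
        lo, hi = max(0, i - half), min(len(y), i + half + 1)
        out[i] = y[lo:hi].mean()
    entries = tuple(
        (int(x), int(round(v))) for x, v in zip(hist.x, out)
    )
    return KmerHistogram(entries=entries, k=hist.k)


def local_maxima(hist: KmerHistogram, L: int,
                 smooth: bool = False) -> list[tuple[int, int]]:
    """Entries maximal within a frequency window of half-width max(L, 1).

    An entry (xi, yi) is reported when yi >= yj for every entry with
    |xj - xi| <= max(L, 1); frequencies absent from the histogram count as 0.
    Within a tied plateau only the smallest-x member is reported.  The
    half-width floor of 1 keeps the definition meaningful when L = 0.
    """
    if len(hist) == 0:
        raise ValueError("empty histogram")
    if L < 0:
        raise ValueError(f"cutoff must be >= 0, got {L}")
    if smooth:
        hist = smooth_counts(hist)
    w = max(L, 1)
    x, y = hist.x, hist.y
    out: list[tuple[int, int]] = []
    lo = 0
    hi = 0
    n = len(x)
    for i in range(n):
        while lo < n and x[lo] < x[i] - w:
            lo += 1
        while hi < n and x[hi] <= x[i] + w:
            hi += 1
        window = y[lo:hi]
        if int(y[i]) < int(window.max()):
            continue
        # plateau tie: suppress if an equal-height entry sits to the left
        # inside the window
        left = y[lo:i]
        if left.size and int(left.max()) >= int(y[i]):
            continue
        out.append((int(x[i]), int(y[i])))
    return out


def homozygous_peak(maxima: list[tuple[int, int]], L: int) -> tuple[int, int]:
    """The highest local maximum strictly right of the cutoff.

    Ties on height resolve toward smaller frequency.  No candidate right of
    ``L`` signals a bad k, a bad error rate, or insufficient coverage.
    """
    if not maxima:
        raise ValueError("no local maxima supplied")
    candidates = [(x, y) for x, y in maxima if x > L]
    if not candidates:
        raise ValueError("no homozygous peak right of cutoff")
    best_y = max(y for _, y in candidates)
    return min((x, y) for x, y in candidates if y == best_y)


def find_valley(hist: KmerHistogram, L: int, xm: int) -> tuple[int, int]:
    """Minimum of the spectrum between the cutoff and the homozygous peak.

    Searches frequencies ``max(L, 1) <= x < xm`` among recorded entries; ties
    resolve toward smaller x.  If the peak sits at the left edge (no entry in
    range), returns ``(max(L, 1), y)`` at that frequency with a warning.
    """
    if xm <= L:
        raise ValueError(f"peak position {xm} must lie right of cutoff {L}")
    if all(x != xm for x, _ in hist.entries):
        raise ValueError(f"peak position {xm} not present in histogram")
    lo = max(L, 1)
    in_range = [(int(x), int(y)) for x, y in hist.entries if lo <= x < xm]
    if not in_range:
        logger.warning(
            "no spectrum entries between cutoff %d and peak %d; "
            "valley defaults to the cutoff edge", L, xm,
        )
        return (lo, hist.y_at(lo))
    best_y = min(y for _, y in in_range)
    return min((x, y) for x, y in in_range if y == best_y)


def call_peaks(hist: KmerHistogram, error_rate: float = 0.01,
               het_mode: bool = False, area_basis: str = "distinct",
               smooth: bool = False) -> PeakCall:
    """Full landmark calling: cutoff -> local maxima -> peak -> valley.

    With ``het_mode`` on, a heterozygous-peak disambiguation rule runs before
    the valley search: among the maxima right of the cutoff, if the two
    highest candidates sit near a 1:2 frequency ratio (the higher frequency
    within [1.7, 2.3] times the lower), the right-hand one is taken as the
    homozygous peak regardless of relative height — allele-specific k-mers
    of a heterozygous diploid pile up near half coverage and can outnumber
    the homozygous peak.  The rule firing is logged prominently.
    """
    cutoff = error_cutoff(hist, error_rate, area_basis=area_basis)
    maxima = local_maxima(hist, cutoff.L, smooth=smooth)
    het_fired = False
    peak: tuple[int, int] | None = None
    if het_mode:
        candidates = [(x, y) for x, y in maxima if x > cutoff.L]
        if len(candidates) >= 2:
            # two highest by height, ties toward smaller x, then order by x
            top2 = sorted(candidates, key=lambda p: (-p[1], p[0]))[:2]
            (p1x, p1y), (p2x, p2y) = sorted(top2)
            if 1.7 * p1x <= p2x <= 2.3 * p1x:
                peak = (p2x, p2y)
                het_fired = True
                logger.warning(
                    "heterozygous-peak heuristic fired: selected peak at "
                    "x=%d over the candidate at x=%d (near half coverage)",
                    p2x, p1x,
                )
    if peak is None:
        peak = homozygous_peak(maxima, cutoff.L)
    valley = find_valley(hist, cutoff.L, peak[0])
    return PeakCall(L=cutoff.L, maxima=tuple(maxima), valley=valley,
                    peak=peak, cutoff=cutoff, het_rule_fired=het_fired)
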