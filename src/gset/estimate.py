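"""Genome-size estimation from the unique-k-mer spectrum.

The native model treats the read set as C-fold uniform coverage of a genome
of size G: with N the total number of k-mer instances and C the k-mer
coverage (identified with the homozygous peak position xm),

    G ≈ N / C.

Because N includes error k-mers, the native estimate runs systematically
large on real data.  The corrected model shrinks it by an empirical factor
built from the valley position xv and peak position xm of the spectrum,

    alpha = xm^2 / (xv^2 + xm^2),        G = alpha * N / xm,

so a spectrum with a negligible error limb (valley at the far left, xv << xm)
is barely corrected, while a heavy error limb pushing the valley toward the
peak shrinks the estimate substantially.  The correction reads the spectrum
directly — no distribution is fitted to it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .histio import KmerHistogram
from .peakcall import PeakCall, call_peaks, total_instances

__all__ = [
    "EstimateResult",
    "native_size",
    "correction_factor",
    "gset_size",
    "choose_k",
    "accuracy_metric",
]

#: k-mer length used by default when no approximate genome size is available
#: to derive one; a distinct valley and homozygous peak in the spectrum are
#: the visual check that the choice is adequate.
DEFAULT_K = 21

TSV_COLUMNS = ("input", "k", "e", "N", "L", "xv", "yv", "xm", "ym",
               "alpha", "G_native", "G_gset")


@dataclass(frozen=True)
class EstimateResult:
    """A genome-size estimate with its full provenance.

    ``G_gset = alpha * G_native`` up to integer rounding, with
    ``alpha = xm^2/(xv^2+xm^2)`` taken from the embedded peak call; since
    ``0 < alpha <= 1``, the corrected estimate never exceeds the native one.
    """

    N: int
    C: int
    alpha: float
    G_native: int
    G_gset: int
    k: int | None
    peakcall: PeakCall
    error_rate: float
    source: str | None = None

    def to_dict(self) -> dict:
        return {
            "input": self.source,
            "k": self.k,
            "e": self.error_rate,
            "N": self.N,
            "C": self.C,
            "L": self.peakcall.L,
            "xv": self.peakcall.xv,
            "yv": self.peakcall.yv,
            "xm": self.peakcall.xm,
            "ym": self.peakcall.ym,
            "alpha": self.alpha,
            "G_native": self.G_native,
            "G_gset": self.G_gset,
            "het_rule_fired": self.peakcall.het_rule_fired,
        }

    def to_tsv_row(self) -> str:
        d = self.to_dict()
        return "\t".join(str(d[c]) for c in TSV_COLUMNS)


def _round_half_up(value: float) -> int:
    return int(Decimal(value).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def native_size(N: float, C: float) -> int:
    """Native genome-size estimate G = N/C, rounded to the nearest base pair."""
    if C < 1:
        raise ValueError(f"coverage must be >= 1, got {C}")
    if N < 0:
        raise ValueError(f"instance total must be >= 0, got {N}")
    return _round_half_up(N / C)


def correction_factor(xv: float, xm: float) -> float:
    """Shrinkage factor alpha = xm^2 / (xv^2 + xm^2), in (0, 1].

    The square of the valley-to-peak frequency ratio tracks the share of
    erroneous k-mer instances in the total; a valley at frequency 0 means no
    correction (alpha = 1) and a valley level with the peak halves the
    estimate.  A valley right of the peak signals an upstream peak-calling
    failure and is rejected.
    """
    if xm < 1:
        raise ValueError(f"peak frequency must be >= 1, got {xm}")
    if xv < 0:
        raise ValueError(f"valley frequency must be >= 0, got {xv}")
    if xv > xm:
        raise ValueError(
            f"valley frequency {xv} right of peak frequency {xm}: "
            "peak calling failed upstream"
        )
    return xm * xm / (xv * xv + xm * xm)


def gset_size(hist: KmerHistogram, error_rate: float = 0.01,
              het_mode: bool = False, area_basis: str = "distinct",
              smooth: bool = False, source: str | None = None) -> EstimateResult:
    """Corrected genome-size estimate G = xm * N / (xv^2 + xm^2).

    Runs the full landmark-calling procedure (error cutoff, windowed local
    maxima, homozygous peak, valley) and applies the correction factor to
    the native estimate N/xm.  Internal arithmetic is double precision;
    genome sizes are rounded to integer base pairs only at the reporting
    boundary.
    """
    call = call_peaks(hist, error_rate=error_rate, het_mode=het_mode,
                      area_basis=area_basis, smooth=smooth)
    N = total_instances(hist)
    xv, xm = call.xv, call.xm
    alpha = correction_factor(xv, xm)
    g_native = native_size(N, xm)
    g_gset = _round_half_up(xm * N / (xv * xv + xm * xm))
    return EstimateResult(N=N, C=xm, alpha=alpha, G_native=g_native,
                          G_gset=g_gset, k=hist.k, peakcall=call,
                          error_rate=error_rate, source=source)


def choose_k(G_approx: float) -> int:
    """k-mer length from an approximate genome size: k = ceil(log4(G) + 1).

    A genome of size G needs k large enough that the 4^k k-mer space
    comfortably exceeds G, keeping chance k-mer collisions rare.  Exact
    powers of 4 are detected explicitly so that floating-point log noise
    cannot push the ceiling up by one.
    """
    if G_approx < 1:
        raise ValueError(f"genome size must be >= 1, got {G_approx}")
    if float(G_approx).is_integer():
        g_int = int(G_approx)
        m = round(math.log(g_int, 4))
        if m >= 0 and 4 ** m == g_int:
            return m + 1
    return math.ceil(math.log(G_approx, 4) + 1)


def accuracy_metric(ref_len: float, est_len: float,
                    rounded: bool = False) -> float:
    """Relative estimation error |ref - est| / ref (lower is better).

    With ``rounded=True`` the value is rounded half away from zero to three
    decimals, the convention used in reports; the unrounded value is what
    JSON output carries.
    """
    if ref_len < 1:
        raise ValueError(f"reference length must be >= 1, got {ref_len}")
    value = abs(ref_len - est_len) / ref_len
    if rounded:
        return float(Decimal(value).quantize(Decimal("0.001"),
                                             rounding=ROUND_HALF_UP))
    return value
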