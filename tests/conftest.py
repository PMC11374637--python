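import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp_oracle(seq: str) -> str:
    """Independent reverse complement used to cross-check canonicalisation."""
    return seq.translate(_COMP)[::-1]


def naive_kmer_spectrum(seqs, k, canonical=True):
    """Occurrence-dictionary k-mer spectrum, the brute-force oracle."""
    from collections import Counter

    occ = Counter()
    for seq in seqs:
        for i in range(len(seq) - k + 1):
            km = seq[i:i + k]
            if set(km) <= set("ACGT"):
                if canonical:
                    km = min(km, revcomp_oracle(km))
                occ[km] += 1
    return tuple(sorted(Counter(occ.values()).items()))


def brute_local_maxima(entries, L):
    """Exhaustive window-scan local maxima with the leftmost-tie rule."""
    w = max(L, 1)
    out = []
    for x, y in entries:
        window = [(xx, yy) for xx, yy in entries if abs(xx - x) <= w]
        if any(yy > y for _, yy in window):
            continue
        if any(yy == y and xx < x for xx, yy in window):
            continue
        out.append((x, y))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20240822)


@pytest.fixture
def random_reads(rng):
    """20 random 50 bp reads over ACGT."""
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return [
        bases[rng.integers(0, 4, size=50)].tobytes().decode()
        for _ in range(20)
    ]
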