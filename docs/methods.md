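# Methods

## The estimation model

A read set counted at k-mer length k yields the unique-k-mer spectrum
{(xᵢ, yᵢ)}: yᵢ distinct k-mers observed exactly xᵢ times. Under the ideal
assumptions — a non-repetitive, homozygous genome sampled uniformly at mean
k-mer depth C — the total number of k-mer instances is N = C·(G − k + 1), so
with G ≫ k the native model G ≈ N/C holds, and C is read off the spectrum as
the homozygous-peak position xₘ.

Real spectra violate the ideal assumptions in a characteristic way: a
steeply decaying limb of error k-mers at low frequency, a repeat tail at
multiples of C, and (in heterozygous diploids) a secondary peak near C/2.
The error limb inflates N without contributing genomic sequence, so the
native estimate is biased upward. The corrected model shrinks it by

    α = xₘ² / (xᵥ² + xₘ²),   G = α·N/xₘ,

where (xᵥ, yᵥ) is the valley between the error limb and the peak. The
squared valley-to-peak frequency ratio is an empirical proxy for the
erroneous share of k-mer instances: a spectrum whose valley hugs the left
edge (thin error limb) is barely corrected (α → 1), while a valley level
with the peak halves the estimate (α = 1/2). No distribution is fitted to
the spectrum at any point; the correction is read directly off its
landmarks, which is the deliberate design contrast with mixture-fitting
estimators (skew-normal or negative-binomial approaches). Those remain the
right tool when per-component decompositions (heterozygosity rate, repeat
fraction) are wanted; this package intentionally does not provide them.

## Landmark calling

1. **Error cutoff L.** Given a sequencing error rate e (default 0.01,
   inside the 0.5–2.5% range typical of Illumina chemistry), the error
   share of the area under the spectrum is S′ = e·S. Accumulating the area
   from the lowest frequency upward, L is the first frequency at which the
   running total reaches S′; e = 0 gives L = 0. "Area" is ambiguous between
   the plotted curve (Σyᵢ, distinct k-mers) and the instance-weighted mass
   (Σxᵢyᵢ); the default is Σyᵢ, because the cutoff only has to land left of
   the homozygous peak — errors barely move that peak — and the literal
   curve area is the quantity the accumulation description refers to. The
   instance basis is available (`area_basis="instances"`) for sensitivity
   analysis; the default is deliberately not data-dependent.
2. **Local maxima.** Points maximal within ± max(L, 1) frequencies; the
   floor of 1 keeps the definition non-degenerate at L = 0 (a window of
   ±2·0 would make every point a maximum). Missing frequencies count as
   zero; within a tied plateau only the leftmost point is reported.
3. **Homozygous peak M.** The highest maximum strictly right of L, ties
   toward smaller frequency (the conservative, reproducible choice). With
   `het_mode` on, a disambiguation rule runs first: if the two highest
   maxima right of L sit near a 1:2 frequency ratio (higher ∈ [1.7, 2.3] ×
   lower), the right-hand one is taken regardless of height, since
   allele-specific k-mers of a heterozygous sample pile up near half
   coverage and can outgrow the homozygous peak. The 1.7–2.3 band allows
   roughly ±15% drift of the half-coverage peak from its ideal position
   before the rule declines to fire; the rule is a documented heuristic,
   logged prominently whenever it decides the call.
4. **Valley V.** The minimum of the spectrum on max(L, 1) ≤ x < xₘ, ties
   toward smaller x. If the range is empty (peak at the left edge) the
   valley defaults to the cutoff edge with y = 0 and a warning; α is then
   xₘ²/(1 + xₘ²), indistinguishable from 1 after rounding for any realistic
   peak position.

An optional width-3 moving-average smoother can be applied to the spectrum
seen by the maxima scan (never to N) for noisy empirical histograms; it is
off by default.

## k selection

With an approximate genome size G available, k = ⌈log₄ G + 1⌉ makes the
k-mer space 4ᵏ comfortably larger than the genome, keeping chance k-mer
collisions rare. Exact powers of four are detected in integer arithmetic so
floating-point log noise cannot push the ceiling up by one. Without any
size prior the default is k = 21, with the usual visual check: a usable
spectrum shows a distinct valley and homozygous peak; if the two are of
comparable height the chosen k is inadequate.

## k-mer counting

The built-in counter is exact and in-memory: reads are concatenated with
sentinel separators, bases 2-bit-encoded, windows packed into 64-bit
integers (k ≤ 31), canonicalised against the reverse complement by taking
the smaller code, and counted via a sort. Windows containing any non-ACGT
character are skipped whole rather than error-corrected — the simplest
defensible convention — and FASTQ qualities are ignored, since the model
uses sequence content only. Canonical (strand-collapsed) counting is the
default, matching Jellyfish/KMC conventions; descriptions of the
method do not state strandedness, so a flag disables it. The counter
targets desk-scale inputs (≲ 100 Mbp of reads, a few hundred MB of working
memory); larger datasets should arrive as precomputed two-column
histograms, which the reader ingests unchanged.

## Synthetic data

Two generators provide ground-truthed inputs at different levels of
realism.

**Spectrum-space** (`simulate_histogram`): G distinct genomic k-mers are
split into a homozygous component at depth C, an optional heterozygous
component at C/2 and a repeat component at 2C, with Poisson depths (or
negative binomial with Var = μ + d·μ² when overdispersion d > 0). The error
limb is modelled directly as geometric frequencies (success probability
0.7, so ~70% of error k-mers are singletons and the limb's mean frequency
is 1/0.7 ≈ 1.43), scaled so it carries a chosen fraction of all instances.
Coverage below 4 is rejected as unresolvable. In `expected` mode the
rounded expected count per frequency is emitted — deterministic and
seed-free — which is the noise-free oracle used throughout the tests. One
numerical quirk to know: Poisson(C) with integer C is bimodal at {C−1, C},
and with rounded expected counts the smaller-x tie rule then calls the peak
at C−1.

**Read-space** (`simulate_reads`): a uniform-random A/C/G/T genome,
⌈G·cov/rl⌉ reads at uniform random starts, independent per-base
substitutions (always to a different base) at a given rate. The error limb
then arises mechanistically from erroneous windows. The edge effect matters
when comparing the two: read coverage cov implies mean k-mer depth
cov·(rl − k + 1)/rl. All randomness flows from one explicit seed; expected
mode ignores the seed entirely.

What the generators do **not** emulate: indels, quality profiles, GC and
coverage bias, paired-end structure, real repeat families, and the
correlated error structure of real instruments. Passing tests on synthetic
data therefore demonstrate correctness of the pipeline and recovery under
the stated generative model, not accuracy on any particular real dataset.

## Behaviour across error regimes

The correction is empirical, calibrated on real datasets where the error
limb is broad enough to push the valley a substantial fraction of the way
toward the peak. With independent per-base substitutions the limb is thin:
an individual error k-mer recurs with rate ≈ C·e/3, so the limb decays by
frequency ~5 and the valley sits low. At a 0.1% substitution rate the
corrected estimate recovers a 2 Mb genome within a few percent (the
low-error regime test). At a 1% substitution rate and k = 17, however,
1 − 0.99¹⁷ ≈ 16% of instances are erroneous: the observed peak drops to
C·(1−e)ᵏ while N keeps every instance, the native estimate overshoots by
≈ 1/(1−e)ᵏ ≈ 19%, and the valley-based α ≈ 0.95 recovers only part of
that. The corrected estimate remains strictly more accurate than the native
one in this regime, but its mean relative error (~0.14 over five seeds of
the 2 Mb study) exceeds the 5% the method achieves in low-error settings —
a real limitation of landmark-based correction under heavy uniform error,
and the reason the five-seed simulated study in the acceptance script
reports both estimates side by side.

## Numerical choices and problem sizes

Genome sizes are computed in double precision and rounded half-away-from-
zero to integer base pairs only at the reporting boundary; the relative-
error metric |ref − est|/ref is reported rounded to three decimals (the
unrounded value accompanies it in JSON). All tie-breaks (peak, valley,
plateau) resolve toward smaller frequency. The simulated-read studies in
the tests and the acceptance script use a 2 Mb genome at 30× coverage with
125 bp reads and five seeds, and a 0.5 Mb genome for the low-error
regression — sizes chosen so the whole pipeline, including exact k-mer
counting, completes on a single CPU in minutes while keeping the spectrum's
sampling noise far below the effects being measured.
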