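# gset — genome size estimation from k-mer spectra

`gset` estimates the size of a genome from the unique-k-mer frequency
spectrum of a short-read dataset. It is aimed at anyone who needs a quick,
assembly-free genome-size figure from raw Illumina-style reads — for survey
sequencing, for sizing an assembly job, or for sanity-checking a flow-cytometry
value — using either a precomputed histogram (Jellyfish/KMC two-column
format) or, for desk-scale inputs, the built-in k-mer counter.

## The model

For a read set counted at k-mer length *k*, let *N* = Σᵢ xᵢ·yᵢ be the total
number of k-mer instances (frequency xᵢ, yᵢ distinct k-mers at that
frequency) and *C* the k-mer coverage, identified with the position *x*ₘ of
the spectrum's homozygous peak M(*x*ₘ, *y*ₘ). The native model is

    G ≈ N / C.

Sequencing errors inflate *N* with low-frequency k-mers, so the native
estimate runs systematically large. Instead of fitting a parametric mixture
to the spectrum, `gset` applies a correction factor built directly from the
spectrum's landmarks — the valley V(*x*ᵥ, *y*ᵥ) between the error limb and
the peak:

    α = xₘ² / (xᵥ² + xₘ²),        G = α · N / xₘ = xₘ · Σᵢ xᵢ·yᵢ / (xᵥ² + xₘ²).

The landmarks are found by (1) an error cutoff L — the frequency at which
the accumulated area under the spectrum reaches the error-rate share *e*·S
of the total area S; (2) local maxima within a ±max(L, 1) frequency window;
(3) the homozygous peak = the highest maximum right of L (with an optional
heterozygous-mode rule that prefers a candidate near twice the frequency of
the largest maximum); and (4) the valley = the spectrum minimum between the
cutoff and the peak. When only an approximate genome size G is known,
k = ⌈log₄ G + 1⌉ is a good k-mer length; k = 21 is the default.

## Worked example

Simulate a 2 Mb genome at 30× k-mer depth with 5% of k-mer instances in the
error limb, then estimate its size from the spectrum alone:

```bash
gset simulate --genome-size 2000000 --coverage 30 --error-rate 0.05 \
     --spectrum-only --expected --out-prefix demo
gset estimate demo.histo -k 21 --ref-len 2000000
```

which prints (abridged):

```json
{
  "N": 63157888,
  "L": 1,
  "xv": 10,
  "xm": 29,
  "alpha": 0.8937300743889479,
  "G_native": 2177858,
  "G_gset": 1946417,
  "accuracy": 0.027,
  "accuracy_native": 0.089
}
```

Read: the spectrum carries N ≈ 63.2 M k-mer instances; the homozygous peak
sits at frequency 29 and the valley at 10, giving α ≈ 0.894. The native
estimate N/xₘ ≈ 2.18 Mb overshoots the true 2 Mb by 8.9%; the corrected
estimate 1.95 Mb is within 2.7%. The same workflow runs from reads
(`gset hist reads.fastq.gz -k 21 -o reads.histo`, or `gset estimate
reads.fastq -k 17`), and `--plot spectrum.png` renders the spectrum with L,
V and M annotated.

## Library use

```python
from gset import simulate_reads, count_kmers, gset_size

reads, truth = simulate_reads(500_000, 125, 30.0, 0.001, seed=42)
result = gset_size(count_kmers(reads, k=17))
print(result.G_gset, result.alpha)
```

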