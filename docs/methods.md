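# Methods

This note documents the models, algorithms and design choices behind
`amplimeth`, in the spirit of the methods documentation of packages such as
msprime or statsmodels: what is computed, under which assumptions, and what
the synthetic validation does and does not establish.

## Read model and simulator

A multiplexed bisulfite amplicon read is modelled as

```
read = tag + bisulfite_converted(amplicon, pattern) + sequencing errors
```

where `tag` is a 9–10 nt sample identifier (MID) and the amplicon begins
with the locus-specific forward primer. The simulator operates on the
forward strand only; reverse-complement reads are not generated by default
(the demultiplexer has an optional reverse-complement scan for data that
need it).

**Reference amplicons** (`build_locus`) are random A/C/G/T sequences of
100–350 bp with a declared primer extent and a declared, ordered set of CpG
sites. Two deliberate constraints make downstream semantics unambiguous:

* No stray CpG dinucleotides occur outside the declared sites. During
  sequential base sampling a G is never placed directly after a C; the
  blocked G probability mass is redirected to C so the marginal G+C
  fraction still equals the requested `gc_fraction`. Consequently every
  non-site cytosine is a CpH (C followed by A, C or T), and scanning a
  reference for `CG` recovers exactly the declared sites.
* At least one homopolymer run of length ≥ 4 is guaranteed (an `AAAA`
  patch is inserted if none arose), so homopolymer error handling is always
  exercised. An A-run is used because it survives bisulfite conversion
  unchanged.

**Epiallele mixture** (`EpiallelePatternModel`). A molecule is fully
methylated with probability `p_full`, fully unmethylated with `p_none`, and
otherwise draws each CpG independently as Bernoulli(`site_probs[i]`). This
three-component mixture spans the empirically observed spectrum from
dichotomous (all-or-nothing) to heterogeneous methylation patterns. The
probability of an all-ones row is analytically
`p_full + (1 − p_full − p_none)·∏ site_probs[i]`, which the tests use as an
exact oracle.

**Chemistry and sequencing errors** (`ErrorModel`):

| parameter | meaning | default |
|---|---|---|
| `conversion_failure_rate` | unmethylated C survives conversion (per C) | 0.005 |
| `substitution_rate` | per-base miscall | 0.002 |
| `hp_indel_base_rate` | homopolymer run of length L gets an indel with probability min(1, rate·(L−1)) | 0.01 |
| `deletion_bias` | fraction of homopolymer indels that are deletions | 0.8 |

The defaults reproduce the qualitative error spectrum of 454-era amplicon
data — deletion-dominated homopolymer errors plus occasional partial
conversion — at an overall per-base accuracy near 99.6%. Homopolymer runs
are identified on the converted molecule *before* substitutions are
applied, since flow-space length miscalls arise from the template, not from
individual miscalled bases. Reads span the full amplicon; a separate
read-length model is omitted because the QC filters act on identity and
conversion, not on length.

**Bulk pyrosequencing** is simulated as the realised true per-CpG level
plus Gaussian noise (default SD 3 percentage points, inside the 2–10 point
technical variability typical of the bulk assay), clipped to [0, 100].

**Ground truth.** Every simulated molecule's pattern is recorded; true
per-CpG levels are the realised column means of the pattern matrix
(computed as `100·k/n` in the same operation order as the quantifier, so
error-free recovery is bitwise exact). The truth tables are what recovery
tests compare against — not the mixture parameters, which the finite sample
only approximates.

What the simulator does *not* emulate: flowgram signal processing and
quality scores, emulsion-PCR amplification bias beyond a per-bin read-count
parameter, chimeric reads, or reverse-strand reads. Passing recovery tests
therefore demonstrates correctness of the analysis logic under the stated
error model, not robustness to every artefact of real 454 data.

## Demultiplexing

Tag matching is exact: tags are short, and the packaged set of ten (mixed
9/10 nt) has pairwise Hamming distance ≥ 4 on the common prefix, so a
single sequencing error cannot convert one tag into another. Primer
matching tolerates ≤ 2 mismatches by default (configurable), with no
indels. A read matching more than one record is discarded as `ambiguous`;
other failure reasons are `empty`, `no_tag`, `too_short` and
`primer_mismatch`. Reads are matched independently, so demultiplexing is
order-independent by construction. Funnel counts are reported with
percentages truncated at one decimal (see *Reporting conventions*).

## Bisulfite-aware alignment

The reference is converted in silico assuming the fully unmethylated state,
with labelled positions: plain A/G/T, `h` = T derived from a CpH cytosine,
`g` = T derived from the C of a CpG site. The primer region is excluded
from the alignable reference (reads are tag/primer-trimmed and 5′-anchored).

The pairwise aligner is a Needleman–Wunsch dynamic program with affine gap
costs (a gap of length k costs `gap_open + (k−1)·gap_extend`; defaults
match +1, mismatch −1, open −2, extend −1 — the original studies published
no scoring scheme, so these conventional values are the package's own
choice and fully configurable). It is global in the read with free end
gaps on the read's 3′ side only, since reads may stop short of the amplicon
end; leftover reference is clipped, not penalised. The substitution
contract encodes the chemistry:

* read T or C vs `g` → match (the methylation call, read off later);
* read T vs `h` → match; read C vs `h` → match for scoring but counted as
  a conversion failure;
* all other pairings: standard match/mismatch.

Ties break deterministically (diagonal, then read-consuming gap, then
reference-consuming gap; the rightmost optimal end column is chosen), so
alignments are reproducible. The DP kernel is JIT-compiled with numba
(a pure-Python fallback keeps the package importable without it); its
scores are validated against an independent brute-force recursion over all
monotone alignment paths on thousands of small random instances.

From the gapped pair, three pure functions derive the metrics:

* **identity** = 100 · matched / eligible columns. By default, columns at
  `g` positions are excluded (methylation state must not affect identity)
  and read-C-over-`h` counts as matched (conversion failure has its own
  dedicated filter); gap columns are eligible and unmatched. Because the
  exact denominator used by the original web tools is not documented, a
  single switch (`identity_mode="all"`) provides the strict reading in
  which every column counts and unconverted CpH is a mismatch.
* **conversion** = 100 · (`h` columns read as T) / (`h` columns read as C
  or T); gaps and other bases are excluded from both counts. With no
  countable column the efficiency is defined as 100.0 — absence of
  evidence of failure.
* **per-CpG calls**: read C → methylated, read T → unmethylated, anything
  else (gap, foreign base, beyond the read end) → MISSING; every CpG
  ordinal of the locus receives exactly one call.

## QC filtering and quantification

A read passes iff identity ≥ 90% **and** conversion ≥ 100% (thresholds
inclusive, compared before any rounding; both configurable). With the
default 100% conversion threshold, a single unconverted CpH rejects the
read. Per-CpG levels exclude MISSING calls from both numerator and
denominator — a read with a gap at a site carries no information there.
The per-bin mean level is the unweighted mean over CpG sites with coverage
(the natural reading of "mean methylation of a locus"). Bins with fewer
than 10 passing reads (configurable) are flagged low-coverage and excluded
from cross-method statistics; 100–150 reads per amplicon is the
recommended range for stable per-CpG quantification. The rendered
locus × sample overview table rounds to whole percent and prints `N/A` for
low-coverage or absent bins.

A molecule counts as *fully methylated* only if every site is called and
every call is methylated (default `min_called_sites` = all sites); this
deliberately conservative rule prevents short or gapped reads from
inflating the fully-methylated fraction. The mirror rule applies to fully
unmethylated.

## Concordance statistics

* **Bland–Altman**: difference = deep − bulk (convention stated in every
  output header); the default 95% band is the classical limits of
  agreement, mean ± 1.96·SD. Because "95% tolerance interval" is sometimes
  meant strictly, a normal tolerance-interval mode (Howe's k factor,
  95%/95%) is available behind `ba_mode="tolerance"`.
* **Regression** of deep on bulk includes an intercept by default; a
  through-origin mode exists and is recorded in the report. The slope CI
  is the OLS 95% interval (statsmodels).
* **Congruence fractions**: share of pairs with |difference| strictly
  below 2, 5 and 10 percentage points; the 10-point band is the
  conventional acceptability criterion, matching bulk-assay variability.
* **Coverage threshold**: smallest observed coverage c such that every
  pair with coverage ≥ c lies inside the 95% band (band estimated from all
  pairs); reported as undefined when even the deepest bin strays outside.
  Points are per-CpG pairs carrying their bin's read count.
* **Yield correlation**: Pearson r between amplicon length and mean read
  count per amplicon.

No multiple-testing correction is applied: these are descriptive agreement
statistics, not a family of hypothesis tests.

## Reporting conventions

Funnel and congruence percentages are *truncated* (floor) at one decimal,
computed in integer arithmetic — e.g. 720/869 reports as 82.8%, not 82.9%.
Thresholds are always compared on full-precision values before any
rounding. Coordinates are 0-based half-open internally; only human-facing
tables are 1-based. Every output table begins with comment lines carrying
the tool version, a config hash and the master seed; all randomness flows
from that single seed through per-stage derived seeds, making full runs
byte-for-byte reproducible.

## Validation problem sizes

The test suite validates level recovery with 100 replicates of 10 loci
(160 bp, 6 CpGs each) × 300 reads under the default error model, checking
that recovered per-CpG levels fall inside their 95% binomial intervals for
≥ 93% of sites; rare-epiallele detection uses 5000 molecules with a 1.4%
fully methylated spike-in. The rare-epiallele scenario runs with
conversion-failure noise but without homopolymer indels: the
fully-methylated counter requires complete site coverage, so indel-induced
MISSING calls would deterministically remove part of the spike-in from the
numerator — that is a (documented) property of the conservative counting
rule, not of detection sensitivity, which is what the scenario measures.
The acceptance script runs a 12-locus × 10-sample study (~15k reads) with
per-bin read counts drawn from a length-dependent yield model. These sizes
were chosen as the smallest at which the binomial/Monte-Carlo tolerances
are meaningful.

## Known limitations

* Alignment is forward-strand only; directional libraries are assumed.
* The aligner reports a single optimal alignment; near-optimal alternatives
  (e.g. gap placement within a homopolymer run) are resolved by the fixed
  tie-break, not enumerated.
* The simulator's primer region converts like ordinary template; primer
  synthesis is not modelled separately (a conversion failure inside the
  primer can therefore cost a primer mismatch during demultiplexing).
* Levels are raw proportions; no shrinkage, smoothing or differential
  testing between samples is provided.
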