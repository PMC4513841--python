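# Methods

## The culture model behind the fluctuation test

`negselect.simulate` realises a discrete Lea–Coulson-style birth-and-mutation
process.  A culture grows from N₀ to N_t cells by synchronous deterministic
doubling over G = ⌈log₂(N_t/N₀)⌉ generations; generation g contains N₀·2^(g−1)
divisions, and the total number of divisions is d = N_t − N₀.  Mutational
events arise at rate μ per division, so the event count per culture is
Poisson(μ·d) and the probability of a mutant-free culture is exactly
e^(−μ·d) — the identity the null-class estimator inverts.  An event in
generation g founds a clone of 2^(G−g) cells at plating (summed clone sizes
capped at N_t), which produces the characteristic heavy-tailed "jackpot"
mutant-count distribution: early events yield huge clones, and the mean
mutant count exceeds the median in every sizeable batch.

Assumptions, deliberately minimal: no cell death, no mutant fitness cost, no
phenotypic lag, 100% plating efficiency, and a shared deterministic N_t
across wells (a `poisson_titer` option perturbs titer counts as
Poisson(N_t)).  These match the assumptions implicit in the p0 estimator;
continuous-time birth–death dynamics, differential growth and partial
plating are out of scope, so recovery results here say nothing about how the
estimator degrades under those violations in real data.

All randomness flows from a single integer seed through numpy's splittable
`SeedSequence`, one stream per well: runs are reproducible and wells are
statistically independent regardless of how many are drawn.

## Rate estimation (p0 method)

μ̂ = −ln(n_negative/n_total)/d.  Two division conventions exist in the
fluctuation-test literature; the default `per_culture` divides by the
divisions of one culture, since −ln p₀ counts mutation events per culture.
A `summed` convention (divide additionally by n_total) is available behind a
flag and recorded in output metadata, because the phrase "total number of
cell divisions" is genuinely ambiguous in field usage; the per-culture
convention is the one that reproduces the standard estimator's magnitudes.

Confidence intervals put an exact Clopper–Pearson interval on p₀ and map
both ends through −ln(·)/d; the transform is monotone decreasing, so the p₀
limits swap roles.  Exactness matters at 96-well scale, where normal
approximations misbehave near the boundaries.  The boundaries themselves
never return silent infinities: zero negative wells yields a one-sided
*lower* rate bound from the one-sided CP upper limit of p₀ (point = ∞), and
all-negative yields point 0 with a one-sided upper bound.  Divisions per
culture come from titer wells as mean(N_t) − N₀, rounded to an integer.

Design note: d per culture defaults to ~10⁸ (inoculum 100, final 10⁸ per
well).  Per-well final CFU is a free parameter of the generator because
realistic titers vary with media and incubation; it must be supplied (or
simulated) explicitly for parameter recovery to be meaningful.

## Stringency frequencies

CFU/ml from a dilution series uses the pooled ratio estimator
Σ colonies / Σ (volume/dilution) over plates whose counts fall in the
countable range 3–300 inclusive (standard plate-counting practice; the range
is a module constant).  With no countable plate the least-diluted plates are
used and the result flagged low-confidence; an all-zero series returns 0
with the same flag.

Stringency frequency = breakthrough colonies / cells plated.  Zero colonies
is reported as the rule-of-three 95% upper bound 3/n rather than 0 — at the
detection limit the claim is a bound, not a measurement.  Replicates are
aggregated as the geometric mean with the sample SD of log₁₀ values
(frequencies live on a log scale); zero-colony bounds are excluded from
aggregation by construction and must be reported separately.

## Theoretical maximum stringency

The chain multiplies a genomic per-generation mutation-rate interval down to
cassette scale and restricts it to inactivating changes:

| stage | operation | default |
|---|---|---|
| genomic | input | [1×10⁻³, 3.3×10⁻³] /genome/gen |
| per nucleotide | ÷ genome length | 4,641,652 bp (MG1655 chromosome) |
| per cassette | × cassette length | 811 bp |
| inactivating | × fraction interval | [0.05, 0.40] |
| total escape | + large-deletion interval | [1.79×10⁻⁹, 2.5×10⁻⁷] /gen |

Endpoints are rounded to 2 significant figures *at each stage* by default:
published chains of this kind report rounded intermediates, and the printed
low inactivation endpoint (0.9×10⁻⁸ = 1.8×10⁻⁷ × 0.05) only reproduces with
rounded inputs.  Setting `sig_figs` high gives the unrounded chain, which
the tests verify agrees with a single-expression computation to 10⁻¹² relative.
The genome length default is the standard MG1655 chromosome size, consistent
with the printed per-nucleotide quotients.  Interval classification of an
observed rate is boundary-inclusive.  The inactivating-fraction endpoints
are the expected nonsense share (5%) and the dominant-mutation share (40%);
intermediate estimates for strongly deleterious missense changes fall inside
this bracket and are not modelled separately.

## Coverage-based screening

Hits follow the BLAST tabular convention: 1-based inclusive query
coordinates, reverse-orientation rows with qstart > qend (normalised on
parsing), comment lines tolerated.  Gene coverage merges overlapping *and
adjacent* intervals ([a,b] + [b+1,c] → [a,c]) after clipping to the gene,
and a gene is called present at coverage ≥ 0.80 (inclusive; the cutoff is a
parameter).  A property test checks the merge against a per-base boolean
oracle.  Full-length hits with frameshifts still call "present" — coverage
is a DNA-level criterion by design.  Candidate ranking keeps genes absent
from the target strain, computes the absence fraction over a panel, flags
fractions strictly above ½, and sorts by absence fraction, then gene length
(shorter preferred: less PCR), then name.  Reported identity floors from
threshold calibration (>88% DNA / >84% protein) are descriptive, not
enforced filters.  Running an aligner is out of scope; the module consumes
hit tables.

The synthetic hit-table generator emits 1..k HSPs per present pair whose
merged length equals round(coverage × gene length) within ±1 bp, with gaps
≥ 1 bp so fragments never merge.  Quantisation means an intended coverage
within ~2/L of the cutoff can fall on either side; round-trip tests only
assert calls for coverages outside that band.

## Problem sizes and numerical choices

Simulation studies use the experiment's own design: 100 selective + 10–20
titer wells per test; 200 replicates per rate for two-fold recovery
(μ ∈ {10⁻⁹, 10⁻⁸, 10⁻⁷}, μ·d ∈ {0.5, 1, 2}); 1000 replicates for CI
coverage at the canonical μ·d = 1 design (exact CP coverage there is 96.2%,
inside the 93–97% acceptance band; CP is conservative by construction);
10⁴ cultures per null-class check; 1000 random hit sets for the coverage
oracle; 100 assays per frequency for stringency recovery.  These sizes give
binomial/Poisson standard errors comfortably below the tolerances tested
while keeping the full suite under a minute of simulation time.

Ties and degenerate inputs: mean titer is rounded half-to-even by Python's
`round`; d = 0 (no growth) is rejected by the estimator; frequencies of 0
are rejected by the geometric aggregator; `RateInterval` enforces
0 ≤ low ≤ high at construction.

## Known limitations

* The simulator's deterministic synchronous growth understates culture-size
  variance; real titers vary well-to-well, which widens the estimator's
  spread slightly relative to these tests.
* The p0 method discards the information in mutant counts; maximum-likelihood
  (Ma–Sandri–Sarkar) fluctuation estimators are deliberately not implemented.
* The theory chain treats the inactivating fraction as a static interval; no
  mutation-spectrum or context dependence is modelled, and insertion-element
  inactivation is not included in the deletion term.
* Screening is nucleotide-level only; protein-level corroboration (tblastn)
  is considered already embodied in the 80% DNA-coverage cutoff.
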