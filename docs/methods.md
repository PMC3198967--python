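# Methods

## The marker system and its encoding

The male-specific region of the Y chromosome is uniparental and
non-recombining, so the states of all its markers are inherited as a single
haplotype. `ychap` models a five-character composite:

| character | type | states | weight w |
|---|---|---|---|
| SRY-promoter SNP | binary | A (ancestral) / G | 4 |
| SRYM18 internal SNP | binary | A (ancestral) / T | 4 |
| UMN2303 [TTTTG]m | ordered integer | repeat count ≥ 1 | 3 |
| SRYM18 [TTC]m | ordered integer | repeat count ≥ 1 | 2 |
| SRYM18 [T]n | ordered integer | repeat count ≥ 1 | 1 |

Weights are inverse to mutability: mononucleotide arrays mutate fastest,
trinucleotides slower, pentanucleotides about half as fast as
trinucleotides, and the SNPs are effectively unique events. Binary
characters are coded against the ancestral state (A at both SNPs), which is
the state shared with the outgroup taxa.

### Allele sizes and repeat counts

Fragment sizes relate to repeat counts affinely: UMN2303
size = 95 + 5·m (the pentanucleotide repeat count is not directly reported
for this locus, so the offset fixing m ∈ {6, 7} for the observed 125/130 bp
alleles was chosen once for a realistically short array; every downstream
statistic depends only on repeat *differences* and is invariant to this
choice). SRYM18 comes in two structural variants, [TTC]mA[T]n (western) and
[TTC]m[T]n (eastern), calibrated with independent per-structure offsets
(both 87 bp in total once the internal A is absorbed into the western
offset). Because 3·m + n is not injective, SRYM18 is homoplasic: e.g.
111 bp decodes to (m=3, n=15) or (m=4, n=12). Size decoding therefore
requires the sequenced trinucleotide count; the packaged table stores the
decomposition explicitly and the loader validates sizes against it.

## Statistics

**Haplotype diversity** h = 1 − Σ pᵢ² by default; the unbiased
(n/(n−1))-corrected form is available via `unbiased=True`. The plain form
is the default because it is the conventional reporting scale for these
summaries; both retain full precision internally, and rounding to the
2-decimal reporting convention happens only at the reporting layer
(`report`, the acceptance script).

**Dad** is defined as the absolute difference of *group mean* repeat
counts, individual-weighted: Dad = |Σ c_h r_h / n_A − Σ c_h r_h / n_B| per
motif. It is not the mean pairwise |difference| over individuals — the two
definitions disagree whenever within-group variance is nonzero. Its
variance across resampling schemes is not computed: no well-defined target
exists for it, so only point values are exposed. `mean_repeat_distance`
averages the three motif entries.

## The median-joining network

Distances are Σ_c w_c·δ_c with δ_c the 0/1 mismatch for binary characters
and |Δrepeats| for ordered ones — so a single repeat step and a single SNP
cost w_c each, and ordered characters contribute step-wise chains.
Construction:

1. **ε-relaxed minimum spanning network.** A link (u,v) is feasible iff
   d(u,v) ≤ m(u,v) + ε, where m(u,v) is the minimax path distance (largest
   link on the MST path between u and v). At ε = 0 this is exactly the
   union of all minimum spanning trees (cycle property), the sparsest
   network that keeps every co-minimal connection.
2. **Median insertion.** For every path u–v, u–w through a common node,
   the median vector takes the majority state per binary character and the
   integer median per ordered character. Candidates within ε of the
   round's minimal connection cost (λ criterion) are considered in
   deterministic order (cost, then state tuple) and one is added per round
   iff it strictly lowers the MST cost of the node set. Under the default
   integer weights every reduction is ≥ 1, so termination is guaranteed
   without any iteration cap.
3. **Cleanup.** Unsampled nodes of degree < 3 are peeled off iteratively
   and the network rebuilt. An optional `mp_cleanup` pass additionally
   drops medians whose removal does not raise the spanning cost; it is off
   by default since the sparse ε = 0 network is the standard output.

Ties throughout (MST edge order, median insertion order, node labels) are
broken lexicographically, making the construction deterministic but not
necessarily identical, median-for-median, to other implementations whose
internal schedules differ; agreement is asserted at the level of
sampled-node adjacency and cross-haplogroup substitution counts. Haplotypes
identical under the active character scheme are merged into a single node.
Node frequencies are display metadata and never influence the topology.

## Distances and trees

**Pairwise distances** are computed after complete deletion of gap
columns; sites where either sequence of a pair is undetermined (N) are
dropped for that pair only. Jukes–Cantor: d = −¾ ln(1 − 4p/3). Tamura
3-parameter with GC content θ and h = 2θ(1−θ):
d = −h ln(1 − P/h − Q) − ½(1−h) ln(1 − 2Q); the gamma-rates version
replaces −ln(x) by a(x^(−1/a) − 1) with shape a. With θ = ½ the model is
Kimura's two-parameter distance, and the a → ∞ limit recovers the
uncorrected form (both are regression-tested). θ defaults to the G+C
frequency of the alignment when not supplied; the parameter set estimated
for the SRY-promoter alignment (θ = 0.3216, Ts/Tv = 1.6281, a = 0.4762) is
shipped as `SRY_T92G`. Divergences beyond a model's correctable range
raise `SaturationError` rather than returning infinities, so tree building
fails loudly.

**Neighbor joining** uses the rate-corrected Q criterion; ties are broken
by lexicographic pair label (internal clusters carry their smallest leaf
label). Negative branch length estimates are clamped to zero with the
deficit transferred to the sister branch — the usual display convention;
path lengths on additive inputs are still recovered exactly because
clamping never triggers there. Bootstrap supports resample columns of the
gap-stripped alignment with a seeded generator, recompute distances and
the NJ tree per replicate, and map bipartition frequencies onto the
full-data tree; the procedure canonicalizes taxon order first, so supports
are invariant to input order. Saturated replicates are redrawn and logged.

**Maximum parsimony** scores columns by the Fitch set method (missing data
and gaps are compatible with every base) and searches by stepwise-addition
branch and bound: a partial tree is abandoned once its length exceeds the
best complete tree, which is exact because adding taxa can only add
substitutions. All co-optimal topologies are returned. The search is
exponential and refuses more than `max_taxa` (default 12) taxa.

## The synthetic-data generators

`simulate_founder_chain` emulates the demographic scenario the marker
system is meant to detect: a linear chain of haploid Wright–Fisher demes
(male lineages only — the Y does not recombine, so no diploid machinery),
colonized serially west→east. Each stage, a founder sample (default 10 of
100) from the most recently founded deme seeds the next one, and all demes
then evolve for a fixed number of generations (default 50; 12 demes).
There is no migration between established demes.

- **Microsatellites** follow the single-step model: ±1 repeat with
  per-generation rates mono 5·10⁻³, tri 5·10⁻⁴, penta 2.5·10⁻⁴ (the
  mutability ordering with penta = tri/2), reflecting at one repeat, with
  an optional upward bias for short arrays (default 0).
- **SNPs** obey an infinite-sites rule — each of the two sites mutates at
  most once — and originate at founder events: with probability 0.1 per
  site per colonization, one founder copy acquires the derived allele.
  This is the allele-surfing regime: variants born on an expansion front
  ride it into all subsequently founded demes. The rate gives ≈ 2 derived
  origins per 12-deme chain, the few-SNP regime the composite-haplotype
  method assumes. Placing SNP origins on the front is a deliberate design
  choice, not a simplification: under strictly uniform mutation in space
  and time the expected frequency of a neutral allele is a martingale, so
  its mean spatial profile is flat and no west→east cline can arise in
  expectation — while long-settled western demes would accumulate
  local-only variants, tilting the profile the wrong way (confirmed by
  simulation). With front origination the expected derived frequency is
  exactly zero west of the origin and inherited eastward, producing the
  cline the analysis looks for.

Averaged over replicate chains, the simulator reproduces two qualitative
signatures: the between-end-deme Dad ordering mono > tri > penta, and a
monotone west→east cline of mean derived-SNP frequency (rank correlation
≈ +0.99 over 200 chains). What it does **not** emulate: migration and
admixture between established demes, population size change after
founding, selection and selective sweeps (a real force on a
non-recombining chromosome), paternity variance beyond Wright–Fisher, and
any calibrated mutation-rate-to-time mapping. Passing tests therefore
support the internal consistency of the statistics under a clean serial
founder history, not their behaviour under reticulate or selective
histories.

`simulate_alignment` evolves sequences down a fixed tree by per-site
continuous-time T92 substitution (matrix scaled to one expected
substitution per unit branch length), with among-site rate variation
discretized into equal-probability gamma categories (default 5, matching
the standard analysis setting). Distance-estimator consistency is checked
against the analytic expectation of the generating process (the mixture of
category transition matrices); note the continuous-gamma correction
applied to 5-category data carries a small (<5%) discretization offset,
which vanishes as the category count grows — the recovery test of the
nominal branch length therefore uses a finer discretization (32
categories), while the 5-category default is validated against its own
exact expectation.

## Numerical and interface conventions

- All stochastic components take integer seeds (NumPy `default_rng`) and
  are reproducible byte-for-byte.
- Comparisons of the integer-weighted network distances use a 10⁻⁹
  absolute guard; NJ Q-criterion ties use 10⁻¹².
- Tabular outputs are tab-separated with a `#`-prefixed header; floats are
  written at full precision except in `report`, which applies the
  2-decimal (diversity, repeat distances) and 4-decimal (per-nucleotide
  distances) reporting conventions.
- Count cells in haplotype tables may carry parenthesized sampling-site
  sub-counts; only the leading count is data.
- Degenerate inputs fail with explicit errors: empty groups, empty count
  matrices, duplicate ids, saturated distances, < 3 taxa for NJ, > max_taxa
  for parsimony.

## Known limitations

- The median-joining cleanup criteria of other software are unpublished at
  implementation granularity; only sampled-node adjacency and
  cross-haplogroup substitution counts should be compared across
  implementations.
- `fitch_length` is exact for binary topologies (with a trifurcating or
  leaf root); multifurcating interiors are scored as their pairwise-folded
  binary refinement.
- The branch-and-bound search re-scores partial trees from scratch;
  fine for its ≤ 12-taxon scope, not engineered for large matrices.
- The simulator's demographic defaults are illustrative (no external
  calibration exists for deme sizes or founding times); conclusions should
  rest on its ordering/cline properties, not on absolute values.
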