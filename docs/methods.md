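# Methods

This note documents the models behind `parscout`: what the estimators
compute, what the synthetic-data generator does and does not emulate, the
numerical choices, and the limitations a user should know about.

## The biological model

The package assumes a female-heterogametic (ZW) system with highly
differentiated sex chromosomes and a single terminal PAR on the Z:

* **Female meiosis.** The Z–W bivalent experiences at most one crossover,
  obligate in the sense that exactly half of all gametes are recombinant
  (one crossover involves two of the four chromatids). The crossover
  position follows a piecewise-constant intensity over the PAR: a hotspot
  interval (default: the terminal 150 kb adjacent to the boundary)
  absorbing a configured fraction of events (default 0.8), uniform
  background elsewhere. Because the crossover count is fixed at one, the
  female model has complete interference; crossovers never occur outside
  the PAR.
* **Male meiosis.** Z–Z crossovers are Poisson along the whole chromosome
  at `male_co_rate` (default 3 cM/Mb, an autosome-like rate), with no
  interference. Autosomes use the same Poisson process in both sexes.
* **Ploidy.** Females carry one Z and one W; the W is homologous to the Z
  only across the PAR. Hence females are hemizygous at differentiated-Z
  loci, diploid in the PAR; sons receive the maternal Z, daughters the
  maternal W (which fixes each child's sex within the simulator), and all
  offspring receive a paternal Z gamete.

## Linkage analysis

Transmitted parental alleles are resolved per trio and marker by
elimination against the co-parent (ambiguous double-heterozygote trios are
dropped; impossible configurations are counted as Mendelian errors, with
female heterozygosity at differentiated-Z markers treated as an error per
se). For a marker pair, each parent heterozygous at both markers
contributes a "family": `n` offspring with resolved transmissions, of which
`r` are recombinant under an arbitrary phase labelling.

* Phase is read off the grandparents when the parent's own trio resolves
  the grandparental origin of both alleles; then L(θ) ∝ θ^r (1−θ)^(n−r)
  and the pooled phase-known MLE is exactly r/n.
* Otherwise both phases are summed with equal prior:
  L(θ) ∝ ½[θ^r(1−θ)^(n−r) + θ^(n−r)(1−θ)^r], maximized numerically on
  [0, ½].
* A dam heterozygous at a PAR marker and hemizygous at a differentiated-Z
  marker is still informative: the differentiated "locus" is the identity
  of the transmitted tail (Z to sons, W to daughters), read off offspring
  sex, with phase unknown. This is what lets female map positions extend
  across the PAR boundary (and stay flat beyond it).

LOD = [log L(θ̂) − log L(½)]/ln 10, floored at 0. Candidates are assigned
to the anchor group when their best pairwise LOD exceeds 3.0 (the
conventional linkage threshold). The candidate screen requires ≥1
heterozygote and ≥1 homozygote in each sex, a Hardy–Weinberg chi-square
P ≥ 0.001 (1 df, diploid calls only; the threshold is a common array-QC
choice — no specific α is canonical) and zero Mendelian errors.

Maps are built over a fixed marker order by adjacent-pair two-point
estimation; the sex-averaged map maximizes the pooled-meiosis likelihood
rather than averaging the two sex maps. Map functions: Haldane
d = −50 ln(1−2θ) (default — consistent with the simulator's
no-interference male model) and Kosambi d = 25 ln[(1+2θ)/(1−2θ)].
Uninformative intervals (no doubly-heterozygous parent) advance the map by
0 cM rather than being imputed. θ is capped at 0.499 inside the map
transform: a single interval cannot resolve distances beyond ~300 cM, and
an unlinked-looking θ̂ on sparse data would otherwise dominate the map.
Exhaustive order search is provided for ≤10 markers (minimum total
adjacent θ, lexicographic tie-break); larger sets require a given order.

Interval rates are ΔcM/(Δbp·10⁻⁶); cross-scaffold spans add a configurable
gap padding (default 5 kb per assembly gap). The PAR boundary is the
distal-most marker after which cumulative female cM stops increasing; its
resolution is one marker interval, since crossovers between the last PAR
marker and the first differentiated marker are genuine.

## Coverage classification

Per-base pooled depth is windowed (default 200 kb; the terminal short
window is kept but flagged), the M/F ratio computed from window means
(medians are reported for inspection) and divided by the mean autosomal
window ratio, which makes the autosomal average exactly 1 and absorbs
unequal total sequencing effort. Classification is in log2 space with
tolerance 0.25: |log₂ r| ≤ 0.25 → PAR-like, |log₂ r − 1| ≤ 0.25 →
hemizygous-Z, else ambiguous. Zero-female-depth windows have undefined
ratios and are excluded (no pseudocounts). Scaffold verdicts are majority
votes over informative windows; short terminal windows are excluded unless
they are all a scaffold has (a scaffold shorter than one window would
otherwise never receive a verdict).

## Population genomics

All estimators count sampled chromosomes through the ploidy map, so a
hemizygous female contributes one allele where she has one.

* π is the per-site unbiased pairwise diversity Σ [n/(n−1)]·2p(1−p) over
  sites with ≥2 sampled alleles, divided by the callable length (window
  length, optionally reduced by an exclusion mask) — not by an
  assumed-diploid site count.
* F_ST defaults to Weir–Cockerham variance components in the allele-level
  (haploid-observation) form, as a ratio of sums over sites; this handles
  mixed-ploidy windows uniformly at the cost of ignoring within-individual
  allele correlation. Hudson's 1 − H_w/H_b is provided in plug-in form,
  which has the exact closed-form behavior used in tests (identical
  frequencies → 0, fixed difference → 1).
* d_f counts sites where the two groups share no allele, per callable bp.
* r² is the squared correlation of phased allele indicators;
  E(r²) = 1/(1+αd) is fitted by bounded scalar least squares on α ≥ 0 over
  all site pairs within 20 kb at raw (unbinned) distances. With a sample
  of n haplotypes the fit can include a floor term,
  (1−f)/(1+αd) + f with f = 1/(n−1), the linkage-equilibrium expectation
  of sample r²; without it distant pairs sit on a noise plateau the pure
  curve cannot reach and α is biased toward zero. The raw fit (f = 0) is
  the default and recovers α to machine precision on noiseless curves.
  d(r²=0.1) = 9/α exactly.

## The synthetic-data generator

Defaults are the study conditions the package is validated under: pooled
sequencing of 10 males + 10 females at 5× per individual (Poisson per base,
negative-binomial optional), a 630.5-kb PAR split 436.0/182.2/2.3 kb,
per-site diversity targets 0.0034 (PAR) / 0.0032 (differentiated Z),
fixed-difference densities 0.0001 / 0.0011, LD decay α 0.2 / 0.005776 per
bp, GC 0.492 / 0.399, repeat fractions 0.064 / 0.116, gene densities
34.9 / 10.0 per Mb, and M:F expression effects 0.95 (PAR) / 1.40 (Z) /
1.02 (autosomes) across a nine-tissue, five-replicates-per-sex panel. The
differentiated Z and the autosomes are simulated at a few Mb rather than
chromosome scale; every statistic tested is a per-bp density or ratio, so
region length only sets the Monte-Carlo resolution.

The haplotype panel is a blockwise ancestor-copying model, not a
coalescent. Each scaffold is partitioned by a stationary renewal process
whose segment lengths are Lomax with shape 2 and mean 1/α; this makes the
probability that two positions at distance d fall in the same segment
exactly 1/(1+αd), the assumed decay curve, at every distance (an
exponential-length process matched at a single distance systematically
fails fit recovery). Within a segment, haplotypes split into two local
lineages (frequency u ~ Uniform(0,1) per segment) and every polymorphic
site separates the same two lineages, so within-segment r² is 1. Site
density is 3·π_target per bp because E[2u(1−u)] = ⅓ makes realized
diversity unbiased for the target. The alternate allele is assigned to the
minor lineage, so finite samples cannot mistake low-frequency variants for
fixed inter-species differences. Fixed differences are placed as a
separate Poisson process at d_f per bp.

What this emulates well: per-bp levels of π and d_f, the mean r²-distance
relation, the depth contrasts, ploidy bookkeeping, and exchangeable sexes
(F_ST ≈ 0). What it does not: realistic site-frequency spectra or
demography, gene conversion, selection, mutation-rate heterogeneity, or
read-level artifacts (mapping bias, duplicates). Passing tests therefore
validate the estimators and the pipeline logic, not robustness to
real-data noise. One practical consequence of the heavy-tailed segment
process: a single region's LD fit has large realization variance (a few
long segments dominate), so recovery tests and examples average the fit
over replicate panels.

## Pipeline consensus

A scaffold is called PAR only when (a) at least one of its markers is
LOD-assigned to the Z anchors and shows female recombination, (b) its
coverage verdict is PAR-like, and (c) heterozygous females are present.
All lines disagreeing yields the differentiated-Z call; a mixture yields
"conflicting" with the evidence table retained. The reported PAR physical
length is the sum of called scaffold lengths plus gap padding per junction.
The report is deterministic given the seed: reruns are byte-identical.

## Numerical and testing choices

* All randomness flows through per-stage generators spawned from one seed;
  fixed seed ⇒ bit-identical outputs everywhere.
* File coordinates are 1-based inclusive (VCF/GFF3) or 0-based half-open
  (BED); internal coordinates are uniformly 0-based half-open.
* Undefined statistics (empty windows, monomorphic sites, no informative
  meioses) are flagged or returned as NaN — never silently zero.
* Bootstrap P-values are (k+1)/(B+1) with a floor of 1/(B+1), displayed as
  an inequality when no resample is as extreme.
* Stochastic tests are seeded; statistical assertions use 3-standard-error
  bounds (binomial or replicate-based) at simulation sizes chosen to keep
  the whole suite around a minute of CPU: ~500 meioses per sex for linkage
  recovery, 10,000 draws for crossover properties, 3–5 replicate panels
  for diversity and LD recovery.

## Known limitations

* Two-point linkage only: no multilocus phase reconstruction, so phase
  must come from grandparents or remain marginalized; CRI-MAP-style
  CHROMPIC/FLIPS refinement is out of scope.
* The Weir–Cockerham form ignores within-individual correlation (no
  heterozygosity variance component); for diploid-only panels a
  genotype-level estimator would differ slightly.
* The bootstrap's block resampling wraps circularly over the background
  window list and assumes exchangeable windows.
* `best_order` is exhaustive and limited to 10 markers by design.
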