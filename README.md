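# parscout

**Pseudoautosomal-region identification and characterization for
differentiated sex chromosomes.**

On old, highly differentiated sex chromosomes (ZW in birds, XY in mammals)
recombination between the two sex chromosomes survives only in a small
shared segment, the pseudoautosomal region (PAR). Finding that segment in a
draft assembly is a detective job resting on independent lines of evidence,
and `parscout` implements each of them as a tested, reusable library:

1. **Linkage** (`parscout.linkage`) — candidate PAR markers are SNPs with
   heterozygous *and* homozygous genotypes in both sexes that pass
   Hardy–Weinberg and Mendelian screens. Two-point linkage against known
   Z-linked anchor markers (LOD = log₁₀ L(θ̂) − log₁₀ L(½), assignment at
   LOD > 3) places them on the Z; sex-specific genetic maps (Haldane or
   Kosambi) then reveal the PAR boundary as the point where cumulative
   female cM stops increasing, and interval rates (cM/Mb) localize the
   recombination hotspot. Female hemizygosity is handled throughout: a dam's
   single Z still informs linkage through the sex of her offspring.
2. **Coverage** (`parscout.covscan`) — pooled male and female sequencing
   depth in 200-kb windows; the M/F ratio, normalized by the autosomal
   average, is ~1 in the PAR (two copies in both sexes) and ~2 on the
   female-hemizygous Z. Windows are classified in log2 space, scaffolds by
   majority vote.
3. **Population genomics** (`parscout.popgen`) — ploidy-aware windowed
   nucleotide diversity π = Σ [n/(n−1)]·2p(1−p) / callable bp,
   Weir–Cockerham and Hudson F_ST, fixed-difference density d_f, and LD
   decay fitted as E(r²) = 1/(1 + αd), with d(r²=0.1) = 9/α.
4. **Characterization** (`parscout.charext`) — GC and softmasked-repeat
   fractions in windows, gene density and coding fraction, the
   tissue-specificity index τ, male:female expression ratios, and a
   non-parametric bootstrap comparing a region against background windows.
5. **Synthetic cohorts** (`parscout.sim`) — a ZW simulator producing every
   input above with known truth: obligate single female crossover in a
   terminal PAR (hotspot-weighted), Poisson male crossovers chromosome-wide,
   female hemizygosity, sex-pooled Poisson depth with 1:1:2 copy-number
   contrasts, two-species haplotype panels with target π, d_f and α, and
   softmasked FASTA / GFF3 / expression fixtures.

A thin CLI (`parscout simulate|linkage|covscan|popgen|characterize|run`)
wraps the library; `parscout.pipeline.run_pipeline` aggregates the evidence
into a per-scaffold consensus PAR call (all lines must agree; anything less
is reported as "conflicting").

## Worked example

The package bundles the best-order genetic map of the distal Z chromosome
of the collared flycatcher, whose terminal 630-kb PAR spans three scaffolds
(436.0 + 182.2 + 2.3 kb, with 5 kb of padding per assembly gap).
`examples/03_reference_map_rates.py` reproduces its headline numbers:

```text
PAR physical length: 630.5 kb (reported as 630 kb)
PAR boundary: after N02597:626 (next marker N00781:8697)
female map length across the PAR: 64.3 cM -> 102.1 cM/Mb
male map extension across the PAR: 7.3 cM -> 11.6 cM/Mb
hotspot interval N00378:115359 .. N02597:626: 50.2 cM over 67.5 kb = 744 cM/Mb
```

A 64.3-cM female map over 630 kb (>50 cM) is the signature of an obligate
crossover in female meiosis; 78% of that map length falls in a single
67-kb interval next to the boundary — a recombination hotspot running at
more than 700 cM/Mb, against a 102 cM/Mb regional average and ~3 cM/Mb
genome-wide.

The other examples each exercise one capability on simulated data and print
what they compute — e.g. `examples/05_popgen_windows.py`:

```text
par_1: pi=0.0034  d_f=0.00011  FST(species)=0.350  FST(sexes)=-0.0001  alpha=0.1906  d(r2=0.1)=47 bp
zdiff_1: pi=0.0031  d_f=0.00111  FST(species)=0.463  FST(sexes)=0.0081  alpha=0.007148  d(r2=0.1)=1259 bp
```

PAR diversity matches the differentiated Z, the sexes show no
differentiation (F_ST ≈ 0, as expected when PAR alleles segregate freely in
both sexes), inter-species fixed differences are ten-fold rarer in the PAR,
and LD decays to r² = 0.1 within ~50 bp in the hotspot-rich PAR versus
kilobases on the rest of the Z.

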