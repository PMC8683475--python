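# Methods

## The estimator

A clonal parental culture expanded for D population doublings accumulates
de novo mutations along the single-cell lineage that founds each subclone.
Population doublings are equated with cell divisions in the denominator —
the same substitution the experimental design itself makes — so no lineage
tree is simulated or inferred. With a per-base per-doubling rate r over a
diploid genome of haploid callable length L_eff, the expected number of
heterozygous parental-phase mutations is r · 2 L_eff · D, and the estimator
inverts this:

    r̂ = N̂ / (2 · L_eff · D)

L_eff is measured from binned coverage (default 1-kb..100-kb bins) as the
total length of bins with mean depth ≥ 10 in *both* samples; computing it
on bins rather than per base keeps the computation desk-scale and is exact
for the simulator, whose depth is constant within a bin (bin-edge effects
on real tracks are below 0.2 % at these bin sizes).

### Truncated-Gaussian count extrapolation

After the AF trim at τ only calls with observed AF ≥ τ remain. The AF
distribution of genuine clonal heterozygous mutations is modeled as a
single Gaussian (at 30× depth the binomial sampling distribution of
alt/total around 0.5 has σ ≈ 0.09 and is well approximated by a normal).
The fit maximizes the truncated-normal likelihood on [τ, 1] over (μ, log σ)
by Nelder–Mead from moment-based starting values; σ is floored at 10⁻³ for
degenerate inputs. The total count over AF 0–1 is then

    N̂ = n_obs · [Φ((1−μ)/σ) − Φ(−μ/σ)] / [Φ((1−μ)/σ) − Φ((τ−μ)/σ)].

A naive moment fit on the trimmed data is biased (the trim removes the
left tail, inflating the mean); the test suite demonstrates the bias and
the MLE's correction. A retention fraction below 5 % triggers a warning —
the extrapolation is then mostly model, not data.

Design choices that were genuinely open:

* **Fit method.** Only "a Gaussian model" is specified by the procedure
  this package reimplements; truncated-normal maximum likelihood is the
  defensible reading and is what is implemented.
* **Homozygous calls.** Clonal mode fits one Gaussian over all trimmed
  AFs. Parental hets dominate clonal parent/subclone comparisons, and at
  the observed counts a rare AF ≈ 1 call shifts the fit negligibly. Bulk
  mode instead classifies calls as het/hom at an AF boundary of 0.75
  (inclusive) and does not estimate rates at all — bulk accumulation
  reflects drift and selection of a population, not a per-division rate.
* **Sparse classes.** The truncated fit refuses fewer than 10
  observations (unstable). INDEL counts per subclone sit right at that
  boundary (≈ 10 for a GS-like rate), so the cohort layer pools AFs
  across subclones of the same design and applies the pooled fit's
  retention fraction to each sparse subclone's n_obs. This assumes a
  shared AF distribution across subclones, which holds by design in the
  simulator and is the natural assumption for replicate subclones.
* **Confidence intervals.** Cross-subclone summaries use a t-distribution
  CI on the per-subclone rates (the CI construction behind the published
  intervals is unstated); group comparisons use the exact two-sided
  Mann–Whitney test for ≤ 10 per group without ties, the normal
  approximation (with a warning) otherwise.
* **Outliers.** A subclone whose trimmed SNV count exceeds 3× the cohort
  median is flagged in the report but never auto-excluded; exclusion
  requires an explicit list (`--exclude-subclone`). This reproduces
  transparently the manual judgment such analyses apply to aberrant
  subclones.

## Filtering cascade

Depth (≥ 10 in both samples), class-specific caller quality (≥ 19 SNV,
≥ 14 INDEL), allele-aware blacklist removal, sex-chromosome exclusion, AF
trim at τ. All thresholds are **inclusive** (≥ retained) — the source
wording mixes "less than" and "more than", so one consistent convention is
used and tested. Blacklist matching is on (chrom, pos, ref, alt), not
position alone: a genuine de novo event coinciding with a polymorphic
position but carrying a different alternate allele survives. The first
four stages commute and are idempotent (property-tested); the AF trim runs
last by convention because its removed count feeds the extrapolation.

## The synthetic generator

`clonemut.simulate` emulates the *output contract* of an
alignment-plus-somatic-caller workflow, not its internals:

* **Genome.** Two-tier: context chromosomes (explicit sequence, default
  2 × 1 Mb at GC 0.42, with a fixed cassette guaranteeing all 16
  dinucleotides) and virtual chromosomes (length only, default 19 so the
  autosomal total is ~1.9–2.1 Gb), plus chrX/chrY analogues flagged
  non-autosomal. Genes are single-transcript, non-overlapping, log-normal
  lengths (median 10 kb), both strands, 1-kb flanks kept clear of
  neighbours; FPKM is log-normal with a configurable zero fraction.
* **Mutations.** Parental-phase count ~ Poisson(r · 2L · D) at AF 0.5 (or
  1.0 for a configurable hom fraction). Subclonal-phase events are drawn
  per generation g = 1..10 with count ~ Poisson(r · 2L · 2^(g−1)) at AF
  0.5 · 2⁻ᵍ — 2^(g−1) dividing lineages at generation g, each mutation
  subtending 2⁻ᵍ of the final culture. Ten generations suffice: deeper
  events are undetectable at 30×. Six-type identities follow configurable
  probabilities; two presets mirror a C>T-dominant (63 %/17 %) and a
  C>A-dominant (66 %/20 %) spectrum. On context chromosomes sites are
  rejection-sampled so the reference base matches the drawn type; on
  virtual chromosomes ref/alt and flanking bases are assigned consistently
  (flanks drawn from the GC composition, so no CpG enrichment is modeled).
  INDEL lengths are geometric (p = 0.6, mode 1 bp) with insertion
  probability ratio/(1+ratio), default ratio 0.84.
* **Reads.** total ~ Poisson(mean depth 30), alt ~ Binomial(total,
  AF · (1−c)) with contamination c = 0.5 % by default; a call is emitted
  with ≥ 2 supporting reads. The synthetic caller quality is
  min(60, 3 · alt_reads) — monotone in support, scaled so the default
  thresholds 19/14 correspond to ≥ 7 / ≥ 5 alt reads and cleanly separate
  well-supported calls from contaminant-driven ones (1–3 reads).
* **Contamination.** 2000 feeder-derived sites per comparison, half drawn
  from the polymorphism blacklist (removable by the blacklist filter) and
  half private (removable only by quality/AF trimming), at pooled AF ≤ c.
* **Coverage.** Bin read counts ~ Poisson(depth · bin / read-length) with
  150-bp reads. CNV spike-ins scale expected depth by
  1 + f · (copies − 2)/2 for a cell fraction f.
* **Strand bias.** An optional C>T bias parameter places the pyrimidine of
  genic C>T events on the untranscribed (coding) strand with probability
  ≠ 0.5. It acts only on virtual chromosomes, where the emitted reference
  strand is not pinned by actual sequence.
* **Bulk mode.** Fixed mutations accrue as Poisson(intensity × months)
  between timepoints (defaults 14 SNVs and 0.6 INDELs per month, echoing
  the reported accumulation scale over a 31-month interval), so earlier
  fixed sets are subsets of later ones; observation noise then makes
  timepoint overlaps incomplete, as seen in real series. A segmental
  amplification can be spiked from a chosen timepoint onward.

What the generator does **not** model: alignment artifacts, mappability,
per-base sequencing error haplotypes, GC coverage bias, repeat content,
caller false negatives beyond the emission threshold, and regional rate
heterogeneity. Passing recovery tests therefore shows the estimator chain
is self-consistent and unbiased under binomial read sampling — not that it
is robust to mapping artifacts in real data.

## Mutation characterization

Substitutions are pyrimidine-collapsed (purine-reference events are
reverse-complemented together with their flanks). The 96-context order is
the common alphabetical convention (blocks C>A…T>G; flanks A, C, G, T), so
vectors align with published signature catalogs supplied as TSV; resemblance
is quantified by cosine similarity only — no deconvolution. Virtual-
chromosome calls join the six-type spectrum (their generator-assigned
flanks also give a CpG split) but are excluded, with a count, from the
96-context vector, which uses sequence-derived context only.

Per-chromosome densities (count / length × 10⁸) exclude chromosomes below
10 Mb: a tiny scaffold's density is almost always zero with rare huge
spikes, which breaks the exchangeability the Kruskal–Wallis enrichment
test assumes across chromosomes. The test requires ≥ 2 subclones; its
type-I error is calibrated (≈ 5 %) on 19 comparable chromosomes, and
detecting a 10× single-chromosome enrichment with ≥ 90 % power needs on
the order of 10 replicate subclones.

Genic annotation precedence: UTR ≻ exonic ≻ intronic ≻ flank ≻ intergenic
(every position gets exactly one class); gene bodies are TSS–TES, so
introns are included in strand analysis while 1-kb flanks — which are not
transcribed — are excluded. The strand-bias test is the exact conditional
binomial Binomial(n_u + n_t, ½), the standard exact construction for
comparing two Poisson counts; p-values are exact and therefore discrete —
conservative (super-uniform) at small counts, indistinguishable from
uniform at counts ≳ 1000, which is where the calibration suite checks
uniformity. No multiple-testing correction across the six types by
default (a Bonferroni switch exists), mirroring per-type reporting.
Gene-length and expression comparisons use Mann–Whitney on log₁₀ values
with effect size |Δmean|/pooled SD; zero-FPKM genes are excluded from the
log-expression comparison.

## Copy number

Each track is scaled by its autosomal total, the per-bin ratio is taken,
and the ratio track is then re-anchored so its median unmasked autosomal
bin equals 1. The second step matters: with total-scaling alone a
whole-chromosome trisomy inflates the denominator and lands at
1.5/1.026 ≈ 1.46 on this genome, dragging every other chromosome below 1;
anchoring the diploid mode restores the nominal 1 / 1.5 / 0.5 levels (it
assumes most of the genome is diploid, true in all regimes this analysis
targets). Chromosome states are read from the median ratio with ± 0.1
bands; medians between bands are "intermediate" with mixture fraction
f = 2(m − 1) for gains (f = 2(1 − m) for losses). Segmental events use
median filtering (5 bins) plus run-length thresholding (≥ 1.25 gain /
≤ 0.75 loss, ≥ 10 bins, gaps ≤ 2 merged) rather than formal changepoint
inference — deterministic and sufficient for the multi-megabase events of
interest, at the cost of ± 1 bin endpoint resolution and insensitivity to
events shorter than min_run. Bins with control depth < 10 are masked;
sex chromosomes are excluded.

## Problem sizes and tolerances

Recovery experiments run at the study conditions (L ≈ 2.1 × 10⁹, D = 100,
30×, c = 0.5 %): 6 subclones for SNV-rate recovery, 20 for INDEL rates
(expected counts ≈ 10 per subclone exercise the pooled-fit fallback),
pooled spectra of ~1800+ SNVs and ~8000 INDELs so binomial noise
(se ≈ 1–2 %) sits well inside the reported variability of the quantities;
the sizes are fixed in `clonemut.experiments` and derive every random
stream from one seed. Numerical tolerances: optimizer xatol 10⁻⁶, σ floor
10⁻³, retention-fraction identity verified against numeric integration to
10⁻⁶.

## Known limitations

* The Gaussian AF model ignores the discreteness and slight skew of
  binomial AFs at 30×; the resulting bias is ≪ sampling error at the
  observed counts but would grow at much lower depth.
* The pooled-fit fallback for sparse INDEL cohorts assumes exchangeable
  subclones; a subclone with genuinely different AF structure would be
  mis-extrapolated (it would, however, be flagged by the outlier rule if
  its count were aberrant).
* Rates are genome-wide constants; regional heterogeneity, selection
  during culture, and caller sensitivity differences between SNVs and
  INDELs are out of scope.
* The copy-number caller reports chromosome medians and threshold-run
  segments only; allele-specific states and GC correction are not
  implemented.
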