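# Methods

## Data model

The unit of observation is a CAZyme domain hit: one annotated domain of
a named family (class prefix GT/GH/PL/CE/CBM plus a number) inside one
gene of one species. Genes aggregate their hits in file order — the
domain architecture — and a gene is a CAZyme gene if it has at least
one hit. dbCAN subfamily suffixes (`GH5_7`) are collapsed to the base
family (`GH5`) for every analysis, because repertoire comparisons are
reported at base-family resolution; the raw string is preserved on each
hit for traceability. Coordinates and e-values are carried but never
required: all analyses use family identity and per-gene multiplicity
only. No e-value re-filtering is applied by default (annotations are
taken as given); `max_evalue` is available where a user wants to
tighten them.

## Frequency

Domain counts count every hit, tandem repeats included — this is what
makes a genome's domain total exceed its CAZyme gene count. Class
relative frequencies are percentages of the genome's domain total;
they are undefined (reported missing, not zero) for an empty genome.
Percent CAZyme genes is rounded half-up to two decimals, the precision
at which genome tables print it; all other values are kept at full
precision. The lineage coefficient of variation uses the sample (n−1)
standard deviation; groups of size one and zero-mean cells are
reported missing rather than zero, so "no information" is never
conflated with "no variation".

The bundled 22-genome census is carried verbatim as published,
including four lineage groups (green algae; bryophyte+lycophyte;
monocots; eudicots). Several published rows have per-class counts that
do not sum to the printed domain total; the loader flags these in a
`class_sum_consistent` column instead of reconciling them, and
class-sum checks are asserted only on the nine consistent rows.

## Diversity

Presence means at least one domain occurrence — no minimum-count
threshold, since none is established for this kind of census. Core
sets are exact intersections; the `absent_in` argument expresses
queries like "present in all land plants, absent in both algae". The
occurrence spectrum is reported descriptively (histogram plus the
fraction of families in the two edge modes); no functional form is
fitted to it, as no defensible parametric family exists for a
22-point bimodal histogram.

## Complexity

Gene categories partition CAZyme genes: `single` (one domain),
`repeat_only` (≥2 domains, one family), `mixed` (≥2 distinct
families). Repeat statistics are reported per protein, not per domain.
The multiplicity histogram is fitted by ordinary least squares of
log₁₀ count on log₁₀ k over nonzero bins — zero bins are excluded, not
imputed, and no tail truncation or logarithmic binning is applied. R²
is defined as 1 − SS_res/SS_tot with the convention that an exact fit
(SS_res = 0) scores 1 even for constant counts, where the Pearson
formulation would be 0/0. A combination's identity is the unordered
set of distinct families in a mixed gene; order and multiplicity are
ignored because combinations are conventionally written as unordered
family lists, and a gene with ≥3 distinct families is one combination
of that size (a pairwise projection is available separately). The full
architecture stays on the gene object for future order-aware analyses.

## Expression investment

Replicates are averaged arithmetically; a missing replicate triggers a
warning and averaging over those available. The accounting rule adds a
gene's mean FPKM once to each distinct family it contains, so family
totals per tissue satisfy the identity
Σ_f I(f,t) = Σ_g meanFPKM(g,t)·|families(g)|, which the tests verify
against a brute-force per-gene oracle. Class totals inherit the rule
(a mixed GT/GH gene contributes to both classes). Proportional shares
are computed against the column sum of the investment table itself, so
printed shares always total 100% within a tissue. The "expressed"
threshold defaults to mean FPKM > 0 in at least one tissue and is
configurable. FPKM is treated as an opaque nonnegative abundance;
cross-species concordance compares only the sign of xylem − leaf
within each species. A family with zero investment in both tissues of
one species is `absent_in_one`/`absent_in_both`; an exact tie in an
expressed family — possible only in noise-free synthetic data — gets
its own `tied` label rather than being forced into the
concordant/discordant dichotomy.

## Synthetic data generator

The generator emulates the structure the analyses assume, with every
draw flowing from a single integer seed (identical seeds give
byte-identical files).

Defaults, chosen once as the realistic operating point for this kind
of census: 5 species × 30,000 genes, 2,000 CAZyme genes each; class
ratio 40:30:2:18:10 (GT:GH:PL:CE:CBM); family pools 72/92/13/16/38 per
class (231 families); 65 core families present everywhere and 74
restricted families present in 1–2 species (accessory families fill
intermediate occupancy, yielding a bimodal occurrence spectrum); 17%
multi-domain genes of which 60% are same-family repeats; multiplicity
tail ∝ k^−2.5 truncated at 7 domains; every gene with ≥5 domains
carries GT41, mirroring the O-GlcNAc-transferase repeat proteins that
dominate high-multiplicity CAZymes in plants. Expression: six tissues,
three replicates, lognormal gene baselines (meanlog 2.0, sdlog 1.5 —
heavy-tailed, the standard RNA-seq abundance stand-in), multiplicative
lognormal replicate noise (log-sd 0.5), 20% of genes silent in all
tissues (tissue atlases capture roughly four fifths of CAZyme genes),
and planted tissue-bias factors of 4 for the xylem-biased
secondary-wall families GT2/GT8/GT43/GT47 and the leaf-biased GT1.

Two deliberate design choices keep planted truth exactly recoverable:

- *Guaranteed presence.* One single-domain gene is seeded per
  (species, planted family) before random draws, so presence/absence
  recovery is exact rather than probabilistic. GT41 and the designated
  bias families are forced into the core so every species can realize
  the GT41 rule and the bias design.
- *Compensated class weights.* The guaranteed block (whose class mix
  follows the family pools) and the forced GT41 content of ≥5-domain
  genes add domain mass outside the ratio-driven draws. The per-class
  draw weights are solved so that the *expected* realized class
  marginal equals the planted ratio; without this, the realized GT
  share runs ≈4 points high. Weights are clipped at zero when a target
  is infeasible. Empirically, the pooled class ratio over the default
  design lands within ~1 percentage point of target.

Because the specified multiplicity model draws k = 1 with probability
1 − p_multidomain and only the tail ∝ k^−γ, the full histogram is not
itself a power law for arbitrary p_multidomain;
`power_law_consistent_p_multidomain(γ, kmax)` returns the value making
the whole k = 1..kmax distribution ∝ k^−γ, the regime in which the
fitted slope estimates −γ. Exponent-recovery checks use it.

What the generator does **not** emulate: phylogenetic correlation of
family gain/loss (species are exchangeable), within-class differences
in family popularity (families are uniform within class), gene length
and library-size effects inside FPKM, tissue-correlated noise, and
ortholog structure between species. Passing recovery tests therefore
demonstrate the correctness of the bookkeeping and the estimators
under the stated model, not robustness to these real-data features;
the published 22-genome and two-tree-transcriptome findings depend on
external annotation and expression resources and are not reproduced
numerically here.

## Numerical conventions

Deterministic orderings throughout: families by (class, number) with
class order GT, GH, PL, CE, CBM; combination labels alphabetical by
class prefix then numeric (CBM43+GH17); species in input order.
Undefined quantities (CV of a singleton group, shares of an empty
tissue, relative frequencies of an empty genome) are missing values,
never zeros. A zero denominator in a tissue ratio returns an infinite
sentinel with a warning. Duplicate identical annotation rows are kept
(repeat domains are legitimate) with one aggregate warning per file.

## Problem sizes

The test and acceptance runs use 100 seeded datasets of 2 species ×
250 CAZyme genes for the accounting identity (exact at any size), the
default 5 × 2,000 design for set- and ratio-recovery, 5,000 genes for
exponent recovery, and 2-species default-size designs for direction
recovery — sizes at which each check's sampling error is comfortably
inside its tolerance while the full suite runs in well under a minute.
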