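# Methods

## The assay being modelled

Clone-based bisulfite sequencing reads DNA methylation one molecule at
a time. Genomic DNA from a sorted cell population is bisulfite (BS)
treated — unmethylated C deaminates to U (read T after PCR),
5-methylcytosine is protected — then a strand-specific primer pair
amplifies one strand of one region, products are cloned, and ~20
plasmid clones per (donor × population × region × strand) group are
Sanger-sequenced. Each clone is one molecule from one cell. After
alignment to the region's reference, a CpG C column read as C is called
methylated, read as T unmethylated, anything else (gap, N, other base)
ambiguous. Percent methylation at a CpG is `100·m/(m+u)` over called
clones; ambiguous calls leave both numerator and denominator, and the
per-CpG denominators are recorded. Because BS treatment makes the
strands non-complementary, assaying both strands separately measures
hemimethylation: the per-CpG index is |top% − bottom%| in percentage
points (a signed top−bottom version is also emitted).

Strand and coordinate conventions: internally everything is 0-based,
half-open, on the assayed strand, written 5'→3'. A bottom-strand assay
reverse-complements the genomic sequence once at load; all downstream
logic is strand-agnostic. Reports use 1-based CpG ordinals in
assayed-strand 5'→3' order (the lollipop-figure convention). When the
two strands are compared, the bottom strand's ordinals are reversed:
strand k's CpG i pairs with the other strand's CpG n+1−i over the same
(palindromic) CpG dinucleotide.

## Conversion model and QC

`ConversionModel(conversion_rate, protection_rate)` gives the
probability an unmethylated C reads T and a methylated C reads C;
defaults are 0.995/0.995, the specification of current commercial BS
kits. Per clone, conversion efficiency is estimated as the fraction of
non-CpG reference-C columns read as T among those read as C or T
(non-CpG Cs should always convert). Clones below the QC threshold —
default 0.95, deliberately looser than the kit spec to tolerate Sanger
error on a few dozen assessable sites — are excluded, each with a
logged reason; a clone with no assessable Cs fails QC outright. N bases
are never CpGs, are never converted, and never enter efficiency
denominators.

## Alignment

Clones are aligned globally (Needleman–Wunsch/Gotoh, affine gaps) to
the untreated reference with a bisulfite-asymmetric substitution
scheme: reference C against read T scores as a full match at every
position, so expected conversion at non-CpG sites and either
methylation state at CpG sites are unpenalized, and an unconverted C
(read C at a converted position) is likewise not punished — conversion
failures are QC's job, not the aligner's. Parameters are pinned for
reproducibility: match 2, mismatch −3, gap open −5 (covering the first
gap base), gap extend −2. Both the clone and its reverse complement are
scored and the better orientation kept (inserts can be sequenced in
either direction despite directional cloning). Alignments with identity
below 0.80 over alignment columns are flagged unalignable and excluded
with a reason. The row-vectorized dynamic program is checked against an
independently written plain quadratic-time DP on random pairs in the
test suite.

## Synthetic data

The generator emulates the statistical structure the analysis assumes:

* per-CpG, per-strand methylation probabilities `p_meth` per
  (population, region, strand) group;
* 20 clones per group (the assay sequences 20–22), configurable;
* uniform substitution error 1e-3 per base (Sanger-like), configurable;
* conversion/protection 0.995 by default;
* two within-clone correlation modes: `independent` (each CpG an
  independent Bernoulli; the default for statistical tests) and
  `clone_level` (one epiallele per clone, all-methylated with
  probability mean(p_meth) — the bimodal rows seen in real lollipop
  data). Real data presumably sits between these; neither is asserted
  as the truth.
* optional X-inactivation mosaicism for X-linked regions of female
  donors: each clone is drawn from the inactive-X (fully methylated)
  profile with probability `fraction_inactive`, else from the active
  profile. Following the assay's own practice, pipeline outputs are
  never Xi-corrected; the mosaic exists for sensitivity analysis.

Reproducibility: one master seed; per-group generators derive from
SHA-256 hashes of (donor, population, region, strand), so identical
(config, seed) reruns are byte-identical and groups are independent of
iteration order. The realized per-clone state matrix is kept as ground
truth for recovery tests. A matrix-level fast path
(`simulate_group_percents`) draws the same clone states without the
sequence round trip — the identity under perfect conversion and
error-free calling — and its distributional equivalence to the
per-clone path is itself tested; large replicate studies (calibration,
power) use it.

Canned scenarios fix the study conditions for the 15-CpG TSDR region:
`conventional_male` (Treg subsets p = 0.02, Tcon 0.95, CD34⁺ 0.90,
identical on both strands), `hemimethylated_donor` (bottom/coding
strand p = 1.0 in all populations; top strand conventional — p is kept
at 0.02 rather than exactly 0 in Treg because observed top strands
retain occasional methylated clones, and an exactly constant difference
table would degenerate the model fit), `xi_female` (50:50 mosaic with a
fully methylated inactive profile) and `null_pair` (two populations
with identical p = 0.5 profiles, the maximum-variance null). Reference
sequences are synthetic: deterministic random inter-CpG segments free
of CG dinucleotides with abundant non-CpG Cs (real runs supply their
own FASTA). What passing tests therefore show is that the pipeline
recovers what this generative model encodes; they cannot vouch for
chromatogram-level artefacts, PCR/cloning bias beyond the epiallele
option, or inter-donor heterogeneity patterns absent from the model.

## Paired comparisons

For two paired conditions (Tcon vs a Treg subset in the same donors,
or top vs bottom strand of one group), per-(donor, CpG) differences in
percent methylation are modelled as

    diff[d, c] = μ + a_d + b_c + e[d, c],

with crossed random intercepts for donor and CpG position. The test is
of μ = 0. Default inference (`method="moment"`) is a method-of-moments
fit of this model: with D donors and C CpGs the variance of the grand
mean is estimated as

    Var(μ̂) = var(donor means)/D + (MSB − MSE)₊ / (DC),

where the donor-mean term already carries the donor and residual
components (σ²_a/D + σ²_e/(DC)) and the positive-part term adds the CpG
component σ²_b/C from the CpG mean square; the Wald statistic is
referred to t with D−1 degrees of freedom. This construction was chosen
after simulation showed that the REML fit with a Wald test — the
obvious default — is markedly conservative in this design when the true
variance components are near zero: non-negativity truncation inflates
the intercept SE, and measured type-I error falls to ~0.01–0.02 at
nominal 0.05 (the same behaviour reproduces in lme4/lmerTest). The
moment-based test is exactly t-distributed under a pure-noise null when
the CpG term vanishes, rejects at ~0.034 across simulated null regimes
(no random effects; donor+CpG effects; CpG-only), and has power ~1 for
a 40-point shift at 6 donors × 20 clones. REML (via statsmodels
MixedLM, Wald z) remains available as `method="reml"` for
cross-checking; estimates agree, REML p-values are conservative.

Degenerate inputs are handled explicitly: an all-zero difference table
returns estimate 0, p = 1; a constant non-zero table (zero variance)
and single-CpG tables fall back to the permutation test with a note;
unbalanced tables (donors missing CpG calls) are mean-imputed per CpG
with a warning.

The model-free companion is a donor-level sign-flip permutation: all of
a donor's differences flip jointly (CpG-level flips would break
within-donor correlation). With ≤ 2^20 patterns and n_perm allowing, it
enumerates all 2^D sign assignments and the p-value is exact; otherwise
it samples with add-one correction, deterministic per seed.

Multiple comparisons: each region compares Tcon against three Treg
subsets sharing one Tcon sample, so the family alpha 0.05 is Bonferroni
divided by 3. The reported threshold is floored to three decimals
(0.016, the printed criterion); significance calls use the raw quotient
0.01667 to avoid losing precision.

## Clustering

Cell subtypes are clustered on their donor-averaged per-CpG percent
vectors: Euclidean distances, complete linkage (scipy), which is
monotone, so merge heights never decrease. Rows are sorted by label
before linkage so ties break deterministically by label order; missing
per-CpG averages are mean-imputed with a warning. The merge tree is
exported as Newick with heights as branch lengths (via scikit-bio); a
subtype that joins the final merge alone is reported as the outgroup
(e.g. Tcon against the three Treg subsets under the conventional
pattern).

## Problem sizes and tolerances

The test and acceptance runs use: 200 error-free clones per group for
parameter recovery (binomial 3σ band per CpG around the realized
truth); 2,000 null replicates at 6 donors × 10 CpGs × 20 clones for
type-I error (accepted band 0.03–0.07) and 500 replicates for power
(≥ 0.9 at a 40-point shift); 500 random pairs ≤ 200 nt for
alignment-oracle equivalence; 50 random 4–6 point sets for the
clustering oracle; full 2^6 enumeration for permutation exactness. All
are the package's own choices of scale and are seeded.

## Known limitations

* No chromatogram (AB1) parsing or base-quality model; clones enter as
  FASTA.
* No 5hmC/5mC discrimination — both survive BS treatment as "C".
* The moment-based variance estimator assumes a (near-)balanced
  donor × CpG table; heavily unbalanced designs should prefer
  `method="reml"` or the permutation test.
* Donor-level percentages are treated as the modelling unit; clone-level
  binomial sampling enters only through their variance, not as a
  likelihood.
* The Xi mosaic is a two-profile mixture with a fixed inactive
  fraction; skewed or cell-type-dependent inactivation is not modelled.
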