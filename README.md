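# strandmeth

Strand-resolved analysis of clone-level bisulfite amplicon sequencing,
built for the assay design used to profile CpG methylation of immune
regulatory regions (the *FOXP3* enhancer, promoter, preTSDR and TSDR,
plus *CAMTA1* and *FUT7* regions) across sorted CD4⁺ T-cell populations
— CD34⁺ progenitors, three regulatory T-cell (Treg) subsets
(CD45RA⁺CD15s⁻ naive, CD45RA⁻CD15s⁻, CD45RA⁻CD15s⁺ effector) and
conventional T cells (Tcon).

Bisulfite (BS) treatment converts unmethylated cytosine to uracil (read
as T after PCR) while 5-methylcytosine is protected, and leaves the two
DNA strands non-complementary — so each strand-specific primer pair
amplifies exactly one strand, and methylation can be read *per strand*.
Cloning individual PCR molecules and Sanger-sequencing ~20 clones per
(donor × population × region × strand) group yields one DNA molecule
from one cell per clone. At each CpG,

```
% methylation = 100 · m / (m + u)
```

where `m` clones read C (methylated) and `u` read T (unmethylated);
2 ᵐC out of 20 clones = 10%. Reading the same region from both strands
exposes **hemimethylation** (strand-bias methylation): the headline use
case is the Treg-specific demethylated region (TSDR), where the coding
(genomic bottom) strand can stay 100% methylated in Treg while the top
strand is almost fully demethylated.

The package is aimed at epigenetics groups running (or re-analysing)
clone-based BS assays: it provides the full pipeline as a library plus
a `strandmeth` command-line tool, with a synthetic-data generator in
place of donor sequences.

## What it does

* **Amplicon model & chemistry** (`strandmeth.amplicon`) — CpG
  discovery, strand handling (bottom-strand assays are
  reverse-complemented once at load), stochastic in-silico BS
  conversion with conversion/protection rates, and primer validation
  (no CpG in a footprint, no retained Cs, enough mismatches against
  untreated DNA to be BS-specific).
* **Synthetic data** (`strandmeth.simulate`) — clone-level datasets
  with per-CpG per-strand methylation probabilities, incomplete
  conversion, Sanger-like errors, optional X-inactivation mosaicism,
  canned scenarios (`conventional_male`, `hemimethylated_donor`,
  `xi_female`, `null_pair`) and bit-exact ground truth.
* **Calling** (`strandmeth.calling`) — global affine-gap alignment with
  a bisulfite-asymmetric score (reference C vs read T is a match),
  orientation auto-detection, per-CpG calls, conversion-efficiency QC
  (fraction of non-CpG Cs converted) and methylation matrices.
* **Statistics** (`strandmeth.stats`) — the model

  `diff[d, c] = μ + a_d + b_c + e[d, c]`,

  a crossed random-intercepts model (donor `a_d`, CpG position `b_c`)
  for paired per-(donor, CpG) methylation differences, exposed as
  `PairedMethylationModel.fit() → PairedComparisonResult` with
  `summary()`; donor-level sign-flip permutation as the model-free
  companion; Bonferroni threshold α = 0.05/3 (reported as 0.016);
  hemimethylation index |top% − bottom%|; Euclidean/complete-linkage
  clustering of subtypes with Newick export.

## Worked example

Six synthetic donors with the hemimethylated TSDR pattern (coding
strand fully methylated in every population, top strand demethylated in
Treg), sequenced, called and tested for strand bias in naive Treg:

```python
import strandmeth as sm

configs, amps = sm.make_study("hemimethylated_donor", n_donors=6)
ds = sm.simulate_dataset(configs, amps, seed=42)
matrices, report, _ = sm.call_dataset(ds.clones, ds.sample_sheet, ds.amplicons)

pop = "CD45RA+CD15s-"
top = [m for k, m in matrices.items() if k[1] == pop and k[3] == "top"]
bottom = [m for k, m in matrices.items() if k[1] == pop and k[3] == "bottom"]
res = sm.strand_bias_analysis(top, bottom)
print(round(res.mean_index, 1))
print(res.comparison.summary())
```

prints

```
97.3
Paired methylation comparison
==============================================
contrast:            FOXP3_TSDR CD45RA+CD15s-: top - bottom
method:              mixed_effects
n donors / n CpGs:   6 / 15
mean difference:     -97.33 percentage points
standard error:      0.295
p-value:             4.892e-12
alpha (Bonferroni):  0.016 (raw 0.01667)
significant:         True
```

The mean hemimethylation index of 97.3 percentage points says the two
strands disagree almost completely at every CpG; the mean difference of
−97.33 (top minus bottom) gives the direction — the top strand is the
demethylated one — and the p-value is far below the Bonferroni
threshold of 0.016, so the strand bias is called significant. Per-clone
patterns are available as lollipop tables/text
(`matrices[key].lollipop_text()`, filled = methylated):

```
M1.CD45RApCD15sn.FOXP3_TSDR.top.c001	○○○○○○○○○○○○○○○
M1.CD45RApCD15sn.FOXP3_TSDR.top.c002	○○○●○○○○○○○○○○○
```

The same analysis from the shell:

```bash
strandmeth simulate --scenario hemimethylated_donor --seed 42 --outdir sim/
strandmeth all --reference sim/reference.fasta --clones sim/clones.fasta \
    --sheet sim/sample_sheet.tsv --outdir results/
strandmeth strand-bias --matrices results/matrices.tsv \
    --region FOXP3_TSDR --population "CD45RA+CD15s-" --out-prefix results/tsdr_bias
```

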