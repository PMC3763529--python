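# Methods

## Model and procedure

The package asks, per gene, whether an observed set of *k* point
mutations changed the mRNA's minimum free energy (MFE) less than random
synonymous mutations would. The chain is:

1. **Inputs.** A genome with CDS annotations (GenBank, or FASTA plus a
   1-based gene table), a SNP table (1-based position, ref, alt on the
   forward genomic strand), and an essentiality source: either a label
   TSV for the analysed genome, or a second genome plus labels to be
   transferred by reciprocal best hits.
2. **SNP filtering.** SNPs are classified by interval lookup; only CDS
   SNPs are retained. Intergenic, pseudogene and insertion-element SNPs
   are dropped and counted; SNPs whose reference base disagrees with the
   genome are dropped; all SNPs of a gene are dropped when the annotated
   protein disagrees with the CDS translation or when any SNP hits the
   start codon. Every exclusion is reported per category and per SNP —
   exclusions are never silent and never fatal. A SNP inside two
   overlapping CDSs is assigned to both genes, each analysed
   independently. Genes with ambiguous bases are excluded at read time.
3. **Essentiality transfer.** Local protein alignment (BLOSUM62, affine
   gaps, open 11 / extend 1, all configurable). A pair is orthologous
   iff each gene is the other's unique top-scoring hit and identity
   exceeds 0.75; score ties leave the gene unmapped (conservative).
   Identity is matches over aligned columns including internal gaps;
   local alignment excludes terminal overhangs by construction. Note the
   consequence: a short perfect local hit can reach identity 1.0, which
   is why the reciprocal-best-score requirement, not identity alone,
   carries the orthology decision. An e-value threshold (1e-25) is
   enforced only when an external aligner adapter supplies e-values.
4. **Null family.** All synonymous single-nucleotide variants of the CDS
   are enumerated from the standard codon table; start and stop codons
   are excluded from candidacy (stop-to-stop changes are not treated as
   neutral, since termination context is functional; configurable). A
   family of *k*-substitution mutants is exhaustive when its size is at
   most the cap (default 1000, counted by a distinct-position
   subset-count polynomial), else `cap` distinct members are sampled:
   each substitution draws a strand-symmetric substitution class from
   the target spectrum restricted to classes with available synonymous
   options (uniform by default — free of transition/transversion bias),
   then a uniform (position, alternative) of that class at an unused
   position. Distinctness is enforced with an attempt budget of 50×cap.
5. **Percentile.** |ΔMFE| of the observed mutant versus every family
   member, all folded with one engine. The percentile is the fraction
   of members with strictly smaller |ΔMFE| (default), or with half
   credit for ties (midrank option; see below).
6. **Group comparison.** Essential vs nonessential percentile
   distributions via the Mann–Whitney U test; sign summary of signed
   ΔMFE (decreased/unchanged/increased, zero-band τ = 0 since one
   engine's values are bit-comparable); quartiles by linear
   interpolation between order statistics; synonymous SNP fractions via
   an exact binomial test; ECDF point lists for plotting. No multiple-
   testing adjustment is applied (single planned tests).

## Folding engines

* **`rnafold` adapter** — calls an external ViennaRNA `RNAfold` with the
  lonely-pair prohibition (`--noLP`), parses one MFE per FASTA record,
  and fails loudly if the tool is missing or output is malformed. Tool
  defaults (temperature, dangles) are left untouched. Used for
  full-fidelity analyses.
* **`reference` engine** — an in-package nearest-neighbour model kept
  deliberately simple so it can be verified exhaustively: nested
  structures over {AU, UA, GC, CG, GU, UG}; a pair (i, j) requires
  j−i−1 ≥ 3 (configurable); with `no_lonely_pairs` every helix has at
  least two consecutive pairs; energy is the sum over stacked adjacent
  pairs of −(w₁+w₂)/2 with default weights GC 3.0, AU 2.0, GU 1.0. The
  optimum is computed by a two-matrix dynamic program (pair matrix with
  external-support/no-support split for the lonely-pair rule, segment
  matrix with bifurcation), jit-compiled for speed, and equals a pure-
  Python exhaustive enumeration oracle on every tested sequence. Its
  values are pseudo-kcal/mol: internally consistent and ≤ 0, but not
  calibrated to thermodynamic measurements — the percentile statistic
  only needs a consistent MFE functional. Engine provenance is carried
  on every value and ancestor/mutant comparisons refuse to mix engines.

## Synthetic data and what it shows

`synthetic.generate_catalog` produces random CDSs (start codon, random
sense codons at a target GC, random stop), laid on both strands with
random spacers, with essentiality labels at the *E. coli* K-12 ratio
(620/3746) and optional pseudogene/IS decoy regions.
`plant_observed_mutations` selects 48 essential and 348 nonessential
genes (defaults echoing the analysed data set), draws k per gene from
(0.92, 0.075, 0.005) over {1, 2, 3}, and plants the observed mutation at
rank ⌈qN⌉ of the family's |ΔMFE| ordering with q ~ Beta(1, θ): θ = 1 is
the exact null (uniform quantile), θ > 1 biases toward structure
preservation, with closed-form median 1 − 0.5^{1/θ}. Planting and
pipeline use the same per-gene substream (seed, crc32(gene_id)), so the
pipeline regenerates the identical family and recovery is exact up to
rank discreteness and ties; pass a different pipeline seed to emulate a
"fresh family" with extra noise.

What passing these tests does **not** show: real genomes have codon
usage, operon structure, GC heterogeneity and mutation-rate spectra the
generator does not model, and thermodynamic folding differs from the
reference energies. The synthetic recovery validates the machinery and
its statistics, not the biological effect size.

## Tie handling and the midrank choice

The reference engine's energies live on a half-integer lattice, so null
families contain sizeable |ΔMFE| tie blocks (including many members with
|ΔMFE| = 0). The strict percentile maps any observed value inside a tie
block to the block's lower edge, which biases recovered percentiles
downward (measured over 4 seeds at θ = 2/1: pooled medians 20.0/42.0
against the Beta theory 29.3/50). The midrank variant credits half of
each tied member and is unbiased under ties (measured 31.0/51.1). The
strict rule remains the package default — it is the conservative choice
for real analyses, where an unchanged-MFE observed mutation should not
be credited against the null — while the synthetic recovery
demonstrations and the acceptance script use `ties="midrank"`, the
estimator consistent with the closed-form Beta targets.

## Problem sizes and numerical choices

Pipeline-level demonstrations run at reduced size so they complete in
minutes on one CPU: gene lengths 20–45 codons with family cap 50 for the
θ = 2 recovery (pooled over 3 seeds), 15–30 codons with cap 25 for the
20-seed θ = 3 power run. The generator defaults (50–450 codons,
cap 1000) are unchanged and used for realistic fixtures. Shorter genes
have coarser percentile granularity (1/cap) and larger zero-ΔMFE tie
blocks; the midrank statistic absorbs both.

Other numerical choices: Mann–Whitney is exact by enumeration when
min(n, m) ≤ 8 without ties, else normal approximation with tie and
continuity corrections (an all-identical degenerate input returns
U = nm/2, P = 1); the binomial test's default two-sided convention is
minimum-likelihood with tail-doubling selectable (both are reported by
the acceptance script — the conventions differ in the second decimal);
quartiles use linear interpolation; family members are ordered by
(|ΔMFE|, substitution list) stable sort so planting is deterministic;
per-gene RNG substreams make results independent of gene processing
order; T→U mapping is silent, any other character is an error.

## Known limitations

* Reference-engine energies are not thermodynamic; absolute |ΔMFE|
  magnitudes are not comparable across engines.
* The built-in aligner reports no e-values, so ortholog sets need not
  match a blastp-based mapping exactly near the thresholds.
* Only SNPs are analysed; indels and multi-nucleotide variants are out
  of scope, as are pseudoknots, suboptimal ensembles and explicit
  structure-shape comparison.
* Exhaustive enumeration of k ≥ 2 families is combinatorial; the cap
  keeps it bounded but sampled families then cover a small fraction of
  the space.
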