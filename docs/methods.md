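# Methods

`mirfuse` implements the computational arm of a plant small-RNA study
contrasting maize ovaries with incompletely (IFC) and completely fused
carpels (CFC): read classification, known/isomiR/novel miRNA identification,
differential expression on normalized counts, degradome-based target
calling, and correlation of expression with phytohormone time courses.
This note records the models, conventions and design choices behind each
stage, and what the synthetic-data generator does and does not emulate.

## Read classification

Raw reads are trimmed of their 3' adapter (best suffix-prefix match, at most
10% mismatches, minimum overlap 6 nt) and assigned to exactly one category
by a fixed first-match hierarchy:

    3ADT&length -> junk -> rRNA -> tRNA -> snoRNA -> snRNA -> other Rfam
    -> mRNA -> repeats -> retained

The retained length window defaults to 18-25 nt. Category totals plus valid
reads always sum to the raw total (a partition), and re-classifying retained
output removes nothing.

Two conventions here are package choices rather than community standards:

* **"Junk"** is defined as low complexity: one base making up >=80% of the
  read, a mono-/di-nucleotide repeat covering >=90% of it, or any non-ACGT
  symbol.
* **Contaminant matching** is exact-substring against the category's
  reference sequences, on either strand. This is adequate for 18-25 nt
  reads against curated references and is fully testable; a consequence is
  that the mRNA reference must not contain the antisense target sites of the
  miRNAs under study, or those miRNAs are swallowed by the cascade (the
  generator therefore keeps its mRNA reference separate from the
  target-carrying transcriptome).

## Known miRNA and isomiR identification

Unique retained sequences are placed on database precursors allowing end
shifts of up to 2 nt per end and at most one internal substitution
(positions 2..L-1; differences at the first or last base are treated as end
variation territory and disallowed as substitutions). The best placement
minimizes (mismatches, total end shift, precursor id lexicographically), so
results are independent of database record order. Placements on the arm
opposite the annotated mature, or outside the end-shift envelope, are
arm isoforms.

Variants are named with a suffix grammar in which `L`/`R` tokens describe
5'/3' end shifts and `1ss` a single substitution, e.g. `_L+1` (5' end one
nucleotide longer), `_L-1R-1` (one nucleotide trimmed at each end),
`_R+1_1ss21TA` (3' extension plus a T->A change at position 21 of the
observed read). Substitution positions are 1-based on the observed
sequence. The grammar round-trips: applying the named transformation to the
database mature reproduces the observed sequence, a property enforced by
tests.

Precursor-to-genome placement uses edit-distance alignment (edlib, infix
mode) on both strands, reporting loci with identity >= 90% over >= 95% of
the precursor length.

First-nucleotide composition statistics are computed over *unique*
identified miRNA sequences (not count-weighted); the length histogram is
count-weighted over retained reads.

## Hairpin folding and the eleven criteria

Novel-candidate validation asks whether a read's genomic context folds into
a miRNA-like stem-loop. Folding backends:

* **bundled** (default): a deterministic maximum-pairing dynamic program
  (Nussinov-style; Watson-Crick plus G:U pairs; minimum loop 3 nt) that
  breaks score ties in favour of stacked helices. It reports a pseudo-energy
  `-(0.3 * pairs + 1.5 * stacks)` kcal/mol, calibrated so that genuine
  miRNA-like stems fall well below the -15 kcal/mol criterion while diffuse
  pairing does not. The pair count equals an independent brute-force DP on
  every sequence up to 30 nt (tested). This folder makes the entire
  pipeline reproducible with no external binary; it has no thermodynamic
  ambition.
* **external_mfe**: the `RNAfold` executable (ViennaRNA), when installed.
* Structures may be supplied directly as dot-bracket + energy, so validation
  is backend-independent.

A structure qualifies as a hairpin when it has exactly one terminal loop;
its pairs then form a nested chain. Between consecutive chain pairs, an
internal loop with equal unpaired runs on both strands is a run of
**mismatch errors** (counted per position; two 1:1 loops = 2 errors); an
unequal one is a **biased bulge** whose *size* is the larger side and whose
**biased errors** are the unbalanced positions `|left - right|`. These
terms are package definitions — the upstream literature uses them without
formal definitions. Mature-region metrics count only loops whose unpaired
positions touch the annotated mature interval, clipped to it for the
per-position counts.

The eleven criteria (strict inequalities): bulge in stem < 13 nt; stem
pairs > 15; energy < -15 kcal/mol; hairpin length > 49 nt; terminal loop
< 351 nt; bulge in mature region < 5 nt; biased errors in one mature bulge
< 3; biased bulges in mature < 3; mismatch errors in mature < 5; mature
pairs > 11; mature bases paired > 80%. Criterion 1 is evaluated over the
whole stem and criterion 6 over the mature region only. Enlarging any
single defect can never turn a failing verdict into a passing one
(property-tested).

For novel calling, each unannotated read with a perfect genome match is
extended by 120 nt of flank and folded in two windows (read positioned as
5' arm and as 3' arm). The stem-loop containing the read is extracted from
the folded window: from the terminal loop best overlapping the read, the
pair chain is followed outward while each enclosing pair is the only branch
at its level and is separated from its inner neighbour by at most 12
unpaired nucleotides per strand (matching the stem-bulge criterion); the
candidate precursor is trimmed to the outermost retained pair. A mature
that dangles out of the stem by up to 4 nt in total is kept, with the
dangling bases counted as unpaired. Raw trimming to the outermost pair of
the whole window proved too fragile — distal chance pairs across large
unstructured gaps would absorb genuine hairpins — hence the gap-capped
chain walk.

## Differential expression

Normalized expression: `NE = count / clean_total * 1e6` with no
pseudo-count; per-sample NE sums to one million over all clean reads.
Replicate reproducibility is the Spearman correlation of `log2(NE + 1)`
between replicate vectors over rows with NE > 1 in at least one replicate
(Pearson available).

Fold change is orientation-free: `(max(mean) + eps) / (min(mean) + eps)`
with `eps = 0.01`, so rows with a zero mean (which occur in real summary
tables) stay comparable; direction "up" means higher in IFC. Testing uses
a one-tailed Welch t-test with the tail set by the observed mean
difference. With two replicates per group this test is fragile and
anticonservative; the type-I rate at alpha = 0.05 is bounded at 0.10 in the
test suite rather than 0.05. A row passes when fold change > 1.5, p < 0.05
and its larger condition mean NE > 5; rows enter testing only with
NE > 1 somewhere. Both-groups-constant-and-equal yields p = 1 by
convention. No multiple-testing correction is applied by default, matching
the practice the pipeline reproduces.

The qPCR helper implements the comparative 2^-ddCt method; the calibrator
sample's relative expression is 1 by construction.

## Degradome target calling

Sites are scored with a plant-target penalty scheme: mismatch 1.0, G:U
wobble 0.5, gap 2.0, all doubled at miRNA positions 2-13; alignment is
antiparallel (miRNA 5'->3' against the site read 3'->5') by banded dynamic
programming (band 4). The scheme and the default cutoff (penalty <= 7.0)
follow the plant target-prediction convention. Every transcript window of
miRNA length is scored; reported sites are strict local minima within +-3
nt (leftmost on ties), which collapses the shoulder windows of a single
physical site. The scan equals an independent unbanded recursive scorer on
small transcriptomes (tested).

The cleavage coordinate is 1-based, the first nucleotide of the 3'
cleavage fragment — the position opposite miRNA nucleotide `r` for
register `r` in {9, 10, 11} (canonical 10; for a site starting at `s` with
miRNA length `L`, coordinate `s + L - r`). Both register and coordinate are
reported, since summary tables in this field print the register.

A t-plot counts degradome tag 5' ends per transcript position. Peak
categories: 4 = exactly one read; 0 = unique maximum; 1 = tied maximum;
2 = above the median of covered positions (count >= 1); 3 = at or below it.
The site p-value is the exact binomial upper tail of the peak height under
tags thrown uniformly over transcript positions — chosen for determinism
and testability (a Monte-Carlo multinomial oracle confirms it). Classes:
I = category 0/1 with p <= 0.05; II = category 0/1 with p > 0.05 or any
category 2; III = category 3/4. Category, p and TPB are computed per
condition; a hit's class is the best over covered conditions. TPB is
defined here as tags per billion library tags (the field's tables print the
column without a definition; per-billion matches the printed magnitudes).

## Hormone correlations

Expression of a miRNA or target over both phenotypes x four stages (IFC
stages 0-3 then CFC stages 0-3, n = 8) is Pearson-correlated (two-tailed
default) with the matching hormone series (IAA, ZR+iPA, GA, BR, JA, ABA);
flags are `*` (p < 0.05, critical |r| = 0.7067 at n = 8) and `**`
(p < 0.01). Pair grouping: group 1 = miRNA and target both significant with
opposite signs; group 2 = exactly one significant. The embedded published
correlation table carries flags (e.g. 0.61 starred at n = 8) that are not
reproducible under either tailing at the printed precision; the module
always reports computed flags and never echoes printed ones.

## The synthetic-data generator

The generator emulates the study design: two conditions x two replicates;
a genome carrying validated precursor hairpins (3-nt flanks + mature +
10-15 nt loop + perfect-complement star arm, rejection-sampled until all
eleven criteria pass), a subset withheld from the database to act as novel
miRNAs; a transcriptome with antisense target sites; degradome tags with a
configurable fraction at the true cleavage coordinate (register 10) and the
rest uniform; contaminant fractions shaped like a real maize ovary library
(rRNA 5.5%, mRNA 4.5%, tRNA 2%, ..., relative to the nominal library
depth); a planted 60% 5'-U bias; and hormone panels where expression is a
standardized hormone series plus Gaussian noise of variance `1/r^2 - 1`,
giving a planted correlation of chosen sign and magnitude (exactly +-1 at
r = 1).

Counts are Poisson per (sequence, sample) — the minimal count model, which
keeps planted-fold-change recovery analyzable; planted DE miRNAs have their
mean multiplied by the fold change (default 4) in their high condition.
Each miRNA also emits one isomiR variant (5'/3' end shift or one internal
substitution, 15% of its reads). Degradome tag length is fixed at 20 nt
(MmeI-type libraries). Default problem sizes (12 precursors, 30 kb genome,
10 transcripts of 300 nt, 60k reads/sample, 500 tags/target) are chosen so
the full pipeline runs in seconds; they are scaled-down study conditions,
not tuning knobs.

What the generator does **not** emulate: sequencing error beyond the
planted substitutions, real miRBase families or the real maize genome,
ligation/PCR biases, overdispersed counts, or hormone assay chemistry.
Passing tests therefore demonstrate the correctness of the decision rules
and the recoverability of planted signal under idealized noise — not
performance on real libraries, where dispersion and mapping ambiguity are
harsher.

## Determinism and numerics

Every simulation output is a pure function of the configuration including
its seed (seed sequences derive independent streams per stage); re-running
the pipeline reproduces byte-identical files. Ties are broken
deterministically everywhere (lexicographic precursor ids, smallest DP
split, leftmost site). Undefined statistics (constant series, constant
replicate vectors) signal rather than crash: correlation returns NaN or
raises a typed error; zero-variance equal-mean groups get p = 1.

## Known limitations

* The bundled folder maximizes pairing, not free energy; its pseudo-energies
  are only comparable within this package. Use the ViennaRNA backend for
  thermodynamic work.
* The Welch t-test with n = 2 per group has almost no power control; the
  pipeline reproduces that design faithfully rather than fixing it.
* Exact-substring contaminant matching misses divergent family members; a
  one-mismatch mode would be the first extension for real data.
* Degradome analysis is transcriptome-space only; no genome-space tag
  mapping.
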