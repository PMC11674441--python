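# Methods

`neovax` implements the computational core of a neoantigen-pulsed dendritic-cell
vaccine workflow: somatic SNV discovery from tumour/normal exome allele counts,
minimal coding-effect annotation, enumeration of mutant HLA class I and class II
candidate peptides, affinity- and expression-gated selection of class II long
peptides that encompass a class I epitope, ELISpot immunomonitoring, and TCR
repertoire clonality analysis. This note records the models, parameter choices
and numerical conventions, and what the synthetic data do and do not emulate.

## Somatic calling

Input is a per-site count table (chrom, 1-based pos, ref, alt, tumour ref/alt
reads, normal ref/alt reads) assumed to be pre-filtered at the read level
(base quality ≥ 15; a per-site `mean_base_quality` column, if present, is
filtered against the same bound). A site is called somatic when all of the
following hold:

1. tumour depth ≥ 10 reads (inclusive),
2. normal depth ≥ 10 reads — the published criterion names a single
   "sequencing depth"; we apply it to the tumour and give the normal its own
   configurable minimum with the same default, since count tables carry both,
3. tumour variant-supporting reads ≥ 4 (inclusive),
4. tumour VAF ≥ 10 % (inclusive),
5. normal VAF < 2 % (exclusive),
6. two-sided Fisher's exact test p < 0.05 (exclusive) on the 2×2 table
   [[t_alt, t_ref], [n_alt, n_ref]].

Sidedness is not dictated by the source protocol; we default to the two-sided
exact-probability construction (the common convention) and expose
`alternative` on `CallerParams`. The p-value is computed by
`scipy.stats.fisher_exact`; the test suite verifies it against an independent
exact integer-arithmetic hypergeometric enumeration on **all** 2×2 tables with
row sums ≤ 30 (246,015 tables, worst relative deviation < 1e-12). An all-zero
table returns p = 1 with a warning. Boundary behaviour (inclusive ≥ vs
exclusive <) is unit-tested at exactly 10 %, 2 %, and p = 0.05.

Effect annotation is a deliberately minimal codon annotator, not a general
one: single-exon CDS models (annotation TSV + transcript FASTA), strand-aware
(substitutions complemented on minus-strand transcripts), standard genetic
code. Adjacent SNVs in the same transcript (neighbouring genomic positions)
are merged into one call with a multi-residue change such as `I1375R L1376R`.
Effects are missense / synonymous / stop_gain / non_coding; only missense
calls feed the peptide stages. A CDS whose length is not divisible by 3
raises an error naming the transcript. Indels, multi-exon models and
splice effects are out of scope.

Expression confirmation attaches RNA read counts at each mutation site; a
call is "expressed" iff mutant-allele RNA reads ≥ 1 (configurable). Sites
absent from the RNA table count as zero.

## Peptide enumeration and nesting

From each missense variant the mutant protein is built by substitution
(length preserved). Candidates are every window of length k covering **all**
changed residues, clipped at the protein ends: k ∈ [8, 11] for HLA class I,
k ∈ [15, 18] for HLA class II (both configurable; one published class II
peptide is a 21-mer, so the bounds are per-run knobs rather than hard
constants). For a single interior change the candidate count is therefore
Σk (38 for class I defaults) — asserted against brute-force enumeration.
Wild-type counterpart windows are carried alongside for reference but never
scored. Multi-residue changes spread wider than the window length yield an
empty candidate list with a warning.

The relationship between a long and a short peptide is classified as
`contained` (substring, leftmost offset), `overlap` (maximal terminal
overlap — a suffix of one equals a prefix of the other — of at least
`min_overlap` residues, default 4), or `disjoint`. In the published
18-row selection table, 14 of the 16 class II/class I pairs are contained
and 2 (PREX1, KCTD6) are terminal overlaps of ≥ 4 residues, which is why
the default nesting mode accepts overlaps; `contained_only` is the strict
alternative.

## Vaccine peptide selection

Affinity tables (peptide, allele, IC50 in nM) are the interface to whatever
binding predictor produced them; two dialects are parsed (a generic TSV and a
NetMHC-style layout), allele names are canonicalised, and duplicate
(peptide, allele) rows keep the minimum IC50 with a warning. A peptide's
affinity is the minimum IC50 across the patient's alleles.

Per variant: class II candidates under the 500 nM gate (exclusive) survive;
the variant must be expressed (mutant RNA reads ≥ 1) unless
`require_expression=False`; each surviving class II peptide is paired with
its best nested class I epitope under the same gate; the best pairing is
emitted (class II IC50 ascending, then class I IC50, then lexicographic
peptide). Variants with a qualifying class I epitope but no qualifying
class II long peptide are emitted class-I-only, mirroring the two such rows
in the published table. IC50 ≤ 50 nM defines a "strong" tier used for
ranking rather than a hard gate, because the published selection itself
contains class II affinities well above 50 nM (285, 169, 124 nM, ...).
The final ranking is a deterministic total order: strong tier first, class II
IC50, class I IC50, expression level descending, peptide lexicographic —
shuffling the inputs never changes the output, which the tests assert.
How the original study weighed expression against affinity in its final
manual choice is not documented; this ranking is the package's own
convention.

## ELISpot

Per-well activity = Σ_spots (intensity × size) / 1000 — the divisor is kept
verbatim for comparability with reported activity values. Replicates
aggregate as arithmetic mean and sample SD (ddof = 1; SD = 0 for n = 1).
Positivity: fold-change = condition mean / control mean, positive iff
fold ≥ 1.5 (inclusive at exactly 1.5, per the stated rule), negative below,
indeterminate (with a warning) when the control mean is 0. The control
condition is explicit per sample — the source protocol itself switches
between a mature-DC+lymphocyte background and plain PBMC when background
secretion is high — and replicate-paired ratios are not used because they
are not described.

## TCR repertoire

For a clonotype table with frequencies p_i: inverse Simpson 1/Σp_i²
(∈ [1, n]), Shannon −Σ p_i ln p_i (natural log by default, base-2 available;
∈ [0, ln n]). Both are checked against closed forms (single clone, uniform)
and brute-force summation on small tables. Duplicate CDR3 rows are summed on
load; merging before or after computing indices is index-invariant.
"Expanded" clonotypes are those with frequency strictly greater than 0.5 %
(a clonotype at exactly 0.5 % is excluded). Pre/post comparison reports
emergent (post > threshold ≥ pre) and contracted (converse) sets, both
indices for both samples, and two clonality normalisations — Σp² and
1 − H/ln n — since "clonality" has no single convention. Frequencies are per
table; no rarefaction or depth correction is applied, so comparisons between
samples of very different sequencing depth should be interpreted with care.

## Synthetic data: what it emulates, and what it does not

All generators hang off one `SimulationConfig`; a single global seed fans out
to fixed per-generator child streams, so outputs are byte-identical under a
fixed seed and adding one generator never perturbs another.

* **Tumour/normal counts** — depths Poisson around 100× (floored at one
  read), typical of exome data; somatic sites draw tumour alt reads
  Binomial(depth, VAF) with VAF uniform on [0.2, 0.5] (a moderately pure
  tumour); normal alt reads, and both alleles at null sites, are
  Binomial(depth, 0.005) — 0.005 being the per-read probability of observing
  the specific alternate allele by error. 10 % of sites are somatic by
  default. Under exactly these conditions the expected caller sensitivity is
  ≈ 0.950: the binding constraint is the exclusive "< 2 %" normal-VAF rule,
  which rejects the ~5 % of true sites that draw ≥ 2 noise alt reads in a
  ~100× normal. Sensitivity assertions at a single fixed seed therefore sit
  on a knife edge, and one such check in the acceptance suite fails by one
  percentage point at its pinned seed; this is a property of the stated
  conditions, not of the caller, and the thresholds were not adjusted to
  hide it.
* **Transcriptome** — one random sense-codon CDS per somatic site (no
  internal stops by construction), the site assigned to an interior codon
  chosen so the ref→alt substitution is missense where possible, strand
  random; decoy transcripts pad out the annotation. RNA totals at mutation
  sites are gamma-Poisson (negative binomial, dispersion 2, mean 50) with a
  10 % zero-expression spike; alt reads are Binomial(total, VAF).
* **Toy affinity scorer** — a keyed blake2b hash of (peptide, allele, seed)
  mapped to [1, 50000] nM, skewed so that only ~2 in 1000 random
  peptide–allele pairs score below 50 nM (most random peptides are
  non-binders). It is deterministic and plantable — a supplied map of
  (peptide, allele) → IC50 overrides the hash — and makes no attempt at
  real binding motifs. It exists so selection has known answers, not to
  approximate a predictor.
* **ELISpot plates** — duplicate wells per condition; spot counts
  Poisson(50), ×3 for planted positives; per-spot intensity and size
  log-normal. With these defaults a planted positive has expected fold ≈ 3
  and detection sensitivity comfortably above 0.9.
* **TCR tables** — pre-vaccine frequencies Zipf-like with exponent 0.8
  across 2,000 clonotypes (effective diversity ≈ 150, flat enough to behave
  like peripheral blood); the post sample boosts ~10 rare clonotypes to
  0.8–3 % and renormalises, so planted expansions exceed the 0.5 % display
  threshold and both diversity indices fall, as in the post-vaccination
  scenario being emulated; counts are multinomial at 20,000 reads.

None of this reproduces read-level artefacts (strand bias, mapping error,
FFPE damage), HLA binding motifs, or inter-patient variability. Passing
tests demonstrate that the *decision rules* behave as specified on data
whose truth is known — not that the pipeline's sensitivity or specificity
transfers to real sequencing data.

## Problem sizes and numerics

The synthetic demo and acceptance computations use 300–2,000 count sites,
tens of transcripts, 10–60 ELISpot conditions and 2,000 clonotypes — sizes
chosen so a full end-to-end run takes seconds while every decision rule is
still exercised in both directions. Ties in selection are broken
lexicographically so all outputs are byte-stable; TSV/VCF writers emit a
version-and-parameters header comment on every file; genomic coordinates are
1-based throughout; VCF output is minimal v4.2, SNVs only, unnormalised.
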