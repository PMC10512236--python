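# Methods

This note records the models, conventions and design choices behind
`tyhybrid`, in the order the pipeline runs them.

## Reference construction

A Ty family's reference is built from the annotated copies in one genome
assembly. Only full-length elements — an internal record flanked by two
LTR records sharing an element id — contribute. Copies are extracted
oriented (minus-strand records reverse-complemented) and sorted by
(contig, start) so every downstream tie-break is deterministic.

**Consensus.** Given an alignment of the copies, each column's consensus
base is the unique most frequent non-gap character whose frequency among
non-gap characters is ≥ 0.5 (configurable). A tie for the top frequency
is ambiguous and yields N, even at exactly the threshold — conservative
and deterministic. Columns gapped in every sequence are dropped.
Producing the alignment is the caller's concern; the bundled center-star
aligner (`tyhybrid.msa`) handles the small, closely related copy sets
that arise in practice and in tests, and treats equal-length inputs as
already columnwise comparable.

**Representative.** The copy with the highest Smith–Waterman score
against the consensus is the reference, with BLASTN-like scoring
(match +2, mismatch −3, gap open −5, extend −2; N scores as a mismatch
so ambiguous consensus positions reward no candidate). Ties fall back to
genomic order. A brute-force all-pairs scorer backs this in tests.

**ORFs.** On the canonical layout 5′LTR + internal + 3′LTR, GAG is the
longest ORF (ATG to stop, ≥ 300 nt) starting within 100 bp of the 5′ LTR
end; POL is the longest ORF in a different frame that overlaps GAG's 3′
portion and ends upstream of the 3′ LTR. In canonical full-length
elements the GAG start codon sits 40 bp upstream of the 5′ LTR end and
the POL stop 25 bp upstream of the 3′ LTR. A family without a qualifying
GAG (the Ty5-like case) is recorded as POL-only, not an error.

## Hybrid references

Masking is annotation-driven: every annotated Ty interval — full-length
parts and solo LTRs alike — is replaced by Ns, so no chromosomal copy
(and no spuriously transcribed solo LTR) can attract reads. Masking
preserves lengths and is idempotent. The two masked parents are
concatenated with species-tagged contig names, and one entry per family
is appended:

* `three_prime` — internal + 3′ LTR in one pseudo-chromosome, so 3′-end
  pairs anchored in the internal sequence may extend into the LTR. The
  3′ LTR copy of the representative element is used (which LTR instance
  to take is otherwise arbitrary).
* `separate` — internal and LTR as distinct entries.
* `five_prime` — 5′ LTR + internal, carrying GAG/POL CDS sub-features
  for ribosome profiling.

All features carry `transcript_id`; GTF/GFF3 emission converts the
internal 0-based half-open coordinates to 1-based closed.

## Synthetic data

The generator emulates the study system rather than idealized data: two
parental genomes (two contigs each) with ~40 single-exon CDS genes,
full-length Ty elements and solo LTRs of several families, defaults
Ty1 (both parents, 2 full + 2 solo), Ty3 (both), Tsu4 (parent 2 only)
and a GAG-less Ty5-like family — echoing a cross in which one parent
carries families the other lacks. Orthologous families differ at a
configurable substitution fraction (default 0.10, ~90% identity, the
regime where cross-mapping is measurable but mapping mostly specific);
within-parent copies diverge at 0.02, with copy 0 exact so the
representative choice has a known answer.

Elements are planted constructively: POL's codons are written first in
its own frame, then GAG's, with base-level repair in the 38-bp overlap so
both frames satisfy their start/stop/non-stop constraints jointly; stop
codons are planted immediately upstream of each ORF start so no earlier
in-frame ATG can extend an ORF past its planted coordinates. Ortholog
and copy divergence use a constrained mutator that skips substitutions
which would break an ORF. Truth is asserted at generation time by direct
codon scanning — never by calling the annotator it is meant to test.

Counts are NB draws with Var = μ + αμ² (α = 0 → Poisson); the default
replicate dispersion is 0.05. Hybrid samples express both subgenomes,
with per-family hybrid/parent fold changes. Reads are emitted pre-aligned
(ground-truth SAM; alignment itself is out of scope) plus FASTQ:

* 3′-end pairs: fragment ends decay geometrically (p = 0.005) from the
  transcript 3′ end — mimicking the alternative-polyadenylation spread
  seen in real 3′-end libraries — with a poly-T signature ("TT" start) on
  a configurable 80% of pairs;
* reverse-stranded pairs: uniform fragments, read 2 sense to the
  transcript (read 1 antisense) — the `strandSpecific=2` convention;
* mRNA single-end: uniform 50-mers;
* RPF: lengths 27–32 (default offsets {27:11, 28:12, 29:12, 30:12,
  31:13, 32:13}), 5′ end = codon start − offset, with 8-fold elevated
  occupancy of the initiation codon so the start-codon metagene has the
  peak offsets are read from. Ty RPF codons come from the planted
  GAG/POL frames.

A `crossmap_rate` fraction of reads from families with an ortholog is
placed on the cognate pseudo-chromosome at the same offset. Every read
appears in the truth table exactly once. All randomness derives from
per-stage streams keyed by (seed, crc32(label)), so adding a stage never
perturbs earlier draws and equal seeds give byte-identical output.

What the generator does **not** emulate: sequencing errors (off by
default), PCR duplicates, introns, alignment ambiguity beyond the
configured cross-mapping, and correlated replicate effects. Passing tests
therefore demonstrate correctness of the pipeline's logic and statistics
under the stated model, not robustness to aligner artifacts or real
library noise.

## Counting conventions

Counting is fragment-level: a properly paired pair is one fragment whose
interval spans both mates, whose length is the template length, and whose
orientation is the second mate's (matching the reverse-stranded
definition above); single-end reads are their own fragments. Overlap
means ≥ 1 base. Fragments shorter than 5 are excluded. A fragment
overlapping n features contributes 1/n to each under fractional mode and
nothing under drop mode. Secondary alignments are removed first. In the
3′-end dialect only pairs whose first-in-pair mate starts inside an
internal interval are Ty-assignable (the flag-67 rule); the mate may
extend into the 3′ LTR, and pairs wholly within LTR-only features are
excluded. TPM is 10⁶·(c_i/L_i)/Σ(c_j/L_j). Coverage z-scores standardize
mean depth in 75-bp non-overlapping windows; the trailing partial window
is dropped, and zero variance yields all-zero scores.

## Cross-mapping

Windowed identity splits an interspecific alignment into 100-bp windows
of alignment columns; per window and interspecific pair, identity counts
mismatches only over columns where both sequences have a base (indels
ignored), and the window value averages over pairs. Rates are estimated
from parental libraries — rate[X→Y] = cognate/(own + cognate), replicates
pooled by summing before dividing to stabilize small counts — and
correction inflates the donor per sample on raw counts:
adjusted = observed × (1 + rate). Note the linear rule restores
N(1 − r²), not N exactly: at r = 0.08 the residual is 0.64% of the
family's reads. The exclusion rule flags a family whose cognate is ≥
5-fold more expressed while the cognate→family rate is ≥ 0.05 — the
contamination-dominated situation in which the family's own signal cannot
be separated.

## Differential expression

Size factors, design matrices, dispersion and the Wald test are as in the
README's model statement. Implementation details that matter:

* medians use the midpoint mean on even counts; features containing any
  zero are excluded from the size-factor reference set;
* dispersion is a method-of-moments estimate taken **within design
  cells** (samples sharing a design-matrix row) and pooled — the marginal
  variance would absorb true group effects into α and destroy power —
  then moderated toward the cross-feature median with 10 pseudo-degrees
  of freedom. No mean-dispersion trend is fitted and no empirical-Bayes
  machinery beyond that single pull; with fewer than 3 residual degrees
  of freedom a flat 0.1 is used;
* IRLS runs to relative tolerance 1e-8, at most 100 iterations, with the
  linear predictor clipped to ±30; non-convergent or all-zero features
  carry missing p and are excluded from the BH denominator;
* no independent filtering and no fold-change shrinkage in expression
  contrasts; the translation-efficiency test offers an optional
  normal-prior ridge on the interaction coefficient (prior variance from
  the spread of unshrunk estimates), off by default;
* per-temperature or per-subset analyses recompute size factors within
  the subset.

Contrast orchestration subsets samples to {hybrid, focal parent} and
features to the focal subgenome, requires ≥ 2 replicates per level, and
reports its own enumeration of comparisons rather than assuming a fixed
count.

## Ribosome profiling

CDS starts are padded 50 nt upstream (clamped at zero) to create 5′ UTRs
the offset search can see. Per read length, the offset is the argmax of
the metagene histogram of (start codon − 5′ end) restricted to 5′ ends in
[start − 40, start + 20]; lengths outside 27–32 are discarded, and all
accepted lengths are retained regardless of phasing (phasing fractions
are reported, not filtered on). Phasing is the dominant-frame share of
offset-corrected 5′ ends within CDS intervals, skipping positions claimed
by overlapping ORFs (the GAG/POL frameshift region has no unique frame).
RPF reads are counted at their P-site, mRNA reads at their central
position, restricted to full CDS, the first 60 coding nt (an initiation
proxy), or the POL-specific interval from the GAG stop to the POL stop
(for a GAG-less family, its whole ORF); mRNA central-position counting
uses unpadded CDS intervals. Frameshift-rate estimation is deliberately
out of scope.

## Problem sizes and tolerances

The bundled tests and the acceptance script run on deliberately small
instances chosen to make every property measurable in seconds: genomes
with ~10–40 genes and families of 1–2 full-length copies at internal
length 2.6–5.2 kb; counting checks on ~25k fragments; rate recovery on
50k reads (3σ binomial tolerances); FDR and recovery simulations with
20 seeds at 41–1000 features. Determinism checks compare output tables
byte for byte. Known limitations: per-copy (locus-resolved)
quantification is out of scope by design; the NB machinery is not a
DESeq2 replica (no Cook's outlier handling, no dispersion trend, no
apeglm), which mainly costs power at very small replicate numbers; and
the scalar cross-mapping correction is first-order, as noted above.
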