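# Methods

`neuromine` models the standard maturation biology of secreted neuropeptide
precursors and the downstream analyses a transcriptome-mining study performs
on them. This note records the model, the defaults, the numerical choices,
and what the synthetic data can and cannot tell you about real assemblies.

## Precursor model

A precursor (prepro-peptide) is treated as

    signal peptide | peptide [G] site | peptide [G] site | ... | peptide

* **Cleavage.** Prohormone convertases cut immediately C-terminal to a basic
  site motif. The default grammar is dibasic-only — KR, RK, KK, RR — because
  enabling monobasic R by default would split real peptides with internal
  arginines (several allatostatin-A and orcokinin peptides carry a lone R or
  GR). Monobasic R is an explicit opt-in for the families that use it
  (myosuppressin-type precursors). Scanning is left-to-right and
  non-overlapping: in a run like `KRR` the leftmost motif wins and scanning
  resumes after it. This is a deterministic convention, not a thermodynamic
  claim; it matches how overlapping basics are conventionally annotated.
* **Trimming.** Carboxypeptidase removal takes off exactly the matched motif
  residues — never peptide-intrinsic basics, so a mature tachykinin keeps its
  own terminal R.
* **Amidation.** A glycine exposed at the new C-terminus after trimming (or
  at the precursor terminus) is the amide donor: it is removed and the
  peptide flagged amidated. A consequence worth knowing: an *unamidated*
  peptide that genuinely ends in glycine is indistinguishable from an
  amidated one in this model; the synthetic generator refuses to build such
  precursors rather than silently producing an unrecoverable truth.
* **Pyroglutamate.** N-terminal glutamine is flagged as a pyroglutamate
  candidate but never edited, because both the Q-inclusive and Q-cyclised
  spellings circulate in the literature for the same peptide (corazonin).

Raw segments keep their trailing site motif and trimmed sequences drop it,
so both of the printed conventions (orcokinin rows with trailing KR/KK/RR,
allatostatin rows without) are reproducible from the same objects.

## Signal peptides

Signal peptides are inputs to the biology, not a contribution of this
package, so the recommended mode for real data is an external annotation
table (e.g. from a dedicated predictor). The built-in heuristic is a
von-Heijne-style rule: a cleavage point after residue L (8 ≤ L ≤ 45)
qualifies if the residues at −1 and −3 are small (A/G/S/C/T) and a 6-residue
window upstream of −3 has mean Kyte–Doolittle hydrophobicity > 1.6; the most
hydrophobic qualifying core wins, ties to the shortest signal; proteins
under 15 aa are not called. It resolves the synthetic signals exactly by
construction (Met + Ile core + A-F-A box) and should be trusted on real
sequences only as a rough screen.

## ORF calling

All six frames are scanned with the standard genetic code; ATG is the only
start. Besides complete ATG→stop ORFs, three partial classes are reported
(N-truncated leading segments, stop-less ATG-initiated tails, fully open
frames) because fragmented de novo assemblies routinely truncate
precursors. Within a stop-bounded segment the complete ORF starts at the
*first* Met (the longest candidate); precursor selection takes the longest
ORF, breaking ties complete-before-partial, then by frame order and
position. Codons containing N translate to X and terminate extension.
Note the consequence: a transcript whose 5′ UTR lacks an in-frame stop
yields an edge-truncated ORF longer than the true complete one, and the
longest-ORF rule picks it; the complete ORF is still reported alongside.
Pipeline runs therefore apply a margin policy on top of the bare rule: the
longest *complete* ORF is preferred whenever it reaches 80% of the longest
call, because start/stop evidence outweighs a residue or two of headless
open frame (short UTR-less transcripts routinely have a stop-free reverse
strand), while a genuinely longer partial precursor — the fragmented-assembly
case this class exists for — still wins.

## Family classification

Three evidence channels with fixed precedence motif > scaffold > keyword;
all are data-driven (YAML under `neuromine/data/`), so adding a family is a
config edit. Motif ties resolve to the pattern with more literal residues
(e.g. a 10-mer ending in `GHMRF-amide` is a sulfakinin, not merely an
RF-amide); scaffold ties resolve to the nearest length-range midpoint, with
the ambiguity retained in the assignment. The orcokinin motif is implemented
as `^NFDEID`, taken from the peptides themselves; the figure-style string
"NFDEIRDRxGFGFx" is treated as a typo since no printed peptide contains
"NFDEIRDR". Keyword mining is case-insensitive substring search over the
best-hit description, with a curator-comment fallback for records whose
best hit is an uninformative "hypothetical protein"; descriptions matching
only the generic term "hormone" are binned as `unassigned_hormone`.

## Conservation

Pairwise Needleman–Wunsch with match +1, mismatch 0, gap −1 and a fixed
traceback preference (diagonal > up > left). For the near-identical,
equal-length peptide sets this package targets, no gaps arise and identity
counts are parameter-independent; the binary identity model is deliberate —
a substitution matrix would not change any reported count. Consensus motifs
use strict invariance: a column is a residue only when all members agree,
else X, with an `amide` suffix only when every member is amidated. Unequal
lengths are handled by aligning members against a modal-length reference;
members more than 5 residues off the mode are rejected by name.

Distance matrices are p-distances (1 − identity/100); trees are Saitou–Nei
neighbor joining via scikit-bio, negative branch lengths clamped to zero.
NJ is exact on additive matrices, which the tests verify against closed-form
three-taxon formulas and four-point-condition brute force.

## Expression

RPKM = counts × 10⁹ / (length_nt × lib_size). The tissue contrast is a
one-way ANOVA on untransformed RPKM with the two pooled-sex libraries per
tissue as replicates (n = 2 vs 2, equivalent to the pooled two-sided
t-test); α = 0.05; no multiple-testing correction. A log2(x+1) option
exists and is off by default, mirroring the study design this reproduces.
Sex contrasts (n = 1 per group) are refused rather than computed.

**Power ceiling of the n = 2 design.** With two observations per group the
pooled SD scales with the group means, so for large fold changes the
t-statistic converges to √2/(CV·√χ²₁), independent of the fold. At the
generator's default dispersion 0.1 (CV ≈ 0.32 at high counts) detection
power is therefore capped near P(χ²₁ < 2/(0.1·t²crit)) ≈ 0.70 at α = 0.05,
no matter how large the enrichment — the acceptance suite measures 0.68 at
20-fold and the corresponding ≥95%-power check fails by design of the
conditions, not by implementation error. Reaching 95% power at n = 2 needs
dispersion ≤ ~0.03 or the variance-stabilising log transform. The null
false-positive rate, by contrast, is well calibrated (measured ≈ 0.05).

## Synthetic data

The generator emulates: prepro architecture (signal, dibasic linkers,
amidation glycines, multi-copy repertoires), synonymous-codon transcripts
with random UTRs, and negative-binomial counts (var = μ + 0.1·μ²) for four
libraries at 45 million reads each — scaled down 100× in the test suite,
which leaves all rate estimates unchanged since RPKM is depth-normalised.
It does **not** emulate: assembly artifacts (chimeras, redundant contigs),
sequencing error, unannotated splice variation, signal peptides that break
the (−3,−1) rule, or convertase-site context effects (P′ positions,
proline inhibition). Passing tests therefore demonstrate correctness of the
processing logic under the stated model, not predictive accuracy on
arbitrary real precursors.

## Degenerate inputs and tie-breaks (summary)

* empty FASTA records, duplicate IDs → format error naming the record;
* transcripts < 3 nt → no ORFs; proteins < 15 aa → no signal call;
* adjacent cleavage sites → empty segments dropped; segments that are pure
  linker material are skipped, not errors;
* trimming that would empty a peptide → degenerate-segment error;
* all-equal distance matrices → star-like NJ tree, total length preserved;
* zero-variance equal-mean contrast → p = 1; zero-variance unequal → p = 0.

## Problem sizes

The worked examples are desk-scale: precursors of 22/13/3/11/7/2 peptides,
a 37-transcript annotation table, 2×2 expression designs. Calibration
simulations use 200–600 transcripts at 0.45–4.5 million reads per library.
Everything runs in seconds on one CPU.
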