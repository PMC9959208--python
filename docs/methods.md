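# Methods

`venomest` re-implements, as a reusable library, the standard analysis of a
spider venom-gland cDNA/EST study: quality control of single-pass cDNA
reads, homology-based functional categorisation, greedy clustering into
contigs, segmentation of toxin precursors, cysteine-framework and family
classification, and a MALDI-TOF peptide-mass census. Every stage is
exercised end to end against a synthetic library generator that carries
per-read ground truth.

## EST quality control

A read qualifies as a high-quality EST when its raw length is strictly
greater than 300 nt (a 301-nt insert is the shortest kept). Reads with
characters outside A/C/G/T/N are rejected outright; reads with more than 5%
N are rejected because percent-identity clustering is meaningless on
N-rich sequence (threshold configurable). Library-derived clones carry a 3'
poly-A tail; detection scans from the 3' end for the longest terminal run
of A containing at most one non-A base, ignores runs shorter than 10 nt,
and iterates trimming to a fixpoint so that re-detection on a trimmed read
always returns zero. The poly-A parameters are defaults, not biology: real
tail lengths vary widely, and both the run length and the mismatch budget
are exposed in configuration.

## Translated homology categorisation

Each trimmed EST is translated in all six frames (BLAST frame convention,
standard genetic code); every stop-free run of at least 30 codons is a
candidate ORF — 30 codons being roughly the shortest plausible secreted
toxin precursor region. All ORFs are searched against two bundled protein
panels by Smith–Waterman local alignment (BLOSUM62; gap open 11, charged on
the first gapped column; extension 1). The search spans all ORFs, not just
the longest, because the longest stop-free run in a short cDNA frequently
straddles the untranslated region in the wrong frame. A hit passing 40%
identity over aligned columns *and* 50% query coverage decides the category
(toxin-like or cellular, the toxin panel winning score ties); otherwise the
EST is non-matched. The thresholds are deliberately permissive, in the
spirit of a default-parameter BLAST annotation, and are configuration
values rather than claims about any particular study.

Alignment is delegated to `biotite`'s C-backed `align_optimal`; the test
suite verifies score equality against an independent naive O(nm) affine
dynamic program on hundreds of random pairs. A shared amino-acid 4-mer
prescreen skips subject sequences that cannot be homologous; it is exact
for the identity levels this pipeline cares about and can be disabled.

## Clustering into contigs

ESTs within one category are clustered by single-linkage agglomeration:
two reads are linked when their best local nucleotide alignment spans at
least 100 columns at 96% identity or better. The partition produced equals
the connected components of the pairwise similarity graph (verified
against a brute-force graph oracle on small instances). Reads are processed
longest-first with lexicographic tie-breaks, which fixes cluster numbering
and consensus anchoring across runs and platforms. Consensus sequences are
majority-vote columns of a seed-anchored alignment, ties resolved
alphabetically.

Two exact-k-mer prescreens keep the quadratic scan tractable: a global
16-mer index proposes candidate clusters, and a member-level shared-k-mer
*count* bound skips alignments that cannot reach the thresholds (any
alignment of L columns with m non-matching columns contains at least
(L − m) − (m+1)(k−1) distinct shared k-mers). The bound assumes
non-repetitive sequence; heavily repetitive reads could in principle share
fewer distinct k-mers and be missed, which is a known limitation — poly-A
tails, the dominant repeat in this data, are trimmed before clustering.

Within a cluster, a "unique gene" is a distinct coding nucleotide string
and a "protein" is a distinct translated precursor; both tallies are
emitted because silent substitutions collapse at the protein level only.
Cluster sizes are binned as 1 (singleton), 2–5, 6–10, 11–15, 16–30, >30,
and the clustering proportion of a category is
100·(N − singletons)/N, rounded half-up to two decimals (all reported
percentages use half-up rounding).

## Precursor segmentation

Secreted toxin precursors are signal peptide → optional propeptide →
mature peptide.

*Signal peptide.* The cleavage site is called by a heuristic with the two
classic ingredients of signal-peptidase sites: a hydrophobic core and
small residues at the −1/−3 positions. Candidate positions 15–35 are
scored by mean Kyte–Doolittle hydropathy of the eight residues preceding
position −5; a candidate needs that mean ≥ 1.5 and A/G/S/C/T at −1 and
−3; the best-scoring site wins (earlier on ties). Sequences not starting
with methionine are flagged N-terminally partial. The heuristic is
pluggable so a trained predictor can be swapped in.

*Propeptide.* Cleavage follows the processing quadruplet motif (PQM): a
four-residue window ending in arginine with at least one glutamate in its
first three positions, cleavage after the arginine. Because propeptides
are removed before the disulfide-rich mature domain, only sites preceding
the first cysteine are considered, and when several qualify the last one
wins. This operationalisation of the motif is a documented stand-in — the
motif family is described in the processing literature at varying levels
of strictness — and the rule is configurable.

*Amidation.* A C-terminal -G, -GK or -GGK on the pre-processing mature
region signals conversion of the glycine to a C-terminal amide: at most
one trailing lysine is stripped, then one terminal glycine, setting the
amidated flag. Amidation subtracts 0.984016 Da (monoisotopic).

Toxins are named `<prefix>-<serial>` in input order, with `-P` appended
for N-terminally partial sequences and `-T` for transcriptome-derived
ones.

## Cysteine frameworks and families

The framework of a mature peptide is its ordered cysteine positions
written C1…Cn, hyphen-separated except that immediately adjacent
cysteines are concatenated ("C3C4"). Parsing and serialisation round-trip
exactly. Frameworks index a catalogue of disulfide scaffolds whose
connectivities are assigned by similarity to characterised folds, never
predicted de novo: the six-cysteine inhibitor cystine knot
(C1-C4, C2-C5, C3-C6), its eight-cysteine extension
(C1-C4, C2-C5, C3-C8, C6-C7), a ten-cysteine scaffold
(C1-C4, C2-C5, C3-C7, C6-C9, C8-C10), a fourteen-cysteine scaffold
(C1-C5, C2-C6, C3-C10, C4-C9, C7-C8, C11-C12, C13-C14), an
eight-cysteine non-adjacent scaffold (C1-C4, C2-C8, C3-C7, C5-C6), the
disulfide-directed hairpin (C1-C3, C2-C5, C4-C6) and the Kunitz fold
(C1-C6, C2-C4, C3-C5). DDH and Kunitz share the same framework pattern
(six non-adjacent cysteines), so pattern lookup alone cannot separate
them; `assign_scaffold` takes an optional motif hint and otherwise returns
the first catalogue match. Frameworks matching nothing stay unassigned
rather than guessed.

Families A–K are assigned from framework compatibility plus homology:
candidate templates are those whose framework matches exactly or exceeds
the query by one cysteine (tolerating natural single-site cysteine
losses); the winner is the candidate with the highest mature-peptide
identity at ≥ 60% (with ≥ 60% coverage, so short spurious local
alignments cannot decide). Cysteine-containing peptides with no
qualifying candidate fall into the low-homology catch-all family K;
cysteine-poor queries stay unassigned. Because families D–G and J share
the eight-cysteine ICK framework, the family boundary is carried entirely
by the template exemplars — the bundled templates are synthetic sequences
constructed for separability (pairwise cross-family mature identity well
below the threshold), and users supply their own exemplars for real data.

After clustering, each toxin contig's consensus is translated and
classified the same way, and member ESTs inherit the contig-level family:
majority-vote consensus columns cancel independent per-read substitutions,
which is precisely why assemblers build consensus before annotation.
Single-read classifications are kept for singletons.

## Peptide masses and the MALDI census

Neutral masses follow the additive formula: sum of residue masses plus
water, minus 2 × 1.007825 Da per disulfide, minus 0.984016 Da if amidated
(average-mass analogues likewise). The residue tables are frozen in the
package; the test suite checks them against independent atomic-composition
summation. When a mature peptide's disulfide count is not known from a
scaffold assignment, all cysteines are assumed paired (n/2 bonds), the
default state of secreted cysteine-rich toxins.

Peak lists are plain delimited text (fraction id, m/z). The census keeps
peaks in the 1–10 kDa window — below it matrix-cluster ions dominate,
above it proteins rather than peptides elute — then sorts and greedily
merges peaks within 0.5 Da of a species' running mean. Sorting first makes
the species count invariant under input permutation, and the count is
non-increasing in the tolerance. 0.5 Da is a reflectron-scale default; no
merge tolerance is claimed for any particular instrument. Species are
matched against predicted mature masses trying both monoisotopic and
average values, with an optional proton correction when peak lists are
[M+H]+.

## The synthetic generator

The generator emulates the structure of a venom-gland cDNA library, not
any particular organism's sequences:

* **Genes.** Toxin genes are drawn from the bundled family templates:
  the signal peptide, the first eight post-signal residues, the PQM, the
  mature terminus and all cysteines stay fixed; other propeptide/mature
  positions mutate at 12% from a cysteine- and arginine-free alphabet, so
  the framework, processing sites and amidation signal survive
  diversification by construction. Cellular genes are 10%-mutated copies
  of eight invented housekeeping-like proteins. Non-matched genes are
  uniform random nucleotide sequences, rejection-sampled against the
  panels so the class has no homology hit by construction.
* **cDNAs.** One cDNA per gene: ATG-initiated CDS with uniformly drawn
  synonymous codons, stop codon, random 3'UTR of 180–320 nt (long enough
  that every clean clone passes the 300-nt cutoff), poly-A of 15–40 nt.
* **Copy numbers.** Within each category, gene ranks get weights
  rank^(−1.3) apportioned deterministically to the category's EST total
  (defaults 1020 toxin / 650 cellular / 330 non-matched ESTs over
  60/100/40 genes ≈ 2000 ESTs at the reference study's ~51/32/16 category
  split), counts forced monotone in rank. Family letters are drawn with
  weights proportional to the study's family sizes (family E heaviest).
* **Noise.** Per-copy uniform base substitutions (default 0.5%, the scale
  of single-pass Sanger error) and 5'-only truncation (default
  probability 8%, removing 10–40% of the read) — matching the observed
  artefact classes: N-terminally truncated partial sequences, no indels.
  Indel robustness is out of scope, which keeps clustering behaviour
  analysable.
* **Peaks.** Each distinct true mature species is spotted into one or two
  of 51 simulated HPLC fractions at its computed monoisotopic mass.

What passing tests show — and what they do not: recovery is measured
against a generator whose precursors are built to satisfy the package's
own segmentation rules, so 100% clean recovery demonstrates internal
consistency and correct plumbing of every stage, not that the signal/PQM
heuristics match experimental cleavage sites on real venom data. Real
libraries add vector contamination, chimeras, indels and base-quality
structure that the generator deliberately omits.

## Numerical and determinism choices

All percentages round half-up at two decimals. All randomness flows from a
single integer seed through explicit `random.Random` instances; identical
configuration and seed give byte-identical FASTA, truth tables and
reports. Coordinates are 0-based half-open throughout. Cluster consensus
ties break alphabetically; signal-site score ties break toward the
earlier position; equal-scoring category hits prefer the toxin panel.
Degenerate inputs (empty library, empty category, tally of zero, peptide
reduced to nothing by amidation stripping) raise errors rather than
returning silent defaults.

## Problem sizes

The bundled end-to-end validations run a 200-gene / ~2000-EST library —
the scale of the reference study's 1131-EST library — once clean and once
at 0.5% substitutions; each run takes on the order of 1.5 minutes on one
CPU. Oracle-equivalence checks use 200 random alignment pairs (length ≤
50), 50 clustering instances of ≤ 12 ESTs, and 100 random peptides.

## Known limitations

* The signal-peptide and PQM rules are transparent heuristics, tuned for
  recoverability on synthetic data; swap in a trained predictor for real
  sequences.
* The k-mer count prescreen in clustering is conservative only for
  non-repetitive sequence.
* Scaffold assignment is similarity lookup; a novel framework gets
  "unassigned", never a predicted connectivity.
* Consensus construction assumes substitution-only divergence (no
  indel-aware polishing).
* Whether observed MALDI masses are neutral or protonated is data
  ambiguity; the census exposes an explicit flag rather than guessing.
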