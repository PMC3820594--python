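# Methods

This note documents the models and decision rules implemented in `klfscout`,
the parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical/tie-breaking conventions a maintainer needs.

## Zinc-finger spacing grammar

A C2H2 finger is matched as `C x(g) C x(12) H x(3) [HC]` with the cysteine
gap `g` in a configurable range (default 2–4).  Only the four zinc-binding
anchors are constrained; spacer positions accept any residue, including `X`
(unknown) and `*` (stop, in translated frames).  Two consequences are load
bearing:

* `X` never satisfies an anchor, so N-masked DNA produces missing fingers
  rather than false ones;
* a premature stop codon in a spacer does not hide the finger, which is how
  stop-codon pseudogenes remain detectable.

Matching is greedy left-to-right and non-overlapping; at a fixed start the
smallest admissible cysteine gap wins.  The matcher is a single lazy
regular expression, and the test suite holds it equal to an independent
per-position brute-force scan on random sequences.

Classification by cysteine-gap tuple: `(4,4,2)` with canonical inner gaps,
histidine gaps and 7-residue linkers is strict SP/KLF; `(4,2,2)` is
EGR-like; other tuples from `{2,4}^3` with a canonical frame are relaxed
SP/KLF (the rat-type `(2,2,2)` produced by two-residue deletions lands
here); four fingers `(4,4,2,4)` is WT1-like.  EGR takes precedence over the
relaxed rule, since `(4,2,2)` belongs to both by the raw definitions.  The
terminal zinc-binding position accepts cysteine by default (a C2H2 consensus
tolerance; a known mouse family member carries exactly this substitution) —
a flag disables it.

### DNA-contact conservation

The three base-reading arginines and their acidic partners are checked at
configurable offsets inside the 12-residue inner spacer (the residue checked
is `c2 + 1 + offset`).  Defaults follow the KLF recognition-helix
architecture (the RSD..R arrangement seen in the KLF–DNA co-structure):
arginines at offsets 5 and 11 of finger 2 and 5 of finger 3; aspartate/
glutamate at 7 and 8 of finger 2 and 7 of finger 3.  These are shipped as
configuration, not constants: they parameterize both the detector and the
generator, so conservation reports are meaningful on synthetic data, and can
be recalibrated for real alignments.

## Repeat motif analytics

The KLF18-type repeat `[YC]x[GASTDNPE][QH]` is scanned at every position;
for this pattern two matches can never be closer than 4 residues (the
first-position set is disjoint from the third- and fourth-position sets), so
all-position counts and non-overlapping counts coincide.  Motif density is
hits divided by full protein length — deliberately not by N-terminal-region
length.  Each hit is extended by 5 residues on both sides into a 14-residue
segment; boundary-truncated hits are dropped rather than padded so PFM
columns stay homogeneous.  The PFM counts the 20 standard residues (`X`
excluded); per-column information content is log2(20) minus the Shannon
entropy of the column frequencies.  Tandem runs are maximal hit chains with
successive start differences within 14 ± 4 (the tolerance is configuration;
the repeat literature gives periodicity qualitatively).  The fraction of
hits starting with Y separates KLF18-type repeats from the cysteine-started
matches of keratins.

## Synteny

Loci are located purely by annotation: configurable upstream
(B4GALT2/CCDC24/SLC6A9) and downstream (DMAP1/ERI3/RNF220) anchor gene ids.
One anchor per side suffices; all found anchors are reported
innermost-first.  The interval runs between the innermost anchors, both the
forward arrangement and its mirror image (whole-locus inversion) are
accepted, and intervals longer than 1 Mb (config) are rejected as spurious.
Intervals are 0-based half-open internally; BED is written 0-based
half-open, GFF3 1-based inclusive.

Genome-level status combines per-copy calls: any clean coding copy ⇒
`coding`; else any pseudogene copy ⇒ `pseudogene`; else repeat-motif
similarity in the interval's translations without fingers (e.g. an N-masked
finger region) ⇒ `partial`; else `absent`.

## Translated locus scan and gene models

All six frames are translated with the standard code (stops `*`, N-containing
codons `X`) and scanned with the grammar; consecutive fingers joined by
exactly one canonical linker form a fragment, and peptide coordinates map
back to genomic coordinates exactly (round-trip asserted on both strands).

Gene-model assembly per strand: a fragment covering three fingers is an
intronless copy; a one-finger fragment paired with a downstream two-finger
fragment across a spliceable gap is an intron-containing copy — the
family's conserved intron between finger 1 and fingers 2–3.  The splice
test reconstitutes the linker: for some split k + m = 7, removing k leading
and m trailing linker codons from the gap must leave a GT...AG interval (a
gap that is pure intron is also accepted).  Only GT..AG is recognized;
non-canonical splice sites yield `unknown` structure.  The pairing window is
20 kb (config).

Random DNA occasionally translates into chance fingers and chance GT/AG
pairs, so assembly applies two parsimony rules: among spliceable pairs, a
stop-free exon 1 is preferred, then the smallest intron; and
unknown-structure stray models overlapping a structured model's span
(intron included) are discarded as re-readings of already-explained DNA.

Status calls require the full three-finger signature: `coding` means three
clean fingers; `pseudogene` means three fingers with an in-frame stop inside
the finger-coding segments, or a deteriorated finger — a single zinc-binding
anchor replaced by a standard residue (not X, not a stop) at exactly the
position where a missing neighbor finger should sit, one linker away in the
same frame.  Isolated one- or two-finger matches with no such evidence are
not gene calls (`absent`): a lone C2H2 match in a six-frame translation is
noise, not a family locus.  The deteriorated-finger definition is
deliberately anchors-only; contact-arginine loss is reported but not used
for status (config-visible choice).

## Evolution

**Anchor alignment.**  Finger regions (first cysteine through last
histidine) are aligned by mapping the 12 zinc-binding anchors to shared
columns; inter-anchor spans are padded to the maximal width with gaps
right-aligned against the downstream anchor, so the rat-type two-residue
deletions appear as gaps immediately after the upstream cysteine.  Degapping
any row recovers its input (asserted at run time in tests).

**Distances and trees.**  p-distance over columns ungapped in both rows;
optional Poisson correction −ln(1−p), refusing p ≥ 0.75.  Neighbor joining
follows the Saitou–Nei Q criterion with ties broken by the lexicographic
pair of subtree representative ids and negative branch lengths clamped to
zero.  NJ deliberately replaces likelihood/Bayesian machinery: the claims
carried by this package are clade-recovery properties on synthetic data
(exact topology recovery from additive matrices, monophyly rates), not
branch supports.  Monophyly is evaluated by rooting at an explicit outgroup
(a WT1-like sequence in simulations) and asking whether the taxon set is a
complete clade; a singleton is monophyletic by convention.

**Event histories.**  Each non-root member's parent is its nearest homolog
by finger-region identity, with two refinements: (1) an intron-containing
member never selects an intronless parent — introns are lost to
retrotransposition, never regained; without this rule a parent and its own
retrocopy are equidistant in expectation and orientation is a coin flip;
(2) identity ties break by chromosomal proximity, then id.  Mutual-nearest
cycles are resolved by re-attaching the lexicographically smallest cycle
member to its best non-descendant homolog.  Mechanisms: intronless child of
an intron-containing parent ⇒ RT; same chromosome within 250 kb (config) ⇒
LGD; distal intronless child of an intronless parent ⇒ RT (retrocopies of
retrocopies); anything else ⇒ `distal_unknown`.  Events are emitted
parent-first.  Recovery is scored on mechanism labels per member: when a
branch happens to carry zero substitutions the inferred parent id can tie
onto a grandparent without changing any mechanism.

## Synthetic data

The generator emulates a placental-mammal family survey:

* proteins: an N-terminal region of exactly `n_repeats` 14-residue units
  (flank, motif, flank; the three positions before the motif favor Q, T, L;
  first position Y with probability 0.9, else C; last position Q with
  probability 0.9), then the finger region with planted contact residues.
  Repeat counts default to 10–50 per gene.  Filler alphabets are
  conservative so planted features are the only detectable ones: repeat
  flanks exclude C/Y (no accidental motif starts), finger-region filler
  excludes C/H/Y/Q (no accidental anchors or motif ends);
* loci: seeded uniform back-translation (no codon-usage model); the intron,
  when planted, is GT + random + AG (150 bp default) inserted mid-linker;
  pseudogenization replaces one inner-spacer codon with TAA; N-masking
  blanks the finger-coding interval;
* genomes: chromosome 1 carries the three upstream anchors, the locus
  copies in plan order (tail-to-tail strands as planned), and the three
  downstream anchors; distal copies get their own chromosomes; `near:`
  copies sit immediately after their target.  DNA filler is uniform ACGT,
  resampled in the rare case a stretch happens to translate into a
  grammar-matching finger;
* evolution: per-site substitution at a given rate with zinc-binding anchors
  protected and substitution targets excluding C/H/Y/Q — a crude purifying
  selection that keeps planted structure parseable while all other positions
  drift.  The family simulation evolves a fixed genealogy in which the
  KLF17/KLF18-like pair (and their shared stem) runs at 3x the base rate of
  0.05 per branch, with a long-branch WT1-like outgroup.

What the generator does **not** emulate — and hence what green tests do not
establish about real genomes: codon usage and GC structure, non-canonical
splice sites, indel evolution beyond the fixed two-residue deletion variant,
repeat-array expansion dynamics, sequencing error beyond N-masking, and
empirical amino-acid substitution processes.  Detection thresholds tuned
here (e.g. the three-finger requirement) are validated against this
generator's noise model, not against assembly artifacts.

## Problem sizes and determinism

The shipped tests and the acceptance script use compact instances chosen as
representative: single-locus genomes of ~5–10 kb around the anchored
interval, a 43-genome survey (36 coding / 4 pseudogene / 3 undetected),
50-locus pseudogene panels, 20-seed event-history replicates at 5% rates,
50-replicate monophyly simulations, and exhaustive tree-topology oracles up
to six taxa (105 topologies).  All randomness flows from one top-level seed
through numpy Generators; identical seeds reproduce byte-identical outputs,
and the run manifest records config hashes and input digests to make that
checkable.
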