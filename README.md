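# klfscout

A pipeline for discovering new members of the SP/KLF family of C2H2
zinc-finger transcription factors — genes *and* pseudogenes — in genome
assemblies, and for reconstructing how such families expand by local gene
duplication and retrotransposition.

## The problem

Specificity proteins (SP1–SP9) and Krüppel-like factors (KLF1–KLF17) share a
rigid DNA-binding signature: three C2H2 zinc fingers whose zinc-binding
residues follow the spacing

```
C X4 C X12 H X3 H  x7  C X4 C X12 H X3 H  x7  C X2 C X12 H X3 H
```

i.e. cysteine-pair separations of 4, 4 and 2 residues, 12-residue inner
spacers, 3-residue histidine gaps and 7-residue linkers.  This spacing
grammar separates the family from other C2H2 proteins — EGR-type fingers
show (4,2,2) and the Wilms' tumor protein (WT1) adds a fourth finger with a
4-residue cysteine gap.  Within the fingers, three invariant arginines (two
in finger 2, one in finger 3) read the GC/GT-box, buttressed by three acidic
partners.  New family members can therefore be found without expression data:
by grammar, by conserved gene neighborhood (synteny anchors such as SLC6A9
upstream and DMAP1 downstream), and — where the reading frame has decayed —
by the scars of pseudogenization: premature stop codons inside the
finger-coding region or deteriorated zinc-binding anchors.  KLF18-type
candidates carry an additional mark: N-terminal tandem repeats of the motif
`[YC]x[GASTDNPE][QH]`, typically 10–50 copies, with ~14-residue periodicity.

`klfscout` implements that whole search as a tested, seedable pipeline:

* **zf_grammar** — configurable spacing-grammar finger detection, family
  classification (strict/relaxed SP-KLF, EGR-like, WT1-like), DNA-contact
  residue conservation reports;
* **repeat_motif** — motif scanning, motif density (hits / protein length),
  14-residue segment extraction, position-frequency matrix with per-column
  information content, tandem-run detection, proteome ranking;
* **synteny** — anchored-interval finding (mirror-image tolerant), gene
  orientation calls (tail-to-tail / head-to-head / co-oriented), copy
  counting, cross-genome presence matrices;
* **locus_scan** — six-frame translated scanning of genomic DNA, splice-aware
  assembly of the family's conserved intron (between finger 1 and fingers
  2–3), pseudogene calling;
* **evolution** — anchor-based alignment of finger regions, p-distances,
  neighbor joining, outgroup-rooted monophyly tests, and inference of
  LGD/RT (local-duplication / retrotransposition) expansion histories;
* **synthetic_data** — genomes, proteomes and gene tables with planted truth
  (tandem duplicates, retrocopies, stop-codon pseudogenes, masked loci,
  decoys), so every stage is verifiable end to end without downloads.

## Worked example

The murine expansion scenario — a KLF17-like root, a tail-to-tail local
duplicate (KLF18), a distal retrocopy of its spliced mRNA (Zfp352), a tandem
duplicate of the retrocopy (Zfp352l) and a second retrocopy (Zfp353):

```python
from klfscout import PipelineConfig
from klfscout.pipeline import analyze_genome
from klfscout.synthetic_data import make_genome, murine_spec

genome, genes, truth = make_genome(murine_spec(), seed=42)
analysis = analyze_genome(genome, genes, PipelineConfig())

print(f"locus: {analysis.locus.chrom}:{analysis.locus.start}-{analysis.locus.end}")
print(f"genome status: {analysis.result.status} ({analysis.result.n_copies} copies in locus)")
for model_id, model, status in analysis.models:
    print(f"  {model_id:8s} {model.strand} {model.intron_structure:17s} {status}")

from klfscout.evolution import classify_events
history = classify_events(analysis.members, root_id="KLF17")
for event in history.events:
    print(f"{event.child:8s} <- {event.parent:8s} {event.mechanism}")
```

prints

```
locus: chr1:2700-6170
genome status: coding (2 copies in locus)
  KLF17    + intron_containing coding
  KLF18    - intron_containing coding
  Zfp352   + intronless        coding
  Zfp352l  - intronless        coding
  Zfp353   + intronless        coding
KLF18    <- KLF17    LGD
Zfp352   <- KLF17    RT
Zfp352l  <- Zfp352   LGD
Zfp353   <- Zfp352   RT
```

The anchored interval on chr1 holds the tail-to-tail KLF17/KLF18 pair, both
with the family's conserved intron; the three distal copies are intronless
(the retrotransposition hallmark).  The inferred history reads parent-first:
one local duplication created KLF18, a retrotransposed KLF18 mRNA seeded the
second locus, which duplicated locally, and a second retrotransposition
produced the distal third locus — the LGD, RT, LGD, RT event chain.

## Command line

```bash
klfscout simulate --seed 5 --out sim/ --n-genomes 5     # genomes + truth
klfscout scan-proteome --in sim/proteome.faa --out scan/
klfscout scan-genome --genome sim/genome000.fa --genes sim/genome000.bed --out g0/
klfscout synteny --genes sim/genome000.bed --out synteny.tsv
klfscout evolve --in sim/proteome.faa --out tree/
klfscout report --genomes-dir sim/ --out report/       # full pipeline
```

Exit codes: 0 success, 2 parse/input error, 3 stage failure.  All outputs
are plain TSV/GFF3/Newick/JSON; a run manifest records the config hash and
input digests, and identical seeds reproduce identical outputs.

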