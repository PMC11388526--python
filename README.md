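# denitscan

Denitrification genotyping of (meta)genomes with profile hidden Markov
models, aimed at the phylum *Bacillota* (endospore-forming Firmicutes),
where standard annotation databases routinely miss or mislabel the
nitric oxide reductases (qNOR annotated as cNOR subunit B, bNOR/sNOR as
cytochrome *c* oxidase) and do not separate the two clades of nitrous
oxide reductase.

Denitrification is the stepwise anaerobic respiration

    NO3-  --NAR-->  NO2-  --NIR-->  NO  --NOR-->  N2O  --NOS-->  N2

where each arrow is catalyzed by its own enzyme family: membrane-bound
NarGH or monomeric periplasmic NapA (NAR); copper-type NirK or cytochrome
cd1-type NirS (NIR); any of the heme-copper oxidase family reductases
cNOR/qNOR/bNOR/sNOR (NOR); and NosZ (NOS), which splits into clade I
(Tat-secreted) and clade II (Sec-secreted, accompanied by the essential
membrane lipoprotein NosB and the nosC–nosZ–nosB–nosD–nosY–nosF gene
cluster). `denitscan` ships a twelve-model registry covering exactly this
gene set and classifies each genome as

| fine label | meaning | coarse |
|---|---|---|
| complete | all four steps present | C |
| truncated | NAR+NIR+NOR but no NosZ (end product N2O) | T |
| nor_only / nos_only / modular | partial pathways | M |
| non_denitrifying | no respiratory N gene | N |

## What is inside

* `denitscan.profile_hmm` — build/score/sample/calibrate profile HMMs.
  Glocal scoring (global in the model, local in the sequence), bit scores
  `log2 P(seq,path|model) / P(seq|background)`, deterministic Viterbi
  tie-breaking, and trusted-cutoff (TC) calibration: the only decision
  rule is a per-model bit-score cutoff, no E-values.
* `denitscan.registry` — the 12-gene registry (narG, narH, napA, nirK,
  nirS, cnor, qnor, bnor, snor, nosZI, nosZII, nosB) with step mapping,
  user extension and serialization. TCs are re-derived at load time by
  calibrating model samples against their residue shuffles.
* `denitscan.features` — Kyte–Doolittle transmembrane-helix counting
  (NosB has 4 or 6 helices), Sec/SPI vs Tat signal-peptide heuristics,
  and C-x-x-C-H heme-motif counting (the cytochrome-*c* proxy for NosC).
* `denitscan.genotype` — step-presence rules (narG AND narH, or napA;
  etc.) and the fine/coarse labels, plus DNRA flags (nirBD, nrfAH) as
  external annotations.
* `denitscan.noscluster` — nosZ-anchored gene-neighborhood
  reconstruction of the Nos gene cluster, window measured in gene ranks.
* `denitscan.synthetic` — fully labeled synthetic alignments, proteomes
  and benchmark panels so everything above is testable offline.

## Worked example

Generate a synthetic complete denitrifier and annotate it:

```python
from denitscan.registry import default_registry
from denitscan.synthetic import GenotypeSpec, generate_genome
from denitscan.seqio import write_fasta, write_gff

reg = default_registry()
spec = GenotypeSpec(
    "demo",
    genes=("narG", "narH", "nirK", "qnor", "bnor", "nosZII"),
    ngc_layout=("nosC", "nosZ", "nosB", "nosD", "nosY", "nosF"),
    seed=7,
)
g = generate_genome(spec, reg)
write_fasta(g.proteins, "demo.faa")
write_gff(g.genes, "demo.gff3")
```

```bash
denitscan run --proteome demo.faa --gff demo.gff3 --labels labels.tsv --out-dir out
```

The genotype table (`out/demo.genotypes.tsv`) reads

```
demo	complete	C	narG;narH	nirK	bnor;qnor	nosZII		II
```

— the genome is a complete denitrifier (coarse label C): NAR is backed by
the narG+narH pair, NIR by nirK, NOR by both bnor and qnor, NOS by a
clade II nosZ whose engineered Sec signal peptide corroborates the clade
call (column `II`). The cluster table (`out/demo.ngc.tsv`) recovers the
implanted operon in order:

```
demo	demo_c1	demo_g004	II	demo_g003	demo_g005	demo_g006	demo_g007	demo_g008			nosC>nosZ>nosB>nosD>nosY>nosF
```

and the passing hits (`out/demo.hits.tsv`) show one hit per implanted
gene, e.g. `demo_g004  nosZII  305.6  1 1  17 130`: the aligned span
starts at residue 17 because the 16-residue Sec peptide is flanking
sequence the glocal model does not consume.

A ready-made 12-genome benchmark panel (5 complete, 1 truncated,
4 modular, 2 non-denitrifying) is available via
`denitscan simulate --out panel/ --seed 3`.

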