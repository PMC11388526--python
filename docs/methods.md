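# Methods

## Profile model and scoring

Each gene model is a match/insert/delete profile in the classic
architecture: `begin -> {M1, I0, D1}`, `Mk -> {Mk+1, Ik, Dk+1}`,
`Ik -> {Ik, Mk+1}`, `Dk -> {Dk+1, Mk+1}`, with `MM/IM/DM -> end`.
D→I and I→D moves do not exist. Alignment is *glocal*: the model is
always traversed begin-to-end, while any amount of flanking sequence is
consumed by free flank states that emit at the background distribution.
Because flank emissions cancel against the i.i.d. background null model,
the reported bit score is

    bit = log2 [ P(seq, path | model) / P(seq | background) ]

summed (forward) or maximized (Viterbi) over paths *and* over flank
splits, with no length correction and no E-values — the decision rule is
a per-model trusted cutoff (TC) in bits, as in curated HMM collections.
Scores are therefore not numerically comparable to HMMER's (no sequence
or entropy weighting, different null), but the TC gate makes them
self-consistent.

Estimation from a seed alignment: columns with non-gap fraction
≥ `match_occupancy` (default 0.5) become match states; emissions are
observed counts plus `pseudocount_weight` (default 1.0) spread over the
background; transitions are observed path counts through the implied
M/I/D labeling plus the same weight spread uniformly over the legal moves
out of each state. The background defaults to uniform 1/20. Insert states
emit the background, so inserts contribute zero log-odds. Rows whose
implied move would be D→I or I→D (possible when a deletion abuts an
insert column) contribute no transition count for that pair; pseudocounts
keep every distribution proper.

Numerical choices: the dynamic programming runs in log2 space; the
delete-state chain within a column is resolved by a prefix scan
(`max`/`logaddexp2` accumulate), which requires finite arithmetic, so
structurally impossible moves carry a finite penalty of −1e30 rather than
−inf (2^−1e30 underflows to exactly 0, so forward sums are unaffected).
Viterbi traceback ties break deterministically as M > D > I. `X` residues
emit the background-weighted average emission over the background norm,
which is exactly 0 bits under a uniform background; U/O are normalized to
X on input with a warning. Empty sequences are rejected.

`sequence_probability` exposes the flankless begin-to-end emission
probability of a sequence; summed over all sequences (the empty string
included, via the all-delete path) it converges to 1, which the tests
verify against an independent path-enumeration oracle.

## Trusted-cutoff calibration

`calibrate_tc` scores a positive and a negative set and, when the sets
separate, stores the midpoint of the margin as the TC; overlapping sets
raise an error listing every offending sequence, which is the signal to
re-inspect the seed alignment and iterate — the calibration loop is
deliberately a curate-and-re-run cycle rather than a silent optimizer.
The shipped registry calibrates each model at load time on 30 fresh model
samples versus their residue shuffles (the hardest negatives preserving
length and composition), with the per-gene seeds recorded in
`data/registry.yaml`. The published cutoffs for the original gene set
were never released, so cutoffs here are always re-derived; users
supplying their own seed alignments get the same treatment, or may pin
explicit `tc_bits`.

## Registry

Twelve genes across the four reduction steps plus one accessory:
narG+narH (jointly required for a NAR call), monomeric napA (no napH
requirement anywhere), nirK/nirS, cnor/qnor/bnor/snor, nosZI/nosZII, and
nosB (ACCESSORY). Six entries are of custom-MSA origin (nirK, nirS, qnor,
bnor, snor, nosB); the others are seeded the way per-subunit TIGRFAM
profiles would be. cnor is included although it is absent from the
thermophilic enrichment genomes the gene set was designed around, because
phylum-wide screens need it. The registry is user-extensible (e.g. an
eNOR model under step NOR, or DNRA genes as ACCESSORY); classification
and cluster logic take step membership from the registry, not from
hard-coded names, except for the narG/narH AND rule and the napA
monomer rule, which are part of the NAR contract.

The shipped seed alignments are **synthetic stand-ins** (filenames
`*.synthetic.afa`), generated by `denitscan.synthetic` with frozen seeds
(see `scripts/build_default_data.py`): the curated alignments behind the
original profiles are not redistributable. They make the default registry
buildable and testable offline; for real annotation work users should
drop in curated seed MSAs of the actual enzyme families.

## Feature heuristics

These are explicit, parameterized approximations of the neural predictors
usually used for the same categorical calls; downstream logic consumes
only the category, never a probability.

* **Transmembrane helices** — Kyte–Doolittle hydropathy averaged over a
  sliding window (default 19 residues); window positions with mean > 1.6
  are helix core, maximal runs merge, runs closer than 5 positions merge,
  each surviving run is one helix. NosB candidacy requires a count of 4
  or 6. Defaults are config-exposed (window/threshold in `RunConfig`).
* **Signal peptides** — Tat: a consecutive `RR` within residues 1–35
  followed by an h-region (a 7-residue window of mean hydropathy > 1.5);
  checked first. Sec/SPI: ≥ 1 K/R in residues 1–7, an h-region within
  residues 5–25, and an `[AGS]-x-[AGS]` cleavage motif whose third
  residue lies at positions 15–40 (cleavage after it). Decisions depend
  only on the N-terminal 45 residues; sequences shorter than 30 residues
  are called `none`.
* **Cytochrome c** — the count of non-overlapping `C-x-x-C-H`
  heme-attachment motifs; ≥ 1 is the NosC proxy.

## Genotype classification

Step presence: NAR ⇐ (narG ∧ narH) ∨ napA; NIR ⇐ nirK ∨ nirS; NOR ⇐ any
NOR-step gene; NOS ⇐ either nosZ clade. An unpaired narG or narH backs
nothing but is retained in the evidence. Gene presence is taken from
passing *primary* hits (a protein's highest-scoring passing model, ties
broken by registry order), so one protein never backs two genes. The fine
label is a pure function of the four step bits (see README table);
`truncated` follows the strict reading "lacks only NosZ", i.e. requires
NAR ∧ NIR ∧ NOR — a genome with NIR+NOR but no NAR is `modular`. The
clade call comes from the nosZ model identity, corroborated by the
detected signal peptide; a conflict (clade II model with a Tat peptide,
or clade I with Sec) yields `ambiguous` rather than an override. DNRA
genes (nirBD, nrfAH) are accepted only as external annotation flags —
they were identified by orthology databases upstream, not by this gene
set — and never affect the denitrification label.

## Nos gene cluster reconstruction

One cluster per passing nosZ anchor. Adjacency is measured in gene ranks
along the contig (robust to intergenic length); the default window of 6
ranks each side covers the longest observed layouts (≤ 8 genes). Slot
rules: nosC is the nearest upstream same-strand gene with a heme motif,
"upstream" read in transcription direction (lower rank on +, higher on −;
only nosC is strand-constrained); nosB is the nearest window gene not
claimed by any registry model with 4 or 6 TM helices — excluding model
hits keeps the ~14-helix qNOR out of the slot; nosD/Y/F/L come only from
a user label table; adjacent_nor is any NOR-step hit at rank distance 1
from a cluster member. A gene occupies at most one slot, and anchors are
processed in rank order so clusters on one contig never share components.
Output is independent of input gene order, and enlarging the window never
unfills a slot.

## Synthetic data: what it emulates, and what it does not

`generate_reference_msa` draws an ancestor from a Dirichlet-perturbed
composition and substitutes each descendant site independently at the
given rate (default 0.15 across 12 rows — conserved-family territory,
appropriate for seed alignments of well-characterized enzymes), with
sparse indels at a tenth of that rate (so rate 0 reproduces the ancestor
exactly). `generate_genome` implants fresh model samples for the
requested genes, prepends an engineered Sec peptide to clade II nosZ (Tat
to clade I), realizes cluster layouts as consecutive plus-strand ranks
padded by decoys, engineers the nosC (heme motif) and nosB (4-TM)
neighbors, and uses residue shuffles of the implants as decoys. Free gene
implants are kept off the cluster contig so the truth table's adjacency
labels are exact by construction.

Passing the noise-free benchmark therefore shows that the scanner's
logic — scoring, thresholding, step rules, neighborhood rules — is
correct, not that the heuristics match neural predictors on real
proteins, nor that synthetic profiles capture real enzyme-family
divergence. Real genomes bring fragmented contigs, paralogs near the TC,
non-uniform residue composition and genuinely ambiguous signal peptides;
the noise knobs (substitution rate on implants, decoy counts) exist for
exploring robustness but acceptance is defined on the noise-free regime.

## Problem sizes and determinism

The shipped seed alignments are 12 sequences × 80–140 columns; the
benchmark panel is 12 genomes of roughly 15–25 proteins each, which keeps
a full build–calibrate–scan–classify–cluster cycle under a minute on one
CPU. Oracle comparisons (brute-force path enumeration) run on models with
M ≤ 4 over a two-letter alphabet and sequences of length ≤ 6. All
randomness flows through seeded `numpy` generators; identical
configuration and inputs produce byte-identical outputs (output headers
echo the configuration and contain no timestamps).

## Known limitations

* The model file format is bespoke; there is no HMMER compatibility, no
  E-values, no multi-domain hits and no DNA search.
* Genotype calls are gene-content inferences: co-occurrence of
  denitrification and DNRA genes in one genome means realized
  end-products cannot be predicted from the genotype alone.
* The signal-peptide and TM heuristics are window/motif rules; on real
  proteins they approximate, not reproduce, dedicated predictors.
* Proteins must be provided (no ORF calling), and coordinates must be
  GFF3 with `ID` attributes resolving to the protein FASTA.
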