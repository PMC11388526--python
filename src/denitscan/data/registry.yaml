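# Default denitscan registry: 12 gene models across the four
# denitrification reduction steps plus the nosB accessory.
# Seed alignments are synthetic stand-ins (see filenames);
# trusted cutoffs are calibrated at load time from model
# samples vs their residue shuffles at the recorded seeds.
defaults:
  match_occupancy: 0.5
  pseudocount_weight: 1.0
genes:
- gene: narG
  step: NAR
  origin: tigrfam-seeded
  msa: msas/narG.synthetic.afa
  calibration:
    n: 30
    seed: 101
  active_site:
    8: Q
    11: G
- gene: narH
  step: NAR
  origin: tigrfam-seeded
  msa: msas/narH.synthetic.afa
  calibration:
    n: 30
    seed: 102
  active_site:
    11: G
    14: Q
- gene: napA
  step: NAR
  origin: tigrfam-seeded
  msa: msas/napA.synthetic.afa
  calibration:
    n: 30
    seed: 103
  active_site:
    6: R
    9: Q
  notes: matches monomeric NapA; no napH requirement anywhere
- gene: nirK
  step: NIR
  origin: custom-msa
  msa: msas/nirK.synthetic.afa
  calibration:
    n: 30
    seed: 104
  active_site:
    17: A
    19: M
- gene: nirS
  step: NIR
  origin: custom-msa
  msa: msas/nirS.synthetic.afa
  calibration:
    n: 30
    seed: 105
  active_site:
    7: C
    11: T
- gene: cnor
  step: NOR
  origin: tigrfam-seeded
  msa: msas/cnor.synthetic.afa
  calibration:
    n: 30
    seed: 106
  active_site:
    11: K
    20: D
  notes: absent from the enrichment MAGs but needed for phylum screens
- gene: qnor
  step: NOR
  origin: custom-msa
  msa: msas/qnor.synthetic.afa
  calibration:
    n: 30
    seed: 107
  active_site:
    7: G
    9: Q
- gene: bnor
  step: NOR
  origin: custom-msa
  msa: msas/bnor.synthetic.afa
  calibration:
    n: 30
    seed: 108
  active_site:
    20: L
    23: W
- gene: snor
  step: NOR
  origin: custom-msa
  msa: msas/snor.synthetic.afa
  calibration:
    n: 30
    seed: 109
  active_site:
    10: D
    14: R
- gene: nosZI
  step: NOS
  origin: tigrfam-seeded
  msa: msas/nosZI.synthetic.afa
  calibration:
    n: 30
    seed: 110
  active_site:
    6: E
    12: T
- gene: nosZII
  step: NOS
  origin: tigrfam-seeded
  msa: msas/nosZII.synthetic.afa
  calibration:
    n: 30
    seed: 111
  active_site:
    7: A
    11: W
- gene: nosB
  step: ACCESSORY
  origin: custom-msa
  msa: msas/nosB.synthetic.afa
  calibration:
    n: 30
    seed: 112
  active_site:
    10: C
    27: A
  notes: clade II accessory membrane lipoprotein; 4 or 6 TM helices
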