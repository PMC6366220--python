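# Simulation spec reproducing the genotype margins of the goat PDGFRB
# 10 bp indel panel (1122 ewes, II/ID/DD = 919/200/3) with litter-class
# probabilities conditional on genotype, matching the observed
# heterozygote advantage of about +0.16 lambs.
#
#   indelassoc simulate --spec examples/goat_10bp_cohort.yaml --seed 1 --out cohort.tsv
n: 1122
loci:
  - name: P3_10bp
    counts: [919, 200, 3]
effect:
  locus: P3_10bp
  classes: [1, 2, 3]
  class_probs:
    II: [0.579, 0.409, 0.012]
    ID: [0.420, 0.570, 0.010]
    DD: [0.333, 0.667, 0.000]
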