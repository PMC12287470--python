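# Unit type table for the four variable-region classes.
#
# Every unit is scaffold + variable region: a 25-bp conserved 5' block
# (beginning with the CAGCT anchor) and a 16-bp conserved 3' block flank a
# mid-unit variable region whose consensus motif and width define the type.
# Dashes in the printed motifs mark weakly conserved positions; they are
# matched as wildcards, so the motif WIDTH (not its letter count) equals the
# variable-region length and nominal_length = 41 + width for every type.
#
# default_fill gives the bases the synthetic generator places at wildcard
# positions; the scaffolds here are the generator defaults (arbitrary fixed
# sequences of the conserved lengths, chosen to be anchor-free in tandem
# context) and may be replaced by scaffolds transcribed from real data.
scaffold_5prime: CAGCTGTGCTCATTTCCAATAAGAC
scaffold_3prime: AGGACTCGATTGAACG
var_start: 25        # 0-based offset of the variable region within a unit
types:
  - name: L47
    motif: CATCAG
    nominal_length: 47
    default_fill: ""
  - name: L49
    motif: CAA-A--G
    nominal_length: 49
    default_fill: CAG
  - name: L50
    motif: CAACACCAG
    nominal_length: 50
    default_fill: ""
  - name: L53
    motif: CAGCAGCACC-G
    nominal_length: 53
    default_fill: C
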