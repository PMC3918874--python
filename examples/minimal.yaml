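# Minimal scenario: one well-expressed single-copy locus and a 5-copy
# tandem family with the same total output, shallow sequencing.
seed: 3
background_length: 30000
loci:
  - locus_id: solo
    unit_length: 600
    copy_number: 1
    arrangement: single
    sense_rate: 0.5
    antisense_rate: 0.5
  - locus_id: fam5
    unit_length: 600
    copy_number: 5
    arrangement: tandem
    sense_rate: 0.1
    antisense_rate: 0.1
n_total_reads: 2000
n_sirna_reads: 500
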