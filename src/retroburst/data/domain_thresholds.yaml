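# min_score = ceil(99th percentile) of the Monte-Carlo null: best local
# alignment score of each reference against random 3 kb nucleotide
# sequences (GC 0.5, 200 replicates, seed 0), all six frames.
matrix: BLOSUM62
gap_open: -11
gap_extend: -1
min_score:
  GAG: 49
  AP: 47
  RT: 51
  RH: 45
  INT: 51
  CHROMO: 43
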