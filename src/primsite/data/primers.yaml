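# Nested inverse-PCR primer sets for SB transposon junction recovery.
# The first 16 bases of every primer are a cloning tail and are ignored
# during in-silico annealing (tail_length).
primer_pairs:
  - name: EF1a_p1
    forward: ccccctcgaggtcgacatggctagagacttatcgaaagca
    reverse: attcgatatcaagctccaagatctgcacactggtattt
    tail_length: 16
  - name: EF1a_p2
    forward: ccccctcgaggtcgacgtacacgacatcactttcccagt
    reverse: attcgatatcaagctcacactggtatttcggtttttg
    tail_length: 16
  - name: HS1_3p_p1
    forward: ccccctcgaggtcgacctacactctcagtcagcctatgga
    reverse: attcgatatcaagcttaatcccaaaaggctgatagtctc
    tail_length: 16
  - name: HS1_3p_p2
    forward: ccccctcgaggtcgacacatctctcactttctcatcacca
    reverse: attcgatatcaagctaagtaactgggattacaggagcac
    tail_length: 16
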