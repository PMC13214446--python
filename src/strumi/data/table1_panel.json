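[
 {
  "name": "D2S441",
  "left_flank": "TTTTTGATGTACACGAGTCG",
  "right_flank": "CGCTTTGAACTAGCTTTCGG",
  "motifs": [
   "TCTA",
   "TTTA"
  ],
  "reference_genotype": [
   "TCTA[10]",
   "TCTA[11]TTTA[1]TCTA[2]"
  ],
  "max_read_len": 100
 },
 {
  "name": "D1S1656",
  "left_flank": "CGGGTGCTTAGGTACATGAC",
  "right_flank": "AGGATACAAAAGGTAGCCTG",
  "motifs": [
   "CTAT",
   "AC",
   "AT"
  ],
  "reference_genotype": [
   "AC[5]AT[1]CTAT[12]",
   "AC[6]CTAT[11]"
  ],
  "max_read_len": 137
 },
 {
  "name": "D3S1358",
  "left_flank": "ATATGTAGCTTAAAGCTCAC",
  "right_flank": "CCTGAGCTGAACTCTGCCTT",
  "motifs": [
   "TCTA",
   "TCTG"
  ],
  "reference_genotype": [
   "TCTA[1]TCTG[3]TCTA[14]",
   "TCTA[1]TCTG[3]TCTA[13]"
  ],
  "max_read_len": 139
 },
 {
  "name": "vWA",
  "left_flank": "TATTGCGGTGGTCGCTACCA",
  "right_flank": "ACCCGTACACGACGCACAAA",
  "motifs": [
   "GATA",
   "GACA"
  ],
  "reference_genotype": [
   "GATA[12]GACA[3]GATA[1]",
   "GATA[14]GACA[4]GATA[1]"
  ],
  "max_read_len": 159
 },
 {
  "name": "D8S1179",
  "left_flank": "TTAACAACTGGTCTTTAACG",
  "right_flank": "ATCGGAACTCGATGATGGAG",
  "motifs": [
   "TCTA",
   "TCTG"
  ],
  "reference_genotype": [
   "TCTA[1]TCTG[1]TCTA[12]",
   "TCTA[2]TCTG[1]TCTA[12]"
  ],
  "max_read_len": 232
 },
 {
  "name": "D21S11",
  "left_flank": "CATAGTTTACCAAGACCCGA",
  "right_flank": "CCAGCGCGCAGGTCAAGATA",
  "motifs": [
   "TCTA",
   "TCTG",
   "TATC",
   "TCCA",
   "CATA",
   "ATC",
   "A"
  ],
  "reference_genotype": [
   "TCTA[5]TCTG[6]TCTA[3]TATC[4]ATC[1]TATC[2]CATA[1]TCTA[11]TATC[2]",
   "TCTA[4]TCTG[6]TCTA[3]TATC[4]A[1]TCTA[2]TCCA[1]TATC[12]"
  ],
  "max_read_len": 233
 },
 {
  "name": "D12S391",
  "left_flank": "AGATGTACCGGCCCACGGCG",
  "right_flank": "ATCCGTTTCCCCAGCATGAT",
  "motifs": [
   "TAGA",
   "CAGA"
  ],
  "reference_genotype": [
   "TAGA[12]CAGA[6]",
   "TAGA[15]CAGA[8]_+1T > C"
  ],
  "max_read_len": 241
 }
]
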