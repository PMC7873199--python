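# Synthetic ancestry-specific amylase haplotype tables.
#
# These tables are constructed (no cohort haplotype table is publicly
# available) so that the implied diploid means match the reported
# population means (AMY1: 6.92 Arab / 7.60 Persian; AMY2A: 2.06 / 2.27)
# and so that every haplotype carries AMY1 and AMY2A counts of equal
# parity, which makes diploid AMY1/AMY2A parity exact by construction.
# AMY2B varies rarely and only together with AMY2A, reproducing the
# observation that discordant AMY2A/AMY2B calls almost always leave
# AMY2B at two copies.
#
# Columns: haploid copy counts per gene and the haplotype frequency
# within the ancestry group (frequencies sum to 1 per group).
arab:
  - {amy1: 1, amy2a: 1, amy2b: 1, freq: 0.05}
  - {amy1: 2, amy2a: 0, amy2b: 1, freq: 0.04}
  - {amy1: 2, amy2a: 2, amy2b: 2, freq: 0.04}
  - {amy1: 3, amy2a: 1, amy2b: 1, freq: 0.565}
  - {amy1: 4, amy2a: 0, amy2b: 1, freq: 0.01}
  - {amy1: 4, amy2a: 2, amy2b: 1, freq: 0.04}
  - {amy1: 5, amy2a: 1, amy2b: 1, freq: 0.215}
  - {amy1: 7, amy2a: 1, amy2b: 1, freq: 0.04}
persian:
  - {amy1: 1, amy2a: 1, amy2b: 1, freq: 0.04}
  - {amy1: 2, amy2a: 0, amy2b: 1, freq: 0.03}
  - {amy1: 2, amy2a: 2, amy2b: 2, freq: 0.05}
  - {amy1: 3, amy2a: 1, amy2b: 1, freq: 0.45}
  - {amy1: 3, amy2a: 3, amy2b: 2, freq: 0.03}
  - {amy1: 4, amy2a: 2, amy2b: 1, freq: 0.06}
  - {amy1: 5, amy2a: 1, amy2b: 1, freq: 0.25}
  - {amy1: 7, amy2a: 1, amy2b: 1, freq: 0.07}
  - {amy1: 9, amy2a: 1, amy2b: 1, freq: 0.02}
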