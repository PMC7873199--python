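# Default amylase-locus region definitions (GRCh37 coordinates).
#
# Region strings are 1-based inclusive spans ("chrom:start-end"), the format
# used by samtools; they are converted to 0-based half-open intervals when
# loaded.  AMY1 spans three near-identical ~20-kb paralogous units and is
# counted without a mapping-quality threshold (the repeats depress MAPQ);
# AMY2A/AMY2B use MAPQ >= 20.  unit_length is the normalization length of a
# single repeat unit so that the density ratio scales to diploid copy number.
loci:
  AMY1:
    targets:
      - "chr1:104190000-104210000"
      - "chr1:104227213-104247214"
      - "chr1:104284138-104304150"
    references:
      - "chr1:104059996-104070000"
      - "chr1:104460001-104469995"
    unit_length: 20000
    mapq_min: 0
  AMY2A:
    targets:
      - "chr1:104153700-104161939"
    references:
      - "chr1:104045000-104085000"
    unit_length: 8240
    mapq_min: 20
  AMY2B:
    targets:
      - "chr1:104114335-104135000"
    references:
      - "chr1:104000000-104100000"
      - "chr1:104304000-104500000"
    unit_length: 20666
    mapq_min: 20
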