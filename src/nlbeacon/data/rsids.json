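{
  "version": "synthetic-fixture-1.0",
  "rsids": {
    "rs28602900": {"assembly": "GRCh38", "chrom": "X", "start": 1000000, "ref": "C", "alt": "T"},
    "rs356181": {"assembly": "GRCh38", "chrom": "4", "start": 2000000, "ref": "T", "alt": "C"},
    "rs1000111": {"assembly": "GRCh38", "chrom": "1", "start": 500000, "ref": "A", "alt": "G"},
    "rs2000222": {"assembly": "GRCh38", "chrom": "2", "start": 750000, "ref": "G", "alt": "A"},
    "rs17000333": {"assembly": "GRCh38", "chrom": "17", "start": 300000, "ref": "C", "alt": "A"}
  }
}
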