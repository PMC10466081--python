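# Default 16S rRNA primer sets (editable). Columns: name, forward, reverse, max_mismatch.
# V3V4: 341F / 805R; V1V9: 27F / 1492R; operon: 27F-class / 23S-terminal class
# spanning the 16S-ITS-23S region for long-read amplicons.
name	forward	reverse	max_mismatch
V3V4	CCTACGGGNGGCWGCAG	GACTACHVGGGTATCTAATCC	2
V1V9	AGAGTTTGATCMTGGCTCAG	TACGGYTACCTTGTTACGACTT	2
rrna-operon	AGAGTTTGATCMTGGCTCAG	CCRAMCTGTCTCACGACG	2
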