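"""Amplicon layout constants.

The library molecule read by the sequencer has a fixed architecture:

* Read 2 starts with the ligation oligonucleotide: an 8-base spacer, six
  random bases (first UMI half), a second 8-base spacer, and six more random
  bases (second UMI half).  The first 30 bases of R2 therefore cover the
  complete UMI region (8 + 6 + 8 + 6 = 28, plus two bases of downstream
  sequence).
* Read 1 begins with 6 random bases (cluster-diversity hexamer), followed by
  the 6-base sample index, a stub of constant region, and the rearranged
  V(D)J sequence.
* The index read I1 carries the 6-base Illumina index.
"""

UMI_REGION_LEN = 30
SPACER_LEN = 8
UMI_HALF_LEN = 6
UMI_LEN = 2 * UMI_HALF_LEN
RANDOM_PREFIX_LEN = 6
INDEX_LEN = 6

# 0-based half-open slots within the 30-base UMI region
SPACER1_SLOT = (0, SPACER_LEN)
UMI1_SLOT = (SPACER_LEN, SPACER_LEN + UMI_HALF_LEN)
SPACER2_SLOT = (UMI1_SLOT[1], UMI1_SLOT[1] + SPACER_LEN)
UMI2_SLOT = (SPACER2_SLOT[1], SPACER2_SLOT[1] + UMI_HALF_LEN)

# Slot of the sample index within R1: immediately after the random hexamer.
R1_INDEX_SLOT = (RANDOM_PREFIX_LEN, RANDOM_PREFIX_LEN + INDEX_LEN)

# Default spacer 8-mers used by the bundled synthetic layout (the published
# oligo spacers live in supplementary tables; any fixed pair works and both
# are configurable wherever they are consumed).
DEFAULT_SPACER1 = "GTCGTGAT"
DEFAULT_SPACER2 = "AGATGTGT"

# Constant-region stub placed 5' of the rearrangement in simulated R1 reads.
CONST_REGION_STUB = "CAGTAGCGACCTTGGGTGGA"
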