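# SYNTHETIC PLACEHOLDER gene list.
# The published EphA2-pathway panel (71 genes downstream of EphA2 signaling)
# is distributed with the original study's supplementary material; supply it
# as your own one-id-per-line file for real analyses.  The symbols below are
# plausible EphA2-cascade members provided only so examples and tests can run.
EPHA2
EFNA1
SRC
VAV2
VAV3
RHOA
ROCK1
ROCK2
RAC1
CDC42
PIK3CA
AKT1
PTK2
GRB2
SHC1
MAPK1
MAPK3
ARHGEF7
LIMK1
CFL1
MYL9
ITGB1
ACTB
ACTN1
VCL
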