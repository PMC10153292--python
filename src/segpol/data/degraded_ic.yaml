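# "Degraded" initial condition: a blurred version of the crisp pre-pattern
# stripes on the 1 x 4 row (values per cell 1..4, applied uniformly to the
# six membrane pools where the species is membrane-bound).
#
# PROVENANCE: the archival description of this starting state is a bar
# chart without axes; no numeric values were ever printed.  The values
# below are this package's own reconstruction (the sharp 0.9 stripes of
# the crisp scheme smeared one cell to each side, keeping the
# 0.15/0.4/0.9 level vocabulary) and are meant to be edited.  Species not
# listed start at the 0.15 background.
wg:  [0.4, 0.9, 0.4, 0.15]
IWG: [0.4, 0.9, 0.4, 0.15]
EWG: [0.4, 0.9, 0.4, 0.15]
en:  [0.15, 0.4, 0.9, 0.4]
EN:  [0.15, 0.4, 0.9, 0.4]
hh:  [0.15, 0.4, 0.9, 0.4]
HH:  [0.15, 0.4, 0.9, 0.4]
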