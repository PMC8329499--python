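# Ten-formula degradation-index (I_DEG) set, transcribed from the literature
# convention (Flerus et al. 2012, Biogeosciences 9:1935-1955).
#
# I_DEG = sum(intensities of "positive" formulas)
#       / sum(intensities of "positive" + "negative" formulas)
#
# "positive" formulas gain relative intensity with increasing degradation
# state, "negative" formulas lose it. The study this package re-implements
# cites but does not print the set; verify this transcription against the
# original source before relying on absolute I_DEG values, or edit the lists.
positive:
  - C13H16O8
  - C14H18O8
  - C15H20O8
  - C16H22O8
  - C17H24O8
negative:
  - C13H18O7
  - C14H20O7
  - C15H22O7
  - C15H22O8
  - C16H24O8
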