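# Relative rung offsets of the four glycan densities seen in the initial
# filament maps (anchored asparagines of N-x-[ST] sequons).  Offset 0 is
# the first glycosylated rung; uncertainties are zero because the spacers
# were read directly from the density.
name: tmem106b-glycans
features:
  - {offset: 0, class: glycosylated-asn, uncertainty: 0}
  - {offset: 6, class: glycosylated-asn, uncertainty: 0}
  - {offset: 19, class: glycosylated-asn, uncertainty: 0}
  - {offset: 38, class: glycosylated-asn, uncertainty: 0}
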