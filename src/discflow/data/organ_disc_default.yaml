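# Default Organ-Disc geometry.
#
# provenance: printed  = stated in the device description
#             derived  = back-computed from a printed rpm <-> RCF anchor
#                        (1000 rpm corresponds to 46.4 g at the tissue chamber)
#             assumed  = free placeholder, override for a real device; every
#                        result depending on one of these is flagged
geometry:
  chamber_radius: {value: 41.5, units: mm, provenance: derived}
  r_inner: {value: 10.0, units: mm, provenance: assumed}
  r_outer: {value: 45.0, units: mm, provenance: assumed}
  channel_height: {value: 75.0, units: um, provenance: printed}
  channel_width: {value: 1.4, units: mm, provenance: printed}
  channel_length: {value: 100.0, units: mm, provenance: assumed}
  port_diameter: {value: 2.0, units: mm, provenance: printed}
  head_height: {value: 8.0, units: mm, provenance: printed}
  disc_radius: {value: 50.0, units: mm, provenance: printed}
  n_systems: 4
  chambers_per_system: 5
# Metadata only (not used by the hydraulic model):
#   tissue-layer height 175 um, membrane pore diameter 3 um.
fluid:
  water_at_C: 37
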