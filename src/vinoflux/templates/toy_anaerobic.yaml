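# Anaerobic conditioning template for the bundled toy networks: analogous
# roles to the genome-scale template, using toy identifiers.
block_exchanges:
  - EX_O2
open_uptakes:
  - EX_sterol
block_reactions:
  - SHUTTLE
remove_biomass_components:
  - heme
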