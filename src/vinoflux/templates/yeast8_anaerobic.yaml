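# Anaerobic conditioning template for Yeast-8-class genome-scale models.
# Identifiers follow the yeast-GEM reaction numbering; apply with
# vinoflux.constraint.load_template + apply_anaerobic_template after
# reading the model through the SBML adapter.
block_exchanges:
  - r_1992          # oxygen exchange: vO2 LB = UB = 0
open_uptakes:       # anaerobic growth factors, unrestricted uptake
  - r_1757          # ergosterol
  - r_1915          # lanosterol
  - r_2106          # zymosterol
  - r_2134          # 14-demethyllanosterol
  - r_2137          # ergosta-5,7,22,24(28)-tetraen-3beta-ol
  - r_2189          # oleate
block_reactions:    # oxaloacetate-malate shuttle / glycerol dehydrogenase
  - r_0713
  - r_0714
  - r_0487
remove_biomass_components:
  - s_3714          # heme A, not used anaerobically
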