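# Mandatory warning ("red") FOPL thresholds, first stage (in force January 2020).
# A warning fires when the nutrient amount strictly exceeds the threshold.
# Solids are evaluated per 100 g, beverages per 100 mL.
stage: stage1_2020
solids:
  sugars_g: 13.5
  sodium_mg: 500
  sat_fat_g: 5
beverages:
  sugars_g: 5
  sodium_mg: 400
  sat_fat_g: 3
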