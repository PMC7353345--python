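# Mandatory warning ("red") FOPL thresholds, stricter second stage (January 2021).
stage: stage2_2021
solids:
  sugars_g: 10
  sodium_mg: 400
  sat_fat_g: 4
beverages:
  sugars_g: 5
  sodium_mg: 300
  sat_fat_g: 3
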