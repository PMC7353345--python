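# Israeli positive ("green") FOPL criteria, one rule per subcategory row of the
# published criteria table. Limits are per 100 g edible portion; comparisons are
# explicit (inclusive_max for "<=", strict_max for "<"). Additive tokens are the
# controlled vocabulary used by product tables; water is implicitly allowed for
# plant-based categories and need not be listed. Enrichment disqualifies every
# category and is enforced by the engine, not listed per rule.
version: israeli_positive_v1
warning_thresholds: stage1_2020
combinable_categories: [grains, legumes, fruits, vegetables, seeds_nuts]
rules:
  # --- Dairy products ---
  - category: dairy
    subcategory: liquid_milk
    allowed_additives: []          # plain milk per food standards
    limits: {}
    beverage: true
  - category: dairy
    subcategory: fermented_milk
    allowed_additives: [raw_material]   # no additives except raw materials
    limits:
      total_fat_g: {value: 5, comparison: inclusive_max}
  - category: dairy
    subcategory: cheeses
    allowed_additives: [salt, spice]
    limits:
      total_fat_g: {value: 5, comparison: inclusive_max}
      sodium_mg: {value: 200, comparison: inclusive_max}
  # --- Soy products ---
  - category: soy
    subcategory: tofu
    allowed_additives: [salt, spice, gelling_agent]
    limits:
      sodium_mg: {value: 200, comparison: inclusive_max}
  - category: soy
    subcategory: soy_drink
    allowed_additives: [soybean, water, salt]
    limits:
      sodium_mg: {value: 50, comparison: inclusive_max}
    beverage: true
  # --- Vegetable oils (avocado, almond, olive, safflower, sunflower) ---
  - category: vegetable_oil
    subcategory: oils
    allowed_additives: [tocopherol, ascorbic_acid]
    limits: {}
  # --- Seeds, nuts, almonds ---
  - category: seeds_nuts
    subcategory: raw_roasted_flour_spreads
    allowed_additives: []
    limits: {}
    mixture_base: true
  # --- Grains and pseudo-grains ---
  - category: grains
    subcategory: whole_grains
    allowed_additives: [salt, spice]
    limits:
      sodium_mg: {value: 200, comparison: inclusive_max}
    forbidden_flags: [fried]
    mixture_base: true
  - category: grains
    subcategory: whole_grain_flour
    allowed_additives: []
    limits: {}
  - category: grains
    subcategory: puffed_rice_crackers
    allowed_additives: [salt, spice]
    limits:
      sodium_mg: {value: 200, comparison: inclusive_max}
  - category: grains
    subcategory: whole_pasta
    allowed_additives: []
    limits: {}
  # --- Legumes ---
  - category: legumes
    subcategory: whole_kernel
    allowed_additives: [salt, spice]
    limits:
      sodium_mg: {value: 200, comparison: inclusive_max}
    forbidden_flags: [fried]
    mixture_base: true
  - category: legumes
    subcategory: legume_flour
    allowed_additives: []
    limits: {}
  - category: legumes
    subcategory: legume_spreads
    allowed_additives: [salt, spice, tahini, olive_oil, lemon]
    limits:
      sodium_mg: {value: 200, comparison: inclusive_max}
      total_fat_g: {value: 7, comparison: strict_max}   # "<7%", strict
  # --- Tahini from whole sesame ---
  - category: tahini
    subcategory: raw
    allowed_additives: []
    limits: {}
  - category: tahini
    subcategory: salad
    allowed_additives: [salt, spice]
    limits:
      sodium_mg: {value: 200, comparison: inclusive_max}
  # --- Eggs ---
  - category: eggs
    subcategory: fresh
    allowed_additives: []
    limits: {}
    required_flags: [fresh_raw]    # fresh, unpeeled only
  # --- Fish ---
  - category: fish
    subcategory: fresh_raw
    allowed_additives: []
    limits: {}
    required_flags: [fresh_raw]
  - category: fish
    subcategory: baked_roasted_spiced
    allowed_additives: [spice, salt]
    limits:
      sodium_mg: {value: 200, comparison: inclusive_max}
  - category: fish
    subcategory: canned
    allowed_additives: [spice, salt, water, olive_oil, avocado_oil, almond_oil, safflower_oil, sunflower_oil]
    limits:
      sodium_mg: {value: 200, comparison: inclusive_max}
  # --- Poultry ---
  - category: poultry
    subcategory: fresh_raw
    allowed_additives: []
    limits:
      sodium_mg: {value: 300, comparison: inclusive_max}
    required_flags: [fresh_raw]
  - category: poultry
    subcategory: baked_roasted_spiced
    allowed_additives: [spice, salt]
    limits:
      sodium_mg: {value: 200, comparison: inclusive_max}
  # --- Fruits ---
  - category: fruits
    subcategory: fruits
    allowed_additives: []
    limits: {}
    # no jams/confitures (sweetened), not fried, no juice, not dried/powder;
    # reconstituted freeze-dried is allowed, hence not forbidden here
    forbidden_flags: [fried, juiced, dried, sweetened]
    mixture_base: true
  # --- Vegetables ---
  - category: vegetables
    subcategory: vegetables
    allowed_additives: [spice, salt]
    limits:
      sodium_mg: {value: 200, comparison: inclusive_max}
    forbidden_flags: [fried]
    mixture_base: true
  # --- Tea and herbal infusions ---
  - category: tea
    subcategory: tea
    allowed_additives: []
    limits: {}
    beverage: true
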