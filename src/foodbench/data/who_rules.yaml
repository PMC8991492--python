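# Default category rule table for the marketing-to-children decision.
# Limits are maxima per 100 g/ml; a value exactly at the limit passes.
# The table is deliberately configuration, not code: deployments may
# deactivate thresholds (e.g. added sugars when labels only report total
# sugars) or swap in an updated official table.
version: who-europe-np-default-1
categories:
  chocolate_confectionery:
    always_prohibited: true
  cakes_sweet_biscuits:
    always_prohibited: true
  savoury_snacks:
    max_total_sugars_g: 10
    max_salt_g: 0.1
  juices:
    always_prohibited: true
  milk_drinks:
    max_total_fat_g: 2.5
    max_added_sugars_g: 0
    prohibit_non_sugar_sweeteners: true
  energy_drinks:
    always_prohibited: true
  other_beverages:
    max_added_sugars_g: 0
    prohibit_non_sugar_sweeteners: true
  edible_ices:
    always_prohibited: true
  breakfast_cereals:
    max_total_fat_g: 10
    max_total_sugars_g: 15
    max_salt_g: 1.6
  yoghurts:
    max_total_fat_g: 2.5
    max_total_sugars_g: 10
    max_salt_g: 0.2
  cheese:
    max_total_fat_g: 20
    max_salt_g: 1.3
  ready_made:
    max_total_fat_g: 10
    max_total_sugars_g: 10
    max_salt_g: 1.0
    max_energy_kj: 941
  butter_fats_oils:
    max_saturated_fat_g: 20
    max_salt_g: 1.3
  bread:
    max_total_fat_g: 10
    max_total_sugars_g: 10
    max_salt_g: 1.2
  pasta_rice_grains:
    max_total_fat_g: 10
    max_total_sugars_g: 10
    max_salt_g: 1.2
  fresh_meat_fish:
    max_total_fat_g: 10
  processed_meat:
    max_total_fat_g: 20
    max_salt_g: 1.7
  fresh_fruit_veg:
    max_added_sugars_g: 0
    max_salt_g: 1.0
  processed_fruit_veg:
    max_total_fat_g: 5
    max_total_sugars_g: 10
    max_salt_g: 1.0
  sauces_dips:
    max_total_fat_g: 10
    max_total_sugars_g: 10
    max_salt_g: 1.0
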