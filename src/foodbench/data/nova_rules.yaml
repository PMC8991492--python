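# Default NOVA classification rules.  A curated per-product override
# always wins; otherwise any group-4 marker token forces group 4;
# otherwise the category default applies.
version: nova-default-1
group4_markers:
  - flavouring
  - colour
  - emulsifier
  - sweetener
  - hydrolysed_protein
  - maltodextrin
  - glucose_fructose_syrup
  - modified_starch
category_groups:
  fresh_fruit_veg: 1
  fresh_meat_fish: 1
  pasta_rice_grains: 1
  juices: 1
  milk_drinks: 1
  butter_fats_oils: 2
  bread: 3
  cheese: 3
  processed_meat: 3
  processed_fruit_veg: 3
  yoghurts: 3
  other_beverages: 4
  energy_drinks: 4
  edible_ices: 4
default_group: 3
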