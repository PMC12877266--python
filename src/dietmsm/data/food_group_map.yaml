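# Default FFQ item -> food group map with dairy subtype memberships.
# Every dairy item carries exactly one of {fermented, non_fermented} and one
# of {full_fat, low_fat}; "sugary" is an independent flag.  Butter is treated
# as full-fat non-fermented dairy.  Edit freely: nothing here is hard-coded.
items:
  milk:
    group: dairy
    subtypes: [non_fermented, full_fat]
  milk_skimmed:
    group: dairy
    subtypes: [non_fermented, low_fat]
  yogurt:
    group: dairy
    subtypes: [fermented, full_fat]
  yogurt_lowfat:
    group: dairy
    subtypes: [fermented, low_fat]
  yogurt_flavored:
    group: dairy
    subtypes: [fermented, full_fat, sugary]
  cheese:
    group: dairy
    subtypes: [fermented, full_fat]
  cheese_lowfat:
    group: dairy
    subtypes: [fermented, low_fat]
  cream:
    group: dairy
    subtypes: [non_fermented, full_fat, sugary]
  butter:
    group: dairy
    subtypes: [non_fermented, full_fat]
  dairy_dessert:
    group: dairy
    subtypes: [non_fermented, full_fat, sugary]
  dairy_dessert_lowfat:
    group: dairy
    subtypes: [non_fermented, low_fat, sugary]
  vegetables:
    group: vegetables
  fruits:
    group: fruits
  fish:
    group: fish
  meat:
    group: meat
  eggs:
    group: eggs
  grains:
    group: grains
  alcohol:
    group: alcohol
  sugary_processed:
    group: sugary_processed
  high_fat_foods:
    group: high_fat_foods
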