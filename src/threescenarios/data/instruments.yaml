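# Scoring structure of the three patient-reported instruments.
# Item wordings are not shipped (the instruments are licensed); only the
# arithmetic needed to score a response vector is defined here.
#
# scale: inclusive response range per item
# reverse_items: 1-based indices mapped r -> min + max - r before summing
# scored_items: 1-based indices contributing to the total (omitted = all);
#               other items are fillers
# score_range: attainable range of the total over scored items

stai6:           # short-form state anxiety, 6 items; higher = more anxious
  n_items: 6
  scale: [1, 4]
  reverse_items: [1, 4, 5]   # calm / relaxed / content
  score_range: [6, 24]

hhi:             # hope index, 12 items; higher = more hopeful
  n_items: 12
  scale: [1, 4]
  reverse_items: [3, 6]
  score_range: [12, 48]

lotr:            # revised life-orientation (optimism), 10 items, 4 fillers
  n_items: 10
  scale: [0, 4]
  scored_items: [1, 3, 4, 7, 9, 10]
  reverse_items: [3, 7, 9]
  score_range: [0, 24]
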