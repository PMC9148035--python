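# Pregnancy-modified Mediterranean Diet Score standards.
#
# Ten components (alcohol excluded for pregnancy; milk and dairy treated as
# protective), each scored 0-5 from monthly consumption frequency. For a
# protective component the score is the number of ascending thresholds the
# consumption reaches (>=); for an adverse component that count is
# subtracted from 5 (never consumed -> 5). Thresholds follow the
# 0 / 1-4 / 5-8 / 9-12 / 13-18 / >18 servings-per-month band scheme of the
# original index.
#
# NOTE: the dairy component is reclassified as protective for pregnancy and,
# as an assumption, reuses the same frequency bands as the other protective
# components (the source index scored it as adverse).
version: 1
units: servings/month
components:
  - name: nonrefined_cereals
    direction: protective
    thresholds: [1, 5, 9, 13, 19]
  - name: potatoes
    direction: protective
    thresholds: [1, 5, 9, 13, 19]
  - name: fruits
    direction: protective
    thresholds: [1, 5, 9, 13, 19]
  - name: vegetables
    direction: protective
    thresholds: [1, 5, 9, 13, 19]
  - name: legumes
    direction: protective
    thresholds: [1, 5, 9, 13, 19]
  - name: fish
    direction: protective
    thresholds: [1, 5, 9, 13, 19]
  - name: olive_oil
    direction: protective
    thresholds: [1, 5, 9, 13, 19]
  - name: dairy   # reclassified protective for pregnancy (assumption: same bands)
    direction: protective
    thresholds: [1, 5, 9, 13, 19]
  - name: red_meat_products
    direction: adverse
    thresholds: [1, 5, 9, 13, 19]
  - name: poultry
    direction: adverse
    thresholds: [1, 5, 9, 13, 19]
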