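# Glycemic index values of the carbohydrate-bearing items, on the
# white-bread reference scale (white bread = 100). Glucose-scale values can
# be converted with the optional factor 100/70.
version: 1
reference: white_bread
foods:
  white_bread: 100
  pasta: 65
  fruit: 52
  sweets: 84
  rice: 83
  potatoes: 90
  legumes: 40
  milk: 39
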