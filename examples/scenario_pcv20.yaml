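# Packaged example scenario: 20-serotype panel, skewed IPD-like
# frequency distribution scaled to 10% overall carriage prevalence,
# component tests at 80% sensitivity / 99.75% specificity, with the
# nested PCV vaccine serotype groups.
seed: 1
n_subjects: 4000
target_panel_prev: 0.1
sens: 0.8
spec: 0.9975
weights:
  '8': 0.256
  '3': 0.09
  19A: 0.06
  22F: 0.05
  12F: 0.04
  15B: 0.035
  10A: 0.03
  11A: 0.028
  33F: 0.025
  7F: 0.02
  '1': 0.012
  '4': 0.012
  '14': 0.01
  6A: 0.01
  19F: 0.008
  23F: 0.007
  6B: 0.005
  9V: 0.003
  18C: 0.002
  '5': 0.0
groups:
  PCV7:
  - '4'
  - 6B
  - 9V
  - '14'
  - 18C
  - 19F
  - 23F
  PCV13:
  - '4'
  - 6B
  - 9V
  - '14'
  - 18C
  - 19F
  - 23F
  - '1'
  - '3'
  - '5'
  - 6A
  - 7F
  - 19A
  PCV15:
  - '4'
  - 6B
  - 9V
  - '14'
  - 18C
  - 19F
  - 23F
  - '1'
  - '3'
  - '5'
  - 6A
  - 7F
  - 19A
  - 22F
  - 33F
  PCV20:
  - '8'
  - '3'
  - 19A
  - 22F
  - 12F
  - 15B
  - 10A
  - 11A
  - 33F
  - 7F
  - '1'
  - '4'
  - '14'
  - 6A
  - 19F
  - 23F
  - 6B
  - 9V
  - 18C
  - '5'
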