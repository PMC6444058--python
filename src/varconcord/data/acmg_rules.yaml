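# ACMG-AMP evidence combining rules, frozen as data.
#
# Each rule lists minimum counts of applied evidence strengths on one
# polarity; a rule fires when every listed count is met or exceeded.
# Outcomes on the same side are resolved by precedence: pathogenic beats
# likely pathogenic, benign beats likely benign. When both a
# pathogenic-side and a benign-side rule fire, the combined call is
# uncertain significance with the conflict flag set.
pathogenic:
  - name: "1 very strong + >=1 strong"
    requires: {very_strong: 1, strong: 1}
  - name: "1 very strong + >=2 moderate"
    requires: {very_strong: 1, moderate: 2}
  - name: "1 very strong + 1 moderate + 1 supporting"
    requires: {very_strong: 1, moderate: 1, supporting: 1}
  - name: "1 very strong + >=2 supporting"
    requires: {very_strong: 1, supporting: 2}
  - name: ">=2 strong"
    requires: {strong: 2}
  - name: "1 strong + >=3 moderate"
    requires: {strong: 1, moderate: 3}
  - name: "1 strong + 2 moderate + >=2 supporting"
    requires: {strong: 1, moderate: 2, supporting: 2}
  - name: "1 strong + 1 moderate + >=4 supporting"
    requires: {strong: 1, moderate: 1, supporting: 4}
likely_pathogenic:
  - name: "1 very strong + 1 moderate"
    requires: {very_strong: 1, moderate: 1}
  - name: "1 strong + 1-2 moderate"
    requires: {strong: 1, moderate: 1}
  - name: "1 strong + >=2 supporting"
    requires: {strong: 1, supporting: 2}
  - name: ">=3 moderate"
    requires: {moderate: 3}
  - name: "2 moderate + >=2 supporting"
    requires: {moderate: 2, supporting: 2}
  - name: "1 moderate + >=4 supporting"
    requires: {moderate: 1, supporting: 4}
benign:
  - name: ">=1 stand-alone"
    requires: {stand_alone: 1}
  - name: ">=2 strong"
    requires: {strong: 2}
likely_benign:
  - name: "1 strong + >=1 supporting"
    requires: {strong: 1, supporting: 1}
  - name: ">=2 supporting"
    requires: {supporting: 2}
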