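name: HKY
states: 4
class_label: DNA
frequency_structure: free
allow_double: false
free_param_count: 4
exchangeability:
  A:C: tv
  A:G: ts
  A:U: tv
  C:G: tv
  C:U: ts
  G:U: tv
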