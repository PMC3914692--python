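name: GTR
states: 4
class_label: DNA
frequency_structure: free
allow_double: false
free_param_count: 8
exchangeability:
  A:C: s_AC
  A:G: s_AG
  A:U: s_AU
  C:G: s_CG
  C:U: s_CU
  G:U: s_GU
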