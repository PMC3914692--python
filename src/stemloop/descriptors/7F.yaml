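name: 7F
states: 7
class_label: StablePairs
frequency_structure: strand_symmetric
allow_double: false
free_param_count: 7
exchangeability:
  AU:GU: s_AU_GU
  AU:MM: s_AU_MM
  GU:GC: s_GU_GC
  GU:MM: s_GU_MM
  GC:MM: s_GC_MM
  UA:UG: s_AU_GU
  UA:MM: s_AU_MM
  UG:CG: s_GU_GC
  UG:MM: s_GU_MM
  CG:MM: s_GC_MM
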