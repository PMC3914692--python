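name: 7B
states: 7
class_label: StablePairs
frequency_structure: strand_symmetric
allow_double: true
free_param_count: 14
exchangeability:
  AU:GU: s_AU_GU
  AU:GC: s_AU_GC
  AU:UA: s_AU_UA
  AU:UG: s_AU_UG
  AU:CG: s_AU_CG
  AU:MM: s_AU_MM
  GU:GC: s_GU_GC
  GU:UA: s_AU_UG
  GU:UG: s_GU_UG
  GU:CG: s_GU_CG
  GU:MM: s_GU_MM
  GC:UA: s_AU_CG
  GC:UG: s_GU_CG
  GC:CG: s_GC_CG
  GC:MM: s_GC_MM
  UA:UG: s_AU_GU
  UA:CG: s_AU_GC
  UA:MM: s_AU_MM
  UG:CG: s_GU_GC
  UG:MM: s_GU_MM
  CG:MM: s_GC_MM
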