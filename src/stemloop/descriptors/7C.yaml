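name: 7C
states: 7
class_label: StablePairs
frequency_structure: free
allow_double: true
free_param_count: 16
exchangeability:
  AU:GU: s_AU_GU
  AU:GC: double
  AU:UA: double
  AU:UG: double
  AU:CG: double
  AU:MM: s_AU_MM
  GU:GC: s_GU_GC
  GU:UA: double
  GU:UG: double
  GU:CG: double
  GU:MM: s_GU_MM
  GC:UA: double
  GC:UG: double
  GC:CG: double
  GC:MM: s_GC_MM
  UA:UG: s_UA_UG
  UA:CG: double
  UA:MM: s_UA_MM
  UG:CG: s_UG_CG
  UG:MM: s_UG_MM
  CG:MM: s_CG_MM
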