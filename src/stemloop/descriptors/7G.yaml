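name: 7G
states: 7
class_label: StablePairs
frequency_structure: strand_symmetric
allow_double: false
free_param_count: 4
exchangeability:
  AU:GU: single
  AU:MM: mm
  GU:GC: single
  GU:MM: mm
  GC:MM: mm
  UA:UG: single
  UA:MM: mm
  UG:CG: single
  UG:MM: mm
  CG:MM: mm
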