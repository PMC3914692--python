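name: 7D
states: 7
class_label: StablePairs
frequency_structure: free
allow_double: true
free_param_count: 8
exchangeability:
  AU:GU: single
  AU:GC: double
  AU:UA: double
  AU:UG: double
  AU:CG: double
  AU:MM: mm
  GU:GC: single
  GU:UA: double
  GU:UG: double
  GU:CG: double
  GU:MM: mm
  GC:UA: double
  GC:UG: double
  GC:CG: double
  GC:MM: mm
  UA:UG: single
  UA:CG: double
  UA:MM: mm
  UG:CG: single
  UG:MM: mm
  CG:MM: mm
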