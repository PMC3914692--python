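name: 16F
states: 16
class_label: StableSets
frequency_structure: stable_sets
allow_double: false
free_param_count: 5
exchangeability:
  AA:AC: single
  AA:AG: single
  AA:AU: single
  AA:CA: single
  AA:GA: single
  AA:UA: single
  AC:AG: single
  AC:AU: single
  AC:CC: single
  AC:GC: single
  AC:UC: single
  AG:AU: single
  AG:CG: single
  AG:GG: single
  AG:UG: single
  AU:CU: single
  AU:GU: single
  AU:UU: single
  CA:CC: single
  CA:CG: single
  CA:CU: single
  CA:GA: single
  CA:UA: single
  CC:CG: single
  CC:CU: single
  CC:GC: single
  CC:UC: single
  CG:CU: single
  CG:GG: single
  CG:UG: single
  CU:GU: single
  CU:UU: single
  GA:GC: single
  GA:GG: single
  GA:GU: single
  GA:UA: single
  GC:GG: single
  GC:GU: single
  GC:UC: single
  GG:GU: single
  GG:UG: single
  GU:UU: single
  UA:UC: single
  UA:UG: single
  UA:UU: single
  UC:UG: single
  UC:UU: single
  UG:UU: single
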