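name: 16J
states: 16
class_label: AllPairs
frequency_structure: free
allow_double: false
free_param_count: 16
exchangeability:
  AA:AC: tv
  AA:AG: ts
  AA:AU: tv
  AA:CA: tv
  AA:GA: ts
  AA:UA: tv
  AC:AG: tv
  AC:AU: ts
  AC:CC: tv
  AC:GC: ts
  AC:UC: tv
  AG:AU: tv
  AG:CG: tv
  AG:GG: ts
  AG:UG: tv
  AU:CU: tv
  AU:GU: ts
  AU:UU: tv
  CA:CC: tv
  CA:CG: ts
  CA:CU: tv
  CA:GA: tv
  CA:UA: ts
  CC:CG: tv
  CC:CU: ts
  CC:GC: tv
  CC:UC: ts
  CG:CU: tv
  CG:GG: tv
  CG:UG: ts
  CU:GU: tv
  CU:UU: ts
  GA:GC: tv
  GA:GG: ts
  GA:GU: tv
  GA:UA: tv
  GC:GG: tv
  GC:GU: ts
  GC:UC: tv
  GG:GU: tv
  GG:UG: tv
  GU:UU: tv
  UA:UC: tv
  UA:UG: ts
  UA:UU: tv
  UC:UG: tv
  UC:UU: ts
  UG:UU: tv
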