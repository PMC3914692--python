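name: 16K
states: 16
class_label: AllPairs
frequency_structure: free
allow_double: true
free_param_count: 17
exchangeability:
  AA:AC: tv
  AA:AG: ts
  AA:AU: tv
  AA:CA: tv
  AA:CC: double
  AA:CG: double
  AA:CU: double
  AA:GA: ts
  AA:GC: double
  AA:GG: double
  AA:GU: double
  AA:UA: tv
  AA:UC: double
  AA:UG: double
  AA:UU: double
  AC:AG: tv
  AC:AU: ts
  AC:CA: double
  AC:CC: tv
  AC:CG: double
  AC:CU: double
  AC:GA: double
  AC:GC: ts
  AC:GG: double
  AC:GU: double
  AC:UA: double
  AC:UC: tv
  AC:UG: double
  AC:UU: double
  AG:AU: tv
  AG:CA: double
  AG:CC: double
  AG:CG: tv
  AG:CU: double
  AG:GA: double
  AG:GC: double
  AG:GG: ts
  AG:GU: double
  AG:UA: double
  AG:UC: double
  AG:UG: tv
  AG:UU: double
  AU:CA: double
  AU:CC: double
  AU:CG: double
  AU:CU: tv
  AU:GA: double
  AU:GC: double
  AU:GG: double
  AU:GU: ts
  AU:UA: double
  AU:UC: double
  AU:UG: double
  AU:UU: tv
  CA:CC: tv
  CA:CG: ts
  CA:CU: tv
  CA:GA: tv
  CA:GC: double
  CA:GG: double
  CA:GU: double
  CA:UA: ts
  CA:UC: double
  CA:UG: double
  CA:UU: double
  CC:CG: tv
  CC:CU: ts
  CC:GA: double
  CC:GC: tv
  CC:GG: double
  CC:GU: double
  CC:UA: double
  CC:UC: ts
  CC:UG: double
  CC:UU: double
  CG:CU: tv
  CG:GA: double
  CG:GC: double
  CG:GG: tv
  CG:GU: double
  CG:UA: double
  CG:UC: double
  CG:UG: ts
  CG:UU: double
  CU:GA: double
  CU:GC: double
  CU:GG: double
  CU:GU: tv
  CU:UA: double
  CU:UC: double
  CU:UG: double
  CU:UU: ts
  GA:GC: tv
  GA:GG: ts
  GA:GU: tv
  GA:UA: tv
  GA:UC: double
  GA:UG: double
  GA:UU: double
  GC:GG: tv
  GC:GU: ts
  GC:UA: double
  GC:UC: tv
  GC:UG: double
  GC:UU: double
  GG:GU: tv
  GG:UA: double
  GG:UC: double
  GG:UG: tv
  GG:UU: double
  GU:UA: double
  GU:UC: double
  GU:UG: double
  GU:UU: tv
  UA:UC: tv
  UA:UG: ts
  UA:UU: tv
  UC:UG: tv
  UC:UU: ts
  UG:UU: tv
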