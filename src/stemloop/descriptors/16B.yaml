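name: 16B
states: 16
class_label: AllPairs
frequency_structure: free
allow_double: true
free_param_count: 21
exchangeability:
  AA:AC: s_AC
  AA:AG: s_AG
  AA:AU: s_AU
  AA:CA: s_AC
  AA:CC: double
  AA:CG: double
  AA:CU: double
  AA:GA: s_AG
  AA:GC: double
  AA:GG: double
  AA:GU: double
  AA:UA: s_AU
  AA:UC: double
  AA:UG: double
  AA:UU: double
  AC:AG: s_CG
  AC:AU: s_CU
  AC:CA: double
  AC:CC: s_AC
  AC:CG: double
  AC:CU: double
  AC:GA: double
  AC:GC: s_AG
  AC:GG: double
  AC:GU: double
  AC:UA: double
  AC:UC: s_AU
  AC:UG: double
  AC:UU: double
  AG:AU: s_GU
  AG:CA: double
  AG:CC: double
  AG:CG: s_AC
  AG:CU: double
  AG:GA: double
  AG:GC: double
  AG:GG: s_AG
  AG:GU: double
  AG:UA: double
  AG:UC: double
  AG:UG: s_AU
  AG:UU: double
  AU:CA: double
  AU:CC: double
  AU:CG: double
  AU:CU: s_AC
  AU:GA: double
  AU:GC: double
  AU:GG: double
  AU:GU: s_AG
  AU:UA: double
  AU:UC: double
  AU:UG: double
  AU:UU: s_AU
  CA:CC: s_AC
  CA:CG: s_AG
  CA:CU: s_AU
  CA:GA: s_CG
  CA:GC: double
  CA:GG: double
  CA:GU: double
  CA:UA: s_CU
  CA:UC: double
  CA:UG: double
  CA:UU: double
  CC:CG: s_CG
  CC:CU: s_CU
  CC:GA: double
  CC:GC: s_CG
  CC:GG: double
  CC:GU: double
  CC:UA: double
  CC:UC: s_CU
  CC:UG: double
  CC:UU: double
  CG:CU: s_GU
  CG:GA: double
  CG:GC: double
  CG:GG: s_CG
  CG:GU: double
  CG:UA: double
  CG:UC: double
  CG:UG: s_CU
  CG:UU: double
  CU:GA: double
  CU:GC: double
  CU:GG: double
  CU:GU: s_CG
  CU:UA: double
  CU:UC: double
  CU:UG: double
  CU:UU: s_CU
  GA:GC: s_AC
  GA:GG: s_AG
  GA:GU: s_AU
  GA:UA: s_GU
  GA:UC: double
  GA:UG: double
  GA:UU: double
  GC:GG: s_CG
  GC:GU: s_CU
  GC:UA: double
  GC:UC: s_GU
  GC:UG: double
  GC:UU: double
  GG:GU: s_GU
  GG:UA: double
  GG:UC: double
  GG:UG: s_GU
  GG:UU: double
  GU:UA: double
  GU:UC: double
  GU:UG: double
  GU:UU: s_GU
  UA:UC: s_AC
  UA:UG: s_AG
  UA:UU: s_AU
  UC:UG: s_CG
  UC:UU: s_CU
  UG:UU: s_GU
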