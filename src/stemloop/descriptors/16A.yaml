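name: 16A
states: 16
class_label: AllPairs
frequency_structure: free
allow_double: false
free_param_count: 20
exchangeability:
  AA:AC: s_AC
  AA:AG: s_AG
  AA:AU: s_AU
  AA:CA: s_AC
  AA:GA: s_AG
  AA:UA: s_AU
  AC:AG: s_CG
  AC:AU: s_CU
  AC:CC: s_AC
  AC:GC: s_AG
  AC:UC: s_AU
  AG:AU: s_GU
  AG:CG: s_AC
  AG:GG: s_AG
  AG:UG: s_AU
  AU:CU: s_AC
  AU:GU: s_AG
  AU:UU: s_AU
  CA:CC: s_AC
  CA:CG: s_AG
  CA:CU: s_AU
  CA:GA: s_CG
  CA:UA: s_CU
  CC:CG: s_CG
  CC:CU: s_CU
  CC:GC: s_CG
  CC:UC: s_CU
  CG:CU: s_GU
  CG:GG: s_CG
  CG:UG: s_CU
  CU:GU: s_CG
  CU:UU: s_CU
  GA:GC: s_AC
  GA:GG: s_AG
  GA:GU: s_AU
  GA:UA: s_GU
  GC:GG: s_CG
  GC:GU: s_CU
  GC:UC: s_GU
  GG:GU: s_GU
  GG:UG: s_GU
  GU:UU: s_GU
  UA:UC: s_AC
  UA:UG: s_AG
  UA:UU: s_AU
  UC:UG: s_CG
  UC:UU: s_CU
  UG:UU: s_GU
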