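name: 16C
states: 16
class_label: StablePairs
frequency_structure: pooled_mismatch
allow_double: true
free_param_count: 9
exchangeability:
  AA:AC: mm_mm
  AA:AG: mm_mm
  AA:AU: pair_mm
  AA:CA: mm_mm
  AA:CC: mm_mm
  AA:CG: pair_mm
  AA:CU: mm_mm
  AA:GA: mm_mm
  AA:GC: pair_mm
  AA:GG: mm_mm
  AA:GU: pair_mm
  AA:UA: pair_mm
  AA:UC: mm_mm
  AA:UG: pair_mm
  AA:UU: mm_mm
  AC:AG: mm_mm
  AC:AU: pair_mm
  AC:CA: mm_mm
  AC:CC: mm_mm
  AC:CG: pair_mm
  AC:CU: mm_mm
  AC:GA: mm_mm
  AC:GC: pair_mm
  AC:GG: mm_mm
  AC:GU: pair_mm
  AC:UA: pair_mm
  AC:UC: mm_mm
  AC:UG: pair_mm
  AC:UU: mm_mm
  AG:AU: pair_mm
  AG:CA: mm_mm
  AG:CC: mm_mm
  AG:CG: pair_mm
  AG:CU: mm_mm
  AG:GA: mm_mm
  AG:GC: pair_mm
  AG:GG: mm_mm
  AG:GU: pair_mm
  AG:UA: pair_mm
  AG:UC: mm_mm
  AG:UG: pair_mm
  AG:UU: mm_mm
  AU:CA: pair_mm
  AU:CC: pair_mm
  AU:CG: double
  AU:CU: pair_mm
  AU:GA: pair_mm
  AU:GC: double
  AU:GG: pair_mm
  AU:GU: single
  AU:UA: double
  AU:UC: pair_mm
  AU:UG: double
  AU:UU: pair_mm
  CA:CC: mm_mm
  CA:CG: pair_mm
  CA:CU: mm_mm
  CA:GA: mm_mm
  CA:GC: pair_mm
  CA:GG: mm_mm
  CA:GU: pair_mm
  CA:UA: pair_mm
  CA:UC: mm_mm
  CA:UG: pair_mm
  CA:UU: mm_mm
  CC:CG: pair_mm
  CC:CU: mm_mm
  CC:GA: mm_mm
  CC:GC: pair_mm
  CC:GG: mm_mm
  CC:GU: pair_mm
  CC:UA: pair_mm
  CC:UC: mm_mm
  CC:UG: pair_mm
  CC:UU: mm_mm
  CG:CU: pair_mm
  CG:GA: pair_mm
  CG:GC: double
  CG:GG: pair_mm
  CG:GU: double
  CG:UA: double
  CG:UC: pair_mm
  CG:UG: single
  CG:UU: pair_mm
  CU:GA: mm_mm
  CU:GC: pair_mm
  CU:GG: mm_mm
  CU:GU: pair_mm
  CU:UA: pair_mm
  CU:UC: mm_mm
  CU:UG: pair_mm
  CU:UU: mm_mm
  GA:GC: pair_mm
  GA:GG: mm_mm
  GA:GU: pair_mm
  GA:UA: pair_mm
  GA:UC: mm_mm
  GA:UG: pair_mm
  GA:UU: mm_mm
  GC:GG: pair_mm
  GC:GU: single
  GC:UA: double
  GC:UC: pair_mm
  GC:UG: double
  GC:UU: pair_mm
  GG:GU: pair_mm
  GG:UA: pair_mm
  GG:UC: mm_mm
  GG:UG: pair_mm
  GG:UU: mm_mm
  GU:UA: double
  GU:UC: pair_mm
  GU:UG: double
  GU:UU: pair_mm
  UA:UC: pair_mm
  UA:UG: single
  UA:UU: pair_mm
  UC:UG: pair_mm
  UC:UU: mm_mm
  UG:UU: pair_mm
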