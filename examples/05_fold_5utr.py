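"""Score 5'UTR secondary-structure stability.

The internal engine is a deterministic Nussinov-style DP maximising
weighted base pairs (GC=3, AU=2, GU=1; >=3-nt hairpin loops); its score
is a structure proxy, not a thermodynamic free energy. If RNAfold is on
PATH, the external engine reports a true mfe in kcal/mol.
"""

from utrscape import RNAfoldAdapter, fold_external, fold_internal

gc_rich = "GGGCGCGAAAGCGCGCCC"
au_rich = "AAUUAAAUAAAUUUAAAU"

for name, seq in (("GC-rich", gc_rich), ("AU-rich", au_rich)):
    r = fold_internal(seq)
    print(f"{name}: internal score {r.score:>6.1f}  {r.structure}")
# The GC-rich hairpin scores far below the AU-rich sequence: more and
# stronger pairs, i.e. more predicted structure.

adapter = RNAfoldAdapter()
if adapter.available():
    for name, seq in (("GC-rich", gc_rich), ("AU-rich", au_rich)):
        r = fold_external(seq, adapter)
        print(f"{name}: RNAfold mfe {r.score:>6.1f} kcal/mol  {r.structure}")
else:
    print("RNAfold not on PATH; external engine unavailable")
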