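"""Expanded epigenetic alphabet: complementation and ambiguity codes.

Every symbol encodes a base pair, so modified cytosines (m, h, f, c) have
dedicated guanine partners (1, 2, 3, 4) and complementation loses no
modification information.
"""

from modmotif import expand_symbol, reverse_complement, write_alphabet_definition

# The ZFP57 binding motif TGCCGCG with both CpGs fully methylated is
# written TGCm1m1; its reverse complement carries the same methylation.
motif = "TGCm1m1"
print(f"{motif}  ->  reverse complement  ->  {reverse_complement(motif)}")

# Ambiguity codes express assay uncertainty: x is methylated-or-
# hydroxymethylated, z a cytosine of completely unknown state.
for sym in "xz9":
    print(f"{sym} expands to {{{', '.join(sorted(expand_symbol(sym)))}}}")

# A MEME-suite-style alphabet definition (core pairs, ambiguities, wildcard):
print()
print(write_alphabet_definition(), end="")
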