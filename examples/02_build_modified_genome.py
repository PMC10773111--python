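"""Rewrite a toy assembly into the expanded alphabet.

Modification records have the shape of MLML output (5mC level, 5hmC level,
conflict count, per strand). At threshold t = 0.3: a plus-strand C with
m >= t becomes m; a minus-strand record rewrites the complementary G; any
conflict yields z; sub-threshold levels whose sum reaches t yield x.
"""

from modmotif import ModificationRecord, build_modified_genome

genome = {"chr1": "ACGTCGACGCGT"}
records = [
    ModificationRecord("chr1", 4, "+", level_m=0.9, level_h=0.0),   # -> m
    ModificationRecord("chr1", 5, "-", level_m=0.9, level_h=0.0),   # -> 1
    ModificationRecord("chr1", 9, "+", level_m=0.2, level_h=0.15),  # -> x
    ModificationRecord("chr1", 1, "+", level_m=0.9, level_h=0.0, conflicts=1),  # -> z
]

result = build_modified_genome(genome, records, t=0.3)
print(f"input : {genome['chr1']}")
print(f"output: {result.sequences['chr1']}")
print("per-symbol call counts:", dict(result.call_counts))
# The fully methylated CpG at 4-5 is now m1 on both strands; position 9
# could be either modification (m + h = 0.35 >= 0.3) so it is x; the
# conflicted position 1 is z (unknown modification state).
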