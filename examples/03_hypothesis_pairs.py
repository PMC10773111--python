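"""CpG hypothesis pairs for the c-Myc E-box, with solved pseudocounts.

Each unmodified motif is paired with the six possible CpG
methylation/hydroxymethylation states (a CpG is never both hemi-methylated
and hemi-hydroxymethylated). Because modified symbols are rare in the
background, each modified motif gets a larger pseudocount alpha, solved so
that the relative entropy per column of the pair is exactly equal.
"""

from modmotif import enumerate_cpg_hypotheses, equalization_gap
from modmotif.motifs import mouse_like_background

bg = mouse_like_background()  # GC 0.42, ~2% modified symbols
print(f"{'label':<6}{'modified':<10}{'n_mod':>6}{'alpha':>10}{'alpha_total':>13}"
      f"{'RE/col gap':>12}")
for pair in enumerate_cpg_hypotheses("CACGTG", bg):
    print(f"{pair.label:<6}{pair.mod_string:<10}"
          f"{pair.n_modified_positions:>6}{pair.alpha:>10.4f}"
          f"{pair.alpha_total:>13.4f}{equalization_gap(pair, bg):>12.2e}")
# Hemi patterns modify one strand (1 position per CpG), full patterns both
# (2 per CpG). The motif-wide pseudocount is n_mod x alpha, and the RE/col
# gap column shows the equalization holds to machine precision.
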