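"""Central-enrichment binomial test on a small synthetic region set.

Sequences whose best motif site concentrates at the centre get a small
one-tailed binomial p-value; uniformly scattered sites do not.
"""

import numpy as np

from modmotif import Background, apply_pseudocount, central_enrichment, pwm_from_string

rng = np.random.default_rng(0)
L, w = 101, 6


def make_regions(central: bool, n=50):
    regions = []
    for _ in range(n):
        seq = "".join(rng.choice(list("ACGT"), L))
        pos = (L - w) // 2 if central else int(rng.integers(0, L - w + 1))
        regions.append(seq[:pos] + "CACGTG" + seq[pos + w:])
    return regions


bg = Background.from_sequences(make_regions(True))
pwm = apply_pseudocount(pwm_from_string("CACGTG"), 0.1, bg)

for name, central in (("central sites", True), ("scattered sites", False)):
    res = central_enrichment(make_regions(central), pwm, bg,
                             min_region=21, max_region=21)
    print(f"{name:<16} n_scored={res.n_scored:>3} n_central={res.n_central:>5.1f} "
          f"p_null={res.p_null:.3f} log10(p_adj)={res.log10_p_adjusted:8.2f}")
# The centrally planted set yields an extremely small p-value; the
# scattered set stays near the null (log10 p close to 0).
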