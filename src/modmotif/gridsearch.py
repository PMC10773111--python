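"""Threshold grid search: hypothesis-pair scores across calling thresholds.

The modified-base calling threshold t controls how much evidence a CpG
needs before it is rewritten into the expanded alphabet. Sweeping t (by
default 0.01 to 0.99 inclusive in steps of 0.01) and re-running the whole
pipeline — genome rebuild, region re-extraction, hypothesis re-scoring —
maps out how robust a factor's modification preference is to the
threshold choice. Regions are drawn from the *modified* genome, so every
stage is threshold-dependent and recomputed per threshold; only the input
parsing (genome, records, peaks) is shared across thresholds. Thresholds
are independent work units and results do not depend on evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Union

import pandas as pd

from .centrality import DEFAULT_MAX_REGION, DEFAULT_MIN_REGION, central_enrichment
from .genome import (
    GenomeLike,
    ModificationRecord,
    Peak,
    build_modified_genome,
    extract_regions,
    load_genome,
    read_peaks,
    read_track,
)
from .hypotheses import UNMODIFIED_ALPHA, enumerate_cpg_hypotheses
from .motifs import (
    Background,
    DEFAULT_SITE_SCORE_BITS,
    ExpandedPWM,
    apply_pseudocount,
    pwm_from_string,
)
from .scoring import filter_and_rank, pair_score_log10


def default_thresholds() -> List[float]:
    """The 99-value grid 0.01, 0.02, ..., 0.99."""
    return [round(0.01 * i, 2) for i in range(1, 100)]


@dataclass
class ThresholdSweep:
    thresholds: List[float]
    rows: pd.DataFrame  # columns: threshold, motif, label, score, p_unmod, p_mod

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ValueError("thresholds must be strictly increasing")


def score_hypotheses(regions: Sequence[str], motif: Union[str, ExpandedPWM],
                     bg: Optional[Background] = None,
                     min_region: int = DEFAULT_MIN_REGION,
                     max_region: int = DEFAULT_MAX_REGION,
                     score_threshold: float = DEFAULT_SITE_SCORE_BITS,
                     top_k: Optional[int] = None):
    """Score every CpG hypothesis pair of one motif on a region set.

    The unmodified member scans with the fixed pseudocount 0.1, the
    modified member with its solved motif-wide pseudocount alpha_total;
    both use the same background, central-region widths and site score
    threshold, so their adjusted p-values are directly comparable. With
    ``top_k`` set, only the most significant pairs are retained (pairs
    with min p >= 0.05 dropped), as in the aggregation protocol.
    """
    if bg is None:
        bg = Background.from_sequences(regions)
    pwm = pwm_from_string(motif) if isinstance(motif, str) else motif
    pairs = enumerate_cpg_hypotheses(pwm, bg)
    scores = []
    unmod_scan = apply_pseudocount(pwm, UNMODIFIED_ALPHA, bg, renormalize=True)
    res_unmod = central_enrichment(regions, unmod_scan, bg, min_region,
                                   max_region, score_threshold=score_threshold)
    for pair in pairs:
        mod_scan = apply_pseudocount(pair.modified, pair.alpha_total, bg,
                                     renormalize=True)
        res_mod = central_enrichment(regions, mod_scan, bg, min_region,
                                     max_region, score_threshold=score_threshold)
        scores.append(pair_score_log10(res_unmod.log10_p_adjusted,
                                       res_mod.log10_p_adjusted,
                                       motif=pwm.name, label=pair.label,
                                       pair=pair))
    if top_k is not None:
        scores = filter_and_rank(scores, k=top_k)
    return scores


def run_sweep(genome: GenomeLike,
              records: Union[str, Iterable[ModificationRecord]],
              peaks: Union[str, Sequence[Peak]],
              motifs: Sequence[Union[str, ExpandedPWM]],
              thresholds: Optional[Sequence[float]] = None,
              region_width: int = 500,
              min_region: int = DEFAULT_MIN_REGION,
              max_region: int = DEFAULT_MAX_REGION,
              score_threshold: float = DEFAULT_SITE_SCORE_BITS,
              top_k: int = 3,
              single_channel: bool = False) -> ThresholdSweep:
    """Rebuild, re-extract and re-score all hypothesis pairs per threshold."""
    thresholds = list(thresholds) if thresholds is not None else default_thresholds()
    genome_dict = load_genome(genome)
    record_list = (list(read_track(records)) if isinstance(records, str)
                   else list(records))
    peak_list = read_peaks(peaks) if isinstance(peaks, (str,)) else list(peaks)
    pwms = [pwm_from_string(m) if isinstance(m, str) else m for m in motifs]

    rows = []
    for t in thresholds:
        built = build_modified_genome(genome_dict, record_list, t,
                                      single_channel=single_channel)
        regions, _ = extract_regions(built.sequences, peak_list, region_width)
        bg = Background.from_sequences(regions)
        for pwm in pwms:
            for s in score_hypotheses(regions, pwm, bg, min_region, max_region,
                                      score_threshold, top_k=top_k):
                rows.append({"threshold": t, "motif": s.motif, "label": s.label,
                             "score": s.score, "p_unmod": s.p_unmod,
                             "p_mod": s.p_mod})
    frame = pd.DataFrame(rows, columns=["threshold", "motif", "label",
                                        "score", "p_unmod", "p_mod"])
    return ThresholdSweep(thresholds=thresholds, rows=frame)
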