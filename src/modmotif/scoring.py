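"""Preference scores for modified versus unmodified motifs.

The preference score of a hypothesis pair is

    score = log10(p_unmodified) - log10(p_modified)

over the adjusted central-enrichment p-values: positive scores mean the
modified motif is more centrally enriched (the factor prefers modified
DNA), negative scores the reverse. Scores are clipped to +/-4000 for
display. Downstream rules aggregate replicate scores by maximum absolute
value, retain the top-1 or top-3 most significant pairs per factor
(dropping pairs with min p >= 0.05), partition motifs at a neutrality band
of +/-epsilon (epsilon = 5), and classify each factor's overall preference
from the distribution of its motif scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

#: Display clipping bound for scores.
SCORE_CLIP = 4000.0

#: Neutrality band half-width for partitioning motifs.
DEFAULT_EPSILON = 5.0

#: Significance cutoff below which a hypothesis pair is retained.
DEFAULT_ALPHA_SIG = 0.05


class ScoringError(ValueError):
    pass


@dataclass(frozen=True)
class PreferenceScore:
    """Score of one hypothesis pair, with optional grouping metadata.

    ``p_unmod``/``p_mod`` may underflow to 0.0 for extreme enrichment; the
    log10 fields are always exact and the score is computed from them.
    """

    p_unmod: float
    p_mod: float
    log10_p_unmod: float
    log10_p_mod: float
    score: float
    display_score: float
    factor: str = ""
    motif: str = ""
    label: str = ""
    pair: Optional[object] = field(default=None, compare=False)

    @property
    def significance(self) -> float:
        """min over the pair of log10 p — the more significant member."""
        return min(self.log10_p_unmod, self.log10_p_mod)


def pair_score_log10(log10_p_unmod: float, log10_p_mod: float, factor: str = "",
                     motif: str = "", label: str = "",
                     pair: Optional[object] = None) -> PreferenceScore:
    """Preference score from log10 adjusted p-values (underflow-safe)."""
    if log10_p_unmod > 0 or log10_p_mod > 0:
        raise ScoringError("log10 p-values must be <= 0")
    score = log10_p_unmod - log10_p_mod
    display = max(-SCORE_CLIP, min(SCORE_CLIP, score))
    return PreferenceScore(p_unmod=float(10.0 ** log10_p_unmod),
                           p_mod=float(10.0 ** log10_p_mod),
                           log10_p_unmod=log10_p_unmod,
                           log10_p_mod=log10_p_mod,
                           score=score, display_score=display, factor=factor,
                           motif=motif, label=label, pair=pair)


def pair_score(p_unmod: float, p_mod: float, factor: str = "", motif: str = "",
               label: str = "", pair: Optional[object] = None) -> PreferenceScore:
    """log10 p-value difference of a hypothesis pair; positive favours modified."""
    if not (0.0 < p_unmod <= 1.0) or not (0.0 < p_mod <= 1.0):
        raise ScoringError(f"p-values must lie in (0, 1], got {p_unmod!r}, {p_mod!r}")
    return pair_score_log10(math.log10(p_unmod), math.log10(p_mod),
                            factor=factor, motif=motif, label=label, pair=pair)


def aggregate_pairs(scores: Iterable[PreferenceScore]) -> List[PreferenceScore]:
    """One score per (factor, motif, label) group: the maximum-|score| member.

    Replicates and analysis settings can produce several scores for the
    same hypothesis; the one furthest from zero is kept. Ties keep the
    first occurrence, so output order follows first appearance of each
    group.
    """
    chosen: Dict[tuple, PreferenceScore] = {}
    order: List[tuple] = []
    for s in scores:
        key = (s.factor, s.motif, s.label)
        if key not in chosen:
            chosen[key] = s
            order.append(key)
        elif abs(s.score) > abs(chosen[key].score):
            chosen[key] = s
    return [chosen[k] for k in order]


def filter_and_rank(scores: Iterable[PreferenceScore], k: int = 3,
                    alpha_sig: float = DEFAULT_ALPHA_SIG) -> List[PreferenceScore]:
    """Top-k most significant pairs, dropping those with min p >= alpha_sig.

    Significance of a pair is its more significant member, min(p_unmod,
    p_mod), compared and ranked on the log10 scale so underflowed
    p-values order correctly.
    """
    cut = math.log10(alpha_sig)
    significant = [s for s in scores if s.significance < cut]
    significant.sort(key=lambda s: s.significance)
    return significant[:k]


def partition_motifs(scores: Iterable[PreferenceScore],
                     epsilon: float = DEFAULT_EPSILON,
                     ) -> Dict[str, List[PreferenceScore]]:
    """Partition into unmodified-preferring (< -eps), modified-preferring
    (> eps), and neutral (|score| <= eps) sets."""
    out: Dict[str, List[PreferenceScore]] = {
        "unmodified_preferring": [], "modified_preferring": [], "neutral": []}
    for s in scores:
        if s.score < -epsilon:
            out["unmodified_preferring"].append(s)
        elif s.score > epsilon:
            out["modified_preferring"].append(s)
        else:
            out["neutral"].append(s)
    return out


def _upper_quartile(values: Sequence[float]) -> float:
    """Q3 by the inclusive-median (Tukey hinge) convention."""
    v = sorted(values)
    n = len(v)
    if n == 1:
        return v[0]
    upper = v[n // 2:]  # inclusive: odd n keeps the median in the upper half
    m = len(upper)
    if m % 2 == 1:
        return upper[m // 2]
    return 0.5 * (upper[m // 2 - 1] + upper[m // 2])


def classify_factor(scores: Sequence[float]) -> str:
    """Classify a factor's modification preference from its motif scores.

    First match wins: ``unmodified_only`` if every score is negative;
    ``modified_predominant`` if the upper-quartile score is >= 0;
    ``no_clear_preference`` if all scores lie in [-50, 50] and not every
    score is positive; otherwise ``mixed``.
    """
    vals = [float(s) for s in scores]
    if not vals:
        raise ScoringError("classify_factor requires at least one score")
    if all(v < 0 for v in vals):
        return "unmodified_only"
    if _upper_quartile(vals) >= 0:
        return "modified_predominant"
    if all(-50 <= v <= 50 for v in vals) and not all(v > 0 for v in vals):
        return "no_clear_preference"
    return "mixed"
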