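"""Modified-motif hypotheses and the relative-entropy-equalizing pseudocount.

A hypothesis pair compares an unmodified motif against one modified
counterpart of the same length. At a CpG dinucleotide there are six
possible methylation/hydroxymethylation states in which the CpG is not both
hemi-methylated and hemi-hydroxymethylated:

=====  ==================================================
label  meaning
=====  ==================================================
mG     hemi-methylation, plus strand (C -> m)
C1     hemi-methylation, minus strand (G -> 1)
m1     complete methylation (C -> m, G -> 1)
hG     hemi-hydroxymethylation, plus strand (C -> h)
C2     hemi-hydroxymethylation, minus strand (G -> 2)
h2     complete hydroxymethylation (C -> h, G -> 2)
=====  ==================================================

Because modified symbols are orders of magnitude rarer in the background
than C or G, a modified motif would otherwise receive sharper log-odds
scores and better enrichment p-values for spurious reasons. To equalize
the information content of the pair, the modified motif receives a larger
pseudocount alpha, solved numerically so that the relative entropy per
column of the modified motif (pseudocounted with alpha) equals that of the
unmodified motif (pseudocounted with the fixed default 0.1).

The per-position entropy term is used in the form

    1 + alpha * b * log2((1 + alpha * b) / b)

for a position of motif frequency 1 over background frequency b, with the
pseudocounted entry kept unnormalized. Hemi modifications alter one column
per CpG and solve the single-position equation; complete modifications
alter two columns and solve the two-position (motif + complement) version.
With several CpGs modified uniformly, the total pseudocount is the number
of modified positions times alpha.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.optimize import brentq

from .motifs import (
    Background,
    ExpandedPWM,
    MotifError,
    N_SYMBOLS,
    SYMBOL_INDEX,
    pwm_from_string,
)

#: Fixed pseudocount of the unmodified member of every pair.
UNMODIFIED_ALPHA = 0.1

#: The six CpG modification patterns, as (plus-strand target, minus-strand target);
#: None means that strand's column is left untouched (hemi-modification).
CPG_PATTERNS: Dict[str, Tuple[Optional[str], Optional[str]]] = {
    "mG": ("m", None),
    "C1": (None, "1"),
    "m1": ("m", "1"),
    "hG": ("h", None),
    "C2": (None, "2"),
    "h2": ("h", "2"),
}

_ALPHA_BRACKET = (1e-12, 1e6)


class SolverError(ValueError):
    """Raised when no pseudocount root can be bracketed."""


def _re_term(alpha: float, b: float, freq: float = 1.0) -> float:
    """Per-position entropy term, as-printed: freq + α·b·log2((freq+α·b)/b)."""
    return freq + alpha * b * np.log2((freq + alpha * b) / b)


def solve_alpha_single(b_m: float, b_u: float,
                       alpha_u: float = UNMODIFIED_ALPHA,
                       tol: float = 1e-12) -> float:
    """Pseudocount equalizing one modified position against its unmodified one.

    Solves  1 + α·b_m·log2((1+α·b_m)/b_m) = 1 + α_u·b_u·log2((1+α_u·b_u)/b_u)
    for the positive root α, given the modified symbol's background
    frequency ``b_m`` and the unmodified symbol's ``b_u``.
    """
    _check_bg(b_m, b_u)
    rhs = _re_term(alpha_u, b_u)
    return _solve(lambda a: _re_term(a, b_m) - rhs, tol)


def solve_alpha_complete(b_m1: float, b_m2: float, b_u1: float, b_u2: float,
                         alpha_u: float = UNMODIFIED_ALPHA,
                         tol: float = 1e-12) -> float:
    """Pseudocount for a complete (both-strand) modification of one CpG.

    Two modified positions (e.g. m and its paired 1) share a single alpha,
    equated against the two unmodified positions (C and G) at alpha_u.
    """
    _check_bg(b_m1, b_m2, b_u1, b_u2)
    rhs = _re_term(alpha_u, b_u1) + _re_term(alpha_u, b_u2)
    return _solve(lambda a: _re_term(a, b_m1) + _re_term(a, b_m2) - rhs, tol)


def _check_bg(*freqs: float) -> None:
    for b in freqs:
        if not 0.0 < b < 1.0:
            raise SolverError(f"background frequency {b!r} outside (0, 1)")


def _solve(residual, tol: float) -> float:
    lo, hi = _ALPHA_BRACKET
    r_lo, r_hi = residual(lo), residual(hi)
    if r_lo * r_hi > 0:
        raise SolverError("no positive pseudocount root bracketable in (1e-12, 1e6); "
                          "degenerate background frequencies")
    root = float(brentq(residual, lo, hi, xtol=tol, rtol=8.9e-16, maxiter=500))
    if abs(residual(root)) > 1e-10:
        raise SolverError(f"root residual {residual(root)!r} above tolerance")
    return root


def bisect_alpha(residual, lo: float = _ALPHA_BRACKET[0], hi: float = _ALPHA_BRACKET[1],
                 tol: float = 1e-12, max_iter: int = 200) -> float:
    """Plain bisection on a residual function; independent check for the solver."""
    r_lo = residual(lo)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        r_mid = residual(mid)
        if r_lo * r_mid <= 0:
            hi = mid
        else:
            lo, r_lo = mid, r_mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Motif editing

ModSpec = Tuple[int, str, str]  # (position, mode in {"full","partial","hemi"}, target)

_SOURCE_OF_TARGET = {"m": "C", "h": "C", "f": "C", "c": "C",
                     "1": "G", "2": "G", "3": "G", "4": "G"}


def modify_positions(pwm: ExpandedPWM, spec: Sequence[ModSpec],
                     name: Optional[str] = None) -> ExpandedPWM:
    """Apply modification edits to motif columns.

    ``full`` sets the whole column to a unit vector on the target symbol.
    ``partial`` (and its one-strand synonym ``hemi``) transfers only the
    frequency mass of the cognate unmodified base (C for m/h/f/c, G for
    1/2/3/4) to the target, leaving the other base frequencies untouched.
    A partial edit of a column with no C (or G) mass warns and leaves the
    column unchanged.
    """
    m = pwm.matrix.copy()
    for pos, mode, target in spec:
        if not 0 <= pos < pwm.width:
            raise MotifError(f"position {pos} outside motif of width {pwm.width}")
        if target not in _SOURCE_OF_TARGET:
            raise MotifError(f"target {target!r} is not a modified symbol")
        t_idx = SYMBOL_INDEX[target]
        if mode == "full":
            m[pos, :] = 0.0
            m[pos, t_idx] = 1.0
        elif mode in ("partial", "hemi"):
            s_idx = SYMBOL_INDEX[_SOURCE_OF_TARGET[target]]
            mass = m[pos, s_idx]
            if mass <= 0:
                warnings.warn(f"position {pos} has no {_SOURCE_OF_TARGET[target]} "
                              f"mass to transfer to {target!r}; column unchanged")
                continue
            m[pos, s_idx] = 0.0
            m[pos, t_idx] += mass
        else:
            raise MotifError(f"unknown modification mode {mode!r}")
    return ExpandedPWM(name=name or pwm.name + "_mod", matrix=m)


# ---------------------------------------------------------------------------
# Hypothesis pairs

@dataclass(frozen=True)
class HypothesisPair:
    """An unmodified motif and one modified counterpart of equal length.

    ``alpha`` is the solved per-modified-position pseudocount;
    ``alpha_total`` = n_modified_positions * alpha is the motif-wide
    pseudocount applied to the modified member when scanning. The
    unmodified member always scans with the fixed pseudocount 0.1.
    """

    unmodified: ExpandedPWM
    modified: ExpandedPWM
    label: str
    n_modified_positions: int
    alpha: float
    alpha_total: float

    def __post_init__(self) -> None:
        if self.unmodified.width != self.modified.width:
            raise MotifError("hypothesis pair members must have equal length")
        if self.alpha <= 0:
            raise MotifError("solved pseudocount must be positive")

    @property
    def unmod_string(self) -> str:
        return self.unmodified.consensus()

    @property
    def mod_string(self) -> str:
        return self.modified.consensus()


def find_cpgs(pwm: ExpandedPWM) -> List[int]:
    """Start indices of CpG dinucleotides (dominant symbols C then G)."""
    cons = pwm.consensus()
    return [i for i in range(len(cons) - 1) if cons[i] == "C" and cons[i + 1] == "G"]


def _pattern_pair(pwm: ExpandedPWM, cpgs: Sequence[int],
                  assignment: Sequence[str], bg: Background,
                  label: str) -> HypothesisPair:
    """Build one hypothesis pair for a per-CpG pattern assignment."""
    edits: List[ModSpec] = []
    n_mod = 0
    alphas: List[float] = []
    for cpg, pat in zip(cpgs, assignment):
        plus, minus = CPG_PATTERNS[pat]
        full = plus is not None and minus is not None
        if full:
            edits.append((cpg, "full", plus))
            edits.append((cpg + 1, "full", minus))
            n_mod += 2
            alphas.append(solve_alpha_complete(
                bg[plus], bg[minus], bg["C"], bg["G"]))
        elif plus is not None:
            edits.append((cpg, "partial", plus))
            n_mod += 1
            alphas.append(solve_alpha_single(bg[plus], bg["C"]))
        else:
            edits.append((cpg + 1, "partial", minus))
            n_mod += 1
            alphas.append(solve_alpha_single(bg[minus], bg["G"]))
    modified = modify_positions(pwm, edits)
    modified = ExpandedPWM(name=f"{pwm.name}|{label}", matrix=modified.matrix)
    # Uniform application: all CpGs carry the same pattern, so all per-CpG
    # alphas coincide; mixed assignments use the mean as the shared value.
    alpha = float(np.mean(alphas))
    return HypothesisPair(unmodified=pwm, modified=modified, label=label,
                          n_modified_positions=n_mod, alpha=alpha,
                          alpha_total=n_mod * alpha)


def enumerate_cpg_hypotheses(
        motif: Union[str, ExpandedPWM],
        bg: Background,
        patterns: Iterable[str] = tuple(CPG_PATTERNS),
        combinatorial: bool = False,
        max_combinations: int = 10000) -> List[HypothesisPair]:
    """All CpG methylation/hydroxymethylation hypotheses for a motif.

    In the default uniform mode each of the six patterns is applied to all
    CpGs at once, yielding at most six pairs; a motif without any CpG
    yields an empty list. The combinatorial mode instead enumerates every
    per-CpG pattern assignment (6^k for k CpGs, capped at
    ``max_combinations``).
    """
    pwm = pwm_from_string(motif) if isinstance(motif, str) else motif
    patterns = list(patterns)
    unknown = [p for p in patterns if p not in CPG_PATTERNS]
    if unknown:
        raise MotifError(f"unknown CpG patterns: {unknown}")
    cpgs = find_cpgs(pwm)
    if not cpgs:
        return []
    pairs: List[HypothesisPair] = []
    if not combinatorial:
        for pat in patterns:
            pairs.append(_pattern_pair(pwm, cpgs, [pat] * len(cpgs), bg, pat))
        return pairs
    total = len(patterns) ** len(cpgs)
    if total > max_combinations:
        raise MotifError(
            f"combinatorial enumeration would produce {total} pairs "
            f"(> cap {max_combinations})")
    for assignment in itertools.product(patterns, repeat=len(cpgs)):
        label = "+".join(f"{c}:{p}" for c, p in zip(cpgs, assignment))
        pairs.append(_pattern_pair(pwm, cpgs, assignment, bg, label))
    return pairs


# ---------------------------------------------------------------------------
# Relative entropy per column, as-printed convention

def re_per_col_printed(pwm: ExpandedPWM, alpha_by_position: Sequence[float],
                       bg: Background) -> float:
    """RE/col with per-position pseudocounts under the as-printed convention.

    Sums, over entries where the raw motif frequency is positive,
    freq + α_i·b_j·log2((freq + α_i·b_j)/b_j), then divides by the motif
    width. This is the quantity the pseudocount solver equalizes between
    the members of a hypothesis pair.
    """
    if len(alpha_by_position) != pwm.width:
        raise MotifError("need one pseudocount per motif position")
    total = 0.0
    for i in range(pwm.width):
        a = alpha_by_position[i]
        for j in range(N_SYMBOLS):
            freq = pwm.matrix[i, j]
            if freq > 0:
                total += _re_term(a, float(bg.freq[j]), freq)
    return total / pwm.width


def equalization_gap(pair: HypothesisPair, bg: Background) -> float:
    """|RE/col(modified) - RE/col(unmodified)| under the solver's convention.

    The modified member uses the solved alpha at its modified positions and
    the unmodified constant 0.1 elsewhere; the unmodified member uses 0.1
    throughout. By construction of the solver this gap is zero (to solver
    tolerance) whenever the modified columns have unit frequency.
    """
    w = pair.unmodified.width
    diff = np.abs(pair.unmodified.matrix - pair.modified.matrix).sum(axis=1)
    modified_positions = set(np.nonzero(diff > 1e-12)[0].tolist())
    alphas_mod = [pair.alpha if i in modified_positions else UNMODIFIED_ALPHA
                  for i in range(w)]
    alphas_unmod = [UNMODIFIED_ALPHA] * w
    re_mod = re_per_col_printed(pair.modified, alphas_mod, bg)
    re_unmod = re_per_col_printed(pair.unmodified, alphas_unmod, bg)
    return abs(re_mod - re_unmod)
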