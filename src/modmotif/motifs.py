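"""Position weight matrices over the 12-symbol expanded alphabet.

A motif is a column-stochastic frequency matrix with one row per core
symbol (A, C, G, T, m, h, f, c, 1, 2, 3, 4). Motifs can be built from
extended-IUPAC consensus strings, where the standard degeneracy codes
(R, Y, M, K, S, W, B, D, H, V, N) and the modification ambiguity codes
(w, x, y, z, 6, 7, 8, 9) expand to uniform frequencies over their symbol
sets.

Scanning follows the usual log-odds convention, log2(Pr(b)/f(b)) for a
symbol b with background frequency f(b). Because modified symbols are far
rarer in a genome than the four unmodified bases, their log-odds scores are
much larger for the same motif probability — the motivation for the
relative-entropy pseudocount normalization implemented in
:mod:`modmotif.hypotheses`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, TextIO, Tuple

import numpy as np

from .alphabet import (
    ALL_SYMBOLS,
    CORE_SYMBOLS,
    DEFAULT_ALPHABET,
    AlphabetError,
    ModAlphabet,
)

SYMBOL_INDEX: Dict[str, int] = {s: i for i, s in enumerate(CORE_SYMBOLS)}
N_SYMBOLS = len(CORE_SYMBOLS)

# Standard IUPAC degeneracy over the unmodified bases.
_IUPAC: Dict[str, str] = {
    "R": "AG", "Y": "CT", "M": "AC", "K": "GT", "S": "CG", "W": "AT",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

#: Default per-site log-odds score threshold, in bits, below which a window
#: does not count as a motif site.
DEFAULT_SITE_SCORE_BITS = 5.0

_NEG_INF = float("-inf")


class MotifError(ValueError):
    """Raised for malformed motifs or incompatible backgrounds."""


@dataclass(frozen=True)
class Background:
    """Background frequencies over the 12 core symbols (must sum to 1)."""

    freq: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.freq, dtype=float)
        if f.shape != (N_SYMBOLS,):
            raise MotifError(f"background must have {N_SYMBOLS} entries")
        if (f < 0).any():
            raise MotifError("background frequencies must be non-negative")
        if abs(f.sum() - 1.0) > 1e-9:
            raise MotifError(f"background must sum to 1, got {f.sum()!r}")
        object.__setattr__(self, "freq", f)

    def __getitem__(self, sym: str) -> float:
        return float(self.freq[SYMBOL_INDEX[sym]])

    @classmethod
    def uniform(cls) -> "Background":
        return cls(np.full(N_SYMBOLS, 1.0 / N_SYMBOLS))

    @classmethod
    def from_dict(cls, d: Dict[str, float]) -> "Background":
        f = np.zeros(N_SYMBOLS)
        for sym, v in d.items():
            f[SYMBOL_INDEX[sym]] = v
        return cls(f / f.sum())

    @classmethod
    def from_sequences(cls, seqs: Iterable[str], smoothing: float = 1.0) -> "Background":
        """Empirical symbol frequencies with additive (Laplace) smoothing.

        Smoothing keeps every core-symbol frequency strictly positive, which
        the pseudocount solver and log-odds scanner require; ambiguity
        symbols in the input are ignored.
        """
        counts = np.full(N_SYMBOLS, float(smoothing))
        for seq in seqs:
            for ch in seq:
                idx = SYMBOL_INDEX.get(ch)
                if idx is None:
                    idx = SYMBOL_INDEX.get(ch.upper())
                if idx is not None:
                    counts[idx] += 1
        return cls(counts / counts.sum())


def mouse_like_background(gc: float = 0.42, modified_total: float = 0.02) -> Background:
    """Convenience background: GC fraction ``gc``, small mass on the modified
    symbols (mostly m/1, some h/2, trace f/3 and c/4; strictly positive
    everywhere so it is scannable)."""
    f = np.zeros(N_SYMBOLS)
    at = (1 - gc - modified_total) / 2
    gcf = gc / 2
    f[SYMBOL_INDEX["A"]] = f[SYMBOL_INDEX["T"]] = at
    f[SYMBOL_INDEX["C"]] = f[SYMBOL_INDEX["G"]] = gcf
    f[SYMBOL_INDEX["m"]] = f[SYMBOL_INDEX["1"]] = modified_total * 0.40
    f[SYMBOL_INDEX["h"]] = f[SYMBOL_INDEX["2"]] = modified_total * 0.095
    f[SYMBOL_INDEX["f"]] = f[SYMBOL_INDEX["3"]] = modified_total * 0.0025
    f[SYMBOL_INDEX["c"]] = f[SYMBOL_INDEX["4"]] = modified_total * 0.0025
    return Background(f / f.sum())


@dataclass(frozen=True)
class ExpandedPWM:
    """A motif frequency matrix over the expanded core alphabet.

    ``matrix`` has shape (length, 12); each column (row of the array) sums
    to 1 before pseudocount application. ``normalized`` records whether the
    columns are probability-normalized — pseudocounted matrices kept in
    unnormalized form (column sums 1 + alpha) are used by the
    relative-entropy equalization machinery, while scanning requires
    normalized columns. The effective number of observed sites is fixed
    at 1.
    """

    name: str
    matrix: np.ndarray
    normalized: bool = True
    nsites_effective: float = 1.0

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != N_SYMBOLS or m.shape[0] < 1:
            raise MotifError(f"matrix must be (length, {N_SYMBOLS}), got {m.shape}")
        if (m < 0).any():
            raise MotifError("motif frequencies must be non-negative")
        if self.normalized and np.abs(m.sum(axis=1) - 1.0).max() > 1e-9:
            raise MotifError("motif columns must each sum to 1")
        object.__setattr__(self, "matrix", m)

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def consensus(self) -> str:
        """Dominant symbol per column (ties broken by alphabet order)."""
        return "".join(CORE_SYMBOLS[j] for j in self.matrix.argmax(axis=1))

    def reverse_complement(self, alphabet: ModAlphabet = DEFAULT_ALPHABET) -> "ExpandedPWM":
        perm = [SYMBOL_INDEX[alphabet.complement_map[s]] for s in CORE_SYMBOLS]
        rc = self.matrix[::-1, :][:, perm]
        return replace(self, name=self.name + "_rc", matrix=rc)


def pwm_from_string(motif: str, name: Optional[str] = None,
                    alphabet: ModAlphabet = DEFAULT_ALPHABET) -> ExpandedPWM:
    """Build a PWM from an extended-IUPAC consensus string.

    Core symbols become unit columns; IUPAC degeneracy codes and
    modification ambiguity codes become uniform frequencies over their
    expansion sets.
    """
    rows = []
    for i, ch in enumerate(motif):
        cu = ch.upper() if ch.upper() in _IUPAC else ch
        col = np.zeros(N_SYMBOLS)
        if ch in SYMBOL_INDEX or (ch.upper() in SYMBOL_INDEX and ch.isalpha()):
            key = ch if ch in SYMBOL_INDEX else ch.upper()
            col[SYMBOL_INDEX[key]] = 1.0
        elif cu in _IUPAC:
            for s in _IUPAC[cu]:
                col[SYMBOL_INDEX[s]] = 1.0 / len(_IUPAC[cu])
        else:
            try:
                expansion = alphabet.expand_symbol(ch)
            except AlphabetError:
                raise MotifError(f"unknown motif character {ch!r} at position {i}") from None
            for s in expansion:
                col[SYMBOL_INDEX[s]] = 1.0 / len(expansion)
        rows.append(col)
    return ExpandedPWM(name=name or motif, matrix=np.array(rows))


def apply_pseudocount(pwm: ExpandedPWM, alpha: float, bg: Background,
                      renormalize: bool = True) -> ExpandedPWM:
    """Add ``alpha`` times the background to every entry: m'_ij = m_ij + α·b_j.

    With ``renormalize`` each column is rescaled to sum to 1 (required for
    scanning); without it the raw pseudocounted entries are kept, column
    sums 1 + alpha, matching the form the relative-entropy equalization is
    written in.
    """
    if alpha < 0:
        raise MotifError("pseudocount must be non-negative")
    m = pwm.matrix + alpha * bg.freq[None, :]
    if renormalize:
        m = m / m.sum(axis=1, keepdims=True)
    return replace(pwm, matrix=m, normalized=renormalize)


def relative_entropy(pwm: ExpandedPWM, bg: Background) -> Tuple[float, float]:
    """Kullback-Leibler divergence of the motif from the background, in bits.

    D_RE(m, b) = Σ_i Σ_j m_ij · log2(m_ij / b_j), with 0·log(0) = 0.
    Returns (total bits, bits per column).
    """
    m = pwm.matrix
    support = m > 0
    if (support & (bg.freq <= 0)[None, :]).any():
        raise MotifError("background is zero where the motif has support")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(support, m * np.log2(np.where(support, m, 1.0) / bg.freq[None, :]), 0.0)
    total = float(terms.sum())
    return total, total / pwm.width


def log_odds(pwm: ExpandedPWM, bg: Background) -> np.ndarray:
    """Log-odds score matrix: entry_ij = log2(Pr_ij / b_j), base 2.

    The motif must already be pseudocounted and normalized; any zero entry
    over a positive-background symbol is rejected (apply a pseudocount
    first).
    """
    if not pwm.normalized:
        raise MotifError("log-odds requires a normalized (probability) matrix")
    if (pwm.matrix <= 0).any():
        raise MotifError("zero probability entry; apply a pseudocount before log-odds")
    if (bg.freq <= 0).any():
        raise MotifError("log-odds requires strictly positive background")
    return np.log2(pwm.matrix / bg.freq[None, :])


def encode_sequence(seq: str) -> np.ndarray:
    """Map a sequence to core-symbol indices; unscorable symbols become -1.

    Ambiguity symbols (x, z, 7, 9, ...) and any non-alphabet character are
    unscorable: windows covering them score -inf and can never be best
    sites. Soft-masked (lowercase) letters are scored as their uppercase
    symbol; lowercase of modified letters that collide with core symbols
    (m, h, f, c are themselves lowercase) are taken verbatim.
    """
    idx = np.empty(len(seq), dtype=np.int64)
    for i, ch in enumerate(seq):
        j = SYMBOL_INDEX.get(ch)
        if j is None and ch.upper() in SYMBOL_INDEX:
            j = SYMBOL_INDEX[ch.upper()]
        idx[i] = -1 if j is None else j
    return idx


def _window_scores(encoded: np.ndarray, score_matrix: np.ndarray) -> np.ndarray:
    """Total log-odds at each offset; -inf where a window is unscorable."""
    n, w = encoded.size, score_matrix.shape[0]
    n_off = n - w + 1
    if n_off <= 0:
        raise MotifError(f"sequence length {n} shorter than motif width {w}")
    padded = np.where(encoded >= 0, encoded, 0)
    bad = encoded < 0
    totals = np.zeros(n_off)
    any_bad = np.zeros(n_off, dtype=bool)
    for i in range(w):
        totals += score_matrix[i, padded[i:i + n_off]]
        any_bad |= bad[i:i + n_off]
    totals[any_bad] = _NEG_INF
    return totals


@dataclass(frozen=True)
class BestSite:
    offset: int
    strand: str  # '+' or '-'
    score: float


def scan_scores(seq: str, pwm: ExpandedPWM, bg: Background,
                scan_both_strands: bool = True,
                alphabet: ModAlphabet = DEFAULT_ALPHABET,
                ) -> Tuple[np.ndarray, Optional[np.ndarray]]:
    """Per-offset log-odds totals on the forward (and optionally reverse) strand.

    Reverse-strand scores are computed by scanning the reverse-complemented
    motif (under the expanded complement map, m<->1 etc.) at the same
    forward-coordinate offsets, so offset o always refers to the window
    seq[o:o+w].
    """
    scores = log_odds(pwm, bg)
    encoded = encode_sequence(seq)
    fwd = _window_scores(encoded, scores)
    rev = None
    if scan_both_strands:
        rc = pwm.reverse_complement(alphabet)
        rev = _window_scores(encoded, log_odds(rc, bg))
    return fwd, rev


def best_site(seq: str, pwm: ExpandedPWM, bg: Background,
              scan_both_strands: bool = True,
              score_threshold: float = DEFAULT_SITE_SCORE_BITS,
              alphabet: ModAlphabet = DEFAULT_ALPHABET,
              tol: float = 1e-9) -> Optional[BestSite]:
    """Best-scoring motif window in ``seq``, or None if below threshold.

    Scores within ``tol`` are treated as tied (the two strand scans sum the
    same terms in different orders, so exact equality cannot be relied on);
    ties are broken toward the smallest offset and then the forward strand.
    """
    fwd, rev = scan_scores(seq, pwm, bg, scan_both_strands, alphabet)
    best: Optional[BestSite] = None
    for strand, totals in (("+", fwd), ("-", rev)):
        if totals is None:
            continue
        off = int(totals.argmax())
        sc = float(totals[off])
        if sc < score_threshold:
            continue
        if best is None or sc > best.score + tol or \
                (sc >= best.score - tol and off < best.offset):
            best = BestSite(offset=off, strand=strand, score=sc)
    return best


def best_site_offsets_fractional(
        seq: str, pwm: ExpandedPWM, bg: Background,
        scan_both_strands: bool = True,
        score_threshold: float = DEFAULT_SITE_SCORE_BITS,
        tol: float = 1e-9,
        alphabet: ModAlphabet = DEFAULT_ALPHABET) -> Dict[int, float]:
    """Offsets of the maximal-scoring site(s) with fractional tie weights.

    When several offsets tie for the best score (within ``tol``), each
    receives weight 1/#ties; the weights sum to 1 for a scored sequence and
    the dict is empty if no window reaches the threshold. Used by the
    central-enrichment tally so ties do not bias positional counts.
    """
    fwd, rev = scan_scores(seq, pwm, bg, scan_both_strands, alphabet)
    stacked = fwd if rev is None else np.maximum(fwd, rev)
    top = float(stacked.max())
    if top < score_threshold:
        return {}
    tied = np.nonzero(stacked >= top - tol)[0]
    wgt = 1.0 / tied.size
    return {int(o): wgt for o in tied}


def read_background(path) -> Background:
    """Background from a two-column TSV: symbol, frequency."""
    d: Dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            sym, freq = line.split()[:2]
            d[sym] = float(freq)
    return Background.from_dict(d)


def write_background(bg: Background, path) -> None:
    with open(path, "w") as fh:
        for s in CORE_SYMBOLS:
            fh.write(f"{s}\t{bg[s]:.8g}\n")


# ---------------------------------------------------------------------------
# Minimal MEME-style motif I/O with the custom alphabet header.

def write_meme_motifs(pwms: Sequence[ExpandedPWM], bg: Background,
                      dest: TextIO) -> None:
    dest.write("MEME version 4\n\n")
    dest.write("ALPHABET \"Expanded epigenetic DNA\" DNA-LIKE\n\n")
    dest.write("Background letter frequencies\n")
    dest.write(" ".join(f"{s} {bg[s]:.6f}" for s in CORE_SYMBOLS) + "\n\n")
    for pwm in pwms:
        dest.write(f"MOTIF {pwm.name}\n")
        dest.write(f"letter-probability matrix: alength= {N_SYMBOLS} "
                   f"w= {pwm.width} nsites= {pwm.nsites_effective:g}\n")
        for row in pwm.matrix:
            dest.write(" ".join(f"{v:.6f}" for v in row) + "\n")
        dest.write("\n")


def read_meme_motifs(src: TextIO) -> List[ExpandedPWM]:
    pwms: List[ExpandedPWM] = []
    name = None
    rows: List[List[float]] = []
    expect = 0
    for line in src:
        line = line.strip()
        if line.startswith("MOTIF"):
            name = line.split(None, 2)[1]
        elif line.startswith("letter-probability matrix"):
            fields = dict(zip(line.split()[2::2], line.split()[3::2]))
            expect = int(fields.get("w=", 0))
            rows = []
        elif expect and line and name is not None:
            rows.append([float(v) for v in line.split()])
            if len(rows) == expect:
                pwms.append(ExpandedPWM(name=name, matrix=np.array(rows)))
                name, rows, expect = None, [], 0
    return pwms
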