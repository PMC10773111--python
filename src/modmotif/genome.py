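"""Modified-genome construction from per-base modification levels.

An unmodified assembly is rewritten into the expanded epigenetic alphabet
using stranded, thresholded modification calls. Input modification data
has the shape of MLML output: per-position maximum-likelihood estimates of
the 5mC level (m), the 5hmC level (h), both in [0, 1], plus a conflict
count (with two sequencing channels, WGBS and oxWGBS, conflicts take
values 0, 1, or 2).

Calling rules for a threshold t, on the plus strand:

* any conflicts  -> z (unknown modification state), irrespective of levels
* m >= t, h >= t -> x (a modification is present but cannot be
  disambiguated confidently)
* m >= t         -> m
* h >= t         -> h
* m + h >= t     -> x (half-threshold rule: if t suffices to call either
  modification alone, their sum reaching t suffices to call
  methylated-or-hydroxymethylated)
* otherwise      -> C (unmodified)

Minus-strand records sit on the complementary guanine and receive the
complement symbol (1, 2, 7, 9), preserving strandedness so that
hemi-modification is representable. One BED track per emitted symbol
records exactly the rewritten positions.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Mapping, Sequence, Tuple, Union

logger = logging.getLogger(__name__)

_TOL = 1e-9

#: Plus-strand call -> minus-strand (guanine) symbol.
_MINUS_SYMBOL = {"m": "1", "h": "2", "x": "7", "z": "9", "C": "G"}

GenomeLike = Union[str, Path, Mapping[str, str]]


class GenomeError(ValueError):
    pass


@dataclass(frozen=True)
class ModificationRecord:
    """Stranded per-position modification estimate (MLML-shaped)."""

    chrom: str
    pos: int  # 0-based, forward-strand coordinate
    strand: str  # '+' or '-'
    level_m: float
    level_h: float
    conflicts: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise GenomeError(f"strand must be + or -, got {self.strand!r}")
        if not (0.0 <= self.level_m <= 1.0 and 0.0 <= self.level_h <= 1.0):
            raise GenomeError("modification levels must lie in [0, 1]")
        if self.level_m + self.level_h > 1.0 + _TOL:
            raise GenomeError(
                f"level_m + level_h = {self.level_m + self.level_h} exceeds 1")
        if self.conflicts < 0:
            raise GenomeError("conflict count must be non-negative")
        if self.pos < 0:
            raise GenomeError("position must be non-negative")


def _check_threshold(t: float) -> None:
    if not 0.0 < t <= 1.0:
        raise GenomeError(f"calling threshold must lie in (0, 1], got {t!r}")


def call_symbol(rec: ModificationRecord, t: float) -> str:
    """Plus-strand cytosine call in {C, m, h, x, z} for one record."""
    _check_threshold(t)
    if rec.conflicts > 0:
        return "z"
    if rec.level_m >= t and rec.level_h >= t:
        return "x"
    if rec.level_m >= t:
        return "m"
    if rec.level_h >= t:
        return "h"
    if rec.level_m + rec.level_h >= t:
        return "x"
    return "C"


def call_symbol_single_channel(rec: ModificationRecord, t: float,
                               relabel_x_as_m: bool = False) -> str:
    """Call from one bisulfite channel (WGBS only; level_m holds m+h).

    A single channel cannot separate 5mC from 5hmC, so modified calls are
    x/7; ``relabel_x_as_m`` renames them to m/1 for convenience (most such
    positions are simply methylated).
    """
    _check_threshold(t)
    if rec.conflicts > 0:
        return "z"
    if rec.level_m + rec.level_h >= t:
        return "m" if relabel_x_as_m else "x"
    return "C"


def combine_channels(wgbs_level: float, oxwgbs_level: float,
                     tolerance: float = _TOL) -> Tuple[float, float, int]:
    """Two-channel combiner: WGBS estimates m + h, oxWGBS estimates m.

    Returns (level_m, level_h, conflicts): the hydroxymethylation level is
    the excess of the WGBS level over the oxWGBS level, and a negative
    excess (oxidative channel above the conventional one) flags a
    conflict. This is a simplified consistent-estimator stand-in with the
    same output shape as MLML.
    """
    for v in (wgbs_level, oxwgbs_level):
        if not 0.0 <= v <= 1.0:
            raise GenomeError(f"channel level {v!r} outside [0, 1]")
    conflicts = 1 if wgbs_level - oxwgbs_level < -tolerance else 0
    level_h = max(0.0, wgbs_level - oxwgbs_level)
    return oxwgbs_level, level_h, conflicts


# ---------------------------------------------------------------------------
# FASTA / track / BED I/O helpers

def load_genome(genome: GenomeLike) -> Dict[str, str]:
    """Sequences keyed by name, from a FASTA path or a dict (passed through)."""
    if isinstance(genome, Mapping):
        return dict(genome)
    from Bio import SeqIO
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(genome), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: Union[str, Path],
                line_width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i:i + line_width] + "\n")


def read_track(path: Union[str, Path]) -> Iterator[ModificationRecord]:
    """Parse a bedGraph-like modification track.

    Tab-separated columns: chrom, start, end, strand, level_m, level_h,
    conflicts. Intervals are 0-based half-open and single-base.
    """
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise GenomeError(f"{path}:{lineno}: expected 7 columns, "
                                  f"got {len(fields)}")
            chrom, start, _end, strand, lm, lh, conf = fields[:7]
            yield ModificationRecord(chrom=chrom, pos=int(start), strand=strand,
                                     level_m=float(lm), level_h=float(lh),
                                     conflicts=int(conf))


def write_track(records: Iterable[ModificationRecord],
                path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.pos}\t{r.pos + 1}\t{r.strand}\t"
                     f"{r.level_m:.6g}\t{r.level_h:.6g}\t{r.conflicts}\n")


# ---------------------------------------------------------------------------
# Genome building

@dataclass
class BuildResult:
    sequences: Dict[str, str]
    tracks: Dict[str, List[Tuple[str, int]]]  # symbol -> [(chrom, pos)]
    call_counts: Counter
    n_skipped: int = 0


def build_modified_genome(
        genome: GenomeLike,
        records: Iterable[ModificationRecord],
        t: float,
        single_channel: bool = False,
        relabel_x_as_m: bool = False,
        on_reference_mismatch: str = "skip",
        merge: str = "first",
        unmask_c: bool = True) -> BuildResult:
    """Rewrite an assembly with thresholded, stranded modification calls.

    Plus-strand records must lie on a reference C and write the called
    symbol; minus-strand records must lie on a reference G (the modified
    cytosine being on the reverse strand) and write the complement symbol.
    Positions without records are untouched, so output chromosomes keep
    their input length, headers and soft-masking — except that soft-masked
    ``c`` is uppercased by default (``unmask_c``), because lowercase c is
    the 5-carboxylcytosine symbol in the expanded alphabet.

    ``on_reference_mismatch``: "skip" drops records on a non-C/G base with
    a warning count; "abort" raises. ``merge``: with several records at one
    (chrom, pos, strand), "first" keeps the first seen, "max" the one with
    the highest total modification level. Processing is chromosome-keyed
    and per-position, so peak memory scales with the largest chromosome.
    """
    _check_threshold(t)
    if on_reference_mismatch not in ("skip", "abort"):
        raise GenomeError("on_reference_mismatch must be 'skip' or 'abort'")
    if merge not in ("first", "max"):
        raise GenomeError("merge must be 'first' or 'max'")

    seqs = {name: list(seq) for name, seq in load_genome(genome).items()}
    if unmask_c:
        for name, chars in seqs.items():
            seqs[name] = ["C" if ch == "c" else ch for ch in chars]
    tracks: Dict[str, List[Tuple[str, int]]] = defaultdict(list)
    counts: Counter = Counter()
    seen: Dict[Tuple[str, int, str], ModificationRecord] = {}
    n_skipped = 0

    for rec in records:
        if rec.chrom not in seqs:
            raise GenomeError(f"record chromosome {rec.chrom!r} not in genome")
        if rec.pos >= len(seqs[rec.chrom]):
            raise GenomeError(f"record position {rec.pos} outside "
                              f"{rec.chrom} (length {len(seqs[rec.chrom])})")
        key = (rec.chrom, rec.pos, rec.strand)
        prev = seen.get(key)
        if prev is not None:
            if merge == "max" and (rec.level_m + rec.level_h
                                   > prev.level_m + prev.level_h):
                seen[key] = rec
            continue
        seen[key] = rec

    for (chrom, pos, strand), rec in seen.items():
        ref = seqs[chrom][pos]
        expected = "C" if strand == "+" else "G"
        if ref.upper() != expected:
            if on_reference_mismatch == "abort":
                raise GenomeError(
                    f"{chrom}:{pos}: {strand} record on reference base {ref!r}, "
                    f"expected {expected}")
            n_skipped += 1
            continue
        if single_channel:
            plus_call = call_symbol_single_channel(rec, t, relabel_x_as_m)
        else:
            plus_call = call_symbol(rec, t)
        if plus_call == "C":
            continue
        sym = plus_call if strand == "+" else _MINUS_SYMBOL[plus_call]
        seqs[chrom][pos] = sym
        tracks[sym].append((chrom, pos))
        counts[sym] += 1

    if n_skipped:
        logger.warning("skipped %d records on non-C/G reference bases", n_skipped)
    for sym, cnt in sorted(counts.items()):
        logger.info("called %d positions as %s", cnt, sym)
    return BuildResult(sequences={k: "".join(v) for k, v in seqs.items()},
                       tracks=dict(tracks), call_counts=counts,
                       n_skipped=n_skipped)


def write_bed_tracks(result: BuildResult, out_prefix: Union[str, Path]) -> List[Path]:
    """One BED file per emitted symbol: 0-based half-open length-1 intervals."""
    paths = []
    for sym, positions in sorted(result.tracks.items()):
        path = Path(f"{out_prefix}.{sym}.bed")
        with open(path, "w") as fh:
            for chrom, pos in sorted(positions):
                fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{sym}\n")
        paths.append(path)
    return paths


def apply_bed_tracks(genome: GenomeLike,
                     tracks: Mapping[str, Sequence[Tuple[str, int]]],
                     unmask_c: bool = True) -> Dict[str, str]:
    """Reapply per-symbol position tracks to an unmodified assembly.

    Re-reading the emitted BED tracks and applying them reproduces the
    modified FASTA exactly (the round-trip consistency check).
    """
    seqs = {name: list(seq) for name, seq in load_genome(genome).items()}
    if unmask_c:
        for name, chars in seqs.items():
            seqs[name] = ["C" if ch == "c" else ch for ch in chars]
    for sym, positions in tracks.items():
        for chrom, pos in positions:
            seqs[chrom][pos] = sym
    return {k: "".join(v) for k, v in seqs.items()}


def read_bed_track(path: Union[str, Path]) -> List[Tuple[str, int]]:
    positions = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start = line.split("\t")[:2]
            positions.append((chrom, int(start)))
    return positions


# ---------------------------------------------------------------------------
# Region extraction

@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int
    end: int
    summit: int  # absolute forward-strand coordinate


def read_peaks(path: Union[str, Path]) -> List[Peak]:
    """Parse a BED/narrowPeak file; column 10, when present, is the summit
    offset relative to the interval start, otherwise the midpoint is used."""
    peaks = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GenomeError(f"{path}:{lineno}: malformed BED line "
                                  f"({len(fields)} columns)")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                summit = (start + int(fields[9]) if len(fields) >= 10
                          else (start + end) // 2)
            except ValueError as exc:
                raise GenomeError(f"{path}:{lineno}: malformed BED line: {exc}")
            peaks.append(Peak(chrom=chrom, start=start, end=end, summit=summit))
    return peaks


def extract_regions(genome: GenomeLike,
                    peaks: Union[str, Path, Sequence[Peak]],
                    width: int = 500) -> Tuple[List[str], int]:
    """Fixed-width, summit-centred sequences from a (modified) assembly.

    Each returned sequence has exactly ``width`` symbols, covering
    [summit - width//2, summit - width//2 + width). Regions that would be
    truncated at a chromosome edge are dropped; the drop count is
    returned and logged.
    """
    if width < 1:
        raise GenomeError("region width must be positive")
    seqs = load_genome(genome)
    if not isinstance(peaks, (str, Path)):
        peak_list: Sequence[Peak] = peaks
    else:
        peak_list = read_peaks(peaks)
    regions: List[str] = []
    dropped = 0
    for pk in peak_list:
        if pk.chrom not in seqs:
            raise GenomeError(f"peak chromosome {pk.chrom!r} not in genome")
        lo = pk.summit - width // 2
        hi = lo + width
        if lo < 0 or hi > len(seqs[pk.chrom]):
            dropped += 1
            continue
        regions.append(seqs[pk.chrom][lo:hi])
    if dropped:
        logger.info("dropped %d peak regions truncated at chromosome edges", dropped)
    return regions, dropped
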