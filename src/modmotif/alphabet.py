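"""Expanded epigenetic DNA alphabet.

The standard DNA alphabet is extended with symbols for covalently modified
cytosines and, because every symbol implicitly encodes a base *pair*, with
symbols for the guanine paired opposite each modified cytosine:

====== ============================ ==========
symbol base                         complement
====== ============================ ==========
m      5-methylcytosine (5mC)       1
h      5-hydroxymethylcytosine      2
f      5-formylcytosine (5fC)       3
c      5-carboxylcytosine (5caC)    4
====== ============================ ==========

The guanine partners are numbered in the order in which TET oxidation acts
on 5mC (m -> h -> f -> c). Ambiguity codes capture common kinds of assay
uncertainty: ``z/9`` a cytosine of completely unknown modification state,
``y/8`` a cytosine that is neither methylated nor hydroxymethylated,
``x/7`` a methylated-or-hydroxymethylated cytosine, and ``w/6`` a
formylated-or-carboxylated cytosine. Carrying distinct symbols for each
strand keeps complementation lossless, so hemi-modification (one strand
modified, the other not) survives reverse complementation.

Lowercase letters are treated as soft-masked variants of the same symbol and
masking is preserved through complementation; digit symbols have no case.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, TextIO

CORE_SYMBOLS: List[str] = ["A", "C", "G", "T", "m", "h", "f", "c", "1", "2", "3", "4"]
AMBIGUITY_SYMBOLS: List[str] = ["w", "x", "y", "z", "6", "7", "8", "9"]
ALL_SYMBOLS: List[str] = CORE_SYMBOLS + AMBIGUITY_SYMBOLS

_COMPLEMENT_PAIRS = [
    ("A", "T"), ("C", "G"),
    ("m", "1"), ("h", "2"), ("f", "3"), ("c", "4"),
    ("w", "6"), ("x", "7"), ("y", "8"), ("z", "9"),
]

_AMBIGUITY_EXPANSIONS: Dict[str, FrozenSet[str]] = {
    "w": frozenset("fc"),
    "x": frozenset("mh"),
    "y": frozenset("Cfc"),
    "z": frozenset("Cmhfc"),
    "6": frozenset("34"),
    "7": frozenset("12"),
    "8": frozenset("G34"),
    "9": frozenset("G1234"),
}

# Advisory display palette (genome-browser track hints); not normative.
_DEFAULT_COLORS: Dict[str, str] = {
    "A": "8510A8", "C": "A89610", "G": "A89610", "T": "8510A8",
    "m": "D73027", "1": "F46D43", "h": "4575B4", "2": "74ADD1",
    "f": "1A9850", "3": "66BD63", "c": "762A83", "4": "9970AB",
    "w": "AAAAAA", "x": "AAAAAA", "y": "AAAAAA", "z": "888888",
    "6": "CCCCCC", "7": "CCCCCC", "8": "CCCCCC", "9": "666666",
}

# Internal wildcard used only in alphabet definition files, never in genomes.
WILDCARD = "?"


class AlphabetError(ValueError):
    """Raised for symbols outside the expanded alphabet."""


@dataclass(frozen=True)
class ModAlphabet:
    """The expanded epigenetic alphabet: symbols, complements, ambiguities.

    The default instance covers the four cytosine modifications (m, h, f, c),
    their paired guanines (1-4) and the eight ambiguity codes. The symbol
    table is configurable so that further modifications (e.g. 5hmU, 6mA)
    could be added, but none ship by default.
    """

    core_symbols: tuple = tuple(CORE_SYMBOLS)
    complement_map: Mapping[str, str] = field(default_factory=lambda: dict(
        p for a, b in _COMPLEMENT_PAIRS for p in [(a, b), (b, a)]
    ))
    ambiguity_map: Mapping[str, FrozenSet[str]] = field(
        default_factory=lambda: dict(_AMBIGUITY_EXPANSIONS)
    )
    display_colors: Mapping[str, str] = field(default_factory=lambda: dict(_DEFAULT_COLORS))

    def __post_init__(self) -> None:
        for s in self.symbols:
            t = self.complement_map[s]
            if self.complement_map[t] != s:
                raise AlphabetError(f"complement map is not an involution at {s!r}")
        for amb, expansion in self.ambiguity_map.items():
            if not expansion <= set(self.core_symbols):
                raise AlphabetError(f"ambiguity {amb!r} expands outside the core symbols")

    @property
    def symbols(self) -> List[str]:
        return list(self.core_symbols) + list(self.ambiguity_map)

    def complement(self, sym: str) -> str:
        """Complement a single symbol, preserving soft-mask case."""
        if sym in self.complement_map:
            return self.complement_map[sym]
        up = sym.upper() if sym.upper() in self.complement_map else sym.lower()
        if up in self.complement_map and up != sym:
            comp = self.complement_map[up]
            if not comp.isalpha():
                return comp
            masked = comp.swapcase()
            # a masked variant that collides with a canonical symbol (masked
            # C would read as the 5caC letter c) is emitted unmasked instead
            return comp if masked in self.complement_map else masked
        raise AlphabetError(f"unknown symbol {sym!r}")

    def complement_sequence(self, seq: str, reverse: bool = False) -> str:
        """Complement ``seq`` symbol-by-symbol; reverse order if requested.

        Complementation is lossless: applying it twice returns the input.
        Unknown characters are rejected with their position.
        """
        out = []
        for i, ch in enumerate(seq):
            try:
                out.append(self.complement(ch))
            except AlphabetError:
                raise AlphabetError(
                    f"unknown symbol {ch!r} at position {i}"
                ) from None
        if reverse:
            out.reverse()
        return "".join(out)

    def reverse_complement(self, seq: str) -> str:
        return self.complement_sequence(seq, reverse=True)

    def expand_symbol(self, sym: str) -> FrozenSet[str]:
        """Set of core symbols a symbol may represent (identity on core)."""
        key = sym if sym in self.complement_map else sym.upper()
        if key not in self.complement_map and sym.lower() in self.complement_map:
            key = sym.lower()
        if key in self.core_symbols:
            return frozenset({key})
        if key in self.ambiguity_map:
            return self.ambiguity_map[key]
        raise AlphabetError(f"unknown symbol {sym!r}")

    def is_valid(self, seq: str) -> bool:
        try:
            self.complement_sequence(seq)
            return True
        except AlphabetError:
            return False


DEFAULT_ALPHABET = ModAlphabet()


def complement_sequence(seq: str, reverse: bool = False,
                        alphabet: ModAlphabet = DEFAULT_ALPHABET) -> str:
    return alphabet.complement_sequence(seq, reverse=reverse)


def reverse_complement(seq: str, alphabet: ModAlphabet = DEFAULT_ALPHABET) -> str:
    return alphabet.reverse_complement(seq)


def expand_symbol(sym: str, alphabet: ModAlphabet = DEFAULT_ALPHABET) -> FrozenSet[str]:
    return alphabet.expand_symbol(sym)


def write_alphabet_definition(alphabet: ModAlphabet = DEFAULT_ALPHABET,
                              dest: TextIO | None = None) -> str:
    """Serialize a MEME-suite-style custom alphabet definition block.

    One line per core complement pair, one line per ambiguity symbol with
    its expansion, and a wildcard covering all core symbols. Round-trips
    through :func:`parse_alphabet_definition`.
    """
    buf = io.StringIO()
    buf.write("ALPHABET \"Expanded epigenetic DNA\" DNA-LIKE\n")
    seen = set()
    for sym in alphabet.core_symbols:
        comp = alphabet.complement_map[sym]
        if sym in seen or comp in seen:
            continue
        seen.update((sym, comp))
        color = alphabet.display_colors.get(sym, "")
        line = f"{sym} ~ {comp}"
        if color:
            line += f" {color}"
        buf.write(line + "\n")
    for amb in alphabet.ambiguity_map:
        expansion = "".join(s for s in alphabet.core_symbols
                            if s in alphabet.ambiguity_map[amb])
        buf.write(f"{amb} = {expansion}\n")
    buf.write(f"{WILDCARD} = {''.join(alphabet.core_symbols)}\n")
    text = buf.getvalue()
    if dest is not None:
        dest.write(text)
    return text


def parse_alphabet_definition(text: str) -> ModAlphabet:
    """Parse the definition format emitted by :func:`write_alphabet_definition`."""
    core: List[str] = []
    comp_map: Dict[str, str] = {}
    amb_map: Dict[str, FrozenSet[str]] = {}
    colors: Dict[str, str] = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("ALPHABET"):
            continue
        if " ~ " in line:
            parts = line.split()
            sym, comp = parts[0], parts[2]
            core.extend([sym, comp])
            comp_map[sym] = comp
            comp_map[comp] = sym
            if len(parts) > 3:
                colors[sym] = parts[3]
        elif " = " in line:
            sym, expansion = (p.strip() for p in line.split("=", 1))
            if sym == WILDCARD:
                continue
            amb_map[sym] = frozenset(expansion)
        else:
            raise AlphabetError(f"unparseable alphabet line {lineno}: {raw!r}")
    # Restore canonical core ordering and pair-derived ambiguity complements.
    ordered = [s for s in CORE_SYMBOLS if s in core] + [s for s in core if s not in CORE_SYMBOLS]
    for amb in amb_map:
        partner = next((b for a, b in _COMPLEMENT_PAIRS if a == amb), None)
        if partner is None:
            partner = next((a for a, b in _COMPLEMENT_PAIRS if b == amb), None)
        if partner is not None:
            comp_map.setdefault(amb, partner)
            comp_map.setdefault(partner, amb)
    full_colors = dict(_DEFAULT_COLORS)
    full_colors.update(colors)
    return ModAlphabet(core_symbols=tuple(ordered), complement_map=comp_map,
                       ambiguity_map=amb_map, display_colors=full_colors)
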