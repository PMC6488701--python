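"""Encoding characters and alphabets for degenerate-base DNA data storage.

An *encoding character* is anything that can occupy one designed position of
an oligonucleotide: a pure base (A, C, G, T) or a degenerate base -- an IUPAC
symbol standing for a mixture of nucleotides dosed at that position during
synthesis, so the molecule pool contains every corresponding sequence variant.
Ratio-skewed variants (e.g. W1 for A:T = 3:7, W2 for A:T = 7:3) carry an
index after the IUPAC letter; in FASTA output both collapse to the plain
IUPAC letter, the mixing ratio being design metadata.

An alphabet of k characters has a theoretical information capacity of
log2(k) bits per designed character.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "BASES",
    "IUPAC_SUPPORTS",
    "EncodingCharacter",
    "Alphabet",
    "UnresolvableCharacterError",
    "standard_alphabet",
    "theoretical_capacity",
    "match_character",
    "save_alphabet",
    "load_alphabet",
]

BASES = ("A", "C", "G", "T")

#: IUPAC degeneracy codes keyed by their base support (alphabetical order).
IUPAC_SUPPORTS: dict[frozenset, str] = {
    frozenset("A"): "A",
    frozenset("C"): "C",
    frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AC"): "M",
    frozenset("AG"): "R",
    frozenset("AT"): "W",
    frozenset("CG"): "S",
    frozenset("CT"): "Y",
    frozenset("GT"): "K",
    frozenset("ACG"): "V",
    frozenset("ACT"): "H",
    frozenset("AGT"): "D",
    frozenset("CGT"): "B",
    frozenset("ACGT"): "N",
}

_SUM_TOL = 1e-9


class UnresolvableCharacterError(ValueError):
    """No character of the alphabet matches an observed base support."""


@dataclass(frozen=True)
class EncodingCharacter:
    """A designed symbol with its nucleotide mixing composition.

    Parameters
    ----------
    symbol:
        Printable identifier. Plain IUPAC letter where one suffices;
        ratio variants append an index (``W1``, ``W2``).
    composition:
        Mapping base -> mixing fraction in (0, 1]; fractions sum to 1.
    """

    symbol: str
    composition: Mapping[str, float]

    def __post_init__(self) -> None:
        comp = dict(self.composition)
        if not comp:
            raise ValueError(f"{self.symbol}: empty composition")
        for base, frac in comp.items():
            if base not in BASES:
                raise ValueError(f"{self.symbol}: unknown base {base!r}")
            if not 0.0 < frac <= 1.0:
                raise ValueError(
                    f"{self.symbol}: fraction for {base} must be in (0, 1], got {frac}"
                )
        total = sum(comp.values())
        if abs(total - 1.0) > _SUM_TOL:
            raise ValueError(f"{self.symbol}: fractions sum to {total}, expected 1.0")
        object.__setattr__(self, "composition", comp)

    @property
    def support(self) -> frozenset:
        """Bases mixed into this character (fraction > 0)."""
        return frozenset(self.composition)

    @property
    def is_pure(self) -> bool:
        return len(self.composition) == 1

    @property
    def iupac(self) -> str:
        """Plain IUPAC letter for this character's support."""
        return IUPAC_SUPPORTS[self.support]

    def fraction(self, base: str) -> float:
        return self.composition.get(base, 0.0)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.symbol


@dataclass(frozen=True)
class Alphabet:
    """An ordered set of encoding characters.

    The declaration order is significant: it fixes the enumeration order of
    the codon table and therefore the entire binary <-> DNA mapping.
    """

    name: str
    characters: tuple

    def __post_init__(self) -> None:
        chars = tuple(self.characters)
        object.__setattr__(self, "characters", chars)
        if len(chars) < 4:
            raise ValueError(f"alphabet {self.name}: needs k >= 4, got {len(chars)}")
        seen = set()
        for ch in chars:
            key = (ch.support, tuple(sorted(ch.composition.items())))
            if key in seen:
                raise ValueError(
                    f"alphabet {self.name}: duplicate support/composition for {ch.symbol}"
                )
            seen.add(key)
        symbols = {ch.symbol for ch in chars}
        if len(symbols) != len(chars):
            raise ValueError(f"alphabet {self.name}: duplicate symbols")
        pure = {ch.iupac for ch in chars if ch.is_pure}
        if not set(BASES) <= pure:
            raise ValueError(
                f"alphabet {self.name}: all four pure bases are required (addresses)"
            )

    @property
    def k(self) -> int:
        """Number of encoding characters."""
        return len(self.characters)

    def __len__(self) -> int:
        return len(self.characters)

    def __iter__(self):
        return iter(self.characters)

    def __getitem__(self, i: int) -> EncodingCharacter:
        return self.characters[i]

    def index_of(self, symbol: str) -> int:
        try:
            return self._symbol_index[symbol]
        except AttributeError:
            idx = {ch.symbol: i for i, ch in enumerate(self.characters)}
            object.__setattr__(self, "_symbol_index", idx)
            return idx[symbol]

    def by_symbol(self, symbol: str) -> EncodingCharacter:
        return self.characters[self.index_of(symbol)]

    def with_support(self, support: Iterable[str]) -> list:
        """All characters whose support equals the given base set."""
        s = frozenset(support)
        return [ch for ch in self.characters if ch.support == s]

    @property
    def min_design_fraction(self) -> float:
        """Smallest mixing fraction any character assigns to a base."""
        return min(f for ch in self.characters for f in ch.composition.values())


def _pure(base: str) -> EncodingCharacter:
    return EncodingCharacter(base, {base: 1.0})


def _even(support: str) -> EncodingCharacter:
    n = len(support)
    return EncodingCharacter(IUPAC_SUPPORTS[frozenset(support)], {b: 1.0 / n for b in support})


def _ratio_pair(support: str) -> list:
    """Two ratio variants of a two-base IUPAC code: X1 = 3:7, X2 = 7:3.

    Bases are taken in alphabetical order, so W1 means A:T = 3:7 (minority
    first) and W2 means A:T = 7:3.
    """
    letter = IUPAC_SUPPORTS[frozenset(support)]
    lo, hi = sorted(support)
    return [
        EncodingCharacter(f"{letter}1", {lo: 0.3, hi: 0.7}),
        EncodingCharacter(f"{letter}2", {lo: 0.7, hi: 0.3}),
    ]


_TWO_BASE = ("AG", "CT", "CG", "AT", "GT", "AC")  # R, Y, S, W, K, M
_THREE_BASE = ("CGT", "AGT", "ACT", "ACG")  # B, D, H, V

STANDARD_ALPHABETS = ("pure4", "ws6", "iupac15", "ratio21")


def standard_alphabet(name: str) -> Alphabet:
    """Build one of the platform's standard alphabets.

    ``pure4``
        A, C, G, T only (classical 2 bits/character ceiling).
    ``ws6``
        pure4 plus W (A/T) and S (C/G) at equal ratios.
    ``iupac15``
        pure4 plus all eleven IUPAC degenerate codes at equal mixing;
        the 15 supports enumerate every non-empty subset of {A,C,G,T}.
    ``ratio21``
        pure4 plus the six two-base codes each in 3:7 and 7:3 ratio
        variants, plus B, D, H, V and N at equal mixing -- 21 characters.
    """
    pure = [_pure(b) for b in BASES]
    if name == "pure4":
        chars = pure
    elif name == "ws6":
        chars = pure + [_even("AT"), _even("CG")]
    elif name == "iupac15":
        chars = pure + [_even(s) for s in _TWO_BASE] + [_even(s) for s in _THREE_BASE]
        chars.append(_even("ACGT"))
    elif name == "ratio21":
        chars = list(pure)
        for s in _TWO_BASE:
            chars.extend(_ratio_pair(s))
        chars.extend(_even(s) for s in _THREE_BASE)
        chars.append(_even("ACGT"))
    else:
        raise ValueError(
            f"unknown alphabet {name!r}; valid options: {', '.join(STANDARD_ALPHABETS)}"
        )
    return Alphabet(name, tuple(chars))


def theoretical_capacity(alphabet) -> float:
    """Maximum information capacity, log2(k) bits per encoding character."""
    k = alphabet.k if isinstance(alphabet, Alphabet) else int(alphabet)
    if k < 1:
        raise ValueError("alphabet size must be >= 1")
    return math.log2(k)


def match_character(
    support: Iterable[str],
    fractions: Mapping[str, float],
    alphabet: Alphabet,
) -> EncodingCharacter:
    """Resolve an observed base set (and call fractions) to a character.

    The support alone identifies the character except when the alphabet
    carries ratio variants sharing a support; those are told apart by
    comparing the observed fractions of the two bases -- the base called
    more often is assigned the larger design ratio.

    Raises
    ------
    UnresolvableCharacterError
        If no character of the alphabet has the observed support.
    """
    s = frozenset(support)
    if not s:
        raise UnresolvableCharacterError("empty base support")
    if not s <= set(BASES):
        raise UnresolvableCharacterError(f"support {sorted(s)} outside A/C/G/T")
    candidates = alphabet.with_support(s)
    if not candidates:
        raise UnresolvableCharacterError(
            f"no character in alphabet {alphabet.name!r} has support {''.join(sorted(s))}"
        )
    if len(candidates) == 1:
        return candidates[0]
    # Ratio variants: renormalise the observed fractions over the support and
    # pick the composition closest in L1 distance (equivalent to assigning
    # the majority base the majority design ratio). Ties keep declaration order.
    obs = {b: max(fractions.get(b, 0.0), 0.0) for b in s}
    total = sum(obs.values())
    if total <= 0:
        return candidates[0]
    obs = {b: v / total for b, v in obs.items()}
    return min(
        candidates,
        key=lambda ch: sum(abs(obs[b] - ch.fraction(b)) for b in s),
    )


def save_alphabet(alphabet: Alphabet, path) -> None:
    """Serialize an alphabet to a YAML config (symbol, bases, fractions)."""
    doc = {
        "name": alphabet.name,
        "characters": [
            {"symbol": ch.symbol, "composition": {b: float(f) for b, f in sorted(ch.composition.items())}}
            for ch in alphabet.characters
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_alphabet(source) -> Alphabet:
    """Load an alphabet from a YAML config file path or parsed mapping."""
    if isinstance(source, Mapping):
        doc = source
    else:
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    chars = tuple(
        EncodingCharacter(c["symbol"], {b: float(f) for b, f in c["composition"].items()})
        for c in doc["characters"]
    )
    return Alphabet(doc["name"], chars)
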