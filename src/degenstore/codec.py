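"""Binary <-> DNA conversion via context-dependent three-character codons.

Data bits are packed into codons of three encoding characters, b bits per
codon with b = floor(log2((k-1)*k^2)) for a k-character alphabet: for a
given *context* (the previous codon's last character, or the address's last
base for the first codon) there are (k-1)*k^2 admissible codons whose first
character differs from the context, and the table keeps the first 2^b of
them in lexicographic order of character indices.  The context rule forbids
a codon's first character from repeating its predecessor's last character,
so no run of four or more identical characters can occur inside or across
codons.

Fragments carry a base-4 pure-base address ahead of the payload and fixed
20-nt adapters (amplification/sequencing primers) at both ends; adapters
are excluded from capacity accounting.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional, Sequence

import numpy as np

from .alphabet import Alphabet, EncodingCharacter, load_alphabet, standard_alphabet

__all__ = [
    "ADAPTER5",
    "ADAPTER3",
    "MASS_PER_NT_GRAMS",
    "FragmentGeometry",
    "CodonTable",
    "Fragment",
    "DesignManifest",
    "CapacityReport",
    "InvalidCodonError",
    "DecodeFailure",
    "build_codon_table",
    "encode_codon",
    "decode_codon",
    "make_address",
    "address_to_index",
    "encode_data",
    "decode_data",
    "capacity_report",
    "max_char_run",
    "demo1_geometry",
    "demo2_geometry",
    "sim200_geometry",
]

#: Default fixed primer-binding adapters (20 nt each, pure bases, no 4-runs).
ADAPTER5 = "ACACGACGCTCTTCCGATCT"
ADAPTER3 = "AGATCGGAAGAGCACACGTC"

#: Average mass of one ssDNA nucleotide: ~327 g/mol / Avogadro.
MASS_PER_NT_GRAMS = 327.0 / 6.02214076e23

_BASE_ORDER = "ACGT"

TABLE_ID = "lex-v1"


class InvalidCodonError(ValueError):
    """A codon is not in the table for its context."""


class DecodeFailure(ValueError):
    """Data cannot be reconstructed; carries the offending fragment indices."""

    def __init__(self, message: str, fragment_indices: Sequence[int] = ()):
        super().__init__(message)
        self.fragment_indices = list(fragment_indices)


@dataclass(frozen=True)
class FragmentGeometry:
    """Designed layout of one fragment.

    ``payload_chars`` counts designed payload characters; all but
    ``pad_chars`` trailing fixed filler positions are codon characters, so
    ``payload_chars - pad_chars`` must be a positive multiple of 3.
    """

    payload_chars: int
    address_chars: int
    adapter5: str = ADAPTER5
    adapter3: str = ADAPTER3
    pad_chars: int = 0

    def __post_init__(self) -> None:
        data_chars = self.payload_chars - self.pad_chars
        if data_chars < 3 or data_chars % 3 != 0:
            raise ValueError(
                f"payload must hold a whole number of 3-character codons; "
                f"got {self.payload_chars} chars with {self.pad_chars} pad"
            )
        if self.address_chars < 1:
            raise ValueError("address_chars must be >= 1")
        if self.pad_chars < 0:
            raise ValueError("pad_chars must be >= 0")
        for name in ("adapter5", "adapter3"):
            seq = getattr(self, name)
            if set(seq) - set(_BASE_ORDER):
                raise ValueError(f"{name} must be pure A/C/G/T")

    @property
    def n_codons(self) -> int:
        return (self.payload_chars - self.pad_chars) // 3

    @property
    def read_length(self) -> int:
        """Length of the sequenced (non-adapter) region: address + payload."""
        return self.address_chars + self.payload_chars

    @property
    def designed_length(self) -> int:
        return len(self.adapter5) + self.read_length + len(self.adapter3)


def demo1_geometry() -> FragmentGeometry:
    """42-character payload, 3-base address, 85 nt total with adapters."""
    return FragmentGeometry(payload_chars=42, address_chars=3)


def demo2_geometry() -> FragmentGeometry:
    """111-character payload (37 codons), 9-base address: 120 non-adapter
    characters, the layout consistent with storing 135,393 bytes in 4503
    fragments at 2.0 bits/character under the W/S alphabet."""
    return FragmentGeometry(payload_chars=111, address_chars=9)


def sim200_geometry() -> FragmentGeometry:
    """200-nt simulation fragment: 20-nt adapters, 12-base address, 148
    payload characters realized as 49 codons plus one fixed pad position."""
    return FragmentGeometry(payload_chars=148, address_chars=12, pad_chars=1)


@dataclass(frozen=True)
class Fragment:
    """One designed fragment: ordinal index, pure-base address, payload."""

    index: int
    address: str
    payload: tuple
    kind: str = "data"  # "data" | "parity"

    def __post_init__(self) -> None:
        if self.kind not in ("data", "parity"):
            raise ValueError(f"kind must be data|parity, got {self.kind!r}")
        object.__setattr__(self, "payload", tuple(self.payload))

    def iupac_sequence(self, alphabet: Alphabet, with_adapters: bool = False,
                       geometry: Optional[FragmentGeometry] = None) -> str:
        """Designed sequence with ratio variants collapsed to IUPAC letters."""
        core = self.address + "".join(alphabet.by_symbol(s).iupac for s in self.payload)
        if with_adapters:
            if geometry is None:
                raise ValueError("geometry required to attach adapters")
            core = geometry.adapter5 + core + geometry.adapter3
        return core


class CodonTable:
    """Deterministic context-dependent codon map for one alphabet.

    ``codons[c, v]`` is the v-th admissible codon (three character indices)
    for context character index c; ``value_of[c, x, y, z]`` inverts it
    (-1 marks codons outside the table).
    """

    def __init__(self, alphabet: Alphabet, bits_per_codon: int,
                 codons: np.ndarray, value_of: np.ndarray):
        self.alphabet = alphabet
        self.bits_per_codon = bits_per_codon
        self.codons = codons
        self.value_of = value_of

    @property
    def k(self) -> int:
        return self.alphabet.k

    @property
    def admissible_per_context(self) -> int:
        k = self.k
        return (k - 1) * k * k

    def context_index(self, context) -> int:
        if isinstance(context, (int, np.integer)):
            return int(context)
        if isinstance(context, EncodingCharacter):
            return self.alphabet.index_of(context.symbol)
        return self.alphabet.index_of(str(context))

    def encode_values(self, values: Sequence[int], context) -> list:
        """Encode codon values left-to-right with a running context.

        Returns the flat list of character indices; the context after each
        codon is that codon's last character.
        """
        c = self.context_index(context)
        nmax = 1 << self.bits_per_codon
        out = []
        codons = self.codons
        for v in values:
            v = int(v)
            if not 0 <= v < nmax:
                raise ValueError(
                    f"codon value {v} out of range [0, {nmax}) for b={self.bits_per_codon}"
                )
            x, y, z = codons[c, v]
            out.extend((int(x), int(y), int(z)))
            c = int(z)
        return out

    def decode_values(self, char_indices: Sequence[int], context) -> np.ndarray:
        """Invert :meth:`encode_values`; raises InvalidCodonError on a codon
        absent from its context's list."""
        c = self.context_index(context)
        idx = np.asarray(char_indices, dtype=np.int64)
        if idx.size % 3 != 0:
            raise ValueError("character count is not a multiple of 3")
        out = np.empty(idx.size // 3, dtype=np.int64)
        vo = self.value_of
        for j in range(out.size):
            x, y, z = idx[3 * j: 3 * j + 3]
            v = vo[c, x, y, z]
            if v < 0:
                raise InvalidCodonError(
                    f"codon #{j} (chars {x},{y},{z}) not admissible for context {c}"
                )
            out[j] = v
            c = int(z)
        return out


def build_codon_table(alphabet: Alphabet) -> CodonTable:
    """Enumerate, per context, the admissible codons in lexicographic order
    of character indices and keep the first 2^b, b = floor(log2((k-1)k^2)).

    The construction is purely combinatorial, so the same alphabet yields a
    byte-identical table on every run and platform.
    """
    k = alphabet.k
    admissible = (k - 1) * k * k
    b = int(math.floor(math.log2(admissible)))
    n = 1 << b

    grid = np.indices((k, k, k)).reshape(3, -1).T  # lex order of (x, y, z)
    codons = np.empty((k, n, 3), dtype=np.uint8)
    value_of = np.full((k, k, k, k), -1, dtype=np.int32)
    for c in range(k):
        adm = grid[grid[:, 0] != c][:n]
        codons[c] = adm
        value_of[c, adm[:, 0], adm[:, 1], adm[:, 2]] = np.arange(n)
    return CodonTable(alphabet, b, codons, value_of)


def encode_codon(value: int, context, table: CodonTable) -> tuple:
    """Single-codon encode: returns the three character symbols."""
    chars = table.encode_values([value], context)
    syms = table.alphabet.characters
    return tuple(syms[i].symbol for i in chars)


def decode_codon(codon: Sequence[str], context, table: CodonTable) -> int:
    """Single-codon decode; inverse of :func:`encode_codon`."""
    idx = [table.alphabet.index_of(s) for s in codon]
    return int(table.decode_values(idx, context)[0])


def make_address(index: int, address_chars: int) -> str:
    """Base-4 representation of the fragment index over (A, C, G, T),
    most-significant digit first."""
    if index < 0:
        raise ValueError("fragment index must be >= 0")
    if index >= 4 ** address_chars:
        raise ValueError(
            f"index {index} does not fit {address_chars} address characters "
            f"({4 ** address_chars} addresses); widen the address"
        )
    digits = []
    v = index
    for _ in range(address_chars):
        digits.append(_BASE_ORDER[v % 4])
        v //= 4
    return "".join(reversed(digits))


def address_to_index(address: str) -> int:
    """Inverse of :func:`make_address`."""
    v = 0
    for ch in address:
        d = _BASE_ORDER.find(ch)
        if d < 0:
            raise ValueError(f"address contains non-pure base {ch!r}")
        v = 4 * v + d
    return v


@dataclass
class DesignManifest:
    """Sidecar bookkeeping required to invert an encoding.

    Self-contained: embeds the alphabet definition (including ratio-variant
    compositions, which FASTA cannot carry), the geometry, the Reed-Solomon
    block layout and a checksum of the original bytes.
    """

    alphabet_name: str
    alphabet_spec: dict
    payload_chars: int
    address_chars: int
    adapter5: str
    adapter3: str
    pad_chars: int
    bits_per_codon: int
    byte_length: int
    n_data_fragments: int
    n_parity_fragments: int = 0
    blocks: list = field(default_factory=list)  # [{data_start, n_data, parity_start, n_parity}]
    sha256: str = ""
    table_id: str = TABLE_ID

    @property
    def geometry(self) -> FragmentGeometry:
        return FragmentGeometry(
            payload_chars=self.payload_chars,
            address_chars=self.address_chars,
            adapter5=self.adapter5,
            adapter3=self.adapter3,
            pad_chars=self.pad_chars,
        )

    @property
    def n_fragments(self) -> int:
        return self.n_data_fragments + self.n_parity_fragments

    def alphabet(self) -> Alphabet:
        return load_alphabet(self.alphabet_spec)

    def matches(self, data: bytes) -> bool:
        return hashlib.sha256(data).hexdigest() == self.sha256

    def to_json(self, path=None) -> str:
        doc = asdict(self)
        text = json.dumps(doc, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "DesignManifest":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        return cls(**doc)


def _alphabet_spec(alphabet: Alphabet) -> dict:
    return {
        "name": alphabet.name,
        "characters": [
            {"symbol": ch.symbol,
             "composition": {b: float(f) for b, f in sorted(ch.composition.items())}}
            for ch in alphabet.characters
        ],
    }


def _pure_index(alphabet: Alphabet, base: str) -> int:
    for i, ch in enumerate(alphabet.characters):
        if ch.is_pure and ch.iupac == base:
            return i
    raise ValueError(f"alphabet lacks pure base {base}")


def pad_symbols(alphabet: Alphabet, last_char_index: int, n_pad: int) -> list:
    """Fixed filler characters: the first pure base differing from the last
    payload character, so padding cannot extend a homopolymer run."""
    out = []
    c = last_char_index
    for _ in range(n_pad):
        for base in _BASE_ORDER:
            i = _pure_index(alphabet, base)
            if i != c:
                out.append(alphabet.characters[i].symbol)
                c = i
                break
    return out


def encode_data(data: bytes, geometry: FragmentGeometry, table: CodonTable):
    """Encode bytes into addressed data fragments.

    The bit stream (most-significant bit first) is cut into payloads of
    ``b * n_codons`` bits, zero-padded at the tail; each payload is encoded
    codon by codon with the running-context rule, the initial context being
    the address's last base.

    Returns ``(fragments, manifest)``.
    """
    alphabet = table.alphabet
    b = table.bits_per_codon
    n_codons = geometry.n_codons
    payload_bits = b * n_codons
    n_frag = -(-8 * len(data) // payload_bits) if data else 0
    if n_frag > 4 ** geometry.address_chars:
        raise ValueError(
            f"{n_frag} fragments exceed the {4 ** geometry.address_chars} "
            f"addresses of a {geometry.address_chars}-character address"
        )

    bits = np.unpackbits(np.frombuffer(data, dtype=np.uint8))
    bits = np.concatenate([bits, np.zeros(n_frag * payload_bits - bits.size, dtype=np.uint8)])
    powers = 1 << np.arange(b - 1, -1, -1, dtype=np.int64)
    values = bits.reshape(n_frag, n_codons, b).astype(np.int64) @ powers

    symbols = [ch.symbol for ch in alphabet.characters]
    fragments = []
    for i in range(n_frag):
        address = make_address(i, geometry.address_chars)
        ctx = _pure_index(alphabet, address[-1])
        chars = table.encode_values(values[i], ctx)
        payload = [symbols[j] for j in chars]
        if geometry.pad_chars:
            payload.extend(pad_symbols(alphabet, chars[-1] if chars else ctx,
                                       geometry.pad_chars))
        fragments.append(Fragment(index=i, address=address, payload=tuple(payload)))

    manifest = DesignManifest(
        alphabet_name=alphabet.name,
        alphabet_spec=_alphabet_spec(alphabet),
        payload_chars=geometry.payload_chars,
        address_chars=geometry.address_chars,
        adapter5=geometry.adapter5,
        adapter3=geometry.adapter3,
        pad_chars=geometry.pad_chars,
        bits_per_codon=b,
        byte_length=len(data),
        n_data_fragments=n_frag,
        sha256=hashlib.sha256(data).hexdigest(),
    )
    return fragments, manifest


def fragment_values(fragment: Fragment, table: CodonTable,
                    geometry: FragmentGeometry) -> np.ndarray:
    """Codon values of one fragment's payload (pad characters ignored)."""
    alphabet = table.alphabet
    ctx = _pure_index(alphabet, fragment.address[-1])
    idx = [alphabet.index_of(s) for s in fragment.payload[: 3 * geometry.n_codons]]
    return table.decode_values(idx, ctx)


def decode_data(fragments: Iterable[Fragment], manifest: DesignManifest,
                table: Optional[CodonTable] = None) -> bytes:
    """Invert :func:`encode_data` from data fragments (post RS recovery).

    Raises :class:`DecodeFailure` listing missing fragment indices, or if a
    payload contains a codon outside the table.
    """
    alphabet = manifest.alphabet()
    if table is None:
        table = build_codon_table(alphabet)
    geometry = manifest.geometry
    by_index = {f.index: f for f in fragments if f.kind == "data"}
    missing = [i for i in range(manifest.n_data_fragments) if i not in by_index]
    if missing:
        raise DecodeFailure(f"missing data fragments: {missing[:10]}...", missing)

    b = table.bits_per_codon
    bad = []
    all_values = np.empty((manifest.n_data_fragments, geometry.n_codons), dtype=np.int64)
    for i in range(manifest.n_data_fragments):
        try:
            all_values[i] = fragment_values(by_index[i], table, geometry)
        except InvalidCodonError:
            bad.append(i)
    if bad:
        raise DecodeFailure(f"invalid codons in fragments {bad[:10]}", bad)
    return values_to_bytes(all_values, b, manifest.byte_length)


def values_to_bytes(values: np.ndarray, bits_per_codon: int, byte_length: int) -> bytes:
    """Unpack a (fragments x codons) value matrix to the original bytes."""
    shifts = np.arange(bits_per_codon - 1, -1, -1, dtype=np.int64)
    bits = ((values[..., None] >> shifts) & 1).astype(np.uint8).reshape(-1)
    return np.packbits(bits[: 8 * byte_length]).tobytes()


@dataclass(frozen=True)
class CapacityReport:
    """Information capacity and, optionally, physical density."""

    input_bits: int
    designed_chars: int  # address + payload, adapters excluded
    capacity_bits_per_char: float
    physical_density_bytes_per_gram: Optional[float] = None


def capacity_report(input_bytes: int, fragments: Sequence[Fragment],
                    geometry: FragmentGeometry,
                    molecules_per_fragment: Optional[float] = None,
                    mass_per_nt: float = MASS_PER_NT_GRAMS) -> CapacityReport:
    """Information capacity = stored bits / designed non-adapter characters
    (data *and* parity fragments count); physical density = stored bytes per
    gram of library when a molecule count per fragment is supplied."""
    n_frag = len(fragments)
    if n_frag == 0:
        raise ValueError("no fragments: capacity undefined")
    chars = n_frag * (geometry.payload_chars + geometry.address_chars)
    capacity = 8 * input_bytes / chars
    density = None
    if molecules_per_fragment is not None:
        grams = n_frag * molecules_per_fragment * geometry.designed_length * mass_per_nt
        density = input_bytes / grams
    return CapacityReport(
        input_bits=8 * input_bytes,
        designed_chars=chars,
        capacity_bits_per_char=capacity,
        physical_density_bytes_per_gram=density,
    )


def max_char_run(symbols: Sequence[str]) -> int:
    """Longest run of identical symbols (homopolymer check helper)."""
    best = run = 0
    prev = None
    for s in symbols:
        run = run + 1 if s == prev else 1
        prev = s
        best = max(best, run)
    return best
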