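"""Reed-Solomon outer code across fragments.

Codon values are the code symbols: a b-bit codon value is an element of
GF(2^b), so parity symbols produced column-wise over a block of fragments
are themselves codon values and re-encode through the same codon table into
ordinary parity fragments (which therefore obey the homopolymer rule).

For each codon column j, the j-th codon values of a block's data fragments
form an RS message; the parity symbols become the j-th codons of the
block's parity fragments.  A dropped-out or invalid fragment erases one
symbol from every column codeword of its block, so e erasures plus t
unknown-position errors are recoverable whenever e + 2t <= parity count.

The decoder is the classical errors-and-erasures machinery: syndromes,
erasure locator, Forney (modified) syndromes, Berlekamp-Massey for the
error locator, Chien search and Forney's magnitude formula.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .codec import (
    CodonTable,
    DesignManifest,
    Fragment,
    FragmentGeometry,
    fragment_values,
    make_address,
    pad_symbols,
    _pure_index,
)

__all__ = [
    "GF2m",
    "ReedSolomon",
    "RedundancyConfig",
    "UnrecoverableBlockError",
    "plan_blocks",
    "add_parity",
    "recover",
    "recover_values",
]

#: Primitive polynomials (with the x^m term) for the field sizes the codon
#: tables produce: b = 5 (pure4), 7 (ws6), 11 (iupac15), 13 (ratio21).
PRIMITIVE_POLYS = {
    4: 0b10011,
    5: 0b100101,
    7: 0b10001001,
    8: 0b100011101,
    11: 0b100000000101,
    13: 0b10000000011011,
}


class UnrecoverableBlockError(ValueError):
    """A block's erasures/errors exceed the parity budget."""

    def __init__(self, message: str, block: Optional[int] = None):
        super().__init__(message)
        self.block = block


class GF2m:
    """GF(2^m) arithmetic via log/antilog tables, generator alpha = x."""

    _cache: dict = {}

    def __new__(cls, m: int):
        if m in cls._cache:
            return cls._cache[m]
        self = super().__new__(cls)
        self._init(m)
        cls._cache[m] = self
        return self

    def _init(self, m: int) -> None:
        if m not in PRIMITIVE_POLYS:
            raise ValueError(f"no primitive polynomial on record for GF(2^{m})")
        self.m = m
        self.order = 1 << m
        self.N = self.order - 1  # multiplicative group order
        poly = PRIMITIVE_POLYS[m]
        exp = np.empty(2 * self.N, dtype=np.int64)
        log = np.full(self.order, -1, dtype=np.int64)
        x = 1
        for i in range(self.N):
            exp[i] = x
            log[x] = i
            x <<= 1
            if x & self.order:
                x ^= poly
        if x != 1 or np.any(log[1:] < 0):
            raise AssertionError(f"polynomial {poly:#x} is not primitive for m={m}")
        exp[self.N:] = exp[: self.N]
        self.exp = exp
        self.log = log

    def mul(self, a: int, b: int) -> int:
        if a == 0 or b == 0:
            return 0
        return int(self.exp[self.log[a] + self.log[b]])

    def div(self, a: int, b: int) -> int:
        if b == 0:
            raise ZeroDivisionError("GF division by zero")
        if a == 0:
            return 0
        return int(self.exp[(self.log[a] - self.log[b]) % self.N])

    def pow_alpha(self, i: int) -> int:
        """alpha^i for any integer i."""
        return int(self.exp[i % self.N])

    def inv(self, a: int) -> int:
        return self.div(1, a)

    # -- polynomials: python lists, index l = coefficient of x^l (LSB first)

    def poly_mul(self, p: Sequence[int], q: Sequence[int]) -> list:
        out = [0] * (len(p) + len(q) - 1)
        for i, a in enumerate(p):
            if a == 0:
                continue
            la = self.log[a]
            for j, b in enumerate(q):
                if b:
                    out[i + j] ^= int(self.exp[la + self.log[b]])
        return out

    def poly_eval(self, p: Sequence[int], x: int) -> int:
        """Horner evaluation of sum p[l] x^l."""
        acc = 0
        for c in reversed(p):
            acc = self.mul(acc, x) ^ c
        return acc


@dataclass(frozen=True)
class RedundancyConfig:
    """Outer-code knobs.

    Either ``parity_fraction`` r (parity per block = ceil(r * data rows)) or
    an explicit ``parity_total`` distributed evenly over blocks (used when a
    fixed overall fragment count is the design target).
    """

    parity_fraction: float = 0.0
    parity_total: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.parity_fraction < 1.0:
            raise ValueError("parity fraction must be in [0, 1)")
        if self.parity_total is not None and self.parity_total < 0:
            raise ValueError("parity_total must be >= 0")


class ReedSolomon:
    """Systematic RS over GF(2^m) with generator roots alpha^0..alpha^(p-1).

    Codeword coefficients (LSB first): positions 0..p-1 hold parity,
    positions p..n-1 hold the message.
    """

    def __init__(self, m: int, n_parity: int):
        self.field = GF2m(m)
        if not 0 <= n_parity <= self.field.N:
            raise ValueError(f"parity count {n_parity} outside [0, {self.field.N}]")
        self.n_parity = n_parity
        g = [1]
        for i in range(n_parity):
            g = self.field.poly_mul(g, [self.field.pow_alpha(i), 1])  # (alpha^i + x)
        self.generator = g  # monic, degree n_parity

    # -- encoding -----------------------------------------------------------

    def encode_columns(self, message: np.ndarray) -> np.ndarray:
        """Parity for many codewords at once.

        ``message`` has shape (d, n_cols): d message symbols per column.
        Returns parity of shape (n_parity, n_cols) such that the codeword
        [parity; message] has all generator roots as roots.
        """
        gf = self.field
        p = self.n_parity
        d, ncols = message.shape
        if d + p > gf.N:
            raise ValueError(f"codeword length {d + p} exceeds field limit {gf.N}")
        if p == 0:
            return np.zeros((0, ncols), dtype=np.int64)
        # Synthetic division of M(x)*x^p by g(x), processing the highest
        # message coefficient first; remainder accumulates in rem[0..p-1].
        rem = np.zeros((p, ncols), dtype=np.int64)
        gcoef = np.array(self.generator[:p], dtype=np.int64)  # below-leading coeffs
        glog = np.where(gcoef > 0, gf.log[gcoef], 0)
        gmask = gcoef > 0
        exp, log = gf.exp, gf.log
        for j in range(d - 1, -1, -1):
            feedback = message[j] ^ rem[-1]
            rem[1:] = rem[:-1]
            rem[0] = 0
            nz = feedback > 0
            if np.any(nz):
                flog = log[feedback[nz]]
                prod = np.zeros((p, int(nz.sum())), dtype=np.int64)
                prod[gmask] = exp[glog[gmask, None] + flog[None, :]]
                rem[:, nz] ^= prod
        return rem

    def encode(self, message: Sequence[int]) -> list:
        """Single-codeword systematic encode: returns parity list (LSB first)."""
        msg = np.asarray(message, dtype=np.int64).reshape(-1, 1)
        return self.encode_columns(msg)[:, 0].tolist()

    # -- decoding -----------------------------------------------------------

    def syndromes_columns(self, cw: np.ndarray) -> np.ndarray:
        """Syndromes S_j = C(alpha^j), j = 0..p-1, for each column of ``cw``
        (shape (n, n_cols), coefficient index LSB first)."""
        gf = self.field
        p = self.n_parity
        n, ncols = cw.shape
        synd = np.zeros((p, ncols), dtype=np.int64)
        nz_r, nz_c = np.nonzero(cw)
        if nz_r.size == 0:
            return synd
        logs = gf.log[cw[nz_r, nz_c]]
        for j in range(p):
            vals = gf.exp[(logs + j * nz_r) % gf.N]
            np.bitwise_xor.at(synd[j], nz_c, vals)
        return synd

    def _erasure_locator(self, positions: Sequence[int]) -> list:
        gf = self.field
        loc = [1]
        for pos in positions:
            loc = gf.poly_mul(loc, [1, gf.pow_alpha(pos)])  # (1 + alpha^pos x)
        return loc

    def _berlekamp_massey(self, seq: Sequence[int]) -> list:
        """Minimal LFSR (error locator, LSB first) for a syndrome sequence."""
        gf = self.field
        C, B = [1], [1]
        L, shift, b = 0, 1, 1
        for n_i, d_n in enumerate(seq):
            delta = d_n
            for i in range(1, L + 1):
                if i < len(C) and C[i] and n_i - i >= 0:
                    delta ^= gf.mul(C[i], seq[n_i - i])
            if delta == 0:
                shift += 1
            else:
                coef = gf.div(delta, b)
                T = list(C)
                adj = [0] * shift + [gf.mul(coef, x) for x in B]
                if len(adj) > len(C):
                    C = C + [0] * (len(adj) - len(C))
                for i, a in enumerate(adj):
                    C[i] ^= a
                if 2 * L <= n_i:
                    L = n_i + 1 - L
                    B, b, shift = T, delta, 1
                else:
                    shift += 1
        while len(C) > 1 and C[-1] == 0:
            C.pop()
        return C

    def decode_column(self, cw: np.ndarray, erasures: Sequence[int],
                      synd: Optional[np.ndarray] = None) -> tuple:
        """Correct one codeword in place; returns (codeword, n_corrected).

        ``erasures`` are coefficient positions whose symbols are unreliable
        (their current content is ignored).  Unknown-position errors are
        located with Berlekamp-Massey on the Forney-modified syndromes.
        """
        gf = self.field
        p = self.n_parity
        n = len(cw)
        e = len(erasures)
        if e > p:
            raise UnrecoverableBlockError(
                f"{e} erasures exceed the {p} parity symbols")
        if synd is None:
            synd = self.syndromes_columns(cw.reshape(-1, 1).astype(np.int64))[:, 0]
        S = [int(s) for s in synd]
        if not any(S):
            return cw, 0
        lam_e = self._erasure_locator(erasures)
        # Forney syndromes: T = S * Lambda_E mod x^p; entries e.. obey the
        # LFSR of the (unknown-position) error locator.
        T = self.field.poly_mul(S, lam_e)[:p]
        T += [0] * (p - len(T))
        sigma = self._berlekamp_massey(T[e:]) if p > e else [1]
        t = len(sigma) - 1
        if e + 2 * t > p:
            raise UnrecoverableBlockError(
                f"{e} erasures + {t} errors exceed parity budget {p}")
        lam = gf.poly_mul(sigma, lam_e)
        deg = len(lam) - 1
        # Chien search over all n positions: roots of Lambda at alpha^{-i}.
        positions = [i for i in range(n) if gf.poly_eval(lam, gf.pow_alpha(-i)) == 0]
        if len(positions) != deg:
            raise UnrecoverableBlockError(
                f"errata locator degree {deg} has {len(positions)} roots; "
                "error pattern exceeds the code's capability")
        omega = gf.poly_mul(S, lam)[:p]
        lam_deriv = [lam[i] if i % 2 == 1 else 0 for i in range(1, len(lam))]
        for i in positions:
            x_inv = gf.pow_alpha(-i)
            den = gf.poly_eval(lam_deriv, x_inv)
            if den == 0:
                raise UnrecoverableBlockError("Forney denominator vanished")
            num = gf.mul(gf.pow_alpha(i), gf.poly_eval(omega, x_inv))
            cw[i] ^= gf.div(num, den)
        check = self.syndromes_columns(cw.reshape(-1, 1).astype(np.int64))
        if np.any(check):
            raise UnrecoverableBlockError("residual syndromes after correction")
        return cw, len(positions)


# ---------------------------------------------------------------------------
# Block layout across fragments


def plan_blocks(n_data: int, bits_per_codon: int,
                config: RedundancyConfig) -> list:
    """Partition data fragments (sequential by index) into RS blocks.

    Returns a list of dicts {data_start, n_data, parity_start, n_parity};
    parity fragments get global indices following all data fragments.
    """
    if n_data == 0:
        return []
    max_n = (1 << bits_per_codon) - 1
    if config.parity_total is not None:
        total_parity = config.parity_total
        if total_parity == 0:
            return []
        n_blocks = max(1, math.ceil((n_data + total_parity) / max_n))
        while True:
            d_hi = math.ceil(n_data / n_blocks)
            p_hi = math.ceil(total_parity / n_blocks)
            if d_hi + p_hi <= max_n:
                break
            n_blocks += 1
        data_sizes = _balanced(n_data, n_blocks)
        parity_sizes = _balanced(total_parity, n_blocks)
    else:
        r = config.parity_fraction
        if r == 0.0:
            return []
        d_cap = max_n
        while d_cap + math.ceil(r * d_cap) > max_n:
            d_cap -= 1
        n_blocks = math.ceil(n_data / d_cap)
        data_sizes = _balanced(n_data, n_blocks)
        parity_sizes = [math.ceil(r * d) for d in data_sizes]
    blocks = []
    d_off, p_off = 0, n_data
    for d, p in zip(data_sizes, parity_sizes):
        blocks.append({"data_start": d_off, "n_data": d,
                       "parity_start": p_off, "n_parity": p})
        d_off += d
        p_off += p
    return blocks


def _balanced(total: int, parts: int) -> list:
    q, r = divmod(total, parts)
    return [q + 1] * r + [q] * (parts - r)


def add_parity(fragments: Sequence[Fragment], config: RedundancyConfig,
               table: CodonTable, manifest: DesignManifest) -> list:
    """Append RS parity fragments; updates the manifest's block layout.

    Parity codon values are re-encoded through the codon table with a
    running context (so parity fragments obey the homopolymer rule) and
    addressed immediately after the data fragments.
    """
    geometry = manifest.geometry
    data = [f for f in fragments if f.kind == "data"]
    blocks = plan_blocks(len(data), table.bits_per_codon, config)
    manifest.blocks = blocks
    manifest.n_parity_fragments = sum(bl["n_parity"] for bl in blocks)
    if manifest.n_fragments > 4 ** geometry.address_chars:
        raise ValueError("address space exhausted by parity fragments; widen the address")
    if not blocks:
        return list(data)

    values = np.stack([fragment_values(f, table, geometry) for f in data])
    alphabet = table.alphabet
    symbols = [ch.symbol for ch in alphabet.characters]
    out = list(data)
    for bl in blocks:
        rs = ReedSolomon(table.bits_per_codon, bl["n_parity"])
        msg = values[bl["data_start"]: bl["data_start"] + bl["n_data"]]
        parity = rs.encode_columns(msg)  # (n_parity, n_codons)
        for t in range(bl["n_parity"]):
            idx = bl["parity_start"] + t
            address = make_address(idx, geometry.address_chars)
            ctx = _pure_index(alphabet, address[-1])
            chars = table.encode_values(parity[t], ctx)
            payload = [symbols[j] for j in chars]
            if geometry.pad_chars:
                payload.extend(pad_symbols(alphabet, chars[-1], geometry.pad_chars))
            out.append(Fragment(index=idx, address=address,
                                payload=tuple(payload), kind="parity"))
    return out


def recover_values(values: np.ndarray, erasure_rows: Iterable[int],
                   manifest: DesignManifest) -> tuple:
    """RS-correct a (n_fragments x n_codons) codon-value matrix in global
    fragment order (parity rows included; erased rows' content is ignored).

    Returns ``(data_values, stats)`` where ``data_values`` is the corrected
    (n_data x n_codons) matrix and stats counts corrected symbols per block.

    Raises :class:`UnrecoverableBlockError` when a block's erasures exceed
    its parity or the error pattern defeats the decoder.
    """
    erasure_rows = set(int(i) for i in erasure_rows)
    b = manifest.bits_per_codon
    stats = {"corrected_symbols": 0, "per_block": []}
    out = np.array(values[: manifest.n_data_fragments], dtype=np.int64, copy=True)
    for bi, bl in enumerate(manifest.blocks):
        p, d = bl["n_parity"], bl["n_data"]
        rs = ReedSolomon(b, p)
        rows = (list(range(bl["parity_start"], bl["parity_start"] + p))
                + list(range(bl["data_start"], bl["data_start"] + d)))
        cw = np.array(values[rows], dtype=np.int64)  # (n, n_codons)
        cw[[i for i, r in enumerate(rows) if r in erasure_rows]] = 0
        erasures = [i for i, r in enumerate(rows) if r in erasure_rows]
        if len(erasures) > p:
            raise UnrecoverableBlockError(
                f"block {bi}: {len(erasures)} erased fragments exceed {p} parity",
                block=bi)
        # A zero-syndrome column is already a valid codeword; with e <= p
        # erasures the codeword is unique given the unerased symbols, so the
        # zero-filled word being valid means the erased symbols were 0.
        synd = rs.syndromes_columns(cw)
        corrected = 0
        for col in np.nonzero(np.any(synd != 0, axis=0))[0]:
            try:
                _, ncorr = rs.decode_column(cw[:, col], erasures, synd[:, col])
            except UnrecoverableBlockError as exc:
                raise UnrecoverableBlockError(f"block {bi}: {exc}", block=bi)
            corrected += ncorr
        out[bl["data_start"]: bl["data_start"] + d] = cw[p:]
        stats["corrected_symbols"] += corrected
        stats["per_block"].append({"block": bi, "corrected": corrected,
                                   "erasures": len(erasures)})
    return out, stats


def recover(fragments: Sequence[Fragment], erasure_indices: Iterable[int],
            manifest: DesignManifest, table: CodonTable) -> list:
    """Fragment-level recovery: rebuilds the full corrected set of *data*
    fragments from a possibly incomplete/corrupted fragment collection."""
    geometry = manifest.geometry
    n_total = manifest.n_fragments
    n_codons = geometry.n_codons
    erasures = set(int(i) for i in erasure_indices)
    values = np.zeros((n_total, n_codons), dtype=np.int64)
    present = set()
    for f in fragments:
        if f.index in erasures:
            continue
        try:
            values[f.index] = fragment_values(f, table, geometry)
            present.add(f.index)
        except Exception:
            erasures.add(f.index)
    erasures |= set(range(n_total)) - present
    data_values, _ = recover_values(values, erasures, manifest)

    alphabet = table.alphabet
    symbols = [ch.symbol for ch in alphabet.characters]
    out = []
    for i in range(manifest.n_data_fragments):
        address = make_address(i, geometry.address_chars)
        ctx = _pure_index(alphabet, address[-1])
        chars = table.encode_values(data_values[i], ctx)
        payload = [symbols[j] for j in chars]
        if geometry.pad_chars:
            payload.extend(pad_symbols(alphabet, chars[-1], geometry.pad_chars))
        out.append(Fragment(index=i, address=address, payload=tuple(payload)))
    return out
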