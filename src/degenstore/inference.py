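"""Statistical decoding of degenerate-base read pools.

The decoder never sees individual molecules' identities; it recovers each
designed character from the *distribution* of base calls at its position.
Pipeline: length-filter the reads, demultiplex by exact address match,
optionally collapse duplicate reads, tabulate per-position A/C/G/T call
fractions, locate the error threshold at the first valley (inflection
point) of the pooled fraction histogram -- substitution-error mass piles up
near zero while intended-base mass sits at the design mixing fractions --
then call each position's base support as the bases above threshold,
match the support (and, for ratio variants, the ratio between the two
bases) to an alphabet character, convert codons back to bits, and run
Reed-Solomon recovery over fragments that dropped out or failed character
inference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .alphabet import Alphabet, UnresolvableCharacterError, match_character
from .codec import (
    CodonTable,
    DesignManifest,
    Fragment,
    InvalidCodonError,
    build_codon_table,
    values_to_bytes,
    _pure_index,
    make_address,
)
from .redundancy import UnrecoverableBlockError, recover_values
from .synthsim import ReadPool

__all__ = [
    "BaseFractionMatrix",
    "ThresholdResult",
    "DecodeStats",
    "EmptyPoolError",
    "filter_reads",
    "demultiplex",
    "deduplicate",
    "base_fractions",
    "find_error_threshold",
    "infer_characters",
    "decode_pool",
    "character_error_rate",
]

logger = logging.getLogger(__name__)

_BASES = "ACGT"


class EmptyPoolError(ValueError):
    """No reads survived filtering."""


@dataclass
class BaseFractionMatrix:
    """Observed base-call counts over one fragment's payload positions."""

    fragment_index: int
    counts: np.ndarray  # (payload_chars, 4) int64

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def fractions(self) -> np.ndarray:
        d = self.depth[:, None]
        with np.errstate(invalid="ignore", divide="ignore"):
            fr = np.where(d > 0, self.counts / d, 0.0)
        return fr


@dataclass
class ThresholdResult:
    """Error/intended-base decision point on call fractions."""

    cutoff: float
    bin_edges: np.ndarray
    counts: np.ndarray
    smoothed: np.ndarray
    inflection_bin: Optional[int]
    fallback: bool
    n_values: int


@dataclass
class DecodeStats:
    """Diagnostics of one decode run."""

    n_reads: int = 0
    n_length_discarded: int = 0
    n_unassigned: int = 0
    n_purged: int = 0
    n_groups: int = 0
    erasure_count: int = 0
    rs_corrected_symbols: int = 0
    char_error_rate: Optional[float] = None
    threshold: Optional[ThresholdResult] = None
    success: bool = False
    failure_reason: Optional[str] = None


def filter_reads(pool: ReadPool, expected_length: int):
    """Keep only reads of exactly the designed (non-adapter) length.

    Returns ``(pool, n_discarded)``; raises :class:`EmptyPoolError` when
    nothing survives.
    """
    n_in = pool.n_reads
    if pool.read_length == expected_length:
        matrix, truth = pool.matrix, pool.truth
    else:
        matrix = np.zeros((0, expected_length), dtype=np.uint8)
        truth = np.zeros(0, dtype=np.int64)
    extra, extra_t = [], []
    for s, t in zip(pool.odd, pool.odd_truth):
        if len(s) == expected_length and not (set(s) - set(_BASES)):
            extra.append(np.frombuffer(s.encode(), dtype=np.uint8))
            extra_t.append(t)
    if extra:
        from .synthsim import _ASCII_TO_CODE
        matrix = np.vstack([matrix, _ASCII_TO_CODE[np.stack(extra)]])
        truth = np.concatenate([truth, np.array(extra_t, dtype=np.int64)])
    out = ReadPool(matrix, truth)
    if out.n_reads == 0:
        raise EmptyPoolError(f"no reads of designed length {expected_length}")
    return out, n_in - out.n_reads


def demultiplex(pool: ReadPool, manifest: DesignManifest):
    """Group reads by exact match of the address segment.

    A read's address digits (base-4 over A, C, G, T) must decode to a
    designed fragment index; anything else -- including a single
    substitution inside the address -- is discarded and counted.

    Returns ``(groups, n_unassigned)`` with groups mapping fragment index
    to a (n_i, L) read matrix.  Empty groups are absent (later erasures).
    """
    w = manifest.address_chars
    powers = 4 ** np.arange(w - 1, -1, -1, dtype=np.int64)
    idx = pool.matrix[:, :w].astype(np.int64) @ powers
    valid = idx < manifest.n_fragments
    n_unassigned = int((~valid).sum())
    idx_v = idx[valid]
    rows = np.nonzero(valid)[0]
    order = np.argsort(idx_v, kind="stable")
    groups = {}
    if order.size:
        sorted_idx = idx_v[order]
        starts = np.flatnonzero(np.r_[True, np.diff(sorted_idx) != 0])
        bounds = np.r_[starts, sorted_idx.size]
        for s, e in zip(bounds[:-1], bounds[1:]):
            groups[int(sorted_idx[s])] = pool.matrix[rows[order[s:e]]]
    return groups, n_unassigned


def deduplicate(matrix: np.ndarray) -> np.ndarray:
    """Collapse exact-duplicate reads to a single copy."""
    if len(matrix) <= 1:
        return matrix
    return np.unique(matrix, axis=0)


def base_fractions(matrix: np.ndarray, fragment_index: int,
                   address_chars: int) -> BaseFractionMatrix:
    """Tabulate A/C/G/T calls per payload position of one read group."""
    if len(matrix) == 0:
        raise EmptyPoolError(f"fragment {fragment_index}: empty read group")
    payload = matrix[:, address_chars:]
    counts = np.stack(
        [(payload == b).sum(axis=0) for b in range(4)], axis=1
    ).astype(np.int64)
    return BaseFractionMatrix(fragment_index=fragment_index, counts=counts)


def find_error_threshold(values: np.ndarray, alphabet: Alphabet,
                         bin_width: float = 0.01, smooth_window: int = 5,
                         search_cap: float = 0.2) -> ThresholdResult:
    """Locate the decision point between error mass and intended-base mass.

    The pooled call fractions are histogrammed on [0, 1], smoothed with a
    centred moving average, and scanned from zero for the first valley:
    the first sign change of the first difference from negative to
    positive marks the valley's end, and walking back over bins within a
    small Poisson noise floor (2 counts) of the valley minimum finds its
    onset.  Substitution-error mass concentrates toward zero and
    intended-base mass sits at the design mixing fractions, so the valley
    separates them; the cutoff is the right edge of the valley's *middle*
    bin, keeping margin against both the error tail and the binomial
    spread of low-depth intended bases.  If no valley appears below
    ``search_cap`` (e.g. an error-free pool drives all error mass into the
    zero bin), the cutoff falls back to half the alphabet's smallest
    design fraction.
    """
    values = np.asarray(values, dtype=float).ravel()
    n = values.size
    if n < 1000:
        logger.warning("threshold estimated from only %d fraction values", n)
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    counts, _ = np.histogram(np.clip(values, 0.0, 1.0), bins=edges)
    kernel = np.ones(smooth_window) / smooth_window
    smoothed = np.convolve(counts, kernel, mode="same")

    noise_floor = 2.0  # smoothed counts within this of the minimum are "empty"
    inflection = None
    if counts.max() < counts.sum():  # not all mass in one bin
        d = np.diff(smoothed)
        seen_neg = False
        for i in range(d.size):
            if d[i] < 0:
                seen_neg = True
            elif d[i] > 0 and seen_neg:
                if float(edges[i + 1]) > search_cap:
                    break  # valley starts beyond the search cap: fall back
                onset = i
                while onset > 0 and smoothed[onset - 1] <= smoothed[i] + noise_floor:
                    onset -= 1
                inflection = (onset + i) // 2  # middle bin of the valley
                break
    fallback = False
    if inflection is not None:
        cutoff = float(edges[inflection + 1])
    if inflection is None:
        cutoff = alphabet.min_design_fraction / 2.0
        fallback = True
    return ThresholdResult(cutoff=cutoff, bin_edges=edges, counts=counts,
                           smoothed=smoothed, inflection_bin=inflection,
                           fallback=fallback, n_values=n)


def _support_table(alphabet: Alphabet):
    """Support bitmask (A=1, C=2, G=4, T=8) -> candidate character indices."""
    lut = [[] for _ in range(16)]
    for i, ch in enumerate(alphabet.characters):
        mask = sum(1 << _BASES.index(b) for b in ch.support)
        lut[mask].append(i)
    return lut


def infer_characters(bfm: BaseFractionMatrix, threshold: ThresholdResult,
                     alphabet: Alphabet):
    """Error-elimination character inference for one fragment.

    Per position, bases whose call fraction exceeds the cutoff form the
    intended support; the support picks the encoding character, with ratio
    variants resolved by comparing the two bases' observed fractions.

    Returns ``(symbols, flags)`` -- symbols has None at unresolvable
    positions, which ``flags`` marks True.
    """
    fr = bfm.fractions
    above = fr > threshold.cutoff
    masks = above @ (1 << np.arange(4))
    lut = _support_table(alphabet)
    chars = alphabet.characters
    symbols, flags = [], []
    for pos in range(fr.shape[0]):
        cands = lut[int(masks[pos])]
        if len(cands) == 1:
            symbols.append(chars[cands[0]].symbol)
            flags.append(False)
        elif not cands:
            symbols.append(None)
            flags.append(True)
        else:
            support = [b for b in _BASES if above[pos, _BASES.index(b)]]
            fractions = {b: float(fr[pos, _BASES.index(b)]) for b in support}
            try:
                ch = match_character(support, fractions, alphabet)
                symbols.append(ch.symbol)
                flags.append(False)
            except UnresolvableCharacterError:
                symbols.append(None)
                flags.append(True)
    return symbols, flags


def character_error_rate(inferred: Sequence, designed: Sequence) -> float:
    """Fraction of character positions differing from the design
    (unresolved positions count as errors)."""
    if len(inferred) != len(designed):
        raise ValueError(
            f"length mismatch: inferred {len(inferred)} vs designed {len(designed)}")
    if not designed:
        return 0.0
    wrong = sum(1 for a, b in zip(inferred, designed) if a != b)
    return wrong / len(designed)


def purge_incompatible_reads(matrix: np.ndarray, bfm: BaseFractionMatrix,
                             cutoff: float, address_chars: int,
                             max_mismatch_fraction: float = 0.2):
    """Drop reads that contradict the group's above-threshold base support
    at too many payload positions.

    A read whose address acquired a substitution lands in the wrong group
    and carries a *foreign* payload: it disagrees with the group's support
    at a large fraction of positions (designs differ almost everywhere),
    whereas a genuine read only misses the support where the sequencer
    erred (~p per base).  Purging such cross-talk matters when fragment
    representation is skewed: a deeply covered neighbour can contaminate a
    shallow group far above the substitution-noise level.
    """
    if len(matrix) < 2:
        return matrix, 0
    support = bfm.fractions > cutoff
    payload = matrix[:, address_chars:]
    pos = np.arange(payload.shape[1])
    compatible = support[pos[None, :], payload]
    mism = (~compatible).sum(axis=1)
    limit = int(np.ceil(max_mismatch_fraction * payload.shape[1]))
    keep = mism <= limit
    if keep.all() or not keep.any():
        return matrix, 0
    return matrix[keep], int((~keep).sum())


def decode_pool(pool: ReadPool, manifest: DesignManifest,
                table: Optional[CodonTable] = None, dedup: bool = True,
                truth_fragments: Optional[Sequence[Fragment]] = None):
    """Full decode: reads -> bytes.

    Runs filter -> demultiplex -> (dedup) -> base fractions -> global
    threshold -> cross-talk purge (re-thresholding the purged pool) ->
    character inference -> codon values -> Reed-Solomon recovery -> bit
    unpacking, and reports diagnostics.  When the designed fragments are
    supplied as ``truth_fragments`` the pre-RS character error rate is
    measured against them (fragments with no surviving reads count every
    position as wrong).

    Returns ``(data, stats)``; ``data`` is None when recovery fails.
    """
    alphabet = manifest.alphabet()
    if table is None:
        table = build_codon_table(alphabet)
    geometry = manifest.geometry
    stats = DecodeStats(n_reads=pool.n_reads)

    try:
        pool, stats.n_length_discarded = filter_reads(pool, geometry.read_length)
    except EmptyPoolError as exc:
        stats.failure_reason = str(exc)
        return None, stats
    groups, stats.n_unassigned = demultiplex(pool, manifest)
    stats.n_groups = len(groups)

    mats, bfms = {}, {}
    for i, mat in groups.items():
        if dedup:
            mat = deduplicate(mat)
        mats[i] = mat
        bfms[i] = base_fractions(mat, i, geometry.address_chars)

    if not bfms:
        stats.failure_reason = "no demultiplexed read groups"
        return None, stats
    pooled = np.concatenate([b.fractions.ravel() for b in bfms.values()])
    thr = find_error_threshold(pooled, alphabet)

    # Second pass: drop address-cross-talk reads and re-estimate.
    purged_any = False
    for i, mat in mats.items():
        mat2, n_purged = purge_incompatible_reads(
            mat, bfms[i], thr.cutoff, geometry.address_chars)
        if n_purged:
            stats.n_purged += n_purged
            bfms[i] = base_fractions(mat2, i, geometry.address_chars)
            purged_any = True
    if purged_any:
        pooled = np.concatenate([b.fractions.ravel() for b in bfms.values()])
        thr = find_error_threshold(pooled, alphabet)
    stats.threshold = thr

    n_total = manifest.n_fragments
    n_codons = geometry.n_codons
    values = np.zeros((n_total, n_codons), dtype=np.int64)
    erasures = set(range(n_total)) - set(bfms)
    inferred = {}
    for i, bfm in bfms.items():
        symbols, flags = infer_characters(bfm, thr, alphabet)
        inferred[i] = symbols
        codon_syms = symbols[: 3 * n_codons]
        if any(s is None for s in codon_syms):
            erasures.add(i)
            continue
        address = make_address(i, geometry.address_chars)
        ctx = _pure_index(alphabet, address[-1])
        try:
            values[i] = table.decode_values(
                [alphabet.index_of(s) for s in codon_syms], ctx)
        except InvalidCodonError:
            erasures.add(i)
    stats.erasure_count = len(erasures)

    if truth_fragments is not None:
        wrong = total = 0
        for f in truth_fragments:
            got = inferred.get(f.index)
            total += len(f.payload)
            if got is None:
                wrong += len(f.payload)
            else:
                wrong += sum(1 for a, b in zip(got, f.payload) if a != b)
        stats.char_error_rate = wrong / total if total else 0.0

    if manifest.blocks:
        try:
            data_values, rstats = recover_values(values, erasures, manifest)
            stats.rs_corrected_symbols = rstats["corrected_symbols"]
        except UnrecoverableBlockError as exc:
            stats.failure_reason = f"Reed-Solomon recovery failed: {exc}"
            return None, stats
    else:
        bad_data = sorted(i for i in erasures if i < manifest.n_data_fragments)
        if bad_data:
            stats.failure_reason = (
                f"{len(bad_data)} data fragments unrecovered (no parity): "
                f"{bad_data[:10]}")
            return None, stats
        data_values = values[: manifest.n_data_fragments]

    data = values_to_bytes(data_values, manifest.bits_per_codon,
                           manifest.byte_length)
    stats.success = manifest.matches(data)
    if not stats.success and stats.failure_reason is None:
        stats.failure_reason = "checksum mismatch after decode"
    return data, stats
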