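"""Monte Carlo model of degenerate-base synthesis and NGS readout.

Each designed fragment describes a *pool* of molecules: at a degenerate
position every synthesized molecule independently carries one base drawn
from the character's mixing composition, so the base-call frequency at that
position follows a binomial (generally multinomial) distribution across
reads.  The simulator draws per-fragment read counts from a multinomial
whose probabilities model uneven fragment representation (PCR amplification
bias; lognormal weights by default), rejects molecules whose GC content
falls outside configured bounds (re-drawing them, which mimics the poor
amplification yield of extreme-GC molecules), and then applies uniform
substitution noise to every emitted base call.

Reads cover the address + payload region only; the fixed adapters are the
sequencing primers and never appear in the read pool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .alphabet import Alphabet, EncodingCharacter
from .codec import Fragment, FragmentGeometry

__all__ = [
    "BASE_CODES",
    "SimulationConfig",
    "ReadPool",
    "sample_molecule",
    "simulate_reads",
    "representation_weights",
    "write_fastq",
    "read_fastq",
    "write_design_fasta",
    "read_design_fasta",
    "write_design_tsv",
    "read_design_tsv",
    "write_truth_tsv",
    "load_weights_tsv",
]

logger = logging.getLogger(__name__)

_BASES = "ACGT"
BASE_CODES = {b: i for i, b in enumerate(_BASES)}
_CODE_TO_BASE = np.frombuffer(_BASES.encode(), dtype=np.uint8)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthesis/sequencing Monte Carlo model.

    coverage
        Mean reads per designed fragment.
    representation
        "lognormal" (weights ~ LogNormal(0, sigma), normalized),
        "uniform", or "empirical" (explicit ``weights``).
    p_sub
        Per-base substitution probability of the sequencer (uniform over
        the three other bases).  2% mirrors the Monte Carlo model; the
        wet-lab substitution estimate is about 1%.
    gc_bounds
        Molecules with GC fraction outside [low, high] are discarded and
        re-synthesized (None disables the filter).
    indel_rate
        Per-base insertion/deletion probability (default 0; such reads
        leave the design length and are meant to exercise the length
        filter).
    """

    coverage: float = 250.0
    representation: str = "lognormal"
    lognormal_sigma: float = 0.5
    weights: Optional[Sequence[float]] = None
    p_sub: float = 0.02
    gc_bounds: Optional[tuple] = (0.40, 0.60)
    indel_rate: float = 0.0
    max_attempts: int = 50

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if not 0.0 <= self.p_sub < 1.0:
            raise ValueError("p_sub must be in [0, 1)")
        if self.gc_bounds is not None:
            lo, hi = self.gc_bounds
            if not 0.0 <= lo < hi <= 1.0:
                raise ValueError("gc_bounds must satisfy 0 <= low < high <= 1")
        if self.representation not in ("lognormal", "uniform", "empirical"):
            raise ValueError("representation must be lognormal|uniform|empirical")
        if self.representation == "empirical" and self.weights is None:
            raise ValueError("empirical representation needs weights")
        if not 0.0 <= self.indel_rate < 1.0:
            raise ValueError("indel_rate must be in [0, 1)")


class ReadPool:
    """A pool of simulated (or parsed) reads.

    Uniform-length reads live in a dense (n, L) uint8 matrix of base codes
    (A=0, C=1, G=2, T=3); reads of any other length (indels) are kept as
    strings in ``odd``.  ``truth`` records each matrix read's originating
    fragment (-1 when unknown) for evaluation only -- the decoder never
    looks at it.
    """

    def __init__(self, matrix: np.ndarray, truth: Optional[np.ndarray] = None,
                 odd: Optional[list] = None, odd_truth: Optional[list] = None):
        self.matrix = np.asarray(matrix, dtype=np.uint8)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (reads x positions)")
        self.truth = (np.full(len(self.matrix), -1, dtype=np.int64)
                      if truth is None else np.asarray(truth, dtype=np.int64))
        self.odd = list(odd or [])
        self.odd_truth = list(odd_truth if odd_truth is not None else [-1] * len(self.odd))

    @property
    def n_reads(self) -> int:
        return len(self.matrix) + len(self.odd)

    @property
    def read_length(self) -> int:
        return self.matrix.shape[1]

    def sequences(self) -> Iterable[str]:
        for row in self.matrix:
            yield row.tobytes().translate(_TRANSLATE).decode()
        yield from self.odd

    @classmethod
    def from_sequences(cls, seqs: Sequence[str], truth: Optional[Sequence[int]] = None,
                       length: Optional[int] = None) -> "ReadPool":
        truth = list(truth) if truth is not None else [-1] * len(seqs)
        if length is None:
            lengths = [len(s) for s in seqs]
            length = max(set(lengths), key=lengths.count) if seqs else 0
        rows, t_rows, odd, t_odd = [], [], [], []
        for s, t in zip(seqs, truth):
            if len(s) == length and not (set(s) - set(_BASES)):
                rows.append(np.frombuffer(s.encode(), dtype=np.uint8))
                t_rows.append(t)
            else:
                odd.append(s)
                t_odd.append(t)
        if rows:
            matrix = _ASCII_TO_CODE[np.stack(rows)]
        else:
            matrix = np.zeros((0, length), dtype=np.uint8)
        return cls(matrix, np.array(t_rows, dtype=np.int64), odd, t_odd)


_TRANSLATE = bytes.maketrans(bytes(range(4)), _BASES.encode())
_ASCII_TO_CODE = np.zeros(128, dtype=np.uint8)
for _b, _i in BASE_CODES.items():
    _ASCII_TO_CODE[ord(_b)] = _i


def _composition_matrix(fragment: Fragment, alphabet: Alphabet) -> np.ndarray:
    """(L, 4) mixing fractions over address + payload positions."""
    L = len(fragment.address) + len(fragment.payload)
    comp = np.zeros((L, 4))
    for i, b in enumerate(fragment.address):
        comp[i, BASE_CODES[b]] = 1.0
    for j, sym in enumerate(fragment.payload):
        ch = alphabet.by_symbol(sym)
        for b, f in ch.composition.items():
            comp[len(fragment.address) + j, BASE_CODES[b]] = f
    return comp


def _draw(cum: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """n molecules from per-position cumulative compositions (L, 4)."""
    u = rng.random((n, cum.shape[0]))
    return (u[:, :, None] > cum[None, :, :]).sum(axis=2).astype(np.uint8)


def sample_molecule(characters: Sequence[EncodingCharacter],
                    rng: np.random.Generator) -> str:
    """Realize one molecule of a designed character sequence: every
    position is drawn independently from its mixing composition."""
    comp = np.zeros((len(characters), 4))
    for i, ch in enumerate(characters):
        for b, f in ch.composition.items():
            comp[i, BASE_CODES[b]] = f
    cum = np.cumsum(comp, axis=1)
    cum[:, -1] = 1.0
    row = _draw(cum, 1, rng)[0]
    return row.tobytes().translate(_TRANSLATE).decode()


def representation_weights(config: SimulationConfig, n_fragments: int,
                           rng: np.random.Generator) -> np.ndarray:
    """Normalized per-fragment representation probabilities."""
    if config.representation == "uniform":
        w = np.ones(n_fragments)
    elif config.representation == "lognormal":
        if config.lognormal_sigma == 0:
            w = np.ones(n_fragments)
        else:
            w = rng.lognormal(0.0, config.lognormal_sigma, n_fragments)
    else:
        w = np.asarray(config.weights, dtype=float)
        if w.shape != (n_fragments,):
            raise ValueError(
                f"empirical weights length {w.size} != {n_fragments} fragments")
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
    return w / w.sum()


def simulate_reads(fragments: Sequence[Fragment], config: SimulationConfig,
                   alphabet: Alphabet, rng: np.random.Generator) -> ReadPool:
    """Simulate an NGS pool over the designed fragments.

    Per fragment, read counts are multinomial with representation-weight
    probabilities (total = coverage x fragment count); each read realizes
    one molecule of the fragment's variant pool, is GC-filtered (with
    regeneration) and then receives substitution noise.
    """
    n_frag = len(fragments)
    weights = representation_weights(config, n_frag, rng)
    total = int(round(config.coverage * n_frag))
    counts = rng.multinomial(total, weights)

    L = len(fragments[0].address) + len(fragments[0].payload)
    matrix = np.empty((total, L), dtype=np.uint8)
    truth = np.empty(total, dtype=np.int64)
    offset = 0
    for frag, n in zip(fragments, counts):
        if n == 0:
            continue
        comp = _composition_matrix(frag, alphabet)
        cum = np.cumsum(comp, axis=1)
        cum[:, -1] = 1.0
        mat = _draw(cum, n, rng)
        if config.gc_bounds is not None:
            lo, hi = config.gc_bounds
            for _ in range(config.max_attempts):
                gc = np.logical_or(mat == 1, mat == 2).mean(axis=1)
                bad = (gc < lo) | (gc > hi)
                if not bad.any():
                    break
                mat[bad] = _draw(cum, int(bad.sum()), rng)
            else:
                gc = np.logical_or(mat == 1, mat == 2).mean(axis=1)
                n_bad = int(((gc < lo) | (gc > hi)).sum())
                if n_bad:
                    logger.warning(
                        "fragment %d: %d molecules still outside GC bounds "
                        "after %d attempts; emitted unfiltered",
                        frag.index, n_bad, config.max_attempts)
        matrix[offset: offset + n] = mat
        truth[offset: offset + n] = frag.index
        offset += n
    matrix = matrix[:offset]
    truth = truth[:offset]

    if config.p_sub > 0:
        mask = rng.random(matrix.shape) < config.p_sub
        n_err = int(mask.sum())
        if n_err:
            matrix[mask] = (matrix[mask] + rng.integers(1, 4, n_err)) % 4

    odd, odd_truth = [], []
    if config.indel_rate > 0:
        n_events = rng.binomial(L, config.indel_rate, size=len(matrix))
        hit = np.nonzero(n_events)[0]
        keep = np.ones(len(matrix), dtype=bool)
        for i in hit:
            seq = list(matrix[i].tobytes().translate(_TRANSLATE).decode())
            for _ in range(n_events[i]):
                pos = int(rng.integers(0, len(seq) + 1))
                if rng.random() < 0.5 and len(seq) > 1:
                    del seq[pos % len(seq)]
                else:
                    seq.insert(pos, _BASES[rng.integers(0, 4)])
            s = "".join(seq)
            if len(s) == L:
                matrix[i] = _ASCII_TO_CODE[np.frombuffer(s.encode(), dtype=np.uint8)]
            else:
                keep[i] = False
                odd.append(s)
                odd_truth.append(int(truth[i]))
        matrix = matrix[keep]
        truth = truth[keep]

    return ReadPool(matrix, truth, odd, odd_truth)


# ---------------------------------------------------------------------------
# File formats


def write_fastq(pool: ReadPool, path) -> None:
    """Plain FASTQ with constant quality; the originating fragment (when
    known) is recorded in the description as ``frag=<index>``."""
    with open(path, "w") as fh:
        i = 0
        for seq, t in zip(pool.sequences(),
                          list(pool.truth) + list(pool.odd_truth)):
            tag = f" frag={t}" if t >= 0 else ""
            fh.write(f"@read{i}{tag}\n{seq}\n+\n{'I' * len(seq)}\n")
            i += 1


def read_fastq(path) -> ReadPool:
    """Parse a FASTQ file into a pool (Biopython parser underneath)."""
    seqs, truth = [], []
    n_ok = 0
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            seqs.append(str(rec.seq).upper())
            t = -1
            for tok in rec.description.split():
                if tok.startswith("frag="):
                    t = int(tok[5:])
            truth.append(t)
            n_ok += 1
    except ValueError as exc:
        raise ValueError(
            f"{path}: malformed FASTQ near line {4 * n_ok + 1}: {exc}") from exc
    return ReadPool.from_sequences(seqs, truth)


def write_design_fasta(fragments: Sequence[Fragment], path, alphabet: Alphabet,
                       geometry: Optional[FragmentGeometry] = None,
                       with_adapters: bool = False) -> None:
    """Designed sequences as IUPAC FASTA, one record per fragment
    (``>frag<k> <kind>``).  Ratio variants collapse to their IUPAC letter;
    the mixing ratios live in the manifest."""
    with open(path, "w") as fh:
        for f in fragments:
            seq = f.iupac_sequence(alphabet, with_adapters=with_adapters,
                                   geometry=geometry)
            fh.write(f">frag{f.index} {f.kind}\n{seq}\n")


def read_design_fasta(path, alphabet: Alphabet, address_chars: int) -> list:
    """Parse a design FASTA back into fragments.

    Requires every IUPAC letter to map to a unique alphabet character
    (alphabets with ratio variants are ambiguous in FASTA; reconstruct
    those from the design TSV instead)."""
    frags = []
    n_ok = 0
    by_support = {}
    for ch in alphabet.characters:
        by_support.setdefault(ch.iupac, []).append(ch)
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            seq = str(rec.seq).upper()
            address, rest = seq[:address_chars], seq[address_chars:]
            payload = []
            for letter in rest:
                cands = by_support.get(letter)
                if not cands:
                    raise ValueError(f"record {rec.id}: unknown IUPAC letter {letter!r}")
                if len(cands) > 1:
                    raise ValueError(
                        f"record {rec.id}: IUPAC letter {letter!r} is ambiguous "
                        "in this alphabet (ratio variants); use the design TSV")
                payload.append(cands[0].symbol)
            parts = rec.description.split()
            kind = parts[1] if len(parts) > 1 else "data"
            index = int(rec.id.replace("frag", "")) if rec.id.startswith("frag") else n_ok
            frags.append(Fragment(index=index, address=address,
                                  payload=tuple(payload), kind=kind))
            n_ok += 1
    except ValueError as exc:
        raise ValueError(f"{path}: near record {n_ok + 1}: {exc}") from exc
    return sorted(frags, key=lambda f: f.index)


def write_design_tsv(fragments: Sequence[Fragment], path) -> None:
    """Lossless fragment table (keeps ratio-variant symbols)."""
    df = pd.DataFrame({
        "index": [f.index for f in fragments],
        "kind": [f.kind for f in fragments],
        "address": [f.address for f in fragments],
        "payload": [" ".join(f.payload) for f in fragments],
    })
    df.to_csv(path, sep="\t", index=False)


def read_design_tsv(path) -> list:
    df = pd.read_csv(path, sep="\t", dtype={"address": str})
    return [Fragment(index=int(r["index"]), address=r["address"],
                     payload=tuple(r["payload"].split()), kind=r["kind"])
            for _, r in df.iterrows()]


def write_truth_tsv(pool: ReadPool, path) -> None:
    """Per-fragment true read counts (evaluation aid)."""
    truth = np.concatenate([pool.truth, np.array(pool.odd_truth, dtype=np.int64)])
    idx, counts = np.unique(truth[truth >= 0], return_counts=True)
    pd.DataFrame({"fragment_index": idx, "n_reads": counts}).to_csv(
        path, sep="\t", index=False)


def load_weights_tsv(path, n_fragments: int) -> np.ndarray:
    """Empirical representation weights: TSV with columns
    ``fragment_index`` and ``weight``; missing fragments get weight 0."""
    df = pd.read_csv(path, sep="\t")
    w = np.zeros(n_fragments)
    w[df["fragment_index"].to_numpy(dtype=int)] = df["weight"].to_numpy(dtype=float)
    return w
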