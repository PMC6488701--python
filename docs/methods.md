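# Methods

This note records the models, numerical choices and known limitations of
the package. It is the place to look when a default seems arbitrary or a
test's tolerance needs justifying.

## Encoding model

**Alphabets.** An encoding character is a probability vector over
{A, C, G, T} (its synthesis mixing composition) with a printable symbol.
The standard sets are:

| name | k | characters | log2(k) |
|---|---|---|---|
| `pure4` | 4 | A, C, G, T | 2.00 |
| `ws6` | 6 | + W (A/T), S (C/G) at 1:1 | 2.58 |
| `iupac15` | 15 | + all 11 IUPAC codes, equal mixing | 3.91 |
| `ratio21` | 21 | pure4 + {R,Y,S,W,K,M} each at 3:7 *and* 7:3 + B,D,H,V + N | 4.39 |

Ratio variants are named IUPAC letter + index with the alphabetically
first base listed first, so `W1` = A:T 3:7 and `W2` = A:T 7:3. FASTA
cannot carry mixing ratios, so designed-sequence files collapse variants
to the plain IUPAC letter; the lossless design TSV and the manifest keep
the variant symbols. All degenerate characters default to equal mixing
(the simulator's binomial model assumes equal mutual probability);
coupling-efficiency skew seen in real synthesis can be expressed by
constructing characters with custom compositions.

**Codons and the homopolymer rule.** Data is carried by codons of three
characters. For context character c (the previous codon's last character;
the address's last base for the first codon) the admissible codons are all
(x, y, z) with x ≠ c — (k−1)k² of them — enumerated in lexicographic order
of character indices; the first 2^b are kept, b = ⌊log2((k−1)k²)⌋. This
yields b = 5/7/11/13 bits per codon for k = 4/6/15/21. Because a codon's
first character never repeats the context, no run of ≥ 4 identical
characters can occur in the payload or across the address/payload
junction; the longest possible run is 3. The table is purely
combinatorial: identical on every platform and run (`lex-v1`).

The actual codon tables used in the wet-lab demonstrations this scheme
models are not public; any deterministic context-respecting bijection
gives the same fragment counts and capacities, which is what the package
reproduces. Simulated capacities for the 200-nt geometry therefore follow
from *this* table's rates (e.g. 49 codons × 11 bits for `iupac15`), not
from any published table.

**Fragments and geometry.** A fragment is adapter5 + address + payload +
adapter3. Addresses are plain base-4 over (A, C, G, T), most significant
digit first. Three geometry presets:

- `demo1`: 42 payload chars (14 codons), 3-char address, 20-nt adapters,
  85 nt total. 854 bytes → ⌈6832/154⌉ = 45 fragments; capacity
  6832/(45·45) = 3.37 bits/char.
- `demo2`: 111 payload chars (37 codons at b = 7), 9-char address. This
  layout is a reconstruction consistent with the published totals: 135,393
  bytes → 4183 data fragments, + 320 parity = 4503, capacity
  1,083,144/(4503·120) = 2.0045 bits/char.
- `sim200`: 148 payload chars (49 codons + 1 fixed pad character), 12-char
  address, 200 nt total.

A wide address can itself contain homopolymer runs (index 0 of a 9-char
address is AAAAAAAAA); the anti-homopolymer guarantee is a property of the
codon stream, not the base-4 address. The 3-char address of `demo1` is too
short for this to occur there. Tail padding of the bit stream is zeros;
the manifest records the original byte length (and a SHA-256 checksum), so
decoding truncates exactly — a sidecar manifest rather than an in-stream
header keeps fragment counts equal to ⌈bits/payload-bits⌉.

## Reed–Solomon redundancy

Codon values are symbols of GF(2^b), so parity computed column-wise over a
block of fragments is itself a sequence of codon values and re-encodes
through the same codon table into ordinary, homopolymer-safe parity
fragments addressed after the data. Blocks are sequential by fragment
index, capped at 2^b − 1 rows; parity per block is ⌈r · data rows⌉ for a
parity fraction r, or an explicit total distributed evenly (used to
reproduce the 4503-fragment layout). The decoder handles e erased
fragments plus t unknown-position errors per block whenever e + 2t ≤
parity, via erasure locator + Forney syndromes + Berlekamp–Massey + Chien
search + Forney's formula, and verifies residual syndromes after
correction. A fragment whose inferred characters fail codon validation is
treated as an erasure (cheaper than an unknown-position error); a fragment
that decodes to valid but wrong codons surfaces as an RS error.

GF(2^m) arithmetic is table-driven with fixed primitive polynomials for
m ∈ {4, 5, 7, 8, 11, 13}; table construction verifies primitivity.

## Synthesis/sequencing simulator

Each read realizes one molecule: every position is drawn independently
from its character's composition (pure positions copy verbatim). The
simulator models:

- **Uneven representation** (PCR amplification bias): per-fragment read
  counts are multinomial with probabilities from normalized
  LogNormal(0, σ) weights, σ = 0.5 by default — a heavy-tailed stand-in
  for the unpublished empirical depth distribution; empirical weights can
  be loaded from TSV. σ = 0 reduces to uniform.
- **GC rejection**: molecules with GC fraction outside [0.40, 0.60] are
  discarded and re-synthesized (mimicking poor amplification of
  extreme-GC molecules), up to 50 rounds; designs that cannot satisfy the
  bounds (e.g. W-rich fragments) are then emitted unfiltered with a
  logged warning rather than dropped, so no address silently vanishes.
  The filter applies to the realized molecule *before* sequencing noise.
- **Substitution noise**: each emitted base flips to a uniformly chosen
  other base with probability p; p = 0.02 is the Monte Carlo default, 0.01
  matches the experimentally estimated call error.
- **Indels** (optional, default 0): per-base insertion/deletion events
  produce off-length reads for the length filter to remove.

Reads cover address + payload only; adapters are the sequencing primers
(the real pipeline merges paired-end reads first — that step is out of
scope, full-length reads are emitted directly). Given one seeded
generator the pool is reproducible byte-for-byte.

What the simulator does *not* model: quality scores, strand-specific or
position-dependent error profiles, synthesis truncations, chimeric reads,
and coupling-efficiency drift of mixing ratios along the oligo. Passing
tests therefore demonstrate correctness of the decoding machinery under
the stated stochastic model, not performance on any particular wet-lab
library.

## Decoder

Pipeline: length filter (exact designed length) → demultiplex by exact
address match (a read's address must decode to a designed fragment index;
anything else is discarded) → optional duplicate removal (default on) →
per-position base-call fraction matrices → global error threshold →
cross-talk purge → character inference → codon validation → RS recovery →
bit unpacking → checksum.

**Error threshold.** All fraction values (all four bases, every payload
position, every fragment) are pooled into one histogram on [0, 1] with
0.01-wide bins, smoothed by a centred 5-bin moving average.
Substitution-error mass piles up near zero; intended-base mass sits at
the design fractions (≥ 0.25 for `iupac15`, ≥ 0.3 ratios aside). Scanning
from zero, the first sign change of the first difference from negative to
positive marks the end of the first valley; walking back over bins within
a small noise floor (2 smoothed counts) of the minimum finds the valley's
onset. The cutoff is the right edge of the valley's **middle** bin. The
midpoint matters: the valley is typically wide and nearly empty, its left
wall is the error tail and its right wall the binomial spread of
low-depth intended bases, and cutting at either wall misclassifies the
corresponding side (cutting at the right wall, for instance, strips
quarter-fraction N bases of fragments that drew few reads). If no valley
appears below 0.2 — characteristic of an error-free pool, where all error
mass is exactly zero — the cutoff falls back to half the alphabet's
smallest design fraction. The threshold is global (one distribution
pooled over all fragments), not per fragment.

**Cross-talk purge.** With skewed representation, a deeply covered
fragment sends a non-negligible number of reads whose *address* acquired
a substitution into a shallow neighbouring group (single-substitution
addresses usually decode to another valid index). Such reads carry a
foreign payload and can push a coherent wrong base above threshold (~15%
contamination was observed in simulation for a 72-read group adjacent to
a 1149-read neighbour). After the first threshold pass, reads that
contradict their group's above-threshold support at more than 20% of
payload positions are discarded — genuine reads miss the support only
where the sequencer erred (~p per base), foreign reads at ~30–70% of
positions — and fractions and threshold are re-estimated once. This is
the same logic as contaminant/chimera screening in amplicon pipelines.

**Character inference.** Per position, bases with fraction > cutoff form
the support; the support selects the alphabet character (error
elimination). Ratio variants sharing a support are resolved by comparing
the two bases' observed fractions — the majority base takes the majority
design ratio (implemented as nearest composition in L1 distance, which is
equivalent for a 3:7/7:3 pair). Positions with an empty or unknown
support are flagged; a fragment with any flagged codon position, or whose
codon fails table validation, becomes an RS erasure. The pre-correction
character error rate is defined per designed payload character position,
against the design, with absent fragments counting every position as
wrong.

**Duplicate removal** mirrors real sequencing pipelines (PCR-duplicate
screening) and is exact-sequence collapsing. For fragments rich in degenerate positions the variant space
is astronomically larger than the depth, so dedup is a no-op and decoding
is invariant to it; for low-diversity fragments (e.g. `pure4`) it
deliberately collapses the group to its distinct variants. Both modes are
available (`dedup=` flag).

## Intrinsic limits worth knowing

- Distinguishing a 3:7 from a 7:3 ratio variant is a binomial decision:
  at depth d the flip probability is P(Bin(d, 0.3) ≥ d/2) — about 10⁻³ at
  d = 50, 10⁻⁵ at d = 100. Error-free round-trip tests for `ratio21`
  therefore run at 150× uniform coverage; at 50× a multi-kilobyte payload
  has a non-trivial chance of a single variant flip even with a perfect
  sequencer. Reed–Solomon parity absorbs such flips when present.
- Below ~100× depth the binomial spread of quarter-fraction bases starts
  to overlap the error tail, which is why decoding reliability degrades
  steeply at low coverage, and why the error rate is monotone decreasing
  in coverage in the sweeps.
- Exact-match demultiplexing wastes reads with any address error (~3% at
  p = 0.01 for a 3-char address) and is the source of the cross-talk the
  purge removes; mismatch-tolerant demultiplexing is deliberately out of
  scope.

## Evaluation defaults and problem sizes

Coverage sweeps and the minimum-coverage search re-run the whole pipeline
(fresh random payload, encode, parity, simulate, decode) per grid point
and repetition, seeded via `SeedSequence([base_seed, grid_index, rep])`
for exact reproducibility. The zero-error coverage search uses a 100 kB
payload — the package's standard desk-scale stand-in for the 100 MB
claims, chosen so a full two-alphabet grid search completes in tens of
seconds; payload size is a parameter for anyone wanting the full-scale
run. The cost model defaults to $0.05/100 nt synthesis, $0.0000012/100 nt
sequencing and a 20% adapter overhead; the read/write cost ratio is
coverage × (sequencing/synthesis price per nt), independent of data
volume, giving 4.8% at 2000×. Dollar-per-megabyte outputs depend strongly
on the capacity and overhead assumptions, which is why they are exposed
as parameters rather than constants.

## Physical density

`capacity_report` converts a molecule count per fragment into a library
mass via the designed length and an average nucleotide mass of
327 g/mol / N_A ≈ 5.43·10⁻²² g, and reports bytes per gram. It is a
straightforward accounting identity; no test asserts a particular
published density, since that depends on experimentally measured molecule
counts.
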