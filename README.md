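# degenstore

DNA-based digital data storage with **degenerate bases** as extra encoding
characters.

Classical DNA storage writes bits into the four nucleotides A, C, G, T, so
each designed position carries at most log2(4) = 2 bits. A *degenerate
base* is an IUPAC symbol (W, S, R, Y, K, M, B, D, H, V, N) standing for a
position where several phosphoramidites are mixed during synthesis: the
resulting oligo pool contains every corresponding sequence variant, and the
symbol can be read back from the *distribution* of base calls at that
position across sequencing reads. Treating the 11 degenerate codes as
first-class encoding characters raises the per-character ceiling to
log2(15) ≈ 3.90 bits; adding ratio-skewed two-base mixtures (e.g. W1 for
A:T = 3:7 and W2 for A:T = 7:3) pushes a 21-character set to log2(21) ≈
4.39 bits. Since synthesis cost is per designed nucleotide — and dwarfs
sequencing cost by a factor of ~50,000 per nt — packing more bits per
designed character directly cuts the cost of writing data into DNA.

The package implements the full platform end-to-end, for people who want to
study, stress or extend statistical decoding of mixed-base DNA storage:

- **alphabet** — encoding characters with mixing compositions; the standard
  `pure4`, `ws6`, `iupac15` and `ratio21` sets; support/ratio matching.
- **codec** — binary → addressed fragments via context-dependent
  three-character codons carrying b = ⌊log2((k−1)k²)⌋ bits each; a codon's
  first character must differ from its predecessor's last, so no
  homopolymer of ≥ 4 characters can form. Base-4 pure-base addresses, fixed
  20-nt adapters, capacity and physical-density accounting.
- **redundancy** — Reed–Solomon parity *fragments* over GF(2^b) codon
  values, column-wise across blocks of fragments; erasure + unknown-error
  decoding (Berlekamp–Massey, Chien, Forney).
- **synthsim** — Monte Carlo model of the molecule pool and NGS readout:
  multinomial read counts under lognormal (or empirical) representation
  bias, per-position binomial base draws, 40–60% GC rejection with
  regeneration, uniform substitution noise, optional indels; FASTQ/FASTA
  I/O.
- **inference** — the statistical decoder: length filter, exact address
  demultiplexing, duplicate removal, per-position base-fraction matrices, a
  global error threshold at the first valley of the pooled fraction
  histogram, cross-talk purging, error-elimination character inference, RS
  recovery.
- **evaluation** — error-rate vs coverage sweeps, minimum zero-error
  coverage search, and a parameterized synthesis/sequencing cost model.

## Worked example

Store an 854-byte file with the 15-character alphabet (42-character
payload, 3-base address, 85 nt total per fragment), sequence it *in
silico* at 250× mean coverage with 1% substitution error and skewed
fragment representation, and decode:

```bash
$ degenstore encode --input hello.bin --alphabet iupac15 --geometry demo1 \
    --manifest design.manifest --design-tsv design.tsv --fasta design.fasta
fragments: 45 (45 data + 0 parity)
information capacity: 3.3738 bits/character (theoretical max 3.9069)

$ degenstore simulate --design-tsv design.tsv --manifest design.manifest \
    --coverage 250 --p-sub 0.01 --sigma 0.5 --seed 4 --out reads.fastq
wrote 11250 reads to reads.fastq

$ degenstore decode --reads reads.fastq --manifest design.manifest \
    --out recovered.bin
decoded 854 bytes -> recovered.bin: OK (checksum verified); erasures=0, rs_corrected=0
```

The 854 bytes (6832 bits) need 45 fragments of 154 payload bits; dividing
by the 45 × 45 designed non-adapter characters gives the realized
**information capacity of 3.37 bits/character** — below the theoretical
3.90 because addresses carry no data and the anti-homopolymer codon rule
discards some codons. `design.fasta` holds the designed sequences as IUPAC
strings, e.g.

```
>frag0 data
AAATHARWRARKCTCWTCSCVYMTGYAKRCRAKCHDMANWADATY
```

The cost model reproduces the reading/writing trade-off at published per-nt
prices ($0.05/100 nt synthesis, $0.0000012/100 nt sequencing):

```bash
$ degenstore cost --coverage 2000
designed nt: 3.495e+06
write cost: $1,747.63
read cost:  $83.89
read/write ratio: 4.8000%
```

Even at an extreme 2000× coverage, reading costs 4.8% of writing.

The same operations are plain library calls (`encode_data`,
`simulate_reads`, `decode_pool`, `coverage_sweep`, …) — see the module
docstrings and `docs/methods.md`.

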