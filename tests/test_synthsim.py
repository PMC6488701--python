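"""Molecule-pool sampling, read simulation and file formats."""

import numpy as np
import pytest
from scipy import stats

from degenstore.alphabet import standard_alphabet
from degenstore.codec import FragmentGeometry, Fragment, encode_data, demo1_geometry
from degenstore.synthsim import (
    ReadPool,
    SimulationConfig,
    load_weights_tsv,
    read_design_fasta,
    read_design_tsv,
    read_fastq,
    representation_weights,
    sample_molecule,
    simulate_reads,
    write_design_fasta,
    write_design_tsv,
    write_fastq,
    write_truth_tsv,
)


def _chars(alphabet, symbols):
    return [alphabet.by_symbol(s) for s in symbols]


def test_degenerate_position_yields_both_variants(alphabets, rng):
    a = alphabets["iupac15"]
    seen = {sample_molecule(_chars(a, "AWC"), rng) for _ in range(200)}
    assert seen == {"AAC", "ATC"}


def test_pure_design_is_deterministic(alphabets, rng):
    a = alphabets["pure4"]
    outs = {sample_molecule(_chars(a, "ACGT"), rng) for _ in range(20)}
    assert outs == {"ACGT"}


def test_ratio_variant_mixing_fraction(alphabets, rng):
    """A W1 (A:T = 3:7) position over many draws shows an A fraction within
    3 sigma of Binomial(n, 0.3)."""
    a = alphabets["ratio21"]
    frag = Fragment(index=0, address="A", payload=("W1",) * 10)
    cfg = SimulationConfig(coverage=10_000, representation="uniform",
                           p_sub=0.0, gc_bounds=None)
    pool = simulate_reads([frag], cfg, a, rng)
    n = len(pool.matrix) * 10
    a_frac = (pool.matrix[:, 1:] == 0).sum() / n
    assert abs(a_frac - 0.3) < 3 * np.sqrt(0.3 * 0.7 / n)


def test_equal_mix_binomial_goodness_of_fit(alphabets, rng):
    """A-counts at a W position across 200 independent depth-100 pools are
    consistent with Binomial(100, 0.5) (chi-square GOF, alpha = 0.01)."""
    a = alphabets["iupac15"]
    frag = Fragment(index=0, address="A", payload=("W",) * 3)
    counts = []
    for _ in range(200):
        cfg = SimulationConfig(coverage=100, representation="uniform",
                               p_sub=0.0, gc_bounds=None)
        pool = simulate_reads([frag], cfg, a, rng)
        counts.append(int((pool.matrix[:, 1] == 0).sum()))
    edges = [0, 44, 48, 52, 56, 101]
    obs = np.histogram(counts, bins=edges)[0]
    cdf = stats.binom(100, 0.5).cdf
    probs = np.diff([0] + [cdf(e - 1) for e in edges[1:-1]] + [1.0])
    chi2 = ((obs - 200 * probs) ** 2 / (200 * probs)).sum()
    assert chi2 < stats.chi2(len(obs) - 1).ppf(0.99)


def test_read_counts_and_validity(alphabets, tables, rng):
    """p=0, uniform weights, coverage 100, 10 fragments -> exactly 1000
    reads, each a legal variant of its fragment's design."""
    a, t = alphabets["iupac15"], tables["iupac15"]
    frags, _ = encode_data(rng.bytes(190), demo1_geometry(), t)
    assert len(frags) == 10
    cfg = SimulationConfig(coverage=100, representation="uniform",
                           p_sub=0.0, gc_bounds=None)
    pool = simulate_reads(frags, cfg, a, rng)
    assert pool.n_reads == 1000
    for f in frags:
        mat = pool.matrix[pool.truth == f.index]
        comp = np.zeros((mat.shape[1], 4), dtype=bool)
        for i, b in enumerate(f.address):
            comp[i, "ACGT".index(b)] = True
        for j, sym in enumerate(f.payload):
            for b in a.by_symbol(sym).support:
                comp[3 + j, "ACGT".index(b)] = True
        assert all(comp[pos, mat[r, pos]] for r in range(len(mat))
                   for pos in range(mat.shape[1]))


def test_gc_bounds_respected(alphabets, rng):
    """Molecules of a GC-flexible design are rejection-sampled into the
    40-60% GC window."""
    a = alphabets["iupac15"]
    frag = Fragment(index=0, address="ACG", payload=("N",) * 42)
    cfg = SimulationConfig(coverage=500, representation="uniform",
                           p_sub=0.0, gc_bounds=(0.40, 0.60))
    pool = simulate_reads([frag], cfg, a, rng)
    gc = np.logical_or(pool.matrix == 1, pool.matrix == 2).mean(axis=1)
    assert gc.min() >= 0.40 and gc.max() <= 0.60


def test_gc_infeasible_design_emitted_with_warning(alphabets, rng, caplog):
    """An A/T-only design can never reach 40% GC; after the attempt cap its
    reads are emitted unfiltered and the event is logged."""
    a = alphabets["iupac15"]
    frag = Fragment(index=0, address="ATA", payload=("W",) * 42)
    cfg = SimulationConfig(coverage=50, representation="uniform",
                           p_sub=0.0, gc_bounds=(0.40, 0.60), max_attempts=5)
    with caplog.at_level("WARNING"):
        pool = simulate_reads([frag], cfg, a, rng)
    assert pool.n_reads == 50
    assert any("GC bounds" in r.message for r in caplog.records)


def test_seed_reproducibility(alphabets, tables, rng):
    a, t = alphabets["ratio21"], tables["ratio21"]
    frags, _ = encode_data(rng.bytes(150), demo1_geometry(), t)
    cfg = SimulationConfig(coverage=50, p_sub=0.02)
    p1 = simulate_reads(frags, cfg, a, np.random.default_rng(9))
    p2 = simulate_reads(frags, cfg, a, np.random.default_rng(9))
    assert p1.matrix.tobytes() == p2.matrix.tobytes()
    assert np.array_equal(p1.truth, p2.truth)


def test_lognormal_sigma_increases_depth_dispersion(alphabets, tables, rng):
    """sigma = 0 gives uniform representation; larger sigma gives a larger
    coefficient of variation of per-fragment depth."""
    cvs = []
    for sigma in (0.0, 0.5, 1.0):
        cfg = SimulationConfig(coverage=100, representation="lognormal",
                               lognormal_sigma=sigma)
        w = representation_weights(cfg, 400, np.random.default_rng(11))
        counts = np.random.default_rng(12).multinomial(40_000, w)
        cvs.append(counts.std() / counts.mean())
    assert cvs[0] < cvs[1] < cvs[2]
    uniform = representation_weights(
        SimulationConfig(coverage=1, representation="lognormal",
                         lognormal_sigma=0.0), 7, rng)
    assert np.allclose(uniform, 1 / 7)


def test_fractions_converge_to_design(alphabets, rng):
    """Law of large numbers: at depth 10^4 and p=0, per-position base
    fractions approach the design compositions within 0.02."""
    a = alphabets["ratio21"]
    payload = ("W1", "S1", "N", "B", "A")
    frag = Fragment(index=0, address="C", payload=payload)
    cfg = SimulationConfig(coverage=10_000, representation="uniform",
                           p_sub=0.0, gc_bounds=None)
    pool = simulate_reads([frag], cfg, a, rng)
    fr = np.stack([(pool.matrix == b).mean(axis=0) for b in range(4)], axis=1)
    for j, sym in enumerate(payload):
        design = np.zeros(4)
        for b, f in a.by_symbol(sym).composition.items():
            design["ACGT".index(b)] = f
        assert np.abs(fr[1 + j] - design).max() < 0.02


def test_indel_reads_leave_design_length(alphabets, tables, rng):
    a, t = alphabets["iupac15"], tables["iupac15"]
    frags, _ = encode_data(rng.bytes(190), demo1_geometry(), t)
    cfg = SimulationConfig(coverage=50, p_sub=0.0, gc_bounds=None,
                           representation="uniform", indel_rate=0.02)
    pool = simulate_reads(frags, cfg, a, rng)
    assert pool.odd  # some reads changed length
    assert all(len(s) != pool.read_length for s in pool.odd)


def test_fastq_roundtrip(alphabets, tables, tmp_path, rng):
    a, t = alphabets["iupac15"], tables["iupac15"]
    frags, _ = encode_data(rng.bytes(100), demo1_geometry(), t)
    pool = simulate_reads(frags, SimulationConfig(coverage=20, p_sub=0.01), a, rng)
    path = tmp_path / "reads.fastq"
    write_fastq(pool, path)
    back = read_fastq(path)
    assert list(back.sequences()) == list(pool.sequences())
    assert np.array_equal(back.truth, pool.truth)


def test_empty_fastq(tmp_path):
    path = tmp_path / "empty.fastq"
    path.write_text("")
    assert read_fastq(path).n_reads == 0


def test_malformed_fastq_reports_line(tmp_path):
    path = tmp_path / "bad.fastq"
    path.write_text("@r0\nACGT\n+\nII\n")  # quality shorter than sequence
    with pytest.raises(ValueError, match="line"):
        read_fastq(path)


def test_design_fasta_roundtrip(alphabets, tables, tmp_path, rng):
    a, t = alphabets["iupac15"], tables["iupac15"]
    frags, _ = encode_data(rng.bytes(100), demo1_geometry(), t)
    path = tmp_path / "design.fasta"
    write_design_fasta(frags, path, a)
    back = read_design_fasta(path, a, address_chars=3)
    assert [(f.index, f.address, f.payload) for f in back] == \
        [(f.index, f.address, f.payload) for f in frags]


def test_design_fasta_parses_iupac_letters(alphabets, tmp_path):
    path = tmp_path / "toy.fasta"
    path.write_text(">frag0 data\nAAWC\n")
    back = read_design_fasta(path, alphabets["iupac15"], address_chars=1)
    assert back[0].payload == ("A", "W", "C")


def test_design_tsv_keeps_ratio_variants(alphabets, tables, tmp_path, rng):
    a, t = alphabets["ratio21"], tables["ratio21"]
    frags, _ = encode_data(rng.bytes(100), demo1_geometry(), t)
    path = tmp_path / "design.tsv"
    write_design_tsv(frags, path)
    back = read_design_tsv(path)
    assert [f.payload for f in back] == [f.payload for f in frags]
    fasta = tmp_path / "design.fasta"
    write_design_fasta(frags, fasta, a)
    with pytest.raises(ValueError, match="ambiguous"):
        read_design_fasta(fasta, a, address_chars=3)


def test_truth_and_weights_tsv(alphabets, tables, tmp_path, rng):
    a, t = alphabets["ws6"], tables["ws6"]
    frags, _ = encode_data(rng.bytes(100), demo1_geometry(), t)
    pool = simulate_reads(frags, SimulationConfig(coverage=30, p_sub=0.0), a, rng)
    path = tmp_path / "truth.tsv"
    write_truth_tsv(pool, path)
    import pandas as pd
    df = pd.read_csv(path, sep="\t")
    assert df["n_reads"].sum() == pool.n_reads
    df.rename(columns={"n_reads": "weight"}).to_csv(
        path.with_name("w.tsv"), sep="\t", index=False)
    w = load_weights_tsv(path.with_name("w.tsv"), len(frags))
    cfg = SimulationConfig(coverage=30, representation="empirical", weights=w)
    pool2 = simulate_reads(frags, cfg, a, rng)
    assert pool2.n_reads == 30 * len(frags)


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(coverage=0)
    with pytest.raises(ValueError):
        SimulationConfig(p_sub=1.0)
    with pytest.raises(ValueError):
        SimulationConfig(gc_bounds=(0.6, 0.4))
    with pytest.raises(ValueError):
        SimulationConfig(representation="empirical")
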