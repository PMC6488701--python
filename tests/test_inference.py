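"""Read filtering, demultiplexing, thresholding and character inference."""

import numpy as np
import pytest
from scipy import stats

from degenstore.codec import demo1_geometry, encode_data
from degenstore.inference import (
    BaseFractionMatrix,
    EmptyPoolError,
    base_fractions,
    character_error_rate,
    decode_pool,
    deduplicate,
    demultiplex,
    filter_reads,
    find_error_threshold,
    infer_characters,
)
from degenstore.synthsim import ReadPool, SimulationConfig, simulate_reads


def _pool_of(seqs, truth=None):
    return ReadPool.from_sequences(seqs, truth)


# -- filtering / demultiplexing ---------------------------------------------

def test_filter_removes_offlength_reads():
    pool = _pool_of(["ACGTA", "ACGT", "ACGTAC"], [0, 0, 0])
    out, discarded = filter_reads(pool, 5)
    assert out.n_reads == 1 and discarded == 2


def test_filter_identity_when_all_correct():
    pool = _pool_of(["ACGTA", "TTTTT"])
    out, discarded = filter_reads(pool, 5)
    assert out.n_reads == 2 and discarded == 0


def test_filter_empty_raises():
    with pytest.raises(EmptyPoolError):
        filter_reads(_pool_of(["ACG"]), 5)


def test_filter_discards_indel_reads(alphabets, tables, rng):
    a, t = alphabets["iupac15"], tables["iupac15"]
    frags, man = encode_data(rng.bytes(190), demo1_geometry(), t)
    cfg = SimulationConfig(coverage=40, p_sub=0.0, gc_bounds=None,
                           representation="uniform", indel_rate=0.05)
    pool = simulate_reads(frags, cfg, a, rng)
    n_odd = len(pool.odd)
    out, discarded = filter_reads(pool, man.geometry.read_length)
    # every length-changing indel read and nothing else is discarded
    assert discarded == sum(1 for s in pool.odd if len(s) != 45)
    assert discarded >= n_odd - sum(1 for s in pool.odd if len(s) == 45)


def test_demultiplex_error_free(alphabets, tables, rng):
    a, t = alphabets["iupac15"], tables["iupac15"]
    frags, man = encode_data(rng.bytes(190), demo1_geometry(), t)
    cfg = SimulationConfig(coverage=30, p_sub=0.0, gc_bounds=None,
                           representation="uniform")
    pool = simulate_reads(frags, cfg, a, rng)
    groups, unassigned = demultiplex(pool, man)
    assert unassigned == 0
    for i, mat in groups.items():
        assert np.all(pool.truth[np.isin(pool.matrix, mat).all(axis=1)] >= 0)
        assert len(mat) == (pool.truth == i).sum()


def test_demultiplex_rejects_address_substitution(tables, rng):
    frags, man = encode_data(rng.bytes(190), demo1_geometry(), tables["iupac15"])
    # fragment 9 has address "AGC"; flip its last base to T -> index 39 >= 10
    seq = "AGT" + "A" * 42
    pool = _pool_of([seq])
    groups, unassigned = demultiplex(pool, man)
    assert unassigned == 1 and not groups


def test_demultiplex_group_sizes_follow_weights(alphabets, tables, rng):
    a, t = alphabets["ws6"], tables["ws6"]
    frags, man = encode_data(rng.bytes(150), demo1_geometry(), t)
    w = np.linspace(1, 3, len(frags))
    cfg = SimulationConfig(coverage=400, representation="empirical",
                           weights=w / w.sum(), p_sub=0.0, gc_bounds=None)
    pool = simulate_reads(frags, cfg, a, rng)
    groups, _ = demultiplex(pool, man)
    obs = np.array([len(groups.get(i, [])) for i in range(len(frags))])
    exp = obs.sum() * w / w.sum()
    assert stats.chisquare(obs, exp).pvalue > 0.01


# -- dedup / fractions -------------------------------------------------------

def test_deduplicate_collapses_exact_copies():
    mat = np.array([[0, 1, 2], [0, 1, 2], [3, 1, 2]], dtype=np.uint8)
    assert len(deduplicate(mat)) == 2
    distinct = np.array([[0, 1], [2, 3]], dtype=np.uint8)
    assert len(deduplicate(distinct)) == 2


def test_pure_fragment_collapses_to_single_read(alphabets, tables, rng):
    a, t = alphabets["pure4"], tables["pure4"]
    frags, man = encode_data(rng.bytes(50), demo1_geometry(), t)
    cfg = SimulationConfig(coverage=250, representation="uniform",
                           p_sub=0.0, gc_bounds=None)
    pool = simulate_reads(frags[:1], cfg, a, rng)
    assert len(deduplicate(pool.matrix)) == 1


def test_base_fractions_sum_to_one(alphabets, tables, rng):
    a, t = alphabets["iupac15"], tables["iupac15"]
    frags, man = encode_data(rng.bytes(100), demo1_geometry(), t)
    pool = simulate_reads(frags, SimulationConfig(coverage=60, p_sub=0.02), a, rng)
    groups, _ = demultiplex(pool, man)
    for i, mat in groups.items():
        bfm = base_fractions(mat, i, 3)
        assert np.allclose(bfm.fractions.sum(axis=1), 1.0, atol=1e-9)


def test_base_fractions_unanimous():
    mat = np.zeros((100, 4), dtype=np.uint8)  # all 'A'
    bfm = base_fractions(mat, 0, 1)
    assert np.allclose(bfm.fractions[0], [1, 0, 0, 0])
    assert bfm.depth[0] == 100


# -- thresholding ------------------------------------------------------------

def test_threshold_on_synthetic_mixture(alphabets, rng):
    """90% error-like mass near 0 and 10% intended mass near 0.25 put the
    cutoff inside the (0.05, 0.2) valley."""
    vals = np.concatenate([
        np.abs(rng.normal(0.01, 0.005, 9000)),
        rng.normal(0.25, 0.02, 1000),
    ])
    thr = find_error_threshold(vals, alphabets["iupac15"])
    assert 0.05 < thr.cutoff < 0.2
    assert not thr.fallback


@pytest.mark.parametrize("valley", [(0.06, 0.18), (0.04, 0.12), (0.08, 0.3)])
def test_threshold_falls_in_known_valley(alphabets, rng, valley):
    lo, hi = valley
    vals = np.concatenate([
        np.clip(rng.normal(lo / 3, lo / 6, 8000), 0, None),
        rng.uniform(min(hi + 0.02, 0.99), 0.99, 4000),
    ])
    thr = find_error_threshold(vals, alphabets["iupac15"])
    assert lo - 0.02 <= thr.cutoff <= min(hi, 0.2) + 0.01


def test_threshold_error_free_pool_falls_back_low(alphabets):
    """With no errors all fraction values are 0 or design fractions; the
    cutoff must end up at or below half the smallest design fraction."""
    vals = np.concatenate([np.zeros(5000), np.full(2500, 0.5), np.full(500, 1.0)])
    thr = find_error_threshold(vals, alphabets["iupac15"])
    assert thr.cutoff <= 0.25 / 2
    assert thr.fallback


def test_threshold_degenerate_histogram(alphabets):
    thr = find_error_threshold(np.zeros(2000), alphabets["iupac15"])
    assert thr.fallback and thr.cutoff == 0.125


# -- character inference -----------------------------------------------------

def _thr(cutoff):
    return type("T", (), {"cutoff": cutoff})()


def _bfm(rows):
    counts = np.round(np.asarray(rows) * 1000).astype(np.int64)
    return BaseFractionMatrix(0, counts)


def test_infer_two_base_support(alphabets):
    syms, flags = infer_characters(
        _bfm([[0.48, 0.02, 0.01, 0.49]]), _thr(0.1), alphabets["iupac15"])
    assert syms == ["W"] and flags == [False]


def test_infer_all_bases_above_cutoff(alphabets):
    syms, _ = infer_characters(
        _bfm([[0.26, 0.24, 0.26, 0.24]]), _thr(0.1), alphabets["iupac15"])
    assert syms == ["N"]


def test_infer_ratio_variant(alphabets):
    syms, _ = infer_characters(
        _bfm([[0.71, 0.01, 0.01, 0.27]]), _thr(0.1), alphabets["ratio21"])
    assert syms == ["W2"]


def test_infer_flags_unresolvable(alphabets):
    # two-base support does not exist in pure4
    syms, flags = infer_characters(
        _bfm([[0.5, 0.0, 0.0, 0.5]]), _thr(0.1), alphabets["pure4"])
    assert syms == [None] and flags == [True]


def test_character_error_rate():
    assert character_error_rate(list("AWCK"), list("AWCK")) == 0.0
    assert character_error_rate(list("AWCK"), list("AWCT")) == 0.25
    assert character_error_rate([None] * 4, list("AWCT")) == 1.0
    with pytest.raises(ValueError):
        character_error_rate(["A"], ["A", "C"])


# -- end-to-end --------------------------------------------------------------

@pytest.mark.parametrize("name", ["pure4", "ws6", "iupac15", "ratio21"])
def test_end_to_end_identity_error_free(alphabets, tables, name, rng):
    """encode -> simulate(p=0, uniform) -> decode restores the bytes for
    every standard alphabet.  150x coverage: distinguishing the 3:7 from
    the 7:3 ratio variant needs enough depth even without sequencing
    errors (binomial ambiguity), see the methods note."""
    data = rng.bytes(400)
    frags, man = encode_data(data, demo1_geometry(), tables[name])
    cfg = SimulationConfig(coverage=150, representation="uniform",
                           p_sub=0.0, gc_bounds=None)
    pool = simulate_reads(frags, cfg, alphabets[name], rng)
    out, st = decode_pool(pool, man, table=tables[name], truth_fragments=frags)
    assert out == data and st.success
    assert st.char_error_rate == 0.0


def test_dedup_invariance_at_high_diversity(alphabets, tables, rng):
    """Fragments rich in degenerate positions decode identically with
    duplicate removal on or off at 250x."""
    data = rng.bytes(500)
    frags, man = encode_data(data, demo1_geometry(), tables["iupac15"])
    assert all(sum(not alphabets["iupac15"].by_symbol(s).is_pure
                   for s in f.payload) >= 10 for f in frags)
    cfg = SimulationConfig(coverage=250, p_sub=0.01, gc_bounds=None)
    pool = simulate_reads(frags, cfg, alphabets["iupac15"],
                          np.random.default_rng(5))
    out_on, _ = decode_pool(pool, man, table=tables["iupac15"], dedup=True)
    out_off, _ = decode_pool(pool, man, table=tables["iupac15"], dedup=False)
    assert out_on == out_off == data


def test_error_rate_decreases_with_coverage(alphabets, tables):
    """Mean pre-correction character error rate is non-increasing in
    coverage (Spearman rho < 0) across a 10x..500x sweep."""
    data = np.random.default_rng(0).bytes(854)
    frags, man = encode_data(data, demo1_geometry(), tables["iupac15"])
    coverages = [10, 50, 100, 250, 500]
    means = []
    for ci, cov in enumerate(coverages):
        errs = []
        for rep in range(5):
            cfg = SimulationConfig(coverage=cov, p_sub=0.02)
            pool = simulate_reads(frags, cfg, alphabets["iupac15"],
                                  np.random.default_rng([ci, rep]))
            _, st = decode_pool(pool, man, table=tables["iupac15"],
                                truth_fragments=frags)
            errs.append(st.char_error_rate)
        means.append(np.mean(errs))
    rho, p = stats.spearmanr(coverages, means)
    assert rho < 0 and p < 0.05
    assert means[0] > means[-1]


def test_decode_failure_without_parity(alphabets, tables, rng):
    """A dropped-out fragment with no Reed-Solomon parity is fatal and
    reported as such."""
    data = rng.bytes(400)
    frags, man = encode_data(data, demo1_geometry(), tables["iupac15"])
    cfg = SimulationConfig(coverage=40, representation="uniform",
                           p_sub=0.0, gc_bounds=None)
    pool = simulate_reads(frags[1:], cfg, alphabets["iupac15"], rng)
    out, st = decode_pool(pool, man, table=tables["iupac15"])
    assert out is None and not st.success
    assert "0" in st.failure_reason
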