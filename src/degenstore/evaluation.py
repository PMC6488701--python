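"""Monte Carlo experiment drivers and the cost-projection model.

Three questions: how does the pre-correction character error rate fall
with sequencing coverage for each alphabet; what is the least coverage at
which decoding with Reed-Solomon redundancy is error-free; and how do
per-nucleotide synthesis (writing) and sequencing (reading) prices trade
off against the coverage the statistical decoder needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .alphabet import Alphabet
from .codec import (
    CodonTable,
    FragmentGeometry,
    build_codon_table,
    encode_data,
    sim200_geometry,
)
from .inference import decode_pool
from .redundancy import RedundancyConfig, add_parity
from .synthsim import SimulationConfig, simulate_reads

__all__ = [
    "SweepResult",
    "MinCoverageResult",
    "CostModel",
    "CostReport",
    "run_trial",
    "coverage_sweep",
    "find_min_zero_error_coverage",
    "project_cost",
]


@dataclass
class SweepResult:
    """Per-trial table plus mean +/- sd error rate per coverage."""

    trials: pd.DataFrame
    base_seed: int

    def summary(self) -> pd.DataFrame:
        g = self.trials.groupby("coverage")
        out = g.agg(
            mean_char_error_rate=("char_error_rate", "mean"),
            sd_char_error_rate=("char_error_rate", "std"),
            n_success=("success", "sum"),
            n_trials=("success", "size"),
        ).reset_index()
        return out


@dataclass
class MinCoverageResult:
    coverage: Optional[float]  # smallest sufficient grid coverage, or None
    trials: pd.DataFrame
    max_tested: float


def run_trial(payload_size: int, geometry: FragmentGeometry, alphabet: Alphabet,
              table: CodonTable, coverage: float, seed_seq,
              rs: Optional[RedundancyConfig] = None,
              p_sub: float = 0.02, lognormal_sigma: float = 0.5,
              gc_bounds: Optional[tuple] = (0.40, 0.60),
              dedup: bool = True) -> dict:
    """One end-to-end experiment: random payload -> encode (-> parity) ->
    simulate -> decode; reports pre-RS character error rate and success."""
    rng = np.random.default_rng(seed_seq)
    payload = rng.bytes(payload_size)
    fragments, manifest = encode_data(payload, geometry, table)
    if rs is not None:
        fragments = add_parity(fragments, rs, table, manifest)
    config = SimulationConfig(coverage=coverage, p_sub=p_sub,
                              representation="lognormal" if lognormal_sigma > 0 else "uniform",
                              lognormal_sigma=lognormal_sigma,
                              gc_bounds=gc_bounds)
    pool = simulate_reads(fragments, config, alphabet, rng)
    data, stats = decode_pool(pool, manifest, table=table, dedup=dedup,
                              truth_fragments=fragments)
    return {
        "coverage": coverage,
        "n_fragments": manifest.n_fragments,
        "char_error_rate": stats.char_error_rate,
        "erasures": stats.erasure_count,
        "rs_corrected": stats.rs_corrected_symbols,
        "success": bool(stats.success and data == payload),
        "threshold": stats.threshold.cutoff if stats.threshold else np.nan,
    }


def coverage_sweep(payload_size: int, geometry: FragmentGeometry,
                   alphabet: Alphabet, coverages: Sequence[float],
                   reps: int = 5, base_seed: int = 0,
                   rs: Optional[RedundancyConfig] = None,
                   **trial_kwargs) -> SweepResult:
    """Character error rate vs coverage; deterministic given ``base_seed``."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    table = build_codon_table(alphabet)
    rows = []
    for ci, cov in enumerate(coverages):
        for rep in range(reps):
            seed_seq = np.random.SeedSequence([base_seed, ci, rep])
            row = run_trial(payload_size, geometry, alphabet, table, cov,
                            seed_seq, rs=rs, **trial_kwargs)
            row["rep"] = rep
            rows.append(row)
    return SweepResult(trials=pd.DataFrame(rows), base_seed=base_seed)


def find_min_zero_error_coverage(payload_size: int, alphabet: Alphabet,
                                 rs_fraction: float, coverage_grid: Sequence[float],
                                 geometry: Optional[FragmentGeometry] = None,
                                 reps: int = 1, base_seed: int = 0,
                                 **trial_kwargs) -> MinCoverageResult:
    """Smallest grid coverage at which every repetition decodes the payload
    with zero residual byte errors (grid scanned in ascending order)."""
    grid = sorted(coverage_grid)
    if geometry is None:
        geometry = sim200_geometry()
    table = build_codon_table(alphabet)
    rs = RedundancyConfig(parity_fraction=rs_fraction) if rs_fraction > 0 else None
    rows = []
    answer = None
    for ci, cov in enumerate(grid):
        ok = True
        for rep in range(reps):
            seed_seq = np.random.SeedSequence([base_seed, ci, rep])
            row = run_trial(payload_size, geometry, alphabet, table, cov,
                            seed_seq, rs=rs, **trial_kwargs)
            row["rep"] = rep
            rows.append(row)
            ok = ok and row["success"]
        if ok:
            answer = cov
            break
    return MinCoverageResult(coverage=answer, trials=pd.DataFrame(rows),
                             max_tested=grid[-1] if answer is None else answer)


@dataclass(frozen=True)
class CostModel:
    """Per-nucleotide price model for writing (synthesis) and reading
    (sequencing at a given coverage).

    Defaults: inkjet-style pooled synthesis at ~$0.05 per 100 nt and
    state-of-the-art sequencing at $0.0000012 per 100 nt.
    """

    synthesis_usd_per_nt: float = 0.05 / 100
    sequencing_usd_per_nt: float = 0.0000012 / 100
    coverage: float = 2000.0
    adapter_fraction: float = 40.0 / 200.0
    capacity_bits_per_char: float = 3.0

    def __post_init__(self) -> None:
        if self.synthesis_usd_per_nt < 0 or self.sequencing_usd_per_nt < 0:
            raise ValueError("costs must be >= 0")
        if not 0.0 <= self.adapter_fraction < 1.0:
            raise ValueError("adapter_fraction must be in [0, 1)")
        if self.coverage < 0:
            raise ValueError("coverage must be >= 0")


@dataclass(frozen=True)
class CostReport:
    designed_nt: float
    write_usd: float
    read_usd: float
    read_write_ratio: float


def project_cost(model: CostModel, megabytes: float) -> CostReport:
    """Writing and reading cost of storing ``megabytes`` of data.

    Designed nucleotides = data bits / capacity, inflated by the adapter
    fraction; every designed nucleotide is sequenced ``coverage`` times.
    The read/write ratio equals coverage x (sequencing/synthesis price per
    nt) -- independent of data volume.
    """
    if model.capacity_bits_per_char <= 0:
        raise ValueError("capacity must be > 0")
    bits = megabytes * 8 * 2 ** 20
    nt = (bits / model.capacity_bits_per_char) / (1.0 - model.adapter_fraction)
    write = nt * model.synthesis_usd_per_nt
    read = nt * model.coverage * model.sequencing_usd_per_nt
    ratio = (model.coverage * model.sequencing_usd_per_nt / model.synthesis_usd_per_nt
             if model.synthesis_usd_per_nt > 0 else float("inf"))
    return CostReport(designed_nt=nt, write_usd=write, read_usd=read,
                      read_write_ratio=ratio)
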