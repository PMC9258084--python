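"""End-to-end experiments: single scans, replicate loops, accuracy tables.

One replicate is a full pipeline pass: simulate the F2 population under
the configured map length, attach the phenotype, bulk the phenotypic
tails, add sequencing noise, compute the nine statistics, call each
peak, and measure its distance to the true QTL. The benchmark repeats
this with a freshly seeded generator per replicate (seed = base seed +
replicate index, so results are independent of execution order) and a
random QTL position per replicate, and aggregates per-statistic
distance summaries in kb.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bulks import (BulkCounts, ReadCounts, binomial_noise,
                    empirical_depth_noise, select_bulks)
from .config import SimulationConfig
from .detect import PeakCall, call_peak, distance_to_truth, null_thresholds
from .simcore import (GenotypeMatrix, alleles_at_position, draw_meioses,
                      materialize_haplotypes)
from .stats import StatTrack, compute_all

logger = logging.getLogger(__name__)

__all__ = ["ScanResult", "BenchmarkResult", "scan_once", "run_replicate",
           "run_benchmark", "demo_scan"]


@dataclass
class ScanResult:
    """Everything produced by one pipeline pass."""

    config: SimulationConfig
    qtl_locus: int | None
    counts: BulkCounts
    tracks: dict[str, StatTrack]
    true_frequency_high: np.ndarray
    true_frequency_low: np.ndarray

    @property
    def positions(self) -> np.ndarray:
        return self.counts.positions

    def tracks_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"position": self.positions.astype(np.int64)})
        for name, track in self.tracks.items():
            df[name] = track.values
        return df


@dataclass
class BenchmarkResult:
    """Per-statistic localization-error summaries across replicates."""

    table: pd.DataFrame
    distances: pd.DataFrame        # one row per replicate, one col per stat
    config: SimulationConfig
    n_failed: int = 0
    qtl_loci: np.ndarray = field(default_factory=lambda: np.empty(0, int))


def _resolve_qtl(config: SimulationConfig, rng: np.random.Generator):
    q = config.qtl_locus
    if q == "random":
        return int(rng.integers(0, config.n_loci))
    if q == "none" or q is None:
        return None
    return int(q)


def scan_once(
    config: SimulationConfig,
    rng: np.random.Generator,
    depth_table: np.ndarray | None = None,
    materialize_population: bool = False,
) -> ScanResult:
    """One full simulate -> bulk -> noise -> statistics pass.

    By default only the bulked individuals' haplotypes are expanded over
    all loci (the phenotype needs the QTL locus only), which matches a
    full-population expansion row for row under the same generator.
    """
    positions = config.positions
    n_hap = 2 * config.n_individuals
    starts, hap_index, breaks = draw_meioses(
        n_hap, config.lambda_morgans, config.chrom_length_bp, rng
    )
    qtl = _resolve_qtl(config, rng)

    eps = rng.standard_normal(config.n_individuals)
    if qtl is not None and config.k > 0:
        alleles = alleles_at_position(starts, hap_index, breaks,
                                      positions[qtl])
        phenotype = config.k * (alleles[0::2] + alleles[1::2]) + eps
    else:
        phenotype = eps

    high, low = select_bulks(phenotype, config.bulk_fraction)

    def bulk_counts(bulk) -> tuple[ReadCounts, np.ndarray]:
        rows = np.sort(np.concatenate([2 * bulk, 2 * bulk + 1]))
        haps = materialize_haplotypes(starts, hap_index, breaks, positions,
                                      rows=None if materialize_population
                                      else rows)
        if materialize_population:
            haps = haps[rows]
        freq = haps.mean(axis=0)
        if config.noise == "empirical":
            if depth_table is None:
                raise ValueError("empirical noise mode needs a depth_table")
            gm = GenotypeMatrix(haplotypes=haps, positions=positions)
            # rows already restricted: the bulk is every individual of gm
            counts = empirical_depth_noise(
                gm, np.arange(bulk.size), depth_table, rng
            )
        else:
            counts = binomial_noise(freq, config.depth, rng,
                                    positions=positions)
        return counts, freq

    high_counts, high_freq = bulk_counts(high)
    low_counts, low_freq = bulk_counts(low)
    counts = BulkCounts(positions=positions, high=high_counts,
                        low=low_counts)
    tracks = compute_all(counts, window_bp=config.window_bp,
                         ed_window_snps=config.ed_window_snps)
    return ScanResult(
        config=config, qtl_locus=qtl, counts=counts, tracks=tracks,
        true_frequency_high=high_freq, true_frequency_low=low_freq,
    )


def run_replicate(
    config: SimulationConfig,
    rng: np.random.Generator,
    depth_table: np.ndarray | None = None,
) -> dict[str, tuple[PeakCall, float]]:
    """One pipeline pass; returns per-statistic (peak, distance-kb)."""
    scan = scan_once(config, rng, depth_table=depth_table)
    if scan.qtl_locus is None:
        raise ValueError("run_replicate needs a QTL (qtl_locus != 'none')")
    out = {}
    for name, track in scan.tracks.items():
        peak = call_peak(track)
        out[name] = (peak, distance_to_truth(peak, scan.qtl_locus,
                                             scan.positions))
    return out


def run_benchmark(
    config: SimulationConfig,
    n_replicates: int,
    base_seed: int | None = None,
    depth_table: np.ndarray | None = None,
) -> BenchmarkResult:
    """Replicate loop measuring localization accuracy per statistic.

    Replicate ``i`` uses an independent generator seeded with
    ``base_seed + i``; a failed replicate is logged and re-drawn with
    the next unused seed.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if base_seed is None:
        base_seed = config.seed
    rows, qtls = [], []
    n_failed = 0
    seed_cursor = base_seed
    while len(rows) < n_replicates:
        rng = np.random.default_rng(seed_cursor)
        seed_cursor += 1
        try:
            rep = run_replicate(config, rng, depth_table=depth_table)
        except Exception:                             # pragma: no cover
            n_failed += 1
            logger.exception("replicate with seed %d failed; re-drawing",
                             seed_cursor - 1)
            if n_failed > 10 * n_replicates:
                raise
            continue
        rows.append({name: dist for name, (_, dist) in rep.items()})
    distances = pd.DataFrame(rows)
    table = pd.DataFrame({
        "statistic": distances.columns,
        "lambda_morgans": config.lambda_morgans,
        "k": config.k,
        "noise": config.noise,
        "n_replicates": n_replicates,
        "mean_kb": distances.mean().to_numpy(),
        "median_kb": distances.median().to_numpy(),
        "sd_kb": distances.std(ddof=1).to_numpy(),
        "seed": base_seed,
    })
    return BenchmarkResult(table=table, distances=distances, config=config,
                           n_failed=n_failed)


def demo_scan(
    config: SimulationConfig | None = None,
    seed: int | None = None,
    thresholds_n_sims: int = 0,
    depth_table: np.ndarray | None = None,
):
    """Single scan with the QTL in the middle of the chromosome.

    Emits the data behind the classic BSA-Seq figure: per-bulk true
    allele frequencies, the nine statistic tracks, the true QTL marker
    and (with ``thresholds_n_sims > 0``) per-statistic null thresholds.
    """
    if config is None:
        config = SimulationConfig()
    config = config.replace(qtl_locus=config.n_loci // 2)
    if seed is None:
        seed = config.seed
    scan = scan_once(config, np.random.default_rng(seed),
                     depth_table=depth_table)
    thresholds = None
    if thresholds_n_sims > 0:
        null_cfg = config.replace(k=0.0, qtl_locus="none")
        thresholds = null_thresholds(null_cfg, thresholds_n_sims,
                                     base_seed=seed + 1,
                                     depth_table=depth_table)
    return scan, thresholds
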