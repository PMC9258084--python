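"""QTL peak calling, localization error, and null significance thresholds.

The QTL call for a statistic track is the locus maximising its decision
function -- the magnitude for the signed allele-frequency-difference
tracks, the value itself for the non-negative statistics. Significance
thresholds come from simulation under the null (no QTL effect): per
replicate the 95% quantile of the decision function across loci, then
the mean of those quantiles across replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import SimulationConfig
from .stats import SIGNED_STATS, StatTrack

__all__ = ["PeakCall", "NullThresholds", "decision_values", "call_peak",
           "distance_to_truth", "null_thresholds"]


@dataclass
class PeakCall:
    """The called QTL peak of one statistic track."""

    statistic: str
    locus: int
    position_bp: float
    value: float


@dataclass
class NullThresholds:
    """Per-statistic significance thresholds from null simulations."""

    thresholds: dict[str, float]
    n_simulations: int
    quantile: float = 0.95
    seed: int | None = None
    pooled: bool = False
    se: dict[str, float] = field(default_factory=dict)


def decision_values(track: StatTrack) -> np.ndarray:
    """Peak-calling decision function: |value| if signed, else value."""
    return np.abs(track.values) if track.name in SIGNED_STATS else track.values


def call_peak(track: StatTrack) -> PeakCall:
    """Locus of the maximum decision value; ties go to the lowest index."""
    decision = decision_values(track)
    if not np.isfinite(decision).any():
        raise ValueError(f"track {track.name!r} has no defined values")
    locus = int(np.nanargmax(decision))
    return PeakCall(
        statistic=track.name,
        locus=locus,
        position_bp=float(track.positions[locus]),
        value=float(track.values[locus]),
    )


def distance_to_truth(peak: PeakCall, true_locus: int,
                      positions: np.ndarray) -> float:
    """Absolute distance between called and true QTL positions, in kb."""
    return abs(peak.position_bp - float(positions[true_locus])) / 1000.0


def null_thresholds(
    config: SimulationConfig,
    n_sims: int,
    base_seed: int | None = None,
    quantile: float = 0.95,
    pooled: bool = False,
    depth_table: np.ndarray | None = None,
) -> NullThresholds:
    """Simulation-based significance thresholds under the null.

    ``config`` must describe a null trait (``k = 0`` or no QTL). Each of
    the ``n_sims`` replicates runs the full pipeline and records, per
    statistic, the ``quantile`` of the decision function across loci
    (linear-interpolation quantile definition); the threshold is the
    mean of those per-replicate quantiles. ``pooled=True`` instead takes
    one quantile of all replicate-by-locus values pooled together.
    Replicate ``i`` is seeded with ``base_seed + i``.
    """
    from .bench import scan_once  # local import: bench builds on detect

    if config.k != 0 and config.qtl_locus not in ("none", None):
        raise ValueError("null_thresholds requires k = 0 or qtl_locus='none'")
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if base_seed is None:
        base_seed = config.seed
    per_rep: dict[str, list] = {}
    for i in range(n_sims):
        rng = np.random.default_rng(base_seed + i)
        scan = scan_once(config, rng, depth_table=depth_table)
        for name, track in scan.tracks.items():
            d = decision_values(track)
            per_rep.setdefault(name, []).append(
                d if pooled else np.nanquantile(d, quantile)
            )
    if pooled:
        thresholds = {
            name: float(np.nanquantile(np.concatenate(v), quantile))
            for name, v in per_rep.items()
        }
        se = {}
    else:
        thresholds = {
            name: float(np.mean(v)) for name, v in per_rep.items()
        }
        se = {
            name: float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1
            else float("nan")
            for name, v in per_rep.items()
        }
    return NullThresholds(
        thresholds=thresholds, n_simulations=n_sims, quantile=quantile,
        seed=base_seed, pooled=pooled, se=se,
    )
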