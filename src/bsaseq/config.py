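"""Simulation configuration.

A single validated record holds every knob of the BSA-Seq forward
simulation and of the downstream statistics: population and chromosome
layout, genetic map length, QTL effect, bulk construction, sequencing
noise, and smoothing windows.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np

QtlLocus = Union[int, str, None]

#: Chromosome map lengths (Morgans) of the three crop case studies.
CASE_STUDY_LAMBDAS = {"pearl_millet": 0.90, "rice": 1.30, "foxtail_millet": 2.15}


@dataclass(frozen=True)
class SimulationConfig:
    """All parameters of one simulated BSA-Seq experiment.

    Parameters
    ----------
    n_individuals : diploid F2 population size.
    n_loci : evenly spaced marker loci on the single model chromosome.
    chrom_length_bp : physical chromosome length.
    lambda_morgans : genetic map length of the chromosome (expected
        crossovers per gamete per meiosis).
    k : additive QTL effect in residual phenotypic standard deviations
        (0 gives a null trait).
    qtl_locus : locus index of the QTL, ``"random"``, or ``"none"``.
    bulk_fraction : fraction of the population bulked in *each* tail.
    depth : binomial trial count of the sequencing-noise model, i.e. the
        maximum read depth per allele per bulk per locus.
    noise : ``"binomial"`` (self-contained) or ``"empirical"`` (per-sample
        read depths resampled from a VCF-derived table).
    window_bp : tricube kernel bandwidth (half-width of the smoothing
        window, and block size of the block-regression smoother).
    ed_window_snps : length in SNPs of the fixed Euclidean-distance window.
    seed : base RNG seed; replicate ``i`` uses ``seed + i``.
    """

    n_individuals: int = 500
    n_loci: int = 10_000
    chrom_length_bp: int = 100_000_000
    lambda_morgans: float = 0.90
    k: float = 1.0
    qtl_locus: QtlLocus = "random"
    bulk_fraction: float = 0.10
    depth: int = 100
    noise: str = "binomial"
    window_bp: float = 3_000_000.0
    ed_window_snps: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ValueError("n_individuals must be >= 2")
        if self.n_loci < 2:
            raise ValueError("n_loci must be >= 2")
        if self.chrom_length_bp <= 0:
            raise ValueError("chrom_length_bp must be positive")
        if self.lambda_morgans <= 0:
            raise ValueError("lambda_morgans must be positive")
        if self.k < 0:
            raise ValueError("k must be >= 0")
        if not 0.0 < self.bulk_fraction <= 0.5:
            raise ValueError("bulk_fraction must be in (0, 0.5]")
        if self.bulk_size < 1:
            raise ValueError(
                "round(n_individuals * bulk_fraction) must be >= 1"
            )
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.noise not in ("binomial", "empirical"):
            raise ValueError("noise must be 'binomial' or 'empirical'")
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")
        if not 1 <= self.ed_window_snps <= self.n_loci:
            raise ValueError("ed_window_snps must be in [1, n_loci]")
        q = self.qtl_locus
        if isinstance(q, str):
            if q not in ("random", "none"):
                raise ValueError("qtl_locus must be an index, 'random' or 'none'")
        elif q is not None and not 0 <= int(q) < self.n_loci:
            raise ValueError(f"qtl_locus {q} out of range [0, {self.n_loci})")

    @property
    def bulk_size(self) -> int:
        """Number of individuals per phenotypic-tail bulk."""
        return int(round(self.n_individuals * self.bulk_fraction))

    @property
    def locus_spacing_bp(self) -> float:
        return self.chrom_length_bp / self.n_loci

    @property
    def positions(self) -> np.ndarray:
        """bp coordinate of each locus: position(i) = (i+1) * spacing.

        Strictly increasing, all within (0, chrom_length_bp].
        """
        return np.arange(1, self.n_loci + 1) * self.locus_spacing_bp

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    # -- flat key = value config files ------------------------------------

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "SimulationConfig":
        """Read a flat ``key = value`` file; keyword overrides win."""
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        values: dict = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in fields:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            values[key] = _parse_value(key, val)
        values.update(overrides)
        return cls(**values)

    def to_file(self, path: str | Path) -> None:
        lines = [
            f"{f.name} = {getattr(self, f.name)}"
            for f in dataclasses.fields(self)
        ]
        Path(path).write_text("\n".join(lines) + "\n")


def _parse_value(key: str, val: str):
    if key in ("qtl_locus",):
        if val.lower() in ("random", "none"):
            return val.lower()
        return int(val)
    if key in ("noise",):
        return val
    if key in (
        "n_individuals", "n_loci", "chrom_length_bp", "depth",
        "ed_window_snps", "seed",
    ):
        return int(val)
    return float(val)
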