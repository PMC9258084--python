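"""Forward simulation of F2 haplotypes and a single-QTL phenotype.

An F2 individual carries two gametic haplotypes, each a mosaic of the two
parental chromosomes. Crossovers follow the Haldane model: no
interference, so the crossover count per gamete is Poisson with mean
equal to the chromosome map length (lambda, in Morgans) and crossover
positions are independent and uniform along the physical chromosome
(genetic and physical distance proportional). Parental alleles are coded
0 (reference parent) and 1 (alternate parent).

The phenotype is standard-normal environmental noise plus an additive
QTL effect: each alternate-allele copy at the QTL adds ``k`` residual
standard deviations by default (see :func:`simulate_phenotype`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import SimulationConfig

__all__ = [
    "GenotypeMatrix",
    "haplotype_from_breakpoints",
    "simulate_haplotype",
    "simulate_population",
    "explained_variance",
    "simulate_phenotype",
]


@dataclass
class GenotypeMatrix:
    """Paired binary haplotypes of a diploid population.

    ``haplotypes`` has shape ``(2 * n_individuals, n_loci)`` with entries
    in {0, 1}; individual ``i`` owns rows ``2i`` and ``2i + 1``.
    """

    haplotypes: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[0] % 2:
            raise ValueError("haplotypes must be a (2n, n_loci) array")
        if self.haplotypes.shape[1] != self.positions.size:
            raise ValueError("positions length must match locus count")

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0] // 2

    @property
    def n_loci(self) -> int:
        return self.haplotypes.shape[1]

    def dosages(self, locus: int | None = None) -> np.ndarray:
        """Alternate-allele dosage (0/1/2) per individual.

        With ``locus`` given, a length-``n_individuals`` vector; otherwise
        the full ``(n_individuals, n_loci)`` matrix.
        """
        h = self.haplotypes if locus is None else self.haplotypes[:, locus]
        return (h[0::2] + h[1::2]).astype(np.int8)

    def allele_frequencies(self) -> np.ndarray:
        """Alternate-allele frequency per locus over all chromosomes."""
        return self.haplotypes.mean(axis=0)

    def to_tsv(self, path) -> None:
        """One row per haplotype, one 0/1 column per locus."""
        np.savetxt(path, self.haplotypes, fmt="%d", delimiter="\t")


def haplotype_from_breakpoints(
    start_origin: int,
    breakpoints_bp: np.ndarray,
    positions: np.ndarray,
) -> np.ndarray:
    """Build a gametic haplotype from explicit crossover positions.

    The parental origin starts at ``start_origin`` (0 or 1) and flips at
    every breakpoint; a locus at position ``p`` is affected by all
    breakpoints at or below ``p``.
    """
    breakpoints_bp = np.asarray(breakpoints_bp, dtype=float)
    flips = np.searchsorted(breakpoints_bp[np.argsort(breakpoints_bp)], positions,
                            side="right")
    return ((start_origin + flips) % 2).astype(np.int8)


def simulate_haplotype(
    lambda_morgans: float,
    n_loci: int,
    rng: np.random.Generator,
    chrom_length_bp: float = 100_000_000,
) -> np.ndarray:
    """Simulate one gametic haplotype under the Haldane model.

    Crossover count ~ Poisson(lambda); positions uniform on the
    chromosome; starting parental origin Bernoulli(1/2).
    """
    if lambda_morgans <= 0:
        raise ValueError("lambda_morgans must be positive")
    positions = np.arange(1, n_loci + 1) * (chrom_length_bp / n_loci)
    c = rng.poisson(lambda_morgans)
    start = int(rng.integers(0, 2))
    breaks = rng.uniform(0.0, chrom_length_bp, c)
    return haplotype_from_breakpoints(start, breaks, positions)


# -- vectorised meiosis machinery -----------------------------------------
#
# Drawing all gametes of a population at once keeps the replicate loop of
# the benchmark fast: crossover counts, starting origins and breakpoint
# positions are drawn in three vectorised calls, and haplotypes are only
# materialised (mosaic expansion over all loci) for the rows that are
# actually needed -- the full population, or just the bulked individuals.


def draw_meioses(n_haplotypes: int, lambda_morgans: float,
                 chrom_length_bp: float, rng: np.random.Generator):
    """Draw the meiotic randomness for ``n_haplotypes`` gametes.

    Returns ``(starts, hap_index, breakpoints_bp)`` where the latter two
    are parallel arrays listing every crossover and its haplotype.
    """
    counts = rng.poisson(lambda_morgans, n_haplotypes)
    starts = rng.integers(0, 2, n_haplotypes).astype(np.int8)
    breakpoints = rng.uniform(0.0, chrom_length_bp, int(counts.sum()))
    hap_index = np.repeat(np.arange(n_haplotypes), counts)
    return starts, hap_index, breakpoints


def alleles_at_position(starts, hap_index, breakpoints_bp,
                        position_bp: float) -> np.ndarray:
    """Allele carried by every haplotype at one physical position."""
    flips = np.zeros(starts.size, dtype=np.int64)
    np.add.at(flips, hap_index[breakpoints_bp <= position_bp], 1)
    return ((starts + flips) % 2).astype(np.int8)


def materialize_haplotypes(starts, hap_index, breakpoints_bp, positions,
                           rows: np.ndarray | None = None) -> np.ndarray:
    """Expand breakpoint mosaics into a 0/1 matrix over all loci.

    ``rows`` restricts the expansion to a subset of haplotypes (order
    preserved); the result always matches a full expansion row-for-row.
    """
    locus_idx = np.searchsorted(positions, breakpoints_bp, side="left")
    if rows is not None:
        rows = np.asarray(rows)
        keep = np.isin(hap_index, rows)
        remap = np.full(starts.size, -1)
        remap[rows] = np.arange(rows.size)
        hap_index = remap[hap_index[keep]]
        locus_idx = locus_idx[keep]
        starts = starts[rows]
    # breakpoints beyond the last locus position cannot occur: positions
    # end at chrom_length_bp and breakpoints are drawn below it
    flips = np.zeros((starts.size, positions.size), dtype=np.int8)
    np.add.at(flips, (hap_index, locus_idx), 1)
    np.cumsum(flips, axis=1, out=flips)
    return (starts[:, None] + flips) % 2


def simulate_population(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> GenotypeMatrix:
    """Simulate ``2 * n_individuals`` independent gametic haplotypes."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    positions = config.positions
    starts, hap_index, breaks = draw_meioses(
        2 * config.n_individuals, config.lambda_morgans,
        config.chrom_length_bp, rng,
    )
    haps = materialize_haplotypes(starts, hap_index, breaks, positions)
    return GenotypeMatrix(haplotypes=haps, positions=positions)


def explained_variance(p: float, k: float, n: int) -> float:
    """Fraction of phenotypic variance explained by the QTL.

    ``pi = p(1-p)k^2 / (p(1-p)k^2 + 1 - 1/n)`` with ``p`` the QTL allele
    frequency (0.5 in an F2), ``k`` the effect in residual standard
    deviations and ``n`` the population size.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must be in (0, 1)")
    if n < 2:
        raise ValueError("n must be >= 2")
    if k < 0:
        raise ValueError("k must be >= 0")
    v = p * (1.0 - p) * k * k
    return v / (v + 1.0 - 1.0 / n)


def simulate_phenotype(
    genotypes: GenotypeMatrix,
    qtl_locus: int | None,
    k: float,
    rng: np.random.Generator,
    per_allele_effect: float | None = None,
) -> np.ndarray:
    """Standard-normal phenotype plus an additive QTL effect.

    value_i = a * g_i + eps_i, with g_i the alternate-allele dosage at
    the QTL and eps_i ~ N(0, 1). The per-allele-copy effect ``a``
    defaults to ``k`` (homozygotes differ by 2k residual SD); pass
    ``per_allele_effect=k / sqrt(2)`` for the calibration under which the
    realized QTL variance equals p(1-p)k^2 of
    :func:`explained_variance`.
    """
    eps = rng.standard_normal(genotypes.n_individuals)
    if qtl_locus is None or k == 0:
        return eps
    if not 0 <= qtl_locus < genotypes.n_loci:
        raise IndexError(f"qtl_locus {qtl_locus} out of range")
    a = k if per_allele_effect is None else per_allele_effect
    return a * genotypes.dosages(qtl_locus) + eps
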