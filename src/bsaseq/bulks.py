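"""Phenotypic-tail bulks and noisy sequencing read counts.

Bulking pools the DNA of the individuals in each phenotype tail; what a
sequencer reports per marker is a pair of allele read counts per bulk.
Two noise models convert true bulk allele frequencies into counts:

``binomial``
    One binomial draw per parental allele per bulk:
    ``alt ~ B(depth, P)`` and ``ref ~ B(depth, 1 - P)`` independently,
    ``depth`` being the maximum read depth per allele (default 100).
    The per-locus total therefore fluctuates around ``depth``. The
    fixed-total variant (``ref = depth - alt``) is available via
    ``per_allele=False``.

``empirical``
    Per-locus read depths are resampled from a table of real per-sample
    depths (harvested from a VCF); every bulked chromosome is assigned a
    real depth and contributes that many reads of its own parental
    allele.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .simcore import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ReadCounts",
    "BulkCounts",
    "select_bulks",
    "true_bulk_frequency",
    "binomial_noise",
    "empirical_depth_noise",
    "read_depth_table",
    "synthetic_depth_table",
    "write_synthetic_depth_vcf",
]


@dataclass
class ReadCounts:
    """Per-locus alternate/reference read counts for one bulk."""

    positions: np.ndarray
    alt: np.ndarray
    ref: np.ndarray

    def __post_init__(self) -> None:
        self.alt = np.asarray(self.alt, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=np.int64)
        if (self.alt < 0).any() or (self.ref < 0).any():
            raise ValueError("read counts must be non-negative")

    @property
    def depth(self) -> np.ndarray:
        return self.alt + self.ref

    def frequency(self) -> np.ndarray:
        """Alternate-allele frequency; NaN at zero-depth loci."""
        with np.errstate(invalid="ignore"):
            return np.where(self.depth > 0, self.alt / self.depth, np.nan)


@dataclass
class BulkCounts:
    """Read counts of the high- and low-phenotype bulks."""

    positions: np.ndarray
    high: ReadCounts
    low: ReadCounts

    @property
    def n_loci(self) -> int:
        return self.positions.size

    def to_tsv(self, path) -> None:
        pd.DataFrame({
            "position": self.positions.astype(np.int64),
            "alt_high": self.high.alt,
            "ref_high": self.high.ref,
            "alt_low": self.low.alt,
            "ref_low": self.low.ref,
        }).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "BulkCounts":
        df = pd.read_csv(path, sep="\t")
        pos = df["position"].to_numpy(dtype=float)
        return cls(
            positions=pos,
            high=ReadCounts(pos, df["alt_high"].to_numpy(),
                            df["ref_high"].to_numpy()),
            low=ReadCounts(pos, df["alt_low"].to_numpy(),
                           df["ref_low"].to_numpy()),
        )


def select_bulks(phenotype: np.ndarray, bulk_fraction: float):
    """Indices of the top and bottom phenotypic tails.

    Returns ``(high, low)``, each ``round(n * bulk_fraction)`` individual
    indices; ties are broken towards the lower index. Bulk membership
    depends on the phenotype only.
    """
    phenotype = np.asarray(phenotype, dtype=float)
    if phenotype.size == 0:
        raise ValueError("phenotype is empty")
    n = phenotype.size
    size = int(round(n * bulk_fraction))
    if not 1 <= size <= n // 2:
        raise ValueError(
            f"bulk size {size} invalid for population of {n}"
        )
    order = np.argsort(phenotype, kind="stable")
    low = np.sort(order[:size])
    high = np.sort(np.argsort(-phenotype, kind="stable")[:size])
    return high, low


def true_bulk_frequency(
    genotypes: GenotypeMatrix, bulk: np.ndarray
) -> np.ndarray:
    """Noise-free alternate-allele frequency of a bulk at every locus.

    The bulk of ``m`` individuals contributes ``2m`` chromosomes.
    """
    bulk = np.asarray(bulk)
    if bulk.size == 0:
        raise ValueError("bulk is empty")
    rows = np.sort(np.concatenate([2 * bulk, 2 * bulk + 1]))
    return genotypes.haplotypes[rows].mean(axis=0)


def binomial_noise(
    frequency: np.ndarray,
    depth: int,
    rng: np.random.Generator,
    positions: np.ndarray | None = None,
    per_allele: bool = True,
) -> ReadCounts:
    """Binomial sequencing noise on a per-locus frequency track.

    Default (``per_allele=True``): independent draws
    ``alt ~ B(depth, P)``, ``ref ~ B(depth, 1 - P)``. With
    ``per_allele=False``: single draw ``alt ~ B(depth, P)`` and
    ``ref = depth - alt`` (fixed per-locus total).
    """
    frequency = np.asarray(frequency, dtype=float)
    if ((frequency < 0) | (frequency > 1)).any():
        raise ValueError("frequencies must lie in [0, 1]")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if positions is None:
        positions = np.arange(frequency.size, dtype=float)
    alt = rng.binomial(depth, frequency)
    if per_allele:
        ref = rng.binomial(depth, 1.0 - frequency)
    else:
        ref = depth - alt
    return ReadCounts(positions=positions, alt=alt, ref=ref)


def empirical_depth_noise(
    genotypes: GenotypeMatrix,
    bulk: np.ndarray,
    depth_table: np.ndarray,
    rng: np.random.Generator,
) -> ReadCounts:
    """Sequencing noise driven by real per-sample read depths.

    For every locus a row of ``depth_table`` (per-SNP, per-sample depths
    from a real resequencing panel) is drawn at random; each of the
    ``2m`` bulked chromosomes is assigned one per-sample depth from that
    row (with replacement) and contributes that many reads carrying its
    own parental allele. Zero-depth loci yield ``alt = ref = 0`` and are
    reported as NaN by downstream statistics.
    """
    depth_table = np.atleast_2d(np.asarray(depth_table, dtype=np.int64))
    if (depth_table < 0).any():
        raise ValueError("depth table entries must be non-negative")
    bulk = np.asarray(bulk)
    if bulk.size == 0:
        raise ValueError("bulk is empty")
    n_loci = genotypes.n_loci
    if depth_table.shape[0] < n_loci:
        logger.warning(
            "depth table has %d rows < %d loci; sampling with replacement",
            depth_table.shape[0], n_loci,
        )
    rows = np.sort(np.concatenate([2 * bulk, 2 * bulk + 1]))
    alleles = genotypes.haplotypes[rows]          # (2m, n_loci)
    snp_rows = rng.integers(0, depth_table.shape[0], n_loci)
    sample_idx = rng.integers(0, depth_table.shape[1], (rows.size, n_loci))
    depths = depth_table[snp_rows[None, :], sample_idx]  # (2m, n_loci)
    alt = (depths * alleles).sum(axis=0)
    ref = (depths * (1 - alleles)).sum(axis=0)
    return ReadCounts(positions=genotypes.positions, alt=alt, ref=ref)


# -- real-depth tables -----------------------------------------------------


def read_depth_table(
    vcf_path: str | Path,
    n_snps: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Harvest per-SNP, per-sample read depths from a VCF.

    Uses the FORMAT ``DP`` field, falling back to summed ``AD``. With
    ``n_snps`` given, rows are subsampled uniformly without replacement
    when enough usable records exist, with replacement otherwise.
    """
    from cyvcf2 import VCF

    rows = []
    vcf = VCF(str(vcf_path))
    if not vcf.samples:
        raise ValueError(f"{vcf_path}: no samples in VCF")
    for variant in vcf:
        dp = variant.format("DP")
        if dp is not None:
            row = dp.astype(np.int64).reshape(-1)
        else:
            ad = variant.format("AD")
            if ad is None:
                raise ValueError(
                    f"{vcf_path}: records carry neither DP nor AD "
                    "FORMAT fields"
                )
            row = np.clip(ad, 0, None).astype(np.int64).sum(axis=1)
        rows.append(np.clip(row, 0, None))
    if not rows:
        raise ValueError(f"{vcf_path}: no variant records")
    table = np.vstack(rows)
    if n_snps is not None:
        rng = np.random.default_rng() if rng is None else rng
        if table.shape[0] >= n_snps:
            idx = rng.choice(table.shape[0], n_snps, replace=False)
        else:
            warnings.warn(
                f"VCF has {table.shape[0]} usable records < {n_snps}; "
                "sampling with replacement"
            )
            idx = rng.choice(table.shape[0], n_snps, replace=True)
        table = table[idx]
    return table


def synthetic_depth_table(
    n_snps: int,
    n_samples: int,
    rng: np.random.Generator,
    mean_depth: float = 30.0,
    dispersion: float = 3.0,
) -> np.ndarray:
    """Synthetic stand-in for a real per-sample depth table.

    Negative-binomial depths (mean ``mean_depth``, shape ``dispersion``)
    mimic the overdispersed coverage of a resequencing panel; used by the
    test fixtures so no external VCF download is needed.
    """
    p = dispersion / (dispersion + mean_depth)
    return rng.negative_binomial(dispersion, p, (n_snps, n_samples))


def write_synthetic_depth_vcf(
    path: str | Path,
    n_snps: int,
    n_samples: int,
    rng: np.random.Generator,
    mean_depth: float = 30.0,
) -> None:
    """Write a minimal synthetic VCF carrying per-sample DP fields."""
    depths = synthetic_depth_table(n_snps, n_samples, rng, mean_depth)
    samples = [f"S{i:03d}" for i in range(n_samples)]
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        "##contig=<ID=1,length=100000000>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples),
    ]
    for i in range(n_snps):
        calls = "\t".join(f"0/1:{d}" for d in depths[i])
        lines.append(f"1\t{10_000 * (i + 1)}\t.\tA\tT\t.\tPASS\t.\tGT:DP\t{calls}")
    Path(path).write_text("\n".join(lines) + "\n")
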