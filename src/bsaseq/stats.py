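"""The nine BSA-Seq statistics.

Four per-SNP measures of allele-frequency divergence between the bulks:

* ``dsnp`` -- delta-SNP index, alt-allele frequency (high) minus (low);
* ``g`` -- the 2x2 G-test (likelihood-ratio) statistic on alt/ref counts;
* ``edm`` -- Euclidean distance between the (alt, ref) frequency vectors;
* ``lod`` -- log10 likelihood ratio of per-bulk vs pooled binomial
  allele-frequency models.

Five smoothed tracks derived from them:

* ``tdsnp``, ``gprime``, ``smlod`` -- Nadaraya-Watson tricube-kernel
  weighted means of dsnp / g / lod within a physical bandwidth window;
* ``afdexp`` -- dsnp averaged in consecutive physical blocks and passed
  through a locally weighted (loess-type) regression of the block means;
* ``ed100_4`` -- fourth power of the edm sum over a fixed window of
  consecutive SNPs (100 by default).

Undefined values (zero-depth loci) are NaN and carry zero weight in all
smoothers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import xlogy
from statsmodels.nonparametric.smoothers_lowess import lowess

from .bulks import BulkCounts

__all__ = [
    "StatTrack", "STAT_NAMES", "SIGNED_STATS",
    "delta_snp", "g_statistic", "euclidean_distance", "lod_statistic",
    "tricube_smooth", "loess_block_smooth", "ed_power_smooth",
    "compute_all",
]

STAT_NAMES = (
    "dsnp", "tdsnp", "afdexp", "g", "gprime",
    "edm", "ed100_4", "lod", "smlod",
)
#: Tracks that can take either sign; peak calling uses their magnitude.
SIGNED_STATS = frozenset({"dsnp", "tdsnp", "afdexp"})

LN10 = np.log(10.0)


@dataclass
class StatTrack:
    """A named per-locus vector of statistic values (NaN = undefined)."""

    name: str
    positions: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.name not in STAT_NAMES:
            raise ValueError(f"unknown statistic {self.name!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != np.shape(self.positions):
            raise ValueError("values and positions must have equal length")


def _frequencies(counts: BulkCounts):
    return counts.high.frequency(), counts.low.frequency()


def delta_snp(counts: BulkCounts) -> StatTrack:
    """Delta-SNP index: alt frequency in high bulk minus low bulk."""
    fh, fl = _frequencies(counts)
    return StatTrack("dsnp", counts.positions, fh - fl)


def g_statistic(counts: BulkCounts) -> StatTrack:
    """G-test statistic of the 2x2 alt/ref x high/low count table.

    G = 2 sum o ln(o/e) over the four cells, with expected counts from
    the table marginals and the 0 ln 0 = 0 convention. Zero grand total
    gives NaN.
    """
    ah, rh = counts.high.alt, counts.high.ref
    al, rl = counts.low.alt, counts.low.ref
    dh, dl = ah + rh, al + rl
    total = dh + dl
    alt_tot = ah + al
    with np.errstate(invalid="ignore", divide="ignore"):
        e = np.array([
            alt_tot * dh, (total - alt_tot) * dh,
            alt_tot * dl, (total - alt_tot) * dl,
        ]) / total
        o = np.array([ah, rh, al, rl])
        g = 2.0 * (xlogy(o, o) - xlogy(o, e)).sum(axis=0)
    g = np.where(total > 0, g, np.nan)
    # guard tiny negative round-off at near-independent tables
    return StatTrack("g", counts.positions, np.clip(g, 0.0, None))


def euclidean_distance(counts: BulkCounts) -> StatTrack:
    """Euclidean distance between the bulks' (alt, ref) frequency vectors.

    ED = sqrt((fa_H - fa_L)^2 + (fr_H - fr_L)^2); since fr = 1 - fa per
    bulk this equals sqrt(2) |dsnp| exactly.
    """
    fh, fl = _frequencies(counts)
    ed = np.sqrt((fh - fl) ** 2 + ((1.0 - fh) - (1.0 - fl)) ** 2)
    return StatTrack("edm", counts.positions, ed)


def lod_statistic(counts: BulkCounts, null_p: float | None = None) -> StatTrack:
    """Binomial likelihood-ratio LOD between bulk allele frequencies.

    LOD = log10 [ L(p_H; high) L(p_L; low) / L(p_0; high) L(p_0; low) ]
    with per-bulk MLEs p_H, p_L and, by default, the pooled MLE p_0
    (identically G / (2 ln 10)). ``null_p`` fixes the null frequency
    instead (e.g. 0.5 to test both bulks against Mendelian expectation).
    """
    ah, al = counts.high.alt, counts.low.alt
    dh, dl = counts.high.depth, counts.low.depth

    def ll(a, d, p):
        with np.errstate(invalid="ignore", divide="ignore"):
            return xlogy(a, p) + xlogy(d - a, 1.0 - p)

    with np.errstate(invalid="ignore", divide="ignore"):
        ph = np.where(dh > 0, ah / np.where(dh > 0, dh, 1), np.nan)
        pl = np.where(dl > 0, al / np.where(dl > 0, dl, 1), np.nan)
        p0 = (
            np.full_like(ph, null_p) if null_p is not None
            else (ah + al) / np.where(dh + dl > 0, dh + dl, 1)
        )
    lod = (ll(ah, dh, ph) + ll(al, dl, pl)
           - ll(ah, dh, p0) - ll(al, dl, p0)) / LN10
    lod = np.where((dh > 0) & (dl > 0), lod, np.nan)
    return StatTrack("lod", counts.positions, np.clip(lod, 0.0, None))


# -- smoothers -------------------------------------------------------------


def _tricube_weights(distance: np.ndarray, h: float) -> np.ndarray:
    return np.clip(1.0 - (np.abs(distance) / h) ** 3, 0.0, None) ** 3


_SMOOTH_NAME = {"dsnp": "tdsnp", "g": "gprime", "lod": "smlod"}


def tricube_smooth(track: StatTrack, window_bp: float,
                   name: str | None = None) -> StatTrack:
    """Nadaraya-Watson tricube smoothing within a physical bandwidth.

    At focal position x the value is the tricube-weighted mean of the
    raw statistic over loci with |pos - x| <= h, where the half-width h
    equals ``window_bp`` (the bandwidth convention of the locfit kernel
    smoother behind QTLseqr's windowed G'). NaN inputs carry zero
    weight; a window with no defined value yields NaN.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    h = float(window_bp)
    positions = np.asarray(track.positions, dtype=float)
    values = track.values
    defined = np.isfinite(values)
    filled = np.where(defined, values, 0.0)
    spacing = np.diff(positions)
    if positions.size > 1 and np.allclose(spacing, spacing[0]):
        # evenly spaced loci: the kernel is shift-invariant -> convolution
        d = spacing[0]
        m = int(h // d)
        kernel = _tricube_weights(np.arange(-m, m + 1) * d, h)
        # centred slice of the full convolution ('same' misbehaves when
        # the kernel is longer than the track)
        n = filled.size
        num = np.convolve(filled, kernel, mode="full")[m:m + n]
        den = np.convolve(defined.astype(float), kernel, mode="full")[m:m + n]
    else:
        num = np.empty_like(filled)
        den = np.empty_like(filled)
        lo = np.searchsorted(positions, positions - h, side="left")
        hi = np.searchsorted(positions, positions + h, side="right")
        for i in range(positions.size):
            sl = slice(lo[i], hi[i])
            w = _tricube_weights(positions[sl] - positions[i], h)
            w = w * defined[sl]
            num[i] = (w * filled[sl]).sum()
            den[i] = w.sum()
    with np.errstate(invalid="ignore"):
        smoothed = np.where(den > 0, num / np.where(den > 0, den, 1), np.nan)
    if name is None:
        name = _SMOOTH_NAME.get(track.name, track.name)
    return StatTrack(name, track.positions, smoothed)


def loess_block_smooth(track: StatTrack, window_bp: float,
                       span: float | None = None) -> StatTrack:
    """Block-regression smoothing of the delta-SNP track (AFDexp).

    The chromosome is cut into consecutive ``window_bp`` blocks treated
    as genetic units; each non-empty block contributes its mean dsnp at
    its mean locus position; a locally weighted linear regression
    (lowess) of block means on block positions is evaluated at the block
    positions and linearly interpolated to every locus. ``span``
    defaults to 3 / n_blocks, the smallest span keeping the local linear
    fit overdetermined.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    positions = np.asarray(track.positions, dtype=float)
    values = track.values
    block = np.floor((positions - positions.min()) / window_bp).astype(int)
    mids, means = [], []
    for b in np.unique(block):
        sel = (block == b) & np.isfinite(values)
        if sel.any():
            mids.append(positions[sel].mean())
            means.append(values[sel].mean())
    if len(mids) < 2:
        raise ValueError("need at least 2 non-empty blocks")
    mids, means = np.asarray(mids), np.asarray(means)
    frac = min(1.0, 3.0 / mids.size) if span is None else span
    fitted = lowess(means, mids, frac=frac, it=0, return_sorted=False)
    smoothed = np.interp(positions, mids, fitted)
    return StatTrack("afdexp", track.positions, smoothed)


def ed_power_smooth(track: StatTrack, ed_window_snps: int = 100) -> StatTrack:
    """Fourth power of the Euclidean-distance sum over a fixed SNP window.

    value(i) = (sum of ED over the ``ed_window_snps``-SNP window centred
    on i)^4; for window length w the window spans w//2 SNPs left and
    w - w//2 - 1 right of the focal SNP. Edge windows are truncated (no
    renormalisation); NaN EDs contribute zero.
    """
    values = track.values
    n = values.size
    w = int(ed_window_snps)
    if not 1 <= w <= n:
        raise ValueError("ed_window_snps must be in [1, n_loci]")
    filled = np.where(np.isfinite(values), values, 0.0)
    right = w - w // 2 - 1
    sums = np.convolve(filled, np.ones(w), mode="full")[right:right + n]
    return StatTrack("ed100_4", track.positions, sums ** 4)


def compute_all(
    counts: BulkCounts,
    window_bp: float = 3_000_000.0,
    ed_window_snps: int = 100,
    lod_null_p: float | None = None,
) -> dict[str, StatTrack]:
    """All nine statistic tracks from one pair of bulk read counts."""
    dsnp = delta_snp(counts)
    g = g_statistic(counts)
    edm = euclidean_distance(counts)
    lod = lod_statistic(counts, null_p=lod_null_p)
    return {
        "dsnp": dsnp,
        "tdsnp": tricube_smooth(dsnp, window_bp),
        "afdexp": loess_block_smooth(dsnp, window_bp),
        "g": g,
        "gprime": tricube_smooth(g, window_bp),
        "edm": edm,
        "ed100_4": ed_power_smooth(edm, ed_window_snps),
        "lod": lod,
        "smlod": tricube_smooth(lod, window_bp),
    }
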