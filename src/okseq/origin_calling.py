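"""Replication-origin calling from stranded Okazaki-fragment coverage.

An origin (initiation zone) shows up in Ok-seq data as an ascending transition
of replication-fork directionality: across the origin the Crick-strand read
count rises and the Watson-strand count falls. The caller implements:

1. Hann smoothing of the 1-kb binned Watson/Crick signals (60-kb window by
   default).
2. Discrete (forward) differentiation of each smoothed signal; the derivative
   at index ``i`` is assigned to the junction between bins ``i`` and ``i+1``.
3. Maximal runs of junctions with DER(Watson) < 0 and DER(Crick) > 0 become
   candidate origins; each junction is scored as
   DER-SCORE = -DER(Watson) * DER(Crick), and the region keeps its maximum
   score (summit = leftmost argmax junction).
4. The log10 scores of all regions (all chromosomes jointly) are filtered at
   the lower bound of the full width at half maximum of their histogram, which
   removes the least efficient origin calls from the negatively skewed score
   distribution.

Convolution uses zero padding; a validity mask excludes half a smoothing
window at each chromosome end from region calling so edge leakage cannot
create spurious calls.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .genomic_io import BinnedStrandedTrack, ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "CallerParams",
    "SmoothedDerivative",
    "OriginCall",
    "hann_window",
    "smooth",
    "derivative",
    "compute_derivative_track",
    "call_regions",
    "fwhm_cutoff",
    "call_origins",
]


@dataclass(frozen=True)
class CallerParams:
    """Tunable parameters of the origin caller.

    window_bp
        Width of the Hann smoothing window in bp; must be a positive multiple
        of ``bin_size`` and at least 3 bins wide. Default 60 kb.
    min_region_bins
        Minimum run length (in junctions) for a region to be reported.
        Default 1 (no minimum).
    fwhm_bins
        Number of histogram bins used to estimate the full width at half
        maximum of the log-score distribution.
    min_scores_for_filter
        Below this many calls the FWHM filter is skipped (with a warning) and
        every call passes; the histogram is too sparse to locate a mode.
    """

    window_bp: int = 60_000
    bin_size: int = 1000
    min_region_bins: int = 1
    fwhm_bins: int = 100
    min_scores_for_filter: int = 50

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValidationError("bin_size must be positive")
        if self.window_bp <= 0 or self.window_bp % self.bin_size != 0:
            raise ValidationError("window_bp must be a positive multiple of bin_size")
        if self.window_bins < 3:
            raise ValidationError("smoothing window must span at least 3 bins")
        if self.min_region_bins < 1:
            raise ValidationError("min_region_bins must be >= 1")
        if self.fwhm_bins < 2:
            raise ValidationError("fwhm_bins must be >= 2")

    @property
    def window_bins(self) -> int:
        return self.window_bp // self.bin_size


@dataclass
class SmoothedDerivative:
    """Per-junction derivatives of the smoothed Watson/Crick signals.

    ``der_w[i]``/``der_c[i]`` sit at the junction between bins ``i`` and
    ``i+1`` (genomic position ``(i+1)*bin_size``). ``valid_mask`` flags
    junctions outside the edge-effect zones.
    """

    chrom: str
    bin_size: int
    der_w: np.ndarray
    der_c: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.der_w) == len(self.der_c) == len(self.valid_mask)):
            raise ValidationError("derivative arrays and mask must have equal length")


@dataclass
class OriginCall:
    """A called initiation region.

    ``region`` is a half-open bin-index interval [a, b); the genomic span is
    [a*bin_size, b*bin_size). ``max_score`` is the regional maximum DER-SCORE
    (units: squared smoothed counts per bin per bin; only relative values
    matter) and ``summit_bp`` the junction position of its leftmost argmax.
    Records loaded from BED carry NaN scores.
    """

    chrom: str
    region: tuple[int, int]
    summit_bp: int
    max_score: float
    log_score: float
    passed_filter: bool = True
    bin_size: int = 1000

    def __post_init__(self) -> None:
        a, b = self.region
        if b <= a:
            raise ValidationError(f"empty region [{a}, {b})")
        if not math.isnan(self.max_score) and self.max_score <= 0:
            raise ValidationError("max_score must be positive")
        if not (a * self.bin_size <= self.summit_bp < b * self.bin_size):
            raise ValidationError("summit must lie inside the region's genomic span")

    @property
    def start_bp(self) -> int:
        return self.region[0] * self.bin_size

    @property
    def end_bp(self) -> int:
        return self.region[1] * self.bin_size


# ---------------------------------------------------------------------------
# Smoothing and differentiation
# ---------------------------------------------------------------------------


def hann_window(m: int) -> np.ndarray:
    """Hann taper of length ``m`` normalized to unit sum.

    w[n] = 0.5 * (1 - cos(2*pi*n/(m-1))), n = 0..m-1; symmetric with zero
    endpoints. Normalization makes smoothing preserve the local mean.
    """
    if m < 3:
        raise ValidationError(f"Hann window needs m >= 3, got {m}")
    n = np.arange(m)
    w = 0.5 * (1.0 - np.cos(2.0 * np.pi * n / (m - 1)))
    return w / w.sum()


def _convolve_same(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    # Zero-padded convolution; the (m-1)//2 offset keeps a step edge's
    # maximal smoothed derivative at the step junction for odd *and* even m.
    m = len(w)
    full = np.convolve(x, w, mode="full")
    o = (m - 1) // 2
    return full[o : o + len(x)]


def smooth(
    track: BinnedStrandedTrack, params: CallerParams | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hann-smooth both strands; returns (smoothed_watson, smoothed_crick, valid_mask).

    ``valid_mask`` is a per-bin flag, False within ceil(m/2) bins of each end
    where zero padding leaks into the average.
    """
    params = params or CallerParams()
    m = params.window_bins
    if track.n_bins < m:
        raise ValidationError(
            f"{track.chrom}: track has {track.n_bins} bins, shorter than the "
            f"{m}-bin smoothing window"
        )
    w = hann_window(m)
    sw = _convolve_same(track.watson, w)
    sc = _convolve_same(track.crick, w)
    valid = np.ones(track.n_bins, dtype=bool)
    k = -(-m // 2)
    valid[:k] = False
    valid[track.n_bins - k :] = False
    return sw, sc, valid


def derivative(signal: np.ndarray) -> np.ndarray:
    """Forward difference d[i] = s[i+1] - s[i], one value per bin junction."""
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1 or len(signal) < 2:
        raise ValidationError("signal must be 1-D with length >= 2")
    return np.diff(signal)


def compute_derivative_track(
    track: BinnedStrandedTrack, params: CallerParams | None = None
) -> SmoothedDerivative:
    """Smooth both strands and differentiate; junction i is valid iff both
    flanking bins are outside the edge zones."""
    params = params or CallerParams()
    sw, sc, valid = smooth(track, params)
    return SmoothedDerivative(
        chrom=track.chrom,
        bin_size=track.bin_size,
        der_w=derivative(sw),
        der_c=derivative(sc),
        valid_mask=valid[:-1] & valid[1:],
    )


# ---------------------------------------------------------------------------
# Region detection and scoring
# ---------------------------------------------------------------------------

# Relative tolerance for the derivative sign test: derivatives smaller than
# this fraction of the chromosome's largest |derivative| are treated as zero,
# so float rounding in exactly-flat stretches cannot seed one-junction regions.
_SIGN_RTOL = 1e-9


def call_regions(der: SmoothedDerivative, params: CallerParams | None = None) -> list[OriginCall]:
    """Maximal runs of valid junctions with DER(W) < 0 and DER(C) > 0.

    Each run of length >= ``min_region_bins`` becomes an OriginCall scored by
    the maximum of -DER(W)*DER(C) over its junctions; ties at the maximum are
    broken toward the leftmost junction.
    """
    params = params or CallerParams()
    scale = max(np.abs(der.der_w).max(initial=0.0), np.abs(der.der_c).max(initial=0.0))
    tol = scale * _SIGN_RTOL
    cond = (der.der_w < -tol) & (der.der_c > tol) & der.valid_mask
    padded = np.concatenate(([False], cond, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[0::2], edges[1::2]
    origins: list[OriginCall] = []
    for s, e in zip(starts, ends):
        if e - s < params.min_region_bins:
            continue
        scores = -der.der_w[s:e] * der.der_c[s:e]
        j = int(np.argmax(scores))
        max_score = float(scores[j])
        origins.append(
            OriginCall(
                chrom=der.chrom,
                region=(int(s), int(e) + 1),
                summit_bp=(int(s) + j + 1) * der.bin_size,
                max_score=max_score,
                log_score=math.log10(max_score),
                passed_filter=True,
                bin_size=der.bin_size,
            )
        )
    return origins


# ---------------------------------------------------------------------------
# FWHM filtering
# ---------------------------------------------------------------------------


def fwhm_cutoff(log_scores: Sequence[float], fwhm_bins: int = 100) -> float:
    """Lower full-width-half-maximum bound of the log-score distribution.

    Scores are median-centered (a monotone shift, so the filtered set is
    unaffected by the centering itself), histogrammed into ``fwhm_bins`` bins,
    and the cutoff is the left edge of the first bin (scanning left to right)
    whose height reaches half the mode height, mapped back to the original
    scale. Calls with log_score >= cutoff pass.
    """
    scores = np.asarray(log_scores, dtype=float)
    if scores.size == 0:
        raise ValidationError("fwhm_cutoff needs at least one score")
    if np.ptp(scores) == 0.0:
        return float(scores[0])
    med = float(np.median(scores))
    centered = scores - med
    hist, edges = np.histogram(centered, bins=fwhm_bins)
    half = hist.max() / 2.0
    idx = int(np.argmax(hist >= half))
    return float(edges[idx] + med)


# ---------------------------------------------------------------------------
# End-to-end calling
# ---------------------------------------------------------------------------


def call_origins(
    tracks: Mapping[str, BinnedStrandedTrack] | BinnedStrandedTrack,
    params: CallerParams | None = None,
    apply_filter: bool = True,
    return_cutoff: bool = False,
):
    """Smooth -> differentiate -> call regions -> joint FWHM filter.

    ``tracks`` may be a single track or a chrom -> track mapping; the FWHM
    cutoff is estimated jointly across chromosomes, so the result does not
    depend on chromosome order. Chromosomes shorter than the smoothing window
    are skipped with a warning. Deterministic given input.

    Returns the sorted list of OriginCall (every call is returned;
    ``passed_filter`` records the filter verdict), plus the cutoff (or None)
    if ``return_cutoff``.
    """
    params = params or CallerParams()
    if isinstance(tracks, BinnedStrandedTrack):
        tracks = {tracks.chrom: tracks}
    origins: list[OriginCall] = []
    for chrom in sorted(tracks):
        track = tracks[chrom]
        if track.n_bins < params.window_bins:
            log.warning(
                "skipping %s: %d bins < %d-bin smoothing window",
                chrom, track.n_bins, params.window_bins,
            )
            continue
        chrom_origins = call_regions(compute_derivative_track(track, params), params)
        log.info("%s: %d candidate origin regions", chrom, len(chrom_origins))
        origins.extend(chrom_origins)
    origins.sort(key=lambda o: (o.chrom, o.region[0], o.region[1]))
    cutoff: float | None = None
    if apply_filter and origins:
        if len(origins) >= params.min_scores_for_filter:
            cutoff = fwhm_cutoff([o.log_score for o in origins], params.fwhm_bins)
            for o in origins:
                o.passed_filter = o.log_score >= cutoff
            log.info(
                "FWHM filter: cutoff=%.4f, %d/%d origins pass",
                cutoff, sum(o.passed_filter for o in origins), len(origins),
            )
        else:
            log.warning(
                "only %d origin calls (< %d): FWHM filter skipped, all calls pass",
                len(origins), params.min_scores_for_filter,
            )
    if return_cutoff:
        return origins, cutoff
    return origins
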