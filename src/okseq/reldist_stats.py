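"""Relative-distance orientation statistics for point sets on a genome.

For a query point *a* lying between consecutive reference points b_left and
b_right, the relative distance is min(a-b_left, b_right-a)/(b_right-b_left),
which lives in [0, 0.5] and is uniformly distributed when the two sets are
independent. A pile-up of origin summits near TSS/TTS annotations therefore
shows as excess mass in the lowest relative-distance bins. Conditions are
compared with a paired t-test over the proportions in the leading k bins
(default k=3: relative distances 0, 0.01, 0.02), paired by bin index.

A display-only exponential-decay curve fit and uniform random control sites
complete the module.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .genomic_io import ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "N_BINS",
    "BIN_WIDTH",
    "RelDistHistogram",
    "BinTestResult",
    "DecayFit",
    "relative_distances",
    "reldist_histogram",
    "paired_bin_ttest",
    "fit_decay_curve",
    "random_control_sites",
]

N_BINS = 51  # 50 bins of width 0.01 on [0, 0.5) plus one bin holding exactly 0.5
BIN_WIDTH = 0.01


@dataclass
class RelDistHistogram:
    """Proportion of query points per 0.01-wide relative-distance bin.

    ``bin_edges`` has 52 entries; bin i is [i/100, (i+1)/100) for i < 50 and
    the final bin holds the maximal value 0.5 exactly. ``proportions`` sum to
    1 when n > 0.
    """

    bin_edges: np.ndarray
    proportions: np.ndarray
    n: int

    def __post_init__(self) -> None:
        if len(self.proportions) != N_BINS or len(self.bin_edges) != N_BINS + 1:
            raise ValidationError("histogram must have 51 bins")
        if self.n > 0 and abs(self.proportions.sum() - 1.0) > 1e-12:
            raise ValidationError("proportions must sum to 1")


@dataclass(frozen=True)
class BinTestResult:
    """Paired t-test over the first k relative-distance bins (df = k-1)."""

    k: int
    t_stat: float
    p_value: float
    side: str


def relative_distances(
    a_points: Mapping[str, Sequence[int]],
    b_points: Mapping[str, Sequence[int]],
) -> tuple[np.ndarray, int]:
    """Relative distance of each a-point to its flanking b-points.

    Per chromosome the b set is sorted and each a-point between two b-points
    scores min(a-b_left, b_right-a)/(b_right-b_left); an a-point coinciding
    with a b-point scores 0. A-points outside the b span, or on chromosomes
    with fewer than two b-points, are dropped (counted in the second return
    value and logged).
    """
    out: list[np.ndarray] = []
    dropped = 0
    for chrom in sorted(a_points):
        a = np.sort(np.asarray(a_points[chrom], dtype=np.int64))
        if a.size == 0:
            continue
        b = np.sort(np.asarray(b_points.get(chrom, ()), dtype=np.int64))
        if b.size < 2:
            log.warning("%s: fewer than 2 reference points; %d query points dropped", chrom, a.size)
            dropped += a.size
            continue
        idx = np.searchsorted(b, a, side="right")
        # a == b[-1] has idx == len(b) but coincides with a reference point
        at_last = (idx == b.size) & (a == b[-1])
        ok = (idx > 0) & (idx < b.size)
        n_drop = int((~ok & ~at_last).sum())
        if n_drop:
            log.info("%s: %d query points outside the reference span dropped", chrom, n_drop)
            dropped += n_drop
        d = np.zeros(a.size, dtype=float)
        sel = np.flatnonzero(ok)
        bl = b[idx[sel] - 1].astype(float)
        br = b[idx[sel]].astype(float)
        af = a[sel].astype(float)
        d[sel] = np.minimum(af - bl, br - af) / (br - bl)
        out.append(d[ok | at_last])
    if not out:
        return np.empty(0, dtype=float), dropped
    return np.concatenate(out), dropped


def reldist_histogram(distances: Sequence[float]) -> RelDistHistogram:
    """Bin relative distances into 51 left-closed 0.01-wide bins."""
    d = np.asarray(distances, dtype=float)
    edges = np.round(np.arange(N_BINS + 1) * BIN_WIDTH, 10)
    if d.size == 0:
        return RelDistHistogram(edges, np.zeros(N_BINS), 0)
    if d.min() < 0 or d.max() > 0.5:
        raise ValidationError("relative distances must lie in [0, 0.5]")
    idx = np.minimum(np.floor(d / BIN_WIDTH).astype(int), N_BINS - 1)
    counts = np.bincount(idx, minlength=N_BINS).astype(float)
    return RelDistHistogram(edges, counts / d.size, int(d.size))


def paired_bin_ttest(
    hist_a: RelDistHistogram,
    hist_b: RelDistHistogram,
    k: int = 3,
    side: str = "greater",
) -> BinTestResult:
    """Paired t-test of the k leading bin proportions, paired by bin index.

    ``side='greater'`` tests for excess low-relative-distance mass in
    ``hist_a`` over ``hist_b``. When all k differences are exactly zero the
    statistic is undefined; by convention t = 0, p = 1.0 is returned.
    """
    if k < 2:
        raise ValidationError("k must be >= 2")
    if side not in ("greater", "less", "two-sided"):
        raise ValidationError(f"unknown side {side!r}")
    d = hist_a.proportions[:k] - hist_b.proportions[:k]
    if np.all(d == 0.0):
        return BinTestResult(k, 0.0, 1.0, side)
    mean = d.mean()
    sd = d.std(ddof=1)
    if sd == 0.0:
        t = float("inf") if mean > 0 else float("-inf")
    else:
        t = float(mean / (sd / np.sqrt(k)))
    df = k - 1
    if side == "greater":
        p = float(stats.t.sf(t, df))
    elif side == "less":
        p = float(stats.t.cdf(t, df))
    else:
        p = float(2.0 * stats.t.sf(abs(t), df))
    return BinTestResult(k, t, min(p, 1.0), side)


@dataclass
class DecayFit:
    """Exponential-plus-floor fit p(r) = a*exp(-r/lam) + c with a delta-method
    confidence band; a display aid, never used for inference. ``fallback`` is
    set when least squares fails and a monotone spline is used instead."""

    a: float
    lam: float
    c: float
    cov: np.ndarray | None
    fallback: object | None = None

    def predict(self, r: np.ndarray) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        if self.fallback is not None:
            return self.fallback(r)
        return self.a * np.exp(-r / self.lam) + self.c

    def confidence_band(self, r: np.ndarray, level: float = 0.90):
        """Pointwise delta-method band; None when only the spline fallback exists."""
        if self.cov is None or self.fallback is not None:
            return None
        r = np.asarray(r, dtype=float)
        e = np.exp(-r / self.lam)
        jac = np.stack([e, self.a * r / self.lam**2 * e, np.ones_like(r)], axis=-1)
        var = np.einsum("ij,jk,ik->i", jac, self.cov, jac)
        z = stats.norm.ppf(0.5 + level / 2.0)
        half = z * np.sqrt(np.maximum(var, 0.0))
        mid = self.predict(r)
        return mid - half, mid + half


def fit_decay_curve(hist: RelDistHistogram) -> DecayFit:
    """Least-squares fit of the histogram to a*exp(-r/lam) + c.

    Requires at least 10 populated bins. Non-convergence falls back to a
    monotone (PCHIP) spline through the bin proportions with a warning.
    """
    y = hist.proportions
    if int((y > 0).sum()) < 10:
        raise ValidationError("decay-curve fit needs >= 10 populated bins")
    x = hist.bin_edges[:-1] + BIN_WIDTH / 2.0

    def model(r, a, lam, c):
        return a * np.exp(-r / lam) + c

    # bounds keep the fit identifiable: proportions live in [0, 1] and decay
    # lengths beyond the relative-distance range are indistinguishable from a
    # constant, which belongs to c
    lower, upper = (0.0, 1e-3, 0.0), (1.0, 1.0, 1.0)
    p0 = (min(max(y[0] - y[-1], 1e-6), 1.0), 0.1, min(max(y[-1], 0.0), 1.0))
    try:
        popt, pcov = optimize.curve_fit(
            model, x, y, p0=p0, bounds=(lower, upper), maxfev=20_000
        )
        if not np.all(np.isfinite(popt)):
            raise RuntimeError("non-finite parameters")
        return DecayFit(a=float(popt[0]), lam=float(popt[1]), c=float(popt[2]), cov=pcov)
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        log.warning("decay-curve fit did not converge (%s); using monotone spline", exc)
        from scipy.interpolate import PchipInterpolator

        spline = PchipInterpolator(x, y, extrapolate=True)
        return DecayFit(a=float("nan"), lam=float("nan"), c=float("nan"), cov=None, fallback=spline)


def random_control_sites(
    chrom_sizes: Mapping[str, int],
    counts_per_chrom: Mapping[str, int],
    seed: int | np.random.Generator,
) -> dict[str, np.ndarray]:
    """Uniform random distinct positions per chromosome (seeded, sorted).

    Mirrors the random-genomic-sites control: the number of sites per
    chromosome is supplied by the caller (e.g. the number of protein-coding
    genes on that chromosome).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sites: dict[str, np.ndarray] = {}
    for chrom in sorted(counts_per_chrom):
        if chrom not in chrom_sizes:
            raise ValidationError(f"no size known for chromosome {chrom!r}")
        size = int(chrom_sizes[chrom])
        count = int(counts_per_chrom[chrom])
        if count > size:
            raise ValidationError(f"{chrom}: cannot draw {count} distinct positions from {size}")
        if size <= 10_000_000:
            pos = rng.choice(size, size=count, replace=False)
        else:  # avoid materializing the full position range
            chosen: set[int] = set()
            while len(chosen) < count:
                chosen.update(rng.integers(0, size, size=count - len(chosen)).tolist())
            pos = np.fromiter(chosen, dtype=np.int64)
        sites[chrom] = np.sort(pos.astype(np.int64))
    return sites
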