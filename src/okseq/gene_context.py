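"""Gene-centric context for called origins.

Covers four analyses downstream of origin calling:

* stratification of genes by transcriptional volume (FPKM x length, split at
  the median);
* assignment of each origin summit to an annotation category
  (TSS / TTS / genic / intergenic under a fixed precedence) with log2
  enrichment against the genomic footprint of each category;
* detection of condition-specific "new TTS origins": genes whose TTS window
  contains at least one treated-sample summit and no control-sample summit,
  the signature of dormant origin firing downstream of transcription under
  replication stress;
* classification of each candidate gene by the geometry of its downstream
  neighbor (tandem / convergent / isolated at a 50-kb threshold).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genomic_io import GeneRecord, ValidationError
from .origin_calling import OriginCall

log = logging.getLogger(__name__)

__all__ = [
    "VolumeStrata",
    "CandidateGene",
    "CATEGORIES",
    "stratify_by_volume",
    "annotate_origins",
    "find_new_tts_origins",
    "classify_neighbor",
    "classify_candidates",
    "intragenic_intergenic_split",
]

CATEGORIES = ("TSS", "TTS", "genic", "intergenic")


@dataclass
class VolumeStrata:
    """Genes split at the median transcriptional volume (strictly above = high)."""

    high: list[GeneRecord]
    low: list[GeneRecord]
    median_volume: float


@dataclass
class CandidateGene:
    """A gene with a treated-only origin near/downstream of its TTS.

    ``distance_to_tts`` is signed in gene orientation (positive = downstream
    of the TTS). ``neighbor_class`` is one of tandem/convergent/isolated once
    classified, else None.
    """

    gene: GeneRecord
    origin: OriginCall
    distance_to_tts: int
    neighbor_class: str | None = None


# ---------------------------------------------------------------------------
# Volume stratification
# ---------------------------------------------------------------------------


def stratify_by_volume(genes: Sequence[GeneRecord]) -> VolumeStrata:
    """Split genes at the median FPKM x length; the high stratum is strict >."""
    if len(genes) < 2:
        raise ValidationError("volume stratification needs at least 2 genes")
    volumes = np.array([g.volume for g in genes], dtype=float)
    median = float(np.median(volumes))
    high = [g for g, v in zip(genes, volumes) if v > median]
    low = [g for g, v in zip(genes, volumes) if v <= median]
    return VolumeStrata(high=high, low=low, median_volume=median)


# ---------------------------------------------------------------------------
# Annotation categories and enrichment
# ---------------------------------------------------------------------------


def _per_chrom_points(genes: Iterable[GeneRecord], attr: str) -> dict[str, np.ndarray]:
    pts: dict[str, list[int]] = {}
    for g in genes:
        pts.setdefault(g.chrom, []).append(getattr(g, attr))
    return {c: np.array(sorted(v), dtype=np.int64) for c, v in pts.items()}


def _near_sorted(points: np.ndarray, pos: int, window: int) -> bool:
    if points.size == 0:
        return False
    i = int(np.searchsorted(points, pos))
    for j in (i - 1, i):
        if 0 <= j < points.size and abs(int(points[j]) - pos) <= window:
            return True
    return False


def _body_index(genes: Sequence[GeneRecord]):
    """Per-chrom (sorted starts, running max of ends, order) for containment tests."""
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    index = {}
    for chrom, gl in by_chrom.items():
        gl = sorted(gl, key=lambda g: (g.start, g.end))
        starts = np.array([g.start for g in gl], dtype=np.int64)
        cummax_end = np.maximum.accumulate(np.array([g.end for g in gl], dtype=np.int64))
        index[chrom] = (starts, cummax_end)
    return index


def _in_body(index, chrom: str, pos: int) -> bool:
    if chrom not in index:
        return False
    starts, cummax_end = index[chrom]
    i = int(np.searchsorted(starts, pos, side="right"))
    return i > 0 and int(cummax_end[i - 1]) > pos


def _merge_intervals(iv: np.ndarray) -> np.ndarray:
    if iv.size == 0:
        return iv.reshape(0, 2)
    iv = iv[np.lexsort((iv[:, 1], iv[:, 0]))]
    merged = [iv[0].tolist()]
    for s, e in iv[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.array(merged, dtype=np.int64)


def _subtract_intervals(iv: np.ndarray, sub: np.ndarray) -> np.ndarray:
    """Set difference iv \\ sub; both inputs merged/sorted."""
    out = []
    j = 0
    for s, e in iv:
        cur = s
        while j < len(sub) and sub[j][1] <= cur:
            j += 1
        k = j
        while k < len(sub) and sub[k][0] < e:
            if sub[k][0] > cur:
                out.append((cur, sub[k][0]))
            cur = max(cur, sub[k][1])
            k += 1
        if cur < e:
            out.append((cur, e))
    return np.array(out, dtype=np.int64).reshape(-1, 2)


def _coverage_bp(
    genes: Sequence[GeneRecord],
    chrom_sizes: Mapping[str, int],
    tss_window: int,
    tts_window: int,
) -> dict[str, int]:
    """Genomic footprint (bp) of each category under the same precedence as
    the per-origin assignment."""
    cov = {c: 0 for c in CATEGORIES}
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, size in chrom_sizes.items():
        gl = by_chrom.get(chrom, [])
        tss_iv = _merge_intervals(
            np.array(
                [[max(0, g.tss - tss_window), min(size, g.tss + tss_window + 1)] for g in gl],
                dtype=np.int64,
            ).reshape(-1, 2)
        )
        tts_iv = _merge_intervals(
            np.array(
                [[max(0, g.tts - tts_window), min(size, g.tts + tts_window + 1)] for g in gl],
                dtype=np.int64,
            ).reshape(-1, 2)
        )
        body_iv = _merge_intervals(
            np.array([[g.start, min(size, g.end)] for g in gl], dtype=np.int64).reshape(-1, 2)
        )
        tts_iv = _subtract_intervals(tts_iv, tss_iv)
        occupied = _merge_intervals(
            np.vstack([tss_iv.reshape(-1, 2), tts_iv.reshape(-1, 2)])
        )
        body_iv = _subtract_intervals(body_iv, occupied)
        tss_bp = int((tss_iv[:, 1] - tss_iv[:, 0]).sum()) if tss_iv.size else 0
        tts_bp = int((tts_iv[:, 1] - tts_iv[:, 0]).sum()) if tts_iv.size else 0
        body_bp = int((body_iv[:, 1] - body_iv[:, 0]).sum()) if body_iv.size else 0
        cov["TSS"] += tss_bp
        cov["TTS"] += tts_bp
        cov["genic"] += body_bp
        cov["intergenic"] += size - tss_bp - tts_bp - body_bp
    return cov


def annotate_origins(
    origins: Sequence[OriginCall],
    genes: Sequence[GeneRecord],
    tss_window: int = 1000,
    tts_window: int = 1000,
    chrom_sizes: Mapping[str, int] | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Assign each origin summit to TSS/TTS/genic/intergenic and tabulate
    log2 enrichment of observed vs genomic category fractions.

    Precedence: within +-tss_window of any TSS beats within +-tts_window of
    any TTS beats inside any gene body beats intergenic. Enrichment needs
    ``chrom_sizes``; without it only categories are returned (the table then
    has NaN genome fractions).
    """
    tss_pts = _per_chrom_points(genes, "tss")
    tts_pts = _per_chrom_points(genes, "tts")
    body_idx = _body_index(genes)
    categories: list[str] = []
    for o in origins:
        pos = o.summit_bp
        if _near_sorted(tss_pts.get(o.chrom, np.empty(0, dtype=np.int64)), pos, tss_window):
            categories.append("TSS")
        elif _near_sorted(tts_pts.get(o.chrom, np.empty(0, dtype=np.int64)), pos, tts_window):
            categories.append("TTS")
        elif _in_body(body_idx, o.chrom, pos):
            categories.append("genic")
        else:
            categories.append("intergenic")
    n = len(categories)
    counts = {c: categories.count(c) for c in CATEGORIES}
    obs_frac = {c: (counts[c] / n if n else np.nan) for c in CATEGORIES}
    if chrom_sizes is not None:
        cov = _coverage_bp(genes, chrom_sizes, tss_window, tts_window)
        total = sum(chrom_sizes.values())
        cov_frac = {c: cov[c] / total for c in CATEGORIES}
    else:
        log.warning("no chrom sizes supplied: annotation enrichment unavailable")
        cov_frac = {c: np.nan for c in CATEGORIES}
    rows = []
    for c in CATEGORIES:
        o, g = obs_frac[c], cov_frac[c]
        enr = np.log2(o / g) if (o and g and o > 0 and g > 0) else np.nan
        rows.append(
            {
                "category": c,
                "n_origins": counts[c],
                "origin_fraction": o,
                "genome_fraction": g,
                "log2_enrichment": enr,
            }
        )
    return categories, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Condition-specific new TTS origins
# ---------------------------------------------------------------------------


def _summit_index(origins: Sequence[OriginCall], only_passing: bool) -> dict[str, tuple[np.ndarray, list[OriginCall]]]:
    by_chrom: dict[str, list[OriginCall]] = {}
    for o in origins:
        if only_passing and not o.passed_filter:
            continue
        by_chrom.setdefault(o.chrom, []).append(o)
    index = {}
    for chrom, ol in by_chrom.items():
        ol = sorted(ol, key=lambda o: o.summit_bp)
        index[chrom] = (np.array([o.summit_bp for o in ol], dtype=np.int64), ol)
    return index


def _tts_window(gene: GeneRecord, upstream_bp: int, downstream_bp: int) -> tuple[int, int]:
    if gene.strand == "+":
        return gene.tts - upstream_bp, gene.tts + downstream_bp
    return gene.tts - downstream_bp, gene.tts + upstream_bp


def find_new_tts_origins(
    origins_treated: Sequence[OriginCall],
    origins_control: Sequence[OriginCall],
    genes: Sequence[GeneRecord],
    upstream_bp: int = 1000,
    downstream_bp: int = 50_000,
    only_passing: bool = True,
) -> list[CandidateGene]:
    """Genes whose oriented TTS window holds >= 1 treated summit and 0 control summits.

    The window is [TTS - upstream_bp, TTS + downstream_bp] in gene orientation
    (both ends inclusive). The closest treated summit is attached with its
    signed distance (positive = downstream). By default only origins that
    passed the efficiency filter are compared (``only_passing=False`` compares
    the pre-filter sets).
    """
    treated = _summit_index(origins_treated, only_passing)
    control = _summit_index(origins_control, only_passing)
    candidates: list[CandidateGene] = []
    for gene in genes:
        lo, hi = _tts_window(gene, upstream_bp, downstream_bp)
        t = treated.get(gene.chrom)
        if t is None:
            continue
        t_pos, t_origins = t
        i0 = int(np.searchsorted(t_pos, lo, side="left"))
        i1 = int(np.searchsorted(t_pos, hi, side="right"))
        if i1 <= i0:
            continue
        c = control.get(gene.chrom)
        if c is not None:
            c_pos = c[0]
            if int(np.searchsorted(c_pos, hi, side="right")) > int(np.searchsorted(c_pos, lo, side="left")):
                continue  # present in control: not a new origin
        in_win = range(i0, i1)
        best = min(in_win, key=lambda i: (abs(int(t_pos[i]) - gene.tts), i))
        summit = int(t_pos[best])
        signed = summit - gene.tts if gene.strand == "+" else gene.tts - summit
        candidates.append(CandidateGene(gene=gene, origin=t_origins[best], distance_to_tts=signed))
    return candidates


# ---------------------------------------------------------------------------
# Neighbor-gene geometry
# ---------------------------------------------------------------------------


def classify_neighbor(
    candidate: CandidateGene,
    genes: Sequence[GeneRecord],
    threshold_bp: int = 50_000,
) -> str:
    """Tandem / convergent / isolated class of a candidate's downstream neighbor.

    Scanning downstream of the candidate's TTS in its direction of
    transcription, the first feature of another gene encountered is that
    gene's TSS if it is co-oriented (tandem geometry) or its TTS if it is
    opposite-oriented (convergent geometry). If that nearest feature lies
    within ``threshold_bp`` of the candidate's TTS origin the corresponding
    class is returned, otherwise ``"isolated"`` (also when no downstream gene
    exists).
    """
    g = candidate.gene
    origin_pos = candidate.origin.summit_bp
    best_pos: int | None = None
    best_gene: GeneRecord | None = None
    for h in genes:
        if h.chrom != g.chrom or h.gene_id == g.gene_id:
            continue
        if g.strand == "+":
            feat = h.start  # '+' neighbor: TSS; '-' neighbor: TTS
            if feat > g.tts and (best_pos is None or feat < best_pos):
                best_pos, best_gene = feat, h
        else:
            feat = h.end - 1  # '-' neighbor: TSS; '+' neighbor: TTS
            if feat < g.tts and (best_pos is None or feat > best_pos):
                best_pos, best_gene = feat, h
    if best_gene is None or abs(best_pos - origin_pos) >= threshold_bp:
        return "isolated"
    return "tandem" if best_gene.strand == g.strand else "convergent"


def classify_candidates(
    candidates: Sequence[CandidateGene],
    genes: Sequence[GeneRecord],
    threshold_bp: int = 50_000,
) -> list[CandidateGene]:
    """Return candidates with ``neighbor_class`` filled in."""
    return [
        replace(c, neighbor_class=classify_neighbor(c, genes, threshold_bp)) for c in candidates
    ]


# ---------------------------------------------------------------------------
# Intragenic / intergenic partition
# ---------------------------------------------------------------------------


def intragenic_intergenic_split(
    origins: Sequence[OriginCall],
    genes: Sequence[GeneRecord],
) -> tuple[list[OriginCall], list[OriginCall]]:
    """Partition origins by summit containment in any gene body [start, end)."""
    body_idx = _body_index(genes)
    intra = [o for o in origins if _in_body(body_idx, o.chrom, o.summit_bp)]
    inter = [o for o in origins if not _in_body(body_idx, o.chrom, o.summit_bp)]
    log.info("%d intragenic / %d intergenic origins", len(intra), len(inter))
    return intra, inter
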