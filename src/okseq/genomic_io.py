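"""Readers/writers for the genomic formats the origin pipeline touches.

Coordinates are 0-based half-open (BED convention) throughout. Strand-resolved
Okazaki-fragment coverage comes in as one bedGraph per strand (Watson = plus
strand, Crick = minus strand) and is assembled into fixed-width binned tracks;
the bin grid is anchored at coordinate 0. A bedGraph value is interpreted as a
per-bin count density over its interval: bin *i* accumulates
``value * overlap([i*bs, (i+1)*bs), interval) / bs``, so an interval exactly
covering k bins contributes ``value`` to each of them. This is robust to both
per-bp and pre-binned exports.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "ValidationError",
    "ParseError",
    "BinnedStrandedTrack",
    "GeneRecord",
    "read_stranded_counts",
    "read_chrom_sizes",
    "read_gene_table",
    "write_gene_table",
    "write_bedgraph",
    "write_origins_bed",
    "read_origins_bed",
    "read_points_bed",
    "write_points_bed",
]


class ValidationError(ValueError):
    """Input violates a documented invariant."""


class ParseError(ValueError):
    """A file could not be parsed; message carries the line number."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class BinnedStrandedTrack:
    """Per-chromosome binned Watson (plus) and Crick (minus) Okazaki read counts.

    Bin ``i`` covers ``[i*bin_size, (i+1)*bin_size)``. Counts may be
    non-integer (densities after apportionment, or noiseless expected counts)
    but must be finite and non-negative.
    """

    chrom: str
    bin_size: int
    watson: np.ndarray
    crick: np.ndarray

    def __post_init__(self) -> None:
        self.watson = np.asarray(self.watson, dtype=float)
        self.crick = np.asarray(self.crick, dtype=float)
        if self.bin_size <= 0:
            raise ValidationError(f"bin_size must be positive, got {self.bin_size}")
        if self.watson.ndim != 1 or self.watson.shape != self.crick.shape:
            raise ValidationError(
                "watson and crick must be 1-D arrays of equal length "
                f"(got {self.watson.shape} vs {self.crick.shape})"
            )
        for name, arr in (("watson", self.watson), ("crick", self.crick)):
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"{name} counts must be finite")
            if np.any(arr < 0):
                raise ValidationError(f"{name} counts must be non-negative")

    @property
    def n_bins(self) -> int:
        return int(self.watson.shape[0])

    def bin_starts(self) -> np.ndarray:
        return np.arange(self.n_bins, dtype=np.int64) * self.bin_size


@dataclass(frozen=True)
class GeneRecord:
    """A stranded gene interval with an RNA-seq expression level (FPKM).

    TSS/TTS are single-bp points: for a '+' gene tss = start and
    tts = end - 1; for a '-' gene the two are swapped. ``volume`` is the
    transcriptional volume FPKM x gene length, a proxy for the number of
    engaged RNA polymerases.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    fpkm: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"gene {self.gene_id}: start must be < end ({self.start} >= {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if not (math.isfinite(self.fpkm) and self.fpkm >= 0):
            raise ValidationError(f"gene {self.gene_id}: fpkm must be finite and >= 0")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def volume(self) -> float:
        return self.fpkm * self.length


# ---------------------------------------------------------------------------
# bedGraph -> binned tracks
# ---------------------------------------------------------------------------


def _parse_bedgraph(path: str | Path) -> dict[str, list[tuple[int, int, float]]]:
    intervals: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            try:
                chrom = parts[0]
                start, end = int(parts[1]), int(parts[2])
                value = float(parts[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if start < 0 or end <= start:
                raise ParseError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            if not math.isfinite(value) or value < 0:
                raise ValidationError(f"{path}:{lineno}: value must be finite and >= 0")
            intervals.setdefault(chrom, []).append((start, end, value))
    return intervals


def _bin_intervals(
    intervals: Iterable[tuple[int, int, float]], n_bins: int, bin_size: int
) -> np.ndarray:
    acc = np.zeros(n_bins, dtype=float)
    limit = n_bins * bin_size
    for start, end, value in intervals:
        start = max(start, 0)
        end = min(end, limit)
        if end <= start or value == 0.0:
            continue
        b0 = start // bin_size
        b1 = (end - 1) // bin_size
        bins = np.arange(b0, b1 + 1)
        overlap = np.minimum(end, (bins + 1) * bin_size) - np.maximum(start, bins * bin_size)
        acc[bins] += value * overlap / bin_size
    return acc


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a 2-column chrom.sizes file (name, length in bp)."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            try:
                sizes[parts[0]] = int(parts[1])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return sizes


def read_stranded_counts(
    watson_path: str | Path,
    crick_path: str | Path,
    bin_size: int = 1000,
    chrom_sizes: Mapping[str, int] | None = None,
) -> dict[str, BinnedStrandedTrack]:
    """Assemble per-chromosome binned stranded tracks from two bedGraph files.

    The chromosome universe is the union of both files unless ``chrom_sizes``
    is given, in which case bins are truncated at the stated chromosome end.
    A chromosome present in only one file gets zero counts on the other strand.
    """
    if bin_size <= 0:
        raise ValidationError("bin_size must be positive")
    watson = _parse_bedgraph(watson_path)
    crick = _parse_bedgraph(crick_path)
    chroms = sorted(set(watson) | set(crick))
    tracks: dict[str, BinnedStrandedTrack] = {}
    for chrom in chroms:
        w_iv = watson.get(chrom, [])
        c_iv = crick.get(chrom, [])
        if chrom_sizes is not None and chrom in chrom_sizes:
            n_bins = -(-chrom_sizes[chrom] // bin_size)
        else:
            max_end = max(end for _, end, _ in w_iv + c_iv)
            n_bins = -(-max_end // bin_size)
        tracks[chrom] = BinnedStrandedTrack(
            chrom=chrom,
            bin_size=bin_size,
            watson=_bin_intervals(w_iv, n_bins, bin_size),
            crick=_bin_intervals(c_iv, n_bins, bin_size),
        )
    return tracks


def write_bedgraph(track: BinnedStrandedTrack, watson_path: str | Path, crick_path: str | Path) -> None:
    """Write a track back to one bedGraph per strand (one line per non-zero bin)."""
    starts = track.bin_starts()
    for path, values in ((watson_path, track.watson), (crick_path, track.crick)):
        with open(path, "w") as fh:
            for s, v in zip(starts, values):
                if v != 0.0:
                    fh.write(f"{track.chrom}\t{s}\t{s + track.bin_size}\t{v:.6g}\n")


# ---------------------------------------------------------------------------
# Gene tables
# ---------------------------------------------------------------------------

_GENE_COLUMNS = ("chrom", "start", "end", "gene_id", "fpkm", "strand")


def read_gene_table(path: str | Path, has_header: bool = False) -> list[GeneRecord]:
    """Read a 6-column TSV (chrom, start, end, gene_id, fpkm, strand).

    Records are validated against the GeneRecord invariants; duplicate
    gene_ids are rejected.
    """
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if has_header and lineno == 1:
                continue
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError(f"{path}:{lineno}: expected 6 columns, got {len(parts)}")
            try:
                rec = GeneRecord(
                    gene_id=parts[3],
                    chrom=parts[0],
                    start=int(parts[1]),
                    end=int(parts[2]),
                    strand=parts[5],
                    fpkm=float(parts[4]),
                )
            except ValueError as exc:
                if isinstance(exc, ValidationError):
                    raise
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if rec.gene_id in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate gene_id {rec.gene_id!r}")
            seen.add(rec.gene_id)
            genes.append(rec)
    return genes


def write_gene_table(genes: Iterable[GeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t{g.fpkm:.6g}\t{g.strand}\n")


# ---------------------------------------------------------------------------
# Origin BED files (BED6 + summit column)
# ---------------------------------------------------------------------------


def write_origins_bed(origins, path: str | Path) -> None:
    """Write origin calls as BED6+1: the 5th column is the log10 score
    rescaled to a 0-1000 integer across the written set and the 7th column is
    the summit position (bp). Records are sorted by (chrom, start).
    """
    origins = sorted(origins, key=lambda o: (o.chrom, o.region[0], o.region[1]))
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\tsummit\n")
        if not origins:
            return
        logs = np.array([o.log_score for o in origins], dtype=float)
        finite = logs[np.isfinite(logs)]
        lo = finite.min() if finite.size else 0.0
        hi = finite.max() if finite.size else 0.0
        for i, o in enumerate(origins):
            if hi > lo and np.isfinite(o.log_score):
                score = int(round(1000 * (o.log_score - lo) / (hi - lo)))
            else:
                score = 1000
            start = o.region[0] * o.bin_size
            end = o.region[1] * o.bin_size
            fh.write(
                f"{o.chrom}\t{start}\t{end}\torigin_{i + 1:05d}\t{score}\t.\t{o.summit_bp}\n"
            )


def read_origins_bed(path: str | Path, bin_size: int = 1000):
    """Read a BED6+1 origin file back into OriginCall records.

    Absolute DER scores are not recoverable from the rescaled BED score
    column, so loaded records carry NaN scores; regions and summits round-trip
    exactly. Loaded origins are marked as having passed filtering.
    """
    from .origin_calling import OriginCall  # local import avoids a cycle

    origins = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 7:
                raise ParseError(f"{path}:{lineno}: expected 7 columns, got {len(parts)}")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                summit = int(parts[6])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            origins.append(
                OriginCall(
                    chrom=chrom,
                    region=(start // bin_size, -(-end // bin_size)),
                    summit_bp=summit,
                    max_score=float("nan"),
                    log_score=float("nan"),
                    passed_filter=True,
                    bin_size=bin_size,
                )
            )
    return origins


# ---------------------------------------------------------------------------
# Point BED files (TSS/TTS/feature points)
# ---------------------------------------------------------------------------


def read_points_bed(path: str | Path) -> dict[str, np.ndarray]:
    """Read a BED file as per-chromosome point sets.

    Single-bp intervals map to their start; wider intervals to their midpoint.
    """
    points: dict[str, list[int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            pos = start if end - start <= 1 else (start + end) // 2
            points.setdefault(parts[0], []).append(pos)
    return {c: np.array(sorted(v), dtype=np.int64) for c, v in points.items()}


def write_points_bed(points: Mapping[str, Iterable[int]], path: str | Path, name: str = "pt") -> None:
    with open(path, "w") as fh:
        i = 0
        for chrom in sorted(points):
            for pos in sorted(points[chrom]):
                i += 1
                fh.write(f"{chrom}\t{int(pos)}\t{int(pos) + 1}\t{name}_{i:05d}\n")
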