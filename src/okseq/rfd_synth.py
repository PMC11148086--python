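"""Stochastic replication-fork-directionality simulator for Ok-seq tracks.

The generative model: in each simulated cell cycle every licensed origin
fires independently with its efficiency (cells with zero firings are redrawn,
since Okazaki fragments only arise from replicated DNA); fired origins emit
two forks of equal speed, so each genomic bin is replicated by the nearest
fired origin — rightward if that origin lies to the bin's left (ties at exact
midpoints go rightward). Averaging over cells gives p_right, the probability
a bin is replicated by a rightward fork; the expected replication-fork
directionality is RFD = (C - W)/(C + W) = 2*p_right - 1.

Reads are sampled per bin as total ~ Poisson(depth), Crick ~
Binomial(total, p_right), Watson = total - Crick: Okazaki fragments from
rightward forks map to the Crick strand, which is what makes an origin appear
as increasing Crick / decreasing Watson.

The replication-stress scenario emulates dormant origin firing downstream of
transcription: the control places efficient origins at TSSs of high-volume
genes and the treated condition adds moderate-efficiency dormant origins
1-30 kb downstream of the TTSs of an implanted subset of those genes.

All randomness flows from a single seed through named substreams (firing,
read sampling, placement) so each stage is independently reproducible.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .gene_context import stratify_by_volume
from .genomic_io import BinnedStrandedTrack, GeneRecord, ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "SimOrigin",
    "SimConfig",
    "SimResult",
    "StressScenario",
    "simulate_fork_directionality",
    "sample_track",
    "simulate",
    "stress_scenario",
    "demo_gene_model",
]

# named RNG substreams
_FIRING, _READS, _PLACEMENT = 1, 2, 3


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


@dataclass(frozen=True)
class SimOrigin:
    """A licensed origin: genomic position (bp) and per-cell-cycle firing
    probability in (0, 1]."""

    position: int
    efficiency: float

    def __post_init__(self) -> None:
        if not (0.0 < self.efficiency <= 1.0):
            raise ValidationError(f"efficiency must be in (0, 1], got {self.efficiency}")
        if self.position < 0:
            raise ValidationError("origin position must be non-negative")


@dataclass
class SimConfig:
    """Inputs for one simulated chromosome."""

    chrom_length: int
    origins: list[SimOrigin]
    bin_size: int = 1000
    n_cells: int = 500
    depth: float = 50.0
    seed: int = 0
    chrom: str = "chrS"
    gene_model: list[GeneRecord] | None = None

    def __post_init__(self) -> None:
        if not self.origins:
            raise ValidationError("at least one origin is required")
        pos = [o.position for o in self.origins]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValidationError("origin positions must be strictly increasing")
        if pos[-1] >= self.chrom_length:
            raise ValidationError("origins must lie inside the chromosome")
        if self.n_cells < 1:
            raise ValidationError("n_cells must be >= 1")
        if self.depth <= 0:
            raise ValidationError("depth must be positive")
        if self.bin_size <= 0:
            raise ValidationError("bin_size must be positive")

    @property
    def n_bins(self) -> int:
        return -(-self.chrom_length // self.bin_size)


@dataclass
class SimResult:
    """Fork-directionality profile, sampled track and the generating truth."""

    p_right: np.ndarray
    track: BinnedStrandedTrack
    truth: list[SimOrigin]


def simulate_fork_directionality(config: SimConfig) -> np.ndarray:
    """Across-cell average probability that each bin is replicated rightward.

    Deterministic given the config seed. With all efficiencies 1 this reduces
    exactly to the closed-form step function of nearest-origin midpoints.
    """
    positions = np.array([o.position for o in config.origins], dtype=np.int64)
    eff = np.array([o.efficiency for o in config.origins], dtype=float)
    n_bins = config.n_bins
    centers = (np.arange(n_bins, dtype=float) + 0.5) * config.bin_size

    rng = _rng(config.seed, _FIRING)
    fires = rng.random((config.n_cells, len(positions))) < eff
    # condition on >= 1 firing: redraw empty cells
    while True:
        empty = ~fires.any(axis=1)
        if not empty.any():
            break
        fires[empty] = rng.random((int(empty.sum()), len(positions))) < eff

    patterns, counts = np.unique(fires, axis=0, return_counts=True)
    p_right = np.zeros(n_bins, dtype=float)
    for pat, cnt in zip(patterns, counts):
        fired = positions[pat].astype(float)
        idx = np.searchsorted(fired, centers, side="right")
        d_left = np.where(idx > 0, centers - fired[np.clip(idx - 1, 0, None)], np.inf)
        d_right = np.where(
            idx < fired.size, fired[np.clip(idx, None, fired.size - 1)] - centers, np.inf
        )
        p_right += cnt * (d_left <= d_right)
    return p_right / config.n_cells


def sample_track(
    p_right: np.ndarray,
    depth: float,
    seed: int,
    bin_size: int = 1000,
    chrom: str = "chrS",
    noiseless: bool = False,
) -> BinnedStrandedTrack:
    """Sample stranded read counts from a fork-directionality profile.

    Per bin: total ~ Poisson(depth), Crick ~ Binomial(total, p_right),
    Watson = total - Crick. With ``noiseless=True`` the expected counts
    (depth * p_right and depth * (1 - p_right)) are returned instead, giving
    the deterministic infinite-depth limit used by closed-form checks.
    """
    p_right = np.asarray(p_right, dtype=float)
    if depth <= 0:
        raise ValidationError("depth must be positive")
    if p_right.min() < 0 or p_right.max() > 1:
        raise ValidationError("p_right must lie in [0, 1]")
    if noiseless:
        crick = depth * p_right
        watson = depth * (1.0 - p_right)
    else:
        rng = _rng(seed, _READS)
        total = rng.poisson(depth, size=p_right.size)
        crick = rng.binomial(total, p_right).astype(float)
        watson = total - crick
    return BinnedStrandedTrack(chrom=chrom, bin_size=bin_size, watson=watson, crick=crick)


def simulate(config: SimConfig, noiseless: bool = False) -> SimResult:
    """Fork-directionality profile plus a sampled track for one chromosome."""
    p_right = simulate_fork_directionality(config)
    track = sample_track(
        p_right, config.depth, config.seed, config.bin_size, config.chrom, noiseless=noiseless
    )
    return SimResult(p_right=p_right, track=track, truth=list(config.origins))


# ---------------------------------------------------------------------------
# Replication-stress scenario
# ---------------------------------------------------------------------------


@dataclass
class StressScenario:
    """Paired control/treated configs plus the implanted-gene truth list."""

    control: SimConfig
    treated: SimConfig
    implanted_gene_ids: list[str]
    genes: list[GeneRecord] = field(default_factory=list)


# Dormant-origin offsets downstream of the TTS: stratified midpoints of the
# thirds of the 1-30 kb placement range, cycled over implanted genes so the
# range is covered evenly rather than left to sampling chance.
DORMANT_OFFSETS_BP = (5_000, 15_000, 25_000)


def stress_scenario(
    genes: Sequence[GeneRecord],
    chrom_length: int | None = None,
    bin_size: int = 1000,
    n_cells: int = 500,
    depth: float = 50.0,
    seed: int = 0,
    n_implant: int = 8,
    tss_efficiency: float = 1.0,
    dormant_efficiency: float = 0.5,
    dormant_offsets_bp: Sequence[int] = DORMANT_OFFSETS_BP,
) -> StressScenario:
    """Build paired control/treated configs for the dormant-TTS-origin study.

    Control: one origin of ``tss_efficiency`` at the TSS of every high-volume
    gene. Treated: additionally one dormant origin of ``dormant_efficiency``
    offset downstream of the TTS (in gene orientation) for a seeded choice of
    ``n_implant`` high-volume genes. All genes must share one chromosome.

    Constitutive TSS origins default to efficiency 1.0: they are the
    deterministic reference against which stochastic dormant firing is
    measured, and always-firing flanks keep passively replicated stretches
    single-stranded so the synthetic genome's sparse origin map (real genomes
    have licensed origins everywhere) does not itself manufacture spurious
    two-strand shot-noise regions.
    """
    genes = sorted(genes, key=lambda g: (g.chrom, g.start))
    chroms = {g.chrom for g in genes}
    if len(chroms) != 1:
        raise ValidationError("stress scenario expects a single-chromosome gene model")
    chrom = chroms.pop()
    strata = stratify_by_volume(genes)
    if not strata.high:
        raise ValidationError("no high-volume genes to place origins at")
    if n_implant > len(strata.high):
        raise ValidationError(
            f"cannot implant {n_implant} genes: only {len(strata.high)} high-volume genes"
        )
    if chrom_length is None:
        chrom_length = max(g.end for g in genes) + 500_000

    rng = _rng(seed, _PLACEMENT)
    high = sorted(strata.high, key=lambda g: g.start)
    implant_idx = np.sort(rng.choice(len(high), size=n_implant, replace=False))
    implanted = [high[i] for i in implant_idx]

    control_origins = [SimOrigin(g.tss, tss_efficiency) for g in high]
    dormant = []
    for j, g in enumerate(implanted):
        off = int(dormant_offsets_bp[j % len(dormant_offsets_bp)])
        pos = g.tts + off if g.strand == "+" else g.tts - off
        if not (0 <= pos < chrom_length):
            raise ValidationError(f"dormant origin for {g.gene_id} falls off the chromosome")
        dormant.append(SimOrigin(pos, dormant_efficiency))

    def _sorted(origins: list[SimOrigin]) -> list[SimOrigin]:
        ordered = sorted(origins, key=lambda o: o.position)
        pos = [o.position for o in ordered]
        if len(set(pos)) != len(pos):
            raise ValidationError("origin positions collide; adjust the gene model")
        return ordered

    common = dict(
        chrom_length=chrom_length, bin_size=bin_size, n_cells=n_cells,
        depth=depth, chrom=chrom, gene_model=list(genes),
    )
    control = SimConfig(origins=_sorted(control_origins), seed=seed, **common)
    treated = SimConfig(origins=_sorted(control_origins + dormant), seed=seed + 1, **common)
    return StressScenario(
        control=control,
        treated=treated,
        implanted_gene_ids=[g.gene_id for g in implanted],
        genes=list(genes),
    )


def demo_gene_model(
    n_genes: int = 20,
    spacing: int = 500_000,
    length: int = 120_000,
    first_start: int = 200_000,
    high_fpkm: float = 20.0,
    low_fpkm: float = 0.5,
    chrom: str = "chrS",
) -> list[GeneRecord]:
    """Regularly spaced single-chromosome gene model for the stress demo.

    Alternate genes are high-volume (every even index); high-volume strands
    alternate +/− starting with '+' and ending '-', so every dormant origin
    placed downstream of a high-volume TTS stays strictly between two
    high-volume TTSs (no dropped points in relative-distance scoring).
    """
    genes: list[GeneRecord] = []
    for i in range(n_genes):
        start = first_start + i * spacing
        if i % 2 == 0:
            strand = "+" if (i // 2) % 2 == 0 else "-"
            fpkm = high_fpkm
        else:
            strand = "-" if (i // 2) % 2 == 0 else "+"
            fpkm = low_fpkm
        genes.append(
            GeneRecord(
                gene_id=f"g{i:02d}",
                chrom=chrom,
                start=start,
                end=start + length,
                strand=strand,
                fpkm=fpkm,
            )
        )
    return genes
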