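"""End-to-end orchestration: simulate -> call -> reldist/test -> annotate -> candidates.

Stages hand off through files in standard formats (bedGraph/BED/TSV/JSON), so
real Ok-seq-derived tracks can replace the simulated ones without code
changes. A JSON manifest lists every output with its SHA-256 content hash;
identical config + inputs give identical manifests.
"""
from __future__ import annotations

import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import genomic_io as gio
from .gene_context import (
    classify_candidates,
    find_new_tts_origins,
    annotate_origins,
    stratify_by_volume,
)
from .genomic_io import ValidationError
from .origin_calling import CallerParams, call_origins
from .reldist_stats import paired_bin_ttest, reldist_histogram, relative_distances
from .rfd_synth import demo_gene_model, sample_track, simulate_fork_directionality, stress_scenario

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "load_run_config"]


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    With ``simulate=True`` (the default demo) the bundled stress scenario is
    generated from ``seed``; otherwise the four bedGraph paths and the gene
    table must point at existing files.
    """

    outdir: str = "okseq_run"
    seed: int = 0
    simulate: bool = True
    # simulated-scenario knobs
    n_genes: int = 20
    n_implant: int = 8
    depth: float = 50.0
    n_cells: int = 500
    # caller
    window_bp: int = 60_000
    bin_size: int = 1000
    min_region_bins: int = 1
    fwhm_filter: bool = True
    # reldist / candidate settings
    k: int = 3
    side: str = "greater"
    upstream_bp: int = 1000
    downstream_bp: int = 50_000
    high_volume_only: bool = True
    # external inputs (used when simulate=False)
    watson_treated: str | None = None
    crick_treated: str | None = None
    watson_control: str | None = None
    crick_control: str | None = None
    genes_path: str | None = None

    def caller_params(self) -> CallerParams:
        return CallerParams(
            window_bp=self.window_bp,
            bin_size=self.bin_size,
            min_region_bins=self.min_region_bins,
        )

    def validate(self) -> None:
        self.caller_params()  # raises on bad caller settings
        if self.side not in ("greater", "less", "two-sided"):
            raise ValidationError(f"unknown test side {self.side!r}")
        if not self.simulate:
            missing = [
                name
                for name in (
                    "watson_treated", "crick_treated",
                    "watson_control", "crick_control", "genes_path",
                )
                if getattr(self, name) is None or not Path(getattr(self, name)).exists()
            ]
            if missing:
                raise ValidationError(f"missing input files for: {', '.join(missing)}")


def load_run_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    unknown = set(data) - set(RunConfig.__dataclass_fields__)
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_hist_tsv(hist, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("bin_low\tbin_high\tproportion\tn\n")
        for lo, hi, p in zip(hist.bin_edges[:-1], hist.bin_edges[1:], hist.proportions):
            fh.write(f"{lo:.2f}\t{hi:.2f}\t{p:.10g}\t{hist.n}\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in dependency order and return the output manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    stats: dict[str, object] = {}
    t0 = time.perf_counter()

    def _stage(name: str, start: float) -> None:
        log.info("stage %-10s done in %.2fs", name, time.perf_counter() - start)

    # -- inputs -------------------------------------------------------------
    ts = time.perf_counter()
    if config.simulate:
        genes = demo_gene_model(n_genes=config.n_genes)
        scen = stress_scenario(
            genes,
            n_cells=config.n_cells,
            depth=config.depth,
            seed=config.seed,
            n_implant=config.n_implant,
            bin_size=config.bin_size,
        )
        tracks = {}
        for label, cfg in (("control", scen.control), ("treated", scen.treated)):
            p_right = simulate_fork_directionality(cfg)
            track = sample_track(p_right, cfg.depth, cfg.seed, cfg.bin_size, cfg.chrom)
            tracks[label] = {cfg.chrom: track}
            wpath, cpath = outdir / f"{label}_watson.bedgraph", outdir / f"{label}_crick.bedgraph"
            gio.write_bedgraph(track, wpath, cpath)
            outputs[f"{label}_watson.bedgraph"] = wpath
            outputs[f"{label}_crick.bedgraph"] = cpath
        gio.write_gene_table(genes, outdir / "genes.tsv")
        outputs["genes.tsv"] = outdir / "genes.tsv"
        truth = {
            "implanted_gene_ids": scen.implanted_gene_ids,
            "control_origins": [[o.position, o.efficiency] for o in scen.control.origins],
            "treated_origins": [[o.position, o.efficiency] for o in scen.treated.origins],
        }
        (outdir / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
        outputs["truth.json"] = outdir / "truth.json"
        chrom_sizes = {scen.control.chrom: scen.control.chrom_length}
        stats["implanted_genes"] = len(scen.implanted_gene_ids)
    else:
        genes = gio.read_gene_table(config.genes_path)
        tracks = {
            "treated": gio.read_stranded_counts(
                config.watson_treated, config.crick_treated, config.bin_size
            ),
            "control": gio.read_stranded_counts(
                config.watson_control, config.crick_control, config.bin_size
            ),
        }
        chrom_sizes = {
            chrom: t.n_bins * t.bin_size
            for sample in tracks.values()
            for chrom, t in sample.items()
        }
    _stage("inputs", ts)

    # -- origin calling -----------------------------------------------------
    ts = time.perf_counter()
    params = config.caller_params()
    origins = {}
    for label in ("control", "treated"):
        calls, cutoff = call_origins(
            tracks[label], params, apply_filter=config.fwhm_filter, return_cutoff=True
        )
        origins[label] = calls
        path = outdir / f"origins_{label}.bed"
        gio.write_origins_bed([o for o in calls if o.passed_filter], path)
        outputs[f"origins_{label}.bed"] = path
        stats[f"origins_{label}"] = sum(o.passed_filter for o in calls)
        stats[f"cutoff_{label}"] = cutoff
        log.info("%s: %d passing origins (cutoff=%s)", label, stats[f"origins_{label}"], cutoff)
    _stage("call", ts)

    # -- relative-distance histograms and condition tests -------------------
    ts = time.perf_counter()
    feature_genes = stratify_by_volume(genes).high if config.high_volume_only else list(genes)
    features = {
        "tss": {},
        "tts": {},
    }
    for g in feature_genes:
        features["tss"].setdefault(g.chrom, []).append(g.tss)
        features["tts"].setdefault(g.chrom, []).append(g.tts)
    summits = {
        label: _summits_by_chrom(origins[label]) for label in ("control", "treated")
    }
    hists = {}
    test_results = {}
    for feat in ("tss", "tts"):
        for label in ("control", "treated"):
            dists, dropped = relative_distances(summits[label], features[feat])
            hists[(feat, label)] = reldist_histogram(dists)
            path = outdir / f"reldist_{feat}_{label}.tsv"
            _write_hist_tsv(hists[(feat, label)], path)
            outputs[f"reldist_{feat}_{label}.tsv"] = path
        res = paired_bin_ttest(
            hists[(feat, "treated")], hists[(feat, "control")], k=config.k, side=config.side
        )
        # strict JSON has no Infinity literal
        t_out = res.t_stat if math.isfinite(res.t_stat) else str(res.t_stat)
        test_results[feat] = {"k": res.k, "t": t_out, "p": res.p_value, "side": res.side}
    (outdir / "reldist_tests.json").write_text(json.dumps(test_results, indent=1, sort_keys=True))
    outputs["reldist_tests.json"] = outdir / "reldist_tests.json"
    stats["reldist_tests"] = test_results
    _stage("reldist", ts)

    # -- annotation enrichment ----------------------------------------------
    ts = time.perf_counter()
    ann_frames = []
    for label in ("control", "treated"):
        passing = [o for o in origins[label] if o.passed_filter]
        _, table = annotate_origins(passing, genes, chrom_sizes=chrom_sizes)
        table.insert(0, "sample", label)
        ann_frames.append(table)
    import pandas as pd

    ann = pd.concat(ann_frames, ignore_index=True)
    ann.to_csv(outdir / "annotation.tsv", sep="\t", index=False, float_format="%.6g")
    outputs["annotation.tsv"] = outdir / "annotation.tsv"
    _stage("annotate", ts)

    # -- candidate genes -----------------------------------------------------
    ts = time.perf_counter()
    candidates = classify_candidates(
        find_new_tts_origins(
            origins["treated"], origins["control"], genes,
            upstream_bp=config.upstream_bp, downstream_bp=config.downstream_bp,
        ),
        genes,
    )
    strata = stratify_by_volume(genes)
    high_ids = {g.gene_id for g in strata.high}
    cand_path = outdir / "candidates.tsv"
    with open(cand_path, "w") as fh:
        fh.write(
            "gene_id\tchrom\tstrand\ttts\torigin_summit\tsigned_distance\t"
            "neighbor_class\tgene_fpkm\tgene_length\tvolume_stratum\n"
        )
        for c in sorted(candidates, key=lambda c: (c.gene.chrom, c.gene.start)):
            g = c.gene
            stratum = "high" if g.gene_id in high_ids else "low"
            fh.write(
                f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tts}\t{c.origin.summit_bp}\t"
                f"{c.distance_to_tts}\t{c.neighbor_class}\t{g.fpkm:.6g}\t{g.length}\t{stratum}\n"
            )
    outputs["candidates.tsv"] = cand_path
    stats["candidates"] = len(candidates)
    log.info("%d candidate genes with new TTS origins", len(candidates))
    _stage("candidates", ts)

    # -- manifest ------------------------------------------------------------
    manifest = {
        "config": asdict(config),
        "outputs": {name: _sha256(path) for name, path in sorted(outputs.items())},
        "stats": stats,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    log.info("pipeline finished in %.2fs", time.perf_counter() - t0)
    return manifest


def _summits_by_chrom(origins) -> dict[str, np.ndarray]:
    out: dict[str, list[int]] = {}
    for o in origins:
        if o.passed_filter:
            out.setdefault(o.chrom, []).append(o.summit_bp)
    return {c: np.array(sorted(v), dtype=np.int64) for c, v in out.items()}
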