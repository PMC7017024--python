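"""End-to-end pipelines with explicit configuration and manifests.

Two runners bind the library modules into the study's two workflows: the
calling-card pipeline (reads -> events -> sites -> peaks -> gene matrix ->
differential binding -> sequence analyses) and the SELEX pipeline
(per-round pools -> k-mer enrichment -> top set -> consensus trajectory).

A run resolves its configuration against module defaults, echoes the fully
explicit config next to its outputs, and writes a manifest of sha256
checksums; re-running with identical config and inputs reproduces
byte-identical text outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import ccparse, ccquant, diffbind, motifs, selex

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or incomplete run configuration (CLI exit code 2)."""


class DataError(RuntimeError):
    """A pipeline stage failed on its input data (CLI exit code 3)."""


@dataclass
class RunConfig:
    """Fully explicit run configuration; every field has the module default."""

    # paths
    genome: str | None = None
    annotation: str | None = None
    samples: dict[str, dict[str, str]] = field(default_factory=dict)  # sample -> {r1, r2}
    pwms: str | None = None
    pools: list[str] = field(default_factory=list)  # round 0 first
    # calling-card parameters
    wt_sample: str | None = None
    max_primer_mismatches: int = 2
    min_mean_quality: float = 20.0
    peak_window: int = 300
    peak_alpha: float = 0.05
    upstream_bp: int = 1000
    downstream_bp: int = 200
    percentile: float = 85.0
    motif_window: int = 300
    kmer_k: int = 7
    pwm_p_threshold: float = 1e-4
    consensus: str = "TGAAACA"
    diff_alpha: float = 0.05
    # SELEX parameters
    selex_k: int = 10
    sd_multiplier: float = 3.0
    # misc
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
        except Exception as exc:
            raise ConfigError(f"cannot parse config {path}: {exc}") from exc
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    def validate_callingcard(self) -> None:
        if not self.genome or not Path(self.genome).exists():
            raise ConfigError(f"genome path missing or not found: {self.genome}")
        if not self.annotation or not Path(self.annotation).exists():
            raise ConfigError(f"annotation path missing or not found: {self.annotation}")
        if not self.samples:
            raise ConfigError("no samples configured")
        for name, paths in self.samples.items():
            for key in ("r1", "r2"):
                if key not in paths or not Path(paths[key]).exists():
                    raise ConfigError(f"sample {name!r}: missing reads file {key}")
        if self.pwms and not Path(self.pwms).exists():
            raise ConfigError(f"pwms path not found: {self.pwms}")

    def validate_selex(self) -> None:
        if len(self.pools) < 2:
            raise ConfigError("need the input pool and at least one round pool")
        for p in self.pools:
            if not Path(p).exists():
                raise ConfigError(f"pool file not found: {p}")
        if not 1 <= self.selex_k <= 36:
            raise ConfigError(f"selex_k must be in [1, 36], got {self.selex_k}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_manifest(out_dir: Path) -> Path:
    manifest = {
        p.name: _sha256(p)
        for p in sorted(out_dir.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def _stage(name: str):
    """Wrap a stage so failures abort with the stage name and cause."""

    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except (ConfigError, DataError):
                raise
            except Exception as exc:
                raise DataError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


def run_callingcard(config: RunConfig, out_dir: str | Path) -> Path:
    """Run the full calling-card pipeline; returns the output directory."""
    config.validate_callingcard()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "resolved_config.yaml")

    index = _stage("index-genome")(ccparse.GenomeIndex.from_fasta)(config.genome)
    from pyfaidx import Fasta

    fa = Fasta(config.genome)
    seqs = {name: str(fa[name][:]) for name in fa.keys()}
    annotation = _stage("read-annotation")(pd.read_csv)(config.annotation, sep="\t")

    all_events = []
    reports = {}
    for sample in sorted(config.samples):
        paths = config.samples[sample]
        events, report = _stage(f"extract-events[{sample}]")(ccparse.extract_events)(
            paths["r1"],
            paths["r2"],
            index,
            sample,
            max_primer_mismatches=config.max_primer_mismatches,
            min_mean_quality=config.min_mean_quality,
        )
        logger.info("sample %s: %d read pairs, %d events", sample, report.total, len(events))
        all_events.extend(events)
        reports[sample] = report.counts
    ccparse.write_events_tsv(all_events, out / "events.tsv")
    (out / "parse_report.json").write_text(json.dumps(reports, indent=2, sort_keys=True) + "\n")

    sites = _stage("collapse-umis")(ccquant.collapse_umis)(all_events)
    sites.to_csv(out / "sites.tsv", sep="\t", index=False)

    chrom_sizes = {c: len(s) for c, s in seqs.items()}
    ttaa = ccquant.ttaa_positions(seqs)
    peak_frames = []
    for sample in sorted(config.samples):
        sub = sites[sites["sample"] == sample]
        peaks = _stage(f"call-peaks[{sample}]")(ccquant.call_peaks)(
            sub, chrom_sizes, window=config.peak_window, alpha=config.peak_alpha, ttaa_sites=ttaa
        )
        peaks.insert(0, "sample", sample)
        peak_frames.append(peaks)
    all_peaks = pd.concat(peak_frames, ignore_index=True)
    all_peaks.to_csv(out / "peaks.tsv", sep="\t", index=False, float_format="%.6g")

    matrix = _stage("gene-matrix")(ccquant.gene_matrix)(sites, annotation)
    matrix.write_tsv(out / "gene_matrix_raw.tsv", view="raw")
    matrix.write_tsv(out / "gene_matrix_log.tsv", view="log")

    focal = config.wt_sample or sorted(config.samples)[0]
    if config.wt_sample and len(config.samples) > 1:
        table = _stage("diff-binding")(diffbind.diff_binding_table)(
            matrix, config.wt_sample, alpha=config.diff_alpha
        )
        table.to_csv(out / "diff_binding.tsv", sep="\t", index=False, float_format="%.6g")

    focal_peaks = all_peaks[all_peaks["sample"] == focal]
    kmers = _stage("kmer-enrichment")(motifs.kmer_enrichment)(focal_peaks, seqs, k=config.kmer_k)
    kmers.to_csv(out / "kmer_enrichment.tsv", sep="\t", index=False, float_format="%.6g")

    dists, fraction = _stage("nearest-distance")(motifs.nearest_motif_distance)(
        focal_peaks, seqs, consensus=config.consensus
    )
    pd.DataFrame({"distance": dists}).to_csv(out / "peak_distances.tsv", sep="\t", index=False)
    (out / "distance_summary.json").write_text(
        json.dumps({"fraction_within_200bp": fraction, "n_peaks": int(len(dists))}, indent=2) + "\n"
    )

    focal_sites = sites[sites["sample"] == focal]
    windows = _stage("high-count-windows")(motifs.high_count_windows)(
        focal_sites, percentile=config.percentile, window=config.motif_window
    )
    windows.to_csv(out / "high_count_windows.tsv", sep="\t", index=False)
    if config.pwms:
        pwms = _stage("parse-pwms")(motifs.parse_meme)(Path(config.pwms))
        hits = _stage("scan-pwms")(motifs.scan_pwms)(
            windows, seqs, pwms, p_threshold=config.pwm_p_threshold
        )
        hits.to_csv(out / "motif_hits.tsv", sep="\t", index=False, float_format="%.6g")
        pairs = _stage("motif-pairs")(motifs.motif_pair_counts)(hits, len(windows))
        pairs.to_csv(out / "motif_pairs.tsv", sep="\t", index=False, float_format="%.6g")

    _write_manifest(out)
    return out


def run_selex(config: RunConfig, out_dir: str | Path) -> Path:
    """Run the SELEX analysis pipeline; returns the output directory."""
    config.validate_selex()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "resolved_config.yaml")

    from .simdata import read_pool

    pools = [_stage(f"read-pool[{i}]")(read_pool)(p) for i, p in enumerate(config.pools)]
    final = pools[-1]
    table = _stage("selex-enrichment")(selex.selex_enrichment)(final, pools[0], k=config.selex_k)
    table.to_csv(out / "enrichment.tsv", sep="\t", index=False, float_format="%.6g")

    top = _stage("top-enriched")(selex.top_enriched)(table, sd_multiplier=config.sd_multiplier)
    top.to_csv(out / "top_enriched.tsv", sep="\t", index=False, float_format="%.6g")

    trajectory = _stage("trajectory")(selex.consensus_trajectory)(pools, consensus=config.consensus)
    pd.DataFrame({"round": range(1, len(trajectory) + 1), "enrichment": trajectory}).to_csv(
        out / "trajectory.tsv", sep="\t", index=False, float_format="%.6g"
    )

    _write_manifest(out)
    return out
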