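"""End-to-end pipeline configuration and orchestration.

Stages: IDR extraction -> N-gram training -> Monte Carlo generation ->
per-length Levenshtein clustering -> subgroup selection. Each stage writes
its documented artifacts plus a run manifest (config, seeds, version); the
full run is byte-reproducible given the global seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Sequence

import yaml

import oligomine
from oligomine.cluster import (
    agglomerate,
    build_matrix,
    cut_subgroups,
    write_newick,
    write_selection_report,
)
from oligomine.corpus import (
    DisorderTrack,
    IDRSegment,
    extract_idrs,
    frequency_profile,
    read_disorder_track,
    read_fasta,
    top_k_residues,
    write_fasta,
    write_idr_table,
)
from oligomine.generate import (
    Candidate,
    GenerationConfig,
    MonteCarloGenerator,
    candidates_by_length,
    filter_admissible,
    rank_and_truncate,
    write_candidate_fasta,
    write_candidate_table,
)
from oligomine.ngram import NeuralNGramModel, NGramConfig, save_model

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised on unknown or invalid configuration keys."""


@dataclass
class ClusterOptions:
    linkage: str = "complete"
    n_subgroups: int = 2
    per_group: int = 3
    min_group_size: int = 2


@dataclass
class PipelineConfig:
    """Structured configuration for the whole pipeline.

    A fully-defaulted config is valid; unknown keys in a config file are
    rejected. Stage seeds are derived deterministically from the global seed.
    """

    seed: int = 0
    idr_threshold: float = 0.5
    idr_min_length: int = 3
    ngram: NGramConfig = field(default_factory=NGramConfig)
    generation: GenerationConfig = field(default_factory=GenerationConfig)
    clustering: ClusterOptions = field(default_factory=ClusterOptions)

    def __post_init__(self) -> None:
        # derive stage seeds from the global seed so one integer pins the run
        self.ngram.seed = int((self.seed * 1_000_003 + 1) % (2**31))
        self.generation.seed = int((self.seed * 1_000_003 + 2) % (2**31))

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        def build(klass, section: dict[str, Any], name: str):
            known = {f.name for f in dataclasses.fields(klass)}
            unknown = set(section) - known
            if unknown:
                raise ConfigError(f"unknown keys in {name!r}: {sorted(unknown)}")
            return klass(**section)

        known_top = {"seed", "idr_threshold", "idr_min_length",
                     "ngram", "generation", "clustering"}
        unknown = set(data) - known_top
        if unknown:
            raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
        cfg = cls(
            seed=int(data.get("seed", 0)),
            idr_threshold=float(data.get("idr_threshold", 0.5)),
            idr_min_length=int(data.get("idr_min_length", 3)),
            ngram=build(NGramConfig, data.get("ngram", {}), "ngram"),
            generation=build(GenerationConfig, data.get("generation", {}), "generation"),
            clustering=build(ClusterOptions, data.get("clustering", {}), "clustering"),
        )
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict[str, Any]:
        return {
            "seed": self.seed,
            "idr_threshold": self.idr_threshold,
            "idr_min_length": self.idr_min_length,
            "ngram": asdict(self.ngram),
            "generation": asdict(self.generation),
            "clustering": asdict(self.clustering),
        }


def write_manifest(config: PipelineConfig, out_dir: Path, extra: dict[str, Any] | None = None) -> None:
    payload = {
        "oligomine_version": oligomine.__version__,
        "config": config.to_dict(),
    }
    if extra:
        payload.update(extra)
    blob = json.dumps(payload, indent=2, sort_keys=True)
    payload["config_sha256"] = hashlib.sha256(blob.encode()).hexdigest()
    (out_dir / "manifest.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n"
    )


@dataclass
class PipelineResult:
    """In-memory artifacts of a full run."""

    idr_segments: list[IDRSegment]
    seeds: list[str]
    model: NeuralNGramModel
    pool: list[Candidate]
    admissible: list[Candidate]
    top_candidates: list[Candidate]
    by_length: dict[int, list[Candidate]]
    subgroup_assignments: dict[int, dict[str, int]]
    selected: dict[int, list[str]]


def run_pipeline(
    tracks: Sequence[DisorderTrack],
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run extraction, training, generation, clustering and selection in memory."""
    config = config or PipelineConfig()

    segments: list[IDRSegment] = []
    for track in tracks:
        segments.extend(
            extract_idrs(track, threshold=config.idr_threshold,
                         min_length=config.idr_min_length)
        )
    if not segments:
        raise ValueError("no IDR segments extracted; nothing to train on")
    seg_seqs = [s.sequence for s in segments]

    profile = frequency_profile(seg_seqs)
    seeds = top_k_residues(profile, k=config.generation.seeds_k)
    logger.info("IDR segments: %d; seed residues: %s", len(segments), "".join(seeds))

    model = NeuralNGramModel(**asdict(config.ngram)).fit(seg_seqs)
    logger.info("trained model: %d windows, final loss %.4f",
                model.n_windows_, model.loss_trace_[-1])

    generator = MonteCarloGenerator(model, config.generation)
    pool = generator.extend_all(seeds)
    admissible = filter_admissible(pool, threshold=config.generation.admission_threshold)
    top = rank_and_truncate(admissible, keep_top=config.generation.keep_top)
    by_length = candidates_by_length(admissible, keep_top=config.generation.keep_top)
    logger.info("pool %d, admissible %d, top %d", len(pool), len(admissible), len(top))

    assignments: dict[int, dict[str, int]] = {}
    selected: dict[int, list[str]] = {}
    copts = config.clustering
    for length, group in by_length.items():
        seqs = [c.sequence for c in group]
        if len(seqs) < max(2, copts.min_group_size):
            continue
        tree = agglomerate(build_matrix(seqs), method=copts.linkage)
        k = min(copts.n_subgroups, len(seqs))
        assignment = cut_subgroups(tree, k=k)
        assignments[length] = assignment
        scores = {c.sequence: c.score for c in group}
        picks: list[str] = []
        n_groups = max(assignment.values()) + 1
        for grp in range(n_groups):
            members = [s for s in seqs if assignment[s] == grp]
            members.sort(key=lambda s: (-scores[s], s))
            picks.extend(members[:copts.per_group])
        selected[length] = picks

    return PipelineResult(
        idr_segments=segments,
        seeds=list(seeds),
        model=model,
        pool=pool,
        admissible=admissible,
        top_candidates=top,
        by_length=by_length,
        subgroup_assignments=assignments,
        selected=selected,
    )


def write_results(result: PipelineResult, config: PipelineConfig, out_dir: str | Path) -> None:
    """Write every stage's artifacts under out_dir."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    write_idr_table(result.idr_segments, out_dir / "idr_segments.tsv")
    write_fasta(result.idr_segments, out_dir / "idr_segments.fasta")
    (out_dir / "seed_residues.txt").write_text("".join(result.seeds) + "\n")
    save_model(result.model, out_dir / "ngram_model.zip")
    write_candidate_table(result.top_candidates, out_dir / "candidates_top.tsv")
    write_candidate_fasta(result.top_candidates, out_dir / "candidates_top.fasta")

    report_rows = []
    for length, group in result.by_length.items():
        write_candidate_table(group, out_dir / f"candidates_len{length}.tsv")
        if length in result.subgroup_assignments:
            seqs = [c.sequence for c in group]
            tree = agglomerate(build_matrix(seqs), method=config.clustering.linkage)
            write_newick(tree, out_dir / f"tree_len{length}.nwk")
            assignment = result.subgroup_assignments[length]
            scores = {c.sequence: c.score for c in group}
            for rank, seq in enumerate(result.selected[length], start=1):
                report_rows.append((seq, length, assignment[seq], scores[seq], rank))
    write_selection_report(report_rows, out_dir / "selected_candidates.tsv")
    write_manifest(config, out_dir, extra={
        "n_idr_segments": len(result.idr_segments),
        "n_pool": len(result.pool),
        "n_admissible": len(result.admissible),
        "n_top": len(result.top_candidates),
    })


def load_tracks(tracks_dir: str | Path) -> list[DisorderTrack]:
    """Read every IUPred-style track file in a directory (sorted by name)."""
    tracks_dir = Path(tracks_dir)
    paths = sorted(tracks_dir.glob("*.tsv")) + sorted(tracks_dir.glob("*.txt"))
    if not paths:
        raise FileNotFoundError(f"no track files (*.tsv, *.txt) in {tracks_dir}")
    tracks = []
    for p in paths:
        pid = p.name.split(".")[0]
        tracks.append(read_disorder_track(p, protein_id=pid))
    return tracks
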