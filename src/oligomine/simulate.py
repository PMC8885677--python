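"""Synthetic protein corpora with known disorder structure and planted motifs.

Each simulated protein carries one contiguous designated-disordered block.
Disorder scores are drawn from a clipped normal around 0.8 inside the block
and 0.2 outside, so threshold-0.5 extraction recovers the designed blocks.
Inside a block, residue filling alternates between emitting a whole planted
motif (with the configured per-step probability) and drawing one background
residue, which plants an over-represented short motif the downstream model
should learn and the generator should resurface. Ground truth (block
intervals, motif placements) is returned for assertions.

The simulator writes the same FASTA and IUPred-style track formats the
corpus module reads; it makes no attempt to imitate the score
autocorrelation of a real disorder predictor beyond the block structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from oligomine.corpus import (
    AMINO_ACIDS,
    DisorderTrack,
    ProteinRecord,
    write_disorder_track,
    write_fasta,
)


class SimulationError(ValueError):
    """Raised on an unsatisfiable corpus specification."""


#: Residue background biased toward the residues over-represented in
#: disordered regions (S, E, G, P, A), mirroring the composition shift
#: between IDRs and full-length sequences.
def biased_idr_background() -> dict[str, float]:
    freqs = {aa: 0.025 for aa in AMINO_ACIDS}
    for aa in "SEGPA":
        freqs[aa] = 0.125
    # remaining 15 residues share the rest
    rest = (1.0 - 5 * 0.125) / 15
    for aa in AMINO_ACIDS:
        if aa not in "SEGPA":
            freqs[aa] = rest
    return freqs


def uniform_background() -> dict[str, float]:
    return {aa: 1.0 / 20.0 for aa in AMINO_ACIDS}


@dataclass
class CorpusSpec:
    """Parameters of a simulated corpus.

    Defaults emulate the study conditions this pipeline targets: 171
    annotated proteins, one disordered block covering ~40% of each protein,
    and a pentapeptide motif planted in disordered blocks at rate 0.3 per
    fill step.
    """

    n_proteins: int = 171
    length_range: tuple[int, int] = (150, 400)
    background_freqs: dict[str, float] = field(default_factory=uniform_background)
    idr_fraction: float = 0.4
    planted_motifs: tuple[tuple[str, float], ...] = (("ESSES", 0.3),)
    idr_score_mean: float = 0.8
    non_idr_score_mean: float = 0.2
    score_noise: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 0:
            raise SimulationError("n_proteins must be >= 0")
        if not (0.0 < self.idr_fraction < 1.0):
            raise SimulationError("idr_fraction must be in (0, 1)")
        lo, hi = self.length_range
        if not (0 < lo <= hi):
            raise SimulationError("length_range must satisfy 0 < min <= max")
        total = sum(self.background_freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise SimulationError("background_freqs must sum to 1")
        for motif, rate in self.planted_motifs:
            if not (3 <= len(motif) <= 10):
                raise SimulationError(f"motif {motif!r} must be 3-10 residues")
            if not (0.0 <= rate <= 1.0):
                raise SimulationError(f"insertion rate {rate} outside [0, 1]")
            if set(motif) - set(AMINO_ACIDS):
                raise SimulationError(f"motif {motif!r} has non-canonical residues")
            min_block = int(lo * self.idr_fraction)
            if len(motif) > min_block:
                raise SimulationError(
                    f"motif {motif!r} longer than the smallest IDR block ({min_block})"
                )


@dataclass
class GroundTruth:
    """Designed disorder intervals and motif placements, for assertions."""

    idr_intervals: dict[str, tuple[int, int]]           # protein_id -> (start, end)
    motif_placements: dict[str, list[tuple[int, str]]]  # protein_id -> [(start, motif)]
    n_fill_steps: int
    n_motif_insertions: int

    @property
    def empirical_insertion_rate(self) -> float:
        if self.n_fill_steps == 0:
            return float("nan")
        return self.n_motif_insertions / self.n_fill_steps


def _draw_background(rng: np.random.Generator, freqs: dict[str, float], n: int) -> str:
    letters = list(freqs.keys())
    p = np.array([freqs[a] for a in letters])
    p = p / p.sum()
    return "".join(rng.choice(letters, size=n, p=p)) if n else ""


def _fill_idr_block(
    rng: np.random.Generator,
    spec: CorpusSpec,
    block_len: int,
) -> tuple[str, list[tuple[int, str]], int, int]:
    """Fill a disordered block: per step, emit a planted motif with its
    configured probability, else one background residue."""
    out: list[str] = []
    placements: list[tuple[int, str]] = []
    pos = 0
    steps = 0
    insertions = 0
    motifs = list(spec.planted_motifs)
    while pos < block_len:
        steps += 1
        inserted = False
        for motif, rate in motifs:
            if pos + len(motif) <= block_len and rng.random() < rate:
                out.append(motif)
                placements.append((pos, motif))
                pos += len(motif)
                insertions += 1
                inserted = True
                break
        if not inserted:
            out.append(_draw_background(rng, spec.background_freqs, 1))
            pos += 1
    return "".join(out), placements, steps, insertions


def _block_scores(
    rng: np.random.Generator, n: int, mean: float, spread: float, high: bool
) -> np.ndarray:
    scores = rng.normal(mean, spread, size=n)
    # keep designed blocks on the right side of the 0.5 threshold even after
    # noise, then clip into the score range
    if high:
        scores = np.clip(scores, 0.501, 1.0)
    else:
        scores = np.clip(scores, 0.0, 0.499)
    return scores


def simulate_corpus(
    spec: CorpusSpec,
) -> tuple[list[ProteinRecord], list[DisorderTrack], GroundTruth]:
    """Generate proteins, matching disorder tracks, and ground truth."""
    rng = np.random.default_rng(spec.seed)
    records: list[ProteinRecord] = []
    tracks: list[DisorderTrack] = []
    intervals: dict[str, tuple[int, int]] = {}
    placements: dict[str, list[tuple[int, str]]] = {}
    total_steps = 0
    total_insertions = 0

    for i in range(spec.n_proteins):
        pid = f"SYN{i + 1:04d}"
        length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        block_len = max(1, int(round(length * spec.idr_fraction)))
        block_len = min(block_len, length)
        max_start = length - block_len
        block_start = int(rng.integers(0, max_start + 1)) if max_start > 0 else 0

        prefix = _draw_background(rng, spec.background_freqs, block_start)
        block, place, steps, ins = _fill_idr_block(rng, spec, block_len)
        suffix = _draw_background(
            rng, spec.background_freqs, length - block_start - block_len
        )
        seq = prefix + block + suffix

        scores = np.empty(length)
        scores[:block_start] = _block_scores(
            rng, block_start, spec.non_idr_score_mean, spec.score_noise, high=False
        )
        scores[block_start:block_start + block_len] = _block_scores(
            rng, block_len, spec.idr_score_mean, spec.score_noise, high=True
        )
        scores[block_start + block_len:] = _block_scores(
            rng,
            length - block_start - block_len,
            spec.non_idr_score_mean,
            spec.score_noise,
            high=False,
        )

        records.append(ProteinRecord(id=pid, sequence=seq))
        tracks.append(
            DisorderTrack(protein_id=pid, residues=seq, scores=tuple(scores))
        )
        intervals[pid] = (block_start, block_start + block_len)
        placements[pid] = [(block_start + p, m) for p, m in place]
        total_steps += steps
        total_insertions += ins

    truth = GroundTruth(
        idr_intervals=intervals,
        motif_placements=placements,
        n_fill_steps=total_steps,
        n_motif_insertions=total_insertions,
    )
    return records, tracks, truth


def write_corpus(
    records: Sequence[ProteinRecord],
    tracks: Sequence[DisorderTrack],
    out_dir: str | Path,
) -> None:
    """Write the corpus in the formats the corpus module reads."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_fasta(records, out_dir / "proteins.fasta")
    tracks_dir = out_dir / "tracks"
    tracks_dir.mkdir(exist_ok=True)
    for track in tracks:
        write_disorder_track(track, tracks_dir / f"{track.protein_id}.iupred.tsv")


def reference_fixture() -> tuple[list[ProteinRecord], list[DisorderTrack], GroundTruth]:
    """The seed-pinned miniature corpus used as the regression snapshot.

    20 proteins, shorter than the default corpus, with the same planted
    pentapeptide; the expected end-to-end candidate table produced from this
    fixture is checked in under tests/data/.
    """
    spec = CorpusSpec(
        n_proteins=20,
        length_range=(120, 200),
        idr_fraction=0.4,
        planted_motifs=(("ESSES", 0.3),),
        seed=20240917,
    )
    return simulate_corpus(spec)


def reference_pipeline_config():
    """The pinned pipeline configuration paired with :func:`reference_fixture`.

    Training is shortened (40 epochs) relative to the default so the
    regression snapshot re-runs quickly; everything else is the default.
    """
    from oligomine.pipeline import PipelineConfig

    cfg = PipelineConfig(seed=20240917)
    cfg.ngram.epochs = 40
    return cfg
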