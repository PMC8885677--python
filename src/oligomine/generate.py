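"""Monte Carlo extension of seed residues into scored oligopeptide candidates.

Starting from the most frequent IDR residues, each cycle samples next
residues from the N-gram model's conditional distribution ("throwing the
dice") and appends them, recording each appended residue's conditional
probability. Candidates are scored by the product of those per-step
probabilities (kept in log space), admissibility-filtered (every step must
beat the 1/20 chance level, strictly), ranked, and truncated to a top pool.

The extension frontier would grow combinatorially if left unchecked, so two
exact-or-conservative controls apply: paths containing an inadmissible step
are recorded but never extended further (they could never produce an
admissible candidate), and the frontier is capped per cycle at the
highest-scoring states (default 2000), deterministically tie-broken.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from oligomine.corpus import AMINO_ACIDS
from oligomine.ngram import NeuralNGramModel


class GenerationError(ValueError):
    """Raised on invalid generator configuration or an unfitted model."""


@dataclass(frozen=True)
class Candidate:
    """A generated oligopeptide with its per-step conditional probabilities.

    ``step_probs`` has one entry per appended residue (the seed contributes
    no factor), so ``len(step_probs) == len(sequence) - 1``. The score is
    the product of step probabilities, stored as a log-sum for numerical
    safety; a bare seed scores 1 by the empty-product convention.
    """

    sequence: str
    seed: str
    step_probs: tuple[float, ...]
    log_score: float

    def __post_init__(self) -> None:
        if len(self.step_probs) != len(self.sequence) - 1:
            raise GenerationError(
                f"candidate {self.sequence!r}: {len(self.step_probs)} step "
                f"probabilities for length {len(self.sequence)}"
            )
        for p in self.step_probs:
            if not (0.0 < p <= 1.0):
                raise GenerationError(
                    f"candidate {self.sequence!r}: step probability {p} outside (0, 1]"
                )

    @property
    def score(self) -> float:
        return math.exp(self.log_score)


def score(candidate: Candidate) -> float:
    """Probability-product score (1.0 for a bare seed)."""
    return candidate.score


@dataclass
class GenerationConfig:
    """Monte Carlo extension settings.

    seeds_k initial residues are taken from the IDR frequency ranking;
    extension proceeds one residue per cycle up to max_length (the emitted
    candidates are lengths 3..max_length; 1-2-mers are internal states).
    admission_threshold is the strict per-step probability floor (chance
    level 1/20 by default); keep_top is the size of the ranked global pool.
    """

    seeds_k: int = 10
    max_length: int = 10
    draws_per_step: int = 200
    admission_threshold: float = 1.0 / 20.0
    keep_top: int = 100
    min_emit_length: int = 3
    max_frontier: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_length < 3:
            raise GenerationError("max_length must be >= 3")
        if not (0.0 < self.admission_threshold < 1.0):
            raise GenerationError("admission_threshold must be in (0, 1)")
        if self.keep_top < 1:
            raise GenerationError("keep_top must be >= 1")
        if self.draws_per_step < 1:
            raise GenerationError("draws_per_step must be >= 1")


def sample_next(model: NeuralNGramModel, context: str, rng: np.random.Generator) -> tuple[str, float]:
    """Draw one next residue from the model's conditional distribution."""
    return model.sample_next(context, rng)


class MonteCarloGenerator:
    """Grows oligopeptide candidates from seed residues with a fitted model.

    The generator is deterministic given ``config.seed``: each run uses a
    single named numpy Generator stream.
    """

    def __init__(self, model: NeuralNGramModel, config: GenerationConfig | None = None):
        if not hasattr(model, "params_"):
            raise GenerationError("generator requires a fitted NeuralNGramModel")
        self.model = model
        self.config = config or GenerationConfig()

    def extend_all(self, seeds: Sequence[str]) -> list[Candidate]:
        """Monte Carlo extension from every seed residue.

        Per cycle, each frontier state receives ``draws_per_step`` sampled
        extensions; distinct children are deduplicated (a child's step
        probability depends only on the residue drawn, so duplicates carry
        identical records). Every candidate of length >= min_emit_length is
        emitted, deduplicated across seeds keeping the max-score path.
        """
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        pool: dict[str, Candidate] = {}

        frontier: list[Candidate] = [
            Candidate(sequence=s, seed=s, step_probs=(), log_score=0.0)
            for s in seeds
        ]
        for s in seeds:
            if len(s) != 1:
                raise GenerationError(f"seed {s!r} must be a single residue")

        def emit(cand: Candidate) -> None:
            if len(cand.sequence) < cfg.min_emit_length:
                return
            prev = pool.get(cand.sequence)
            if prev is None or cand.log_score > prev.log_score:
                pool[cand.sequence] = cand

        while frontier and len(frontier[0].sequence) < cfg.max_length:
            children: dict[str, Candidate] = {}
            for state in frontier:
                probs = self.model.predict_proba(state.sequence)
                cdf = np.cumsum(probs)
                draws = rng.random(cfg.draws_per_step)
                idxs = np.unique(np.searchsorted(cdf, draws, side="right"))
                idxs = np.clip(idxs, 0, len(probs) - 1)
                for idx in idxs:
                    residue = AMINO_ACIDS[idx]
                    p = float(probs[idx])
                    child = Candidate(
                        sequence=state.sequence + residue,
                        seed=state.seed,
                        step_probs=state.step_probs + (p,),
                        log_score=state.log_score + math.log(p),
                    )
                    emit(child)
                    # inadmissible steps terminate the path: no admissible
                    # candidate can descend from them
                    if p > cfg.admission_threshold:
                        prev = children.get(child.sequence)
                        if prev is None or child.log_score > prev.log_score:
                            children[child.sequence] = child
            frontier = sorted(
                children.values(), key=lambda c: (-c.log_score, c.sequence)
            )[: cfg.max_frontier]

        return sorted(pool.values(), key=lambda c: (-c.log_score, c.sequence))


def filter_admissible(candidates: Iterable[Candidate], threshold: float = 1.0 / 20.0) -> list[Candidate]:
    """Keep candidates whose every step probability is strictly above threshold."""
    return [c for c in candidates if all(p > threshold for p in c.step_probs)]


def rank_and_truncate(candidates: Iterable[Candidate], keep_top: int = 100) -> list[Candidate]:
    """Descending probability-product order, lexicographic tie-break, truncated."""
    ranked = sorted(candidates, key=lambda c: (-c.log_score, c.sequence))
    return ranked[:keep_top]


def candidates_by_length(
    candidates: Iterable[Candidate], keep_top: int | None = 100
) -> dict[int, list[Candidate]]:
    """Group candidates by length, each group ranked and truncated.

    ``keep_top`` bounds each length group (None keeps everything) so each
    clustering tree receives a ranked pool of manageable size.
    """
    groups: dict[int, list[Candidate]] = {}
    for c in candidates:
        groups.setdefault(len(c.sequence), []).append(c)
    return {
        length: rank_and_truncate(group, keep_top=keep_top or len(group))
        for length, group in sorted(groups.items())
    }


def write_candidate_table(candidates: Sequence[Candidate], path: str | Path) -> None:
    """TSV with sequence, length, seed, score, log-score, step probs, rank."""
    with open(path, "w") as fh:
        fh.write("rank\tsequence\tlength\tseed\tscore\tlog_score\tstep_probs\n")
        for rank, c in enumerate(candidates, start=1):
            steps = ";".join(f"{p:.6g}" for p in c.step_probs)
            fh.write(
                f"{rank}\t{c.sequence}\t{len(c.sequence)}\t{c.seed}\t"
                f"{c.score:.6g}\t{c.log_score:.6g}\t{steps}\n"
            )


def write_candidate_fasta(candidates: Sequence[Candidate], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rank, c in enumerate(candidates, start=1):
            fh.write(f">cand_{rank} seed={c.seed} score={c.score:.6g}\n{c.sequence}\n")
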