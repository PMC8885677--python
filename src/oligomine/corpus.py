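"""Protein corpus handling: FASTA input, disorder-score tracks, IDR extraction
and residue-composition profiles.

Intrinsically disordered regions (IDRs) are taken to be maximal runs of
residues whose per-residue disorder score is strictly greater than a
threshold (default 0.5), the convention of IUPred-style predictors.
Coordinates are 0-based half-open internally and 1-based inclusive in file
output, matching the 1-based positions of IUPred track files.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 canonical amino acids, alphabetical.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

#: Residue codes that are legal in FASTA but not canonical amino acids.
NONCANONICAL = frozenset("XBZUJO*")


class CorpusError(ValueError):
    """Raised on malformed sequence or track input."""


@dataclass(frozen=True)
class ProteinRecord:
    """One identified amino-acid sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise CorpusError("protein record requires a non-empty id")
        if not self.sequence:
            raise CorpusError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - _AA_SET
        if bad:
            raise CorpusError(
                f"protein {self.id!r}: non-canonical residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DisorderTrack:
    """Per-residue disorder scores for one protein.

    ``binding_scores`` holds the optional fourth column of IUPred2A output
    (ANCHOR-style binding propensity); it is parsed but unused downstream.
    """

    protein_id: str
    residues: str
    scores: tuple[float, ...]
    binding_scores: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.scores) != len(self.residues):
            raise CorpusError(
                f"track {self.protein_id!r}: {len(self.scores)} scores for "
                f"{len(self.residues)} residues"
            )
        for i, s in enumerate(self.scores):
            if not (0.0 <= s <= 1.0):
                raise CorpusError(
                    f"track {self.protein_id!r}: score {s} at position {i + 1} "
                    "outside [0, 1]"
                )

    def __len__(self) -> int:
        return len(self.scores)


@dataclass(frozen=True)
class IDRSegment:
    """A maximal contiguous run of high-disorder residues.

    ``start``/``end`` are 0-based half-open coordinates into the parent
    protein.
    """

    protein_id: str
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise CorpusError(
                f"segment {self.protein_id!r}: bad interval [{self.start}, {self.end})"
            )
        if len(self.sequence) != self.end - self.start:
            raise CorpusError(
                f"segment {self.protein_id!r}: sequence length does not match interval"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ResidueFrequencyProfile:
    """Residue counts and normalized fractions over a sequence set."""

    counts: dict[str, int]
    fractions: dict[str, float]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def _sanitize(seq: str, record_id: str, policy: str) -> str:
    """Uppercase and apply the noncanonical-residue policy.

    policy "drop": remove noncanonical positions with a warning;
    policy "reject": raise on any noncanonical residue.
    """
    seq = seq.upper()
    bad = set(seq) - _AA_SET
    if not bad:
        return seq
    if policy == "reject":
        raise CorpusError(
            f"protein {record_id!r}: non-canonical residues {sorted(bad)}"
        )
    if policy != "drop":
        raise ValueError(f"unknown sanitization policy {policy!r}")
    n_before = len(seq)
    seq = "".join(c for c in seq if c in _AA_SET)
    logger.warning(
        "protein %r: dropped %d non-canonical residue(s) %s",
        record_id,
        n_before - len(seq),
        sorted(bad),
    )
    return seq


def read_fasta(path: str | Path, policy: str = "drop") -> list[ProteinRecord]:
    """Read a protein FASTA file into :class:`ProteinRecord` objects.

    Sequences are uppercased; residues outside the 20-letter alphabet are
    handled per ``policy`` ("drop" with a logged warning, or "reject").
    Entry order is preserved.
    """
    records: list[ProteinRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        if not entry.id:
            raise CorpusError(f"{path}: FASTA entry with empty header")
        seq = _sanitize(str(entry.seq), entry.id, policy)
        if not seq:
            raise CorpusError(f"{path}: entry {entry.id!r} has an empty sequence")
        records.append(ProteinRecord(id=entry.id, sequence=seq))
    return records


def write_fasta(records: Iterable[ProteinRecord | IDRSegment], path: str | Path) -> None:
    """Write records (proteins or IDR segments) as FASTA.

    Segment headers carry 1-based inclusive coordinates: ``id/start-end``.
    """
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, IDRSegment):
                fh.write(f">{rec.protein_id}/{rec.start + 1}-{rec.end}\n")
            else:
                fh.write(f">{rec.id}\n")
            fh.write(rec.sequence + "\n")


def read_disorder_track(path: str | Path, protein_id: str | None = None) -> DisorderTrack:
    """Parse an IUPred2A-style tab-separated disorder track.

    Data lines are ``position<TAB>residue<TAB>score[<TAB>binding_score]``
    with 1-based consecutive positions; lines starting with ``#`` are
    comments. A fourth (binding-score / ANCHOR) column is stored but
    otherwise ignored by the pipeline.
    """
    path = Path(path)
    if protein_id is None:
        protein_id = path.stem
    residues: list[str] = []
    scores: list[float] = []
    binding: list[float] = []
    have_binding = False
    expected_pos = 1
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) not in (3, 4):
                raise CorpusError(
                    f"{path}:{lineno}: expected 3 or 4 columns, got {len(fields)}"
                )
            try:
                pos = int(fields[0])
                score = float(fields[2])
            except ValueError as exc:
                raise CorpusError(f"{path}:{lineno}: unparseable field ({exc})") from exc
            if pos != expected_pos:
                raise CorpusError(
                    f"{path}:{lineno}: position {pos}, expected {expected_pos} "
                    "(positions must be 1-based and consecutive)"
                )
            if not (0.0 <= score <= 1.0):
                raise CorpusError(f"{path}:{lineno}: score {score} outside [0, 1]")
            residues.append(fields[1].upper())
            scores.append(score)
            if len(fields) == 4:
                have_binding = True
                binding.append(float(fields[3]))
            expected_pos += 1
    if not scores:
        raise CorpusError(f"{path}: no data lines")
    return DisorderTrack(
        protein_id=protein_id,
        residues="".join(residues),
        scores=tuple(scores),
        binding_scores=tuple(binding) if have_binding else None,
    )


def write_disorder_track(track: DisorderTrack, path: str | Path) -> None:
    """Write a track in the 3-column IUPred-style dialect (1-based positions)."""
    with open(path, "w") as fh:
        fh.write(f"# disorder track for {track.protein_id}\n")
        fh.write("# POS\tRES\tIUPRED2\n")
        for i, (res, score) in enumerate(zip(track.residues, track.scores), start=1):
            fh.write(f"{i}\t{res}\t{score:.4f}\n")


def extract_idrs(
    track: DisorderTrack, threshold: float = 0.5, min_length: int = 3
) -> list[IDRSegment]:
    """Extract maximal runs of residues with score strictly above ``threshold``.

    Residues scoring exactly at the threshold are excluded (strict
    inequality). Runs shorter than ``min_length`` are discarded. Segments
    are returned sorted by start and never overlap.
    """
    segments: list[IDRSegment] = []
    run_start: int | None = None
    n = len(track)
    for i in range(n + 1):
        inside = i < n and track.scores[i] > threshold
        if inside and run_start is None:
            run_start = i
        elif not inside and run_start is not None:
            if i - run_start >= min_length:
                segments.append(
                    IDRSegment(
                        protein_id=track.protein_id,
                        start=run_start,
                        end=i,
                        sequence=track.residues[run_start:i],
                    )
                )
            run_start = None
    return segments


def write_idr_table(segments: Iterable[IDRSegment], path: str | Path) -> None:
    """Write IDR segments as a TSV with 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write("protein_id\tstart\tend\tsequence\n")
        for seg in segments:
            fh.write(f"{seg.protein_id}\t{seg.start + 1}\t{seg.end}\t{seg.sequence}\n")


def frequency_profile(sequences: Sequence[str]) -> ResidueFrequencyProfile:
    """Residue counts and fractions over a set of sequences.

    With empty input, all counts are zero and fractions are NaN (flagged by
    a warning) so that accidental use downstream surfaces immediately.
    """
    counts = {aa: 0 for aa in AMINO_ACIDS}
    for seq in sequences:
        for ch in seq:
            if ch not in _AA_SET:
                raise CorpusError(f"non-canonical residue {ch!r} in profile input")
            counts[ch] += 1
    total = sum(counts.values())
    if total == 0:
        warnings.warn("frequency_profile: empty input, fractions undefined")
        fractions = {aa: float("nan") for aa in AMINO_ACIDS}
    else:
        fractions = {aa: c / total for aa, c in counts.items()}
    return ResidueFrequencyProfile(counts=counts, fractions=fractions)


def top_k_residues(profile: ResidueFrequencyProfile, k: int = 10) -> list[str]:
    """The ``k`` most frequent residues, ties broken alphabetically.

    Residues with zero count never qualify; if fewer than ``k`` residues
    have nonzero counts, all of them are returned with a warning.
    """
    if k < 1:
        raise ValueError("k must be positive")
    nonzero = [aa for aa in AMINO_ACIDS if profile.counts[aa] > 0]
    if not nonzero:
        raise ValueError("top_k_residues requires a profile with positive total count")
    ranked = sorted(nonzero, key=lambda aa: (-profile.counts[aa], aa))
    if k > len(ranked):
        warnings.warn(
            f"top_k_residues: only {len(ranked)} residues with nonzero count (k={k})"
        )
        return ranked
    return ranked[:k]
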