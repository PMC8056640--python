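"""Core domain containers shared across the pipeline.

Coordinates are 0-based half-open everywhere inside the package; the GTF
reader/writer in :mod:`lncflow.io` is the only place the 1-based inclusive
shift happens.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

from intervaltree import IntervalTree

STRANDS = ("+", "-")
CONDITIONS = ("SD1", "SD2", "NB")


@dataclass(frozen=True)
class TranscriptModel:
    """A stranded, (possibly) multi-exon transcript on one chromosome.

    ``exons`` are 0-based half-open ``(start, end)`` intervals, sorted and
    non-overlapping.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r} for {self.transcript_id}")
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        prev_end = None
        for start, end in self.exons:
            if end <= start:
                raise ValueError(
                    f"empty/inverted exon ({start}, {end}) in {self.transcript_id}"
                )
            if prev_end is not None and start < prev_end:
                raise ValueError(
                    f"exons of {self.transcript_id} are unsorted or overlapping"
                )
            prev_end = end

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def spliced_length(self) -> int:
        return sum(end - start for start, end in self.exons)

    def introns(self) -> tuple[tuple[int, int], ...]:
        """Gaps between consecutive exons, 0-based half-open."""
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
            if self.exons[i + 1][0] > self.exons[i][1]
        )

    def span_overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


class AnnotationSet:
    """A collection of transcripts with gene and interval indexes.

    ``gene_index`` maps gene_id to its transcripts; interval queries are
    served per chromosome by an interval tree over transcript spans.
    """

    def __init__(self, transcripts: Iterable[TranscriptModel]):
        self.transcripts: list[TranscriptModel] = list(transcripts)
        self.gene_index: dict[str, list[TranscriptModel]] = defaultdict(list)
        self._trees: dict[str, IntervalTree] = {}
        seen: set[str] = set()
        for t in self.transcripts:
            if t.transcript_id in seen:
                raise ValueError(f"duplicate transcript_id {t.transcript_id!r}")
            seen.add(t.transcript_id)
            self.gene_index[t.gene_id].append(t)
            self._trees.setdefault(t.chrom, IntervalTree()).addi(t.start, t.end, t)
        self.gene_index = dict(self.gene_index)

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self.transcripts)

    @property
    def transcript_ids(self) -> set[str]:
        return {t.transcript_id for t in self.transcripts}

    @property
    def gene_ids(self) -> set[str]:
        return set(self.gene_index)

    @property
    def chroms(self) -> set[str]:
        return set(self._trees)

    def overlapping(
        self, chrom: str, start: int, end: int, strand: str | None = None
    ) -> list[TranscriptModel]:
        """Transcripts whose span overlaps [start, end); optionally one strand."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(start, end)]
        if strand is not None:
            hits = [t for t in hits if t.strand == strand]
        hits.sort(key=lambda t: (t.start, t.end, t.transcript_id))
        return hits

    def gene_span(self, gene_id: str) -> tuple[str, int, int]:
        """Chromosome and union span over all transcripts of a gene."""
        ts = self.gene_index[gene_id]
        chroms = {t.chrom for t in ts}
        if len(chroms) != 1:
            raise ValueError(f"gene {gene_id} spans multiple chromosomes")
        return ts[0].chrom, min(t.start for t in ts), max(t.end for t in ts)


@dataclass(frozen=True)
class Sample:
    sample_id: str
    condition: str
    replicate: int


class SampleSheet:
    """The study design: sample ids mapped to condition and replicate.

    The default design is 3 conditions (SD1, SD2, NB) x 3 biological
    replicates; any condition used for differential expression must carry
    at least two replicates.
    """

    def __init__(
        self,
        samples: Sequence[Sample],
        allowed_conditions: Sequence[str] = CONDITIONS,
    ):
        ids = [s.sample_id for s in samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample_ids are not unique")
        for s in samples:
            if s.condition not in allowed_conditions:
                raise ValueError(
                    f"unknown condition {s.condition!r} for sample {s.sample_id}"
                )
        self.samples = list(samples)
        self.allowed_conditions = tuple(allowed_conditions)

    @classmethod
    def default_design(cls) -> "SampleSheet":
        """SD1/SD2/NB x replicates 1..3 with ids like ``SD1_1``."""
        return cls(
            [
                Sample(f"{cond}_{rep}", cond, rep)
                for cond in CONDITIONS
                for rep in (1, 2, 3)
            ]
        )

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[Sample]:
        return iter(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            if s.condition not in seen:
                seen.append(s.condition)
        return seen

    def samples_for(self, condition: str) -> list[str]:
        return [s.sample_id for s in self.samples if s.condition == condition]
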