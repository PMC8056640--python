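"""lncRNA candidate filtering and positional classification.

Assembled transcripts are filtered to high-confidence long noncoding RNAs
(spliced length strictly greater than 200 bp, at least two exons, noncoding
consensus) and then assigned one of four positional classes relative to the
reference (protein-coding) gene models:

* ``sense`` — an exon overlaps a reference exon on the same strand;
* ``intronic`` — the transcript span lies fully within a single intron of a
  same-strand reference transcript;
* ``antisense`` — the span overlaps an opposite-strand reference transcript;
* ``lincRNA`` — none of the above (intergenic).

The cascade is evaluated in that order and the first matching rule wins, so
the four classes form a deterministic partition.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .models import AnnotationSet, TranscriptModel

logger = logging.getLogger(__name__)

LNCRNA_CLASSES = ("lincRNA", "intronic", "sense", "antisense")

_STOPS = {"TAA", "TAG", "TGA"}
_VALID_BASES = set("ACGTN")

#: in-house coding call threshold: ORFs of at least 100 codons (300 nt)
DEFAULT_ORF_THRESHOLD_NT = 300
DEFAULT_MIN_LENGTH_BP = 200
DEFAULT_MIN_EXONS = 2


def find_longest_orf(sequence: str) -> int:
    """Length in nt (stop codon included) of the longest ATG-initiated,
    stop-terminated reading frame on the given strand; 0 if none.

    All three frames are scanned; codons containing ``N`` match neither ATG
    nor a stop codon.
    """
    seq = sequence.upper()
    bad = set(seq) - _VALID_BASES
    if bad:
        raise ValueError(f"illegal characters in sequence: {sorted(bad)}")
    best = 0
    n = len(seq)
    for frame in range(3):
        start: int | None = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if start is None:
                if codon == "ATG":
                    start = pos
            elif codon in _STOPS:
                best = max(best, pos + 3 - start)
                start = None
    return best


@dataclass(frozen=True)
class CodingPotentialVerdict:
    """Combined in-house and external coding-potential assessment.

    The consensus is ``noncoding`` only when the in-house call and every
    provided external tool call agree on ``noncoding`` (intersection rule).
    """

    transcript_id: str
    orf_length_nt: int
    in_house_call: str
    external_calls: dict[str, str]
    consensus: str

    def __post_init__(self) -> None:
        if self.orf_length_nt % 3 != 0:
            raise ValueError(
                f"ORF length {self.orf_length_nt} not divisible by 3 "
                f"({self.transcript_id})"
            )


def score_coding_potential(
    transcript: TranscriptModel,
    sequence: str,
    external: Mapping[str, Mapping[str, str]] | None = None,
    orf_threshold_nt: int = DEFAULT_ORF_THRESHOLD_NT,
) -> CodingPotentialVerdict:
    """Score one transcript; ``external`` maps transcript -> tool -> call."""
    if len(sequence) != transcript.spliced_length:
        raise ValueError(
            f"sequence length {len(sequence)} != spliced length "
            f"{transcript.spliced_length} for {transcript.transcript_id}"
        )
    orf = find_longest_orf(sequence)
    in_house = "coding" if orf >= orf_threshold_nt else "noncoding"
    ext = dict((external or {}).get(transcript.transcript_id, {}))
    calls = [in_house, *ext.values()]
    consensus = "noncoding" if all(c == "noncoding" for c in calls) else "coding"
    return CodingPotentialVerdict(
        transcript_id=transcript.transcript_id,
        orf_length_nt=orf,
        in_house_call=in_house,
        external_calls=ext,
        consensus=consensus,
    )


def score_all(
    transcripts: Iterable[TranscriptModel],
    sequences: Mapping[str, str],
    external: Mapping[str, Mapping[str, str]] | None = None,
    orf_threshold_nt: int = DEFAULT_ORF_THRESHOLD_NT,
) -> dict[str, CodingPotentialVerdict]:
    transcripts = list(transcripts)
    if external:
        known = {t.transcript_id for t in transcripts}
        for tid in set(external) - known:
            logger.warning("external verdict for unknown transcript %s ignored", tid)
    return {
        t.transcript_id: score_coding_potential(
            t, sequences[t.transcript_id], external, orf_threshold_nt
        )
        for t in transcripts
    }


def filter_lncrna_candidates(
    transcripts: Iterable[TranscriptModel],
    verdicts: Mapping[str, CodingPotentialVerdict],
    reference_ids: set[str] | None = None,
    min_length_bp: int = DEFAULT_MIN_LENGTH_BP,
    min_exons: int = DEFAULT_MIN_EXONS,
) -> list[TranscriptModel]:
    """Retain transcripts with spliced length strictly > ``min_length_bp``,
    at least ``min_exons`` exons and a noncoding consensus.

    Transcripts whose ids appear in ``reference_ids`` (the annotated mRNA
    universe) are excluded up front.
    """
    reference_ids = reference_ids or set()
    kept = []
    for t in transcripts:
        if t.transcript_id in reference_ids:
            continue
        if t.spliced_length <= min_length_bp or t.exon_count < min_exons:
            continue
        verdict = verdicts.get(t.transcript_id)
        if verdict is None:
            raise ValueError(f"no coding-potential verdict for {t.transcript_id}")
        if verdict.consensus != "noncoding":
            continue
        kept.append(t)
    return kept


def _exon_overlap_same_strand(t: TranscriptModel, ref: AnnotationSet) -> bool:
    for other in ref.overlapping(t.chrom, t.start, t.end, strand=t.strand):
        for es, ee in t.exons:
            for os_, oe in other.exons:
                if es < oe and os_ < ee:
                    return True
    return False


def _contained_in_intron_same_strand(t: TranscriptModel, ref: AnnotationSet) -> bool:
    for other in ref.overlapping(t.chrom, t.start, t.end, strand=t.strand):
        for is_, ie in other.introns():
            if is_ <= t.start and t.end <= ie:
                return True
    return False


def _span_overlap_opposite_strand(t: TranscriptModel, ref: AnnotationSet) -> bool:
    opposite = "-" if t.strand == "+" else "+"
    return bool(ref.overlapping(t.chrom, t.start, t.end, strand=opposite))


def classify_position(t: TranscriptModel, ref: AnnotationSet) -> str:
    """Assign one positional class; first matching rule of the cascade wins."""
    if _exon_overlap_same_strand(t, ref):
        return "sense"
    if _contained_in_intron_same_strand(t, ref):
        return "intronic"
    if _span_overlap_opposite_strand(t, ref):
        return "antisense"
    return "lincRNA"


def classify_all(
    lncrnas: Iterable[TranscriptModel], ref: AnnotationSet
) -> dict[str, str]:
    return {t.transcript_id: classify_position(t, ref) for t in lncrnas}


def class_census(
    lncrnas: Sequence[TranscriptModel],
    classes: Mapping[str, str],
    chrom_lengths: Mapping[str, int],
) -> dict:
    """Per-class counts and per-chromosome lncRNA density (per Mb)."""
    counts = {cls: 0 for cls in LNCRNA_CLASSES}
    per_chrom: dict[str, int] = {}
    for t in lncrnas:
        cls = classes[t.transcript_id]
        if cls not in counts:
            raise ValueError(f"unknown class {cls!r} for {t.transcript_id}")
        counts[cls] += 1
        per_chrom[t.chrom] = per_chrom.get(t.chrom, 0) + 1
    density = {}
    for chrom, n in sorted(per_chrom.items()):
        if chrom not in chrom_lengths:
            raise ValueError(f"missing length for chromosome {chrom}")
        density[chrom] = n / (chrom_lengths[chrom] / 1e6)
    return {"class_counts": counts, "total": len(lncrnas), "density_per_mb": density}
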