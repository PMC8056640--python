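"""Readers and writers for the plain-text formats the pipeline exchanges.

GTF files hold 1-based inclusive coordinates; everything returned to the rest
of the package is 0-based half-open. Only ``exon`` feature rows are
interpreted when reading GTF; other rows are counted and skipped.
"""
from __future__ import annotations

import logging
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.feature import feature_from_line

from .models import AnnotationSet, Sample, SampleSheet, TranscriptModel

logger = logging.getLogger(__name__)


class GtfParseError(ValueError):
    pass


def read_gtf(path: str | Path) -> AnnotationSet:
    """Parse a GTF into an :class:`AnnotationSet`.

    Transcripts are reconstructed by grouping ``exon`` rows by
    ``transcript_id``; exon rows of one transcript on mixed chromosomes or
    strands raise a consistency error.
    """
    exons: dict[str, list[tuple[str, str, str, int, int]]] = defaultdict(list)
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise GtfParseError(
                    f"{path}: malformed GTF line {lineno}: expected 9 fields"
                )
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # gffutils raises assorted types
                raise GtfParseError(f"{path}: malformed GTF line {lineno}: {exc}") from exc
            if feat.featuretype != "exon":
                skipped += 1
                continue
            try:
                gene_id = feat.attributes["gene_id"][0]
                transcript_id = feat.attributes["transcript_id"][0]
            except (KeyError, IndexError) as exc:
                raise GtfParseError(
                    f"{path}: exon line {lineno} lacks gene_id/transcript_id"
                ) from exc
            if feat.strand not in ("+", "-"):
                raise GtfParseError(
                    f"{path}: exon line {lineno} has no usable strand ({feat.strand!r})"
                )
            # GTF 1-based inclusive -> 0-based half-open
            exons[transcript_id].append(
                (gene_id, feat.seqid, feat.strand, feat.start - 1, feat.end)
            )
    if skipped:
        logger.info("read_gtf(%s): skipped %d non-exon feature rows", path, skipped)

    transcripts = []
    for tid, rows in exons.items():
        genes = {r[0] for r in rows}
        chroms = {r[1] for r in rows}
        strands = {r[2] for r in rows}
        if len(chroms) > 1 or len(strands) > 1 or len(genes) > 1:
            raise GtfParseError(
                f"{path}: transcript {tid} has exons on mixed "
                f"chromosomes/strands/genes"
            )
        ivals = sorted((start, end) for _, _, _, start, end in rows)
        transcripts.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=rows[0][0],
                chrom=rows[0][1],
                strand=rows[0][2],
                exons=tuple(ivals),
            )
        )
    transcripts.sort(key=lambda t: (t.chrom, t.start, t.end, t.transcript_id))
    return AnnotationSet(transcripts)


def write_gtf(annotation: AnnotationSet, path: str | Path, source: str = "lncflow") -> Path:
    """Write exon rows for every transcript (1-based inclusive on disk)."""
    path = Path(path)
    with open(path, "w") as fh:
        for t in sorted(
            annotation.transcripts, key=lambda t: (t.chrom, t.start, t.transcript_id)
        ):
            for start, end in t.exons:
                attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
                fh.write(
                    "\t".join(
                        [t.chrom, source, "exon", str(start + 1), str(end),
                         ".", t.strand, ".", attrs]
                    )
                    + "\n"
                )
    return path


def read_fasta(path: str | Path) -> dict[str, str]:
    """Transcript sequences keyed by record id, uppercased."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> Path:
    path = Path(path)
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")
    return path


def read_counts(path: str | Path, samples: SampleSheet) -> pd.DataFrame:
    """Read an integer count TSV (features x samples).

    The first column is the feature id; the remaining columns must cover the
    sample sheet. Column order is normalized to sample-sheet order, so a
    permuted file yields an identical matrix.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate feature ids {dups}")
    missing = [s for s in samples.sample_ids if s not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing sample columns {missing}")
    df = df[samples.sample_ids]
    float_view = df.to_numpy()
    try:
        as_int = df.astype("int64")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: non-integer count cell") from exc
    if (as_int.to_numpy() != float_view).any():
        raise ValueError(f"{path}: non-integer count cell")
    if (as_int.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative count")
    return as_int


def write_counts(counts: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    counts.to_csv(path, sep="\t", index_label="feature_id")
    return path


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t")
    return SampleSheet(
        [
            Sample(str(r.sample_id), str(r.condition), int(r.replicate))
            for r in df.itertuples()
        ]
    )


def write_sample_sheet(samples: SampleSheet, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [
            {"sample_id": s.sample_id, "condition": s.condition, "replicate": s.replicate}
            for s in samples
        ]
    ).to_csv(path, sep="\t", index=False)
    return path


def read_gene_sets(path: str | Path) -> dict[str, dict]:
    """Gene-set TSV (``term_id<TAB>term_name<TAB>gene_id``) -> term table.

    Returns ``{term_id: {"name": term_name, "genes": set}}``. Duplicate
    gene rows collapse (set semantics).
    """
    terms: dict[str, dict] = {}
    df = pd.read_csv(
        path, sep="\t", names=["term_id", "term_name", "gene_id"], dtype=str
    )
    for row in df.itertuples():
        entry = terms.setdefault(row.term_id, {"name": row.term_name, "genes": set()})
        entry["genes"].add(row.gene_id)
    return terms


def write_gene_sets(terms: Mapping[str, dict], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for term_id in sorted(terms):
            name = terms[term_id]["name"]
            for gene in sorted(terms[term_id]["genes"]):
                fh.write(f"{term_id}\t{name}\t{gene}\n")
    return path


EDGE_COLUMNS = ["source", "interaction", "target", "weight"]


def write_edge_list(network, path: str | Path) -> Path:
    """Cytoscape-importable edge table for a regulatory network.

    Columns: source (lncRNA id), interaction (cis|trans), target (mRNA id),
    weight (PCC for trans edges, negative genomic distance for cis edges).
    """
    path = Path(path)
    rows = []
    for lnc, mrna, mode, pair in network.iter_edges():
        weight = pair.pcc if mode == "trans" else -float(pair.distance_bp)
        rows.append({"source": lnc, "interaction": mode, "target": mrna, "weight": weight})
    rows.sort(key=lambda r: (r["source"], r["target"], r["interaction"]))
    pd.DataFrame(rows, columns=EDGE_COLUMNS).to_csv(path, sep="\t", index=False)
    return path


def read_edge_list(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})


def read_external_verdicts(path: str | Path) -> dict[str, dict[str, str]]:
    """External coding-potential calls: ``transcript_id<TAB>tool<TAB>call``.

    ``call`` is ``coding`` or ``noncoding``; returns transcript -> tool -> call.
    """
    out: dict[str, dict[str, str]] = defaultdict(dict)
    df = pd.read_csv(path, sep="\t", names=["transcript_id", "tool", "call"], dtype=str)
    for row in df.itertuples():
        if row.call not in ("coding", "noncoding"):
            raise ValueError(f"{path}: invalid call {row.call!r} for {row.transcript_id}")
        out[row.transcript_id][row.tool] = row.call
    return dict(out)
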