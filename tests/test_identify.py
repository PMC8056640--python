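import numpy as np
import pytest

from lncflow.identify import (
    class_census,
    classify_position,
    filter_lncrna_candidates,
    find_longest_orf,
    score_all,
    score_coding_potential,
)
from lncflow.models import AnnotationSet, TranscriptModel


def brute_force_longest_orf(seq: str) -> int:
    """Exhaustive scan over all ATG/stop pairs in all 3 frames."""
    stops = {"TAA", "TAG", "TGA"}
    best = 0
    n = len(seq)
    for start in range(n - 2):
        if seq[start : start + 3] != "ATG":
            continue
        for stop in range(start + 3, n - 2, 3):
            if seq[stop : stop + 3] in stops:
                best = max(best, stop + 3 - start)
                break
    return best


class TestFindLongestOrf:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("ATGAAATAG", 9),          # single complete ORF, stop included
            ("CCCCCC", 0),             # no ATG
            ("", 0),                   # empty is not an error
            ("ATGAAA", 0),             # no stop codon
            ("AATGAAATAGC", 9),        # frame 1
            ("ATGNNNTAG", 9),          # N inside an open frame is passed over
            ("ATNAAATAG", 0),          # N never completes an ATG
            ("ATGTANTAG", 9),          # N never completes a stop
        ],
    )
    def test_known_cases(self, seq, expected):
        assert find_longest_orf(seq) == expected

    def test_illegal_character(self):
        with pytest.raises(ValueError, match="illegal"):
            find_longest_orf("ATGXAATAG")

    def test_matches_brute_force_on_random_sequences(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            seq = "".join(rng.choice(list("ACGT"), size=1000))
            assert find_longest_orf(seq) == brute_force_longest_orf(seq)


def _transcript(tid="t1", length=300, exons=2):
    step = length // exons
    ivals = tuple((i * (step + 100), i * (step + 100) + step) for i in range(exons))
    # pad the final exon so the spliced length is exact
    last = ivals[-1]
    ivals = ivals[:-1] + ((last[0], last[0] + length - step * (exons - 1)),)
    return TranscriptModel(tid, tid.split(".")[0], "chr1", "+", ivals)


class TestCodingPotential:
    def test_short_orf_is_noncoding(self):
        t = _transcript(length=90)
        v = score_coding_potential(t, "ATGAAATAG" + "C" * 81)
        assert v.orf_length_nt == 9
        assert v.in_house_call == "noncoding"
        assert v.consensus == "noncoding"

    def test_external_coding_call_overrides(self):
        t = _transcript(length=90)
        external = {"t1": {"CPC": "coding"}}
        v = score_coding_potential(t, "ATGAAATAG" + "C" * 81, external)
        assert v.in_house_call == "noncoding"
        assert v.consensus == "coding"

    def test_threshold_monotonicity(self):
        t = _transcript(length=600)
        seq = "C" * 99 + "ATG" + "AAA" * 120 + "TAG" + "C" * (600 - 99 - 366)
        calls = [
            score_coding_potential(t, seq, orf_threshold_nt=thr).in_house_call
            for thr in (150, 300, 366, 367, 600)
        ]
        # raising the threshold never converts noncoding back to coding
        assert calls == ["coding", "coding", "coding", "noncoding", "noncoding"]

    def test_unknown_external_transcript_warned_and_ignored(self, caplog):
        t = _transcript(length=90)
        with caplog.at_level("WARNING"):
            verdicts = score_all([t], {"t1": "C" * 90}, {"ghost": {"CPC": "coding"}})
        assert verdicts["t1"].consensus == "noncoding"
        assert "ghost" in caplog.text


class TestFilterCandidates:
    def _verdict_all_noncoding(self, transcripts):
        return score_all(transcripts, {t.transcript_id: "C" * t.spliced_length
                                       for t in transcripts})

    def test_boundary_rules(self):
        one_exon = TranscriptModel("a", "a", "chr1", "+", ((0, 500),))
        exactly_200 = _transcript("b", length=200)
        just_over = _transcript("c", length=201)
        transcripts = [one_exon, exactly_200, just_over]
        verdicts = self._verdict_all_noncoding(transcripts)
        kept = filter_lncrna_candidates(transcripts, verdicts)
        # 1-exon rejected; 200 bp exactly rejected (strict >); 201 bp kept
        assert [t.transcript_id for t in kept] == ["c"]

    def test_reference_ids_excluded_first(self):
        t = _transcript("known.t1", length=400)
        verdicts = self._verdict_all_noncoding([t])
        assert filter_lncrna_candidates([t], verdicts, reference_ids={"known.t1"}) == []


def _ref_gene(gene_id="g1", chrom="chr1", strand="+", start=10_000):
    exons = ((start, start + 500), (start + 1500, start + 2000),
             (start + 3000, start + 3500))
    return TranscriptModel(f"{gene_id}.t1", gene_id, chrom, strand, exons)


class TestClassifyPosition:
    @pytest.fixture
    def ref(self):
        return AnnotationSet([_ref_gene("g1", strand="+"), _ref_gene("g2", strand="-",
                                                                     start=50_000)])

    def test_intergenic(self, ref):
        t = TranscriptModel("x", "x", "chr1", "+", ((20_000, 20_150), (20_250, 20_400)))
        assert classify_position(t, ref) == "lincRNA"

    def test_intronic_same_strand(self, ref):
        t = TranscriptModel("x", "x", "chr1", "+", ((10_600, 10_750), (10_850, 11_000)))
        assert classify_position(t, ref) == "intronic"

    def test_sense_exon_overlap(self, ref):
        t = TranscriptModel("x", "x", "chr1", "+", ((9_900, 10_100), (10_600, 10_800)))
        assert classify_position(t, ref) == "sense"

    def test_antisense_span_overlap(self, ref):
        t = TranscriptModel("x", "x", "chr1", "-", ((10_400, 10_600), (10_700, 10_900)))
        assert classify_position(t, ref) == "antisense"

    def test_opposite_strand_intron_containment_is_antisense(self, ref):
        t = TranscriptModel("x", "x", "chr1", "-", ((10_600, 10_750), (10_850, 11_000)))
        assert classify_position(t, ref) == "antisense"

    def test_recovers_planted_positional_classes(self, study):
        lnc = [t for t in study.assembled
               if t.transcript_id in study.truth.positional_class]
        for t in lnc:
            assert (
                classify_position(t, study.reference)
                == study.truth.positional_class[t.transcript_id]
            )

    def test_agrees_with_brute_force_on_random_annotations(self):
        rng = np.random.default_rng(7)
        genes = []
        for i in range(60):
            start = int(rng.integers(0, 180_000))
            strand = "+" if rng.random() < 0.5 else "-"
            n_ex = int(rng.integers(1, 4))
            exons, pos = [], start
            for _ in range(n_ex):
                length = int(rng.integers(100, 600))
                exons.append((pos, pos + length))
                pos += length + int(rng.integers(200, 1200))
            genes.append(
                TranscriptModel(f"g{i}.t1", f"g{i}", "chr1", strand, tuple(exons))
            )
        ref = AnnotationSet(genes)
        for i in range(500):
            start = int(rng.integers(0, 190_000))
            strand = "+" if rng.random() < 0.5 else "-"
            e1 = (start, start + int(rng.integers(50, 400)))
            gap = int(rng.integers(50, 500))
            e2_start = e1[1] + gap
            e2 = (e2_start, e2_start + int(rng.integers(50, 400)))
            t = TranscriptModel(f"q{i}", f"q{i}", "chr1", strand, (e1, e2))
            assert classify_position(t, ref) == brute_force_classify(t, genes)


def brute_force_classify(t, genes):
    """All-pairs interval scan re-implementing the decision cascade."""
    same = [g for g in genes if g.strand == t.strand]
    opposite = [g for g in genes if g.strand != t.strand]
    for g in same:
        for es, ee in t.exons:
            for gs, ge in g.exons:
                if es < ge and gs < ee:
                    return "sense"
    for g in same:
        for i in range(len(g.exons) - 1):
            intron = (g.exons[i][1], g.exons[i + 1][0])
            if intron[0] <= t.start and t.end <= intron[1]:
                return "intronic"
    for g in opposite:
        if t.start < g.end and g.start < t.end:
            return "antisense"
    return "lincRNA"


class TestClassCensus:
    def test_density_and_totals(self):
        lncs = [
            TranscriptModel(f"l{i}", f"l{i}", "chr1", "+",
                            ((i * 1000, i * 1000 + 150), (i * 1000 + 250, i * 1000 + 400)))
            for i in range(7)
        ]
        classes = {t.transcript_id: "lincRNA" for t in lncs}
        census = class_census(lncs, classes, {"chr1": 2_000_000})
        assert census["density_per_mb"]["chr1"] == pytest.approx(3.5)
        assert census["total"] == 7
        assert sum(census["class_counts"].values()) == 7

    def test_empty_set(self):
        census = class_census([], {}, {"chr1": 1_000_000})
        assert census["total"] == 0
        assert all(v == 0 for v in census["class_counts"].values())

    def test_missing_chromosome_length_errors(self):
        t = TranscriptModel("l0", "l0", "chrZ", "+", ((0, 150), (250, 400)))
        with pytest.raises(ValueError, match="chrZ"):
            class_census([t], {"l0": "lincRNA"}, {"chr1": 1_000_000})

    def test_partition_on_simulated_study(self, study):
        from lncflow.identify import classify_all

        lnc = [t for t in study.assembled
               if t.transcript_id in study.truth.positional_class]
        classes = classify_all(lnc, study.reference)
        census = class_census(lnc, classes, study.chrom_lengths)
        assert sum(census["class_counts"].values()) == len(lnc)
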