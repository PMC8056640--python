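"""End-to-end orchestration: simulate/load inputs, run every stage, write a
machine-readable summary.

The default thresholds are the study's stated cutoffs: lncRNA candidates
need spliced length > 200 bp and >= 2 exons; the in-house coding call uses a
300 nt ORF; expressed features need mean FPKM > 0.1 (lncRNA) or > 1 (mRNA);
DE calls need FDR < 0.05 and |log2FC| >= 1; cis targets lie within 100 kb;
trans targets need |PCC| > 0.9 with P < 0.01; enrichment uses corrected
P < 0.05. Identical config and seed produce a byte-identical summary.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import de as lde
from . import expression as lexpr
from . import flowering as lflower
from . import identify as lident
from . import io as lio
from . import network as lnet
from . import simulate as lsim
from . import targets as ltarg
from .enrich import enrich as run_enrichment
from .enrich import results_to_frame as enrichment_frame

logger = logging.getLogger(__name__)

COMPARISONS = ("SD1_vs_SD2", "SD2_vs_NB")


@dataclass
class PipelineConfig:
    """All inputs, outputs and thresholds of one run."""

    outdir: str = "lncflow_run"
    simulate: bool = True
    seed: int = 0
    # input paths, used when simulate is False
    reference_gtf: str | None = None
    assembled_gtf: str | None = None
    transcripts_fasta: str | None = None
    counts_tsv: str | None = None
    samples_tsv: str | None = None
    gene_sets_tsv: str | None = None
    external_verdicts_tsv: str | None = None
    # thresholds (defaults reproduce the study's stated cutoffs)
    min_length_bp: int = 200
    min_exons: int = 2
    orf_threshold_nt: int = 300
    fpkm_threshold_lncrna: float = 0.1
    fpkm_threshold_mrna: float = 1.0
    fdr_threshold: float = 0.05
    min_abs_log2fc: float = 1.0
    cis_window_bp: int = 100_000
    pcc_cutoff: float = 0.9
    pcc_p_cutoff: float = 0.01
    enrich_alpha: float = 0.05
    comparisons: tuple[str, str] = COMPARISONS
    sim: lsim.SimulationConfig | None = None

    def resolved_sim(self) -> lsim.SimulationConfig:
        if self.sim is not None:
            return dataclasses.replace(self.sim, seed=self.seed)
        return lsim.SimulationConfig(seed=self.seed)


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    if d.get("sim") and isinstance(d["sim"].get("n_lncrnas_per_class"), dict):
        d["sim"]["n_lncrnas_per_class"] = dict(d["sim"]["n_lncrnas_per_class"])
    return d


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage, write per-stage TSVs plus ``summary.json``.

    Returns the summary dictionary. Stage outputs are pure functions of the
    inputs and config; reruns with the same seed are byte-identical.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # ------------------------------------------------------------------ inputs
    truth = None
    gene_sets = None
    if config.simulate:
        study = lsim.simulate_study(config.resolved_sim())
        study.write(outdir / "inputs")
        reference, assembled = study.reference, study.assembled
        sequences, counts = study.sequences, study.counts
        samples, lengths = study.samples, study.feature_lengths
        chrom_lengths = study.chrom_lengths
        truth = study.truth
        gene_sets = lsim.emit_gene_sets(truth, study.config)
        lio.write_gene_sets(gene_sets, outdir / "inputs" / "gene_sets.tsv")
    else:
        for name in ("reference_gtf", "assembled_gtf", "transcripts_fasta",
                     "counts_tsv", "samples_tsv"):
            if getattr(config, name) is None:
                raise ValueError(f"pipeline input {name} is required unless simulating")
        reference = lio.read_gtf(config.reference_gtf)
        assembled = lio.read_gtf(config.assembled_gtf)
        sequences = lio.read_fasta(config.transcripts_fasta)
        samples = lio.read_sample_sheet(config.samples_tsv)
        counts = lio.read_counts(config.counts_tsv, samples)
        lengths = pd.Series(
            {
                t.transcript_id: t.spliced_length
                for t in assembled
                if t.transcript_id in counts.index
            }
        )
        for gid in reference.gene_ids:
            if gid in counts.index:
                lengths[gid] = max(t.spliced_length for t in reference.gene_index[gid])
        chrom_lengths = {
            c: max(t.end for t in assembled if t.chrom == c) for c in assembled.chroms
        }
        if config.gene_sets_tsv:
            gene_sets = lio.read_gene_sets(config.gene_sets_tsv)

    external = (
        lio.read_external_verdicts(config.external_verdicts_tsv)
        if config.external_verdicts_tsv
        else None
    )

    # ---------------------------------------------------------- identification
    reference_ids = reference.transcript_ids
    candidates = [t for t in assembled if t.transcript_id not in reference_ids]
    verdicts = lident.score_all(
        candidates, sequences, external, config.orf_threshold_nt
    )
    lncrnas = lident.filter_lncrna_candidates(
        candidates, verdicts, reference_ids, config.min_length_bp, config.min_exons
    )
    classes = lident.classify_all(lncrnas, reference)
    census = lident.class_census(lncrnas, classes, chrom_lengths)
    pd.DataFrame(
        [
            {
                "transcript_id": t.transcript_id,
                "class": classes[t.transcript_id],
                "chrom": t.chrom,
                "start": t.start,
                "end": t.end,
                "strand": t.strand,
                "spliced_length": t.spliced_length,
                "orf_length_nt": verdicts[t.transcript_id].orf_length_nt,
            }
            for t in lncrnas
        ]
    ).to_csv(outdir / "lncrnas.tsv", sep="\t", index=False)

    lnc_ids = [t.transcript_id for t in lncrnas if t.transcript_id in counts.index]
    mrna_ids = sorted(g for g in reference.gene_ids if g in counts.index)

    # -------------------------------------------------------------- expression
    fpkm = lexpr.compute_fpkm(counts, lengths)
    fpkm.to_csv(outdir / "fpkm.tsv", sep="\t", index_label="feature_id")
    venn_lnc = lexpr.expressed_sets(
        fpkm.loc[lnc_ids], samples, "lncRNA", config.fpkm_threshold_lncrna
    )
    venn_mrna = lexpr.expressed_sets(
        fpkm.loc[mrna_ids], samples, "mRNA", config.fpkm_threshold_mrna
    )
    qc = lexpr.sample_correlation(fpkm)
    qc.to_csv(outdir / "sample_spearman.tsv", sep="\t")

    # ---------------------------------------------------------------------- DE
    de_results: dict[str, pd.DataFrame] = {}
    for comparison in config.comparisons:
        de = lde.nb_wald_test(
            counts, samples, comparison,
            fdr_threshold=config.fdr_threshold,
            min_abs_log2fc=config.min_abs_log2fc,
        )
        de.to_csv(outdir / f"de_{comparison}.tsv", sep="\t", index=False)
        de_results[comparison] = de

    lnc_set, mrna_set = set(lnc_ids), set(mrna_ids)
    de_lnc = {
        c: df[df["feature_id"].isin(lnc_set)] for c, df in de_results.items()
    }
    de_mrna = {
        c: df[df["feature_id"].isin(mrna_set)] for c, df in de_results.items()
    }
    summary_lnc = lde.de_summary(de_lnc)
    summary_mrna = lde.de_summary(de_mrna)

    # ----------------------------------------------------------------- targets
    cis = ltarg.cis_targets(
        [t for t in lncrnas if t.transcript_id in lnc_set],
        reference,
        config.cis_window_bp,
    )
    trans = ltarg.trans_targets(
        fpkm.loc[lnc_ids], fpkm.loc[mrna_ids],
        config.pcc_cutoff, config.pcc_p_cutoff,
    )
    all_pairs = cis + trans
    ltarg.pairs_to_frame(all_pairs).to_csv(
        outdir / "target_pairs.tsv", sep="\t", index=False
    )

    # --------------------------------------------------------------- flowering
    sd_comp, nb_comp = config.comparisons
    calls = lflower.call_flowering(de_lnc[sd_comp], de_lnc[nb_comp])
    lflower.calls_to_frame(calls).to_csv(
        outdir / "flowering_calls.tsv", sep="\t", index=False
    )
    venn = lflower.venn_census(
        lflower.de_direction_map(de_lnc[sd_comp]),
        lflower.de_direction_map(de_lnc[nb_comp]),
    )

    # ---------------------------------------------------------------- networks
    pos_net = lnet.build_network(calls, all_pairs, "positive")
    neg_net = lnet.build_network(calls, all_pairs, "negative")
    lio.write_edge_list(pos_net, outdir / "network_positive_edges.tsv")
    lio.write_edge_list(neg_net, outdir / "network_negative_edges.tsv")
    common = lnet.common_targets(pos_net, neg_net)

    # -------------------------------------------------------------- enrichment
    enrichment_rows = []
    if gene_sets:
        universe = set(counts.index[(counts.sum(axis=1) > 0)]) & mrna_set
        query = common["common"] & universe
        results = run_enrichment(query, universe, gene_sets) if universe else []
        frame = enrichment_frame(results)
        frame.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        enrichment_rows = [
            {"term_id": r.term_id, "corrected_p": round(r.corrected_p, 6),
             "significant": bool(r.significant)}
            for r in results
        ]

    # ----------------------------------------------------------------- summary
    summary = {
        "config": _config_dict(config),
        "lncrna_census": census,
        "expressed_venn_lncrna": venn_lnc["venn_counts"],
        "expressed_venn_mrna": venn_mrna["venn_counts"],
        "de_summary_lncrna": summary_lnc.to_dict(orient="records"),
        "de_summary_mrna": summary_mrna.to_dict(orient="records"),
        "de_lncrna_venn": venn,
        "flowering_calls": {
            "positive": sorted(c.lncrna_id for c in calls if c.label == "positive"),
            "negative": sorted(c.lncrna_id for c in calls if c.label == "negative"),
        },
        "n_target_pairs": {"cis": len(cis), "trans": len(trans)},
        "network": {
            "positive_edges": pos_net.n_edges,
            "negative_edges": neg_net.n_edges,
            "n_common_targets": common["n_common"],
            "n_pos_targets": common["n_pos_targets"],
            "n_neg_targets": common["n_neg_targets"],
            "share_of_pos_pct": common["share_of_pos_pct"],
            "share_of_neg_pct": common["share_of_neg_pct"],
        },
        "enrichment": enrichment_rows,
    }
    if truth is not None:
        summary["recovery"] = _recovery_metrics(summary, truth, cis, trans)

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return summary


def _recovery_metrics(summary, truth, cis, trans) -> dict:
    """Precision/recall of planted labels and planted target pairs."""
    called_pos = set(summary["flowering_calls"]["positive"])
    called_neg = set(summary["flowering_calls"]["negative"])
    true_pos = {t for t, c in truth.planted_class.items() if c == "positive"}
    true_neg = {t for t, c in truth.planted_class.items() if c == "negative"}

    def prf(called: set, true: set) -> dict:
        tp = len(called & true)
        precision = tp / len(called) if called else None
        recall = tp / len(true) if true else None
        return {"tp": tp, "n_called": len(called), "n_true": len(true),
                "precision": precision, "recall": recall}

    cis_found = {(p.lncrna_id, p.mrna_id) for p in cis}
    trans_found = {(p.lncrna_id, p.mrna_id) for p in trans}
    cis_recall = (
        len(truth.planted_cis_pairs & cis_found) / len(truth.planted_cis_pairs)
        if truth.planted_cis_pairs
        else None
    )
    trans_recall = (
        len(truth.planted_trans_pairs & trans_found) / len(truth.planted_trans_pairs)
        if truth.planted_trans_pairs
        else None
    )
    return {
        "positive": prf(called_pos, true_pos),
        "negative": prf(called_neg, true_neg),
        "cis_pair_recall": cis_recall,
        "trans_pair_recall": trans_recall,
    }
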