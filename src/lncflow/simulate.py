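"""Synthetic short-day / night-break study with planted ground truth.

The generator emits a complete toy study — reference annotation, assembled
transcripts (coding plus lncRNA), transcript sequences, an integer count
matrix for the 3-condition x 3-replicate design, and the ground truth of
what was planted — so every downstream stage is testable without any
external download.

What is planted:

* positional classes realized geometrically: intergenic lincRNAs (some near
  genes, some isolated beyond the cis window), lncRNAs inside an intron of a
  same-strand host gene, exon-overlapping sense lncRNAs, and opposite-strand
  antisense lncRNAs;
* coding transcripts carry a long open reading frame, lncRNA sequences are
  rejection-sampled until their longest ORF is short;
* *positive* regulators rise from SD1 to SD2 and fall from SD2 to NB
  (condition mean multipliers 1 : 2^effect : 1), *negative* regulators the
  reverse (2^effect : 1 : 2^effect);
* counts follow a negative-binomial model (variance mu + alpha * mu^2) with
  a genome-wide dispersion, per-feature baseline means and log-uniform
  library size factors;
* each regulator receives trans-correlated mRNA targets whose log-scale
  profiles track the regulator's realized expression at the configured
  latent correlation.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import io as lio
from .identify import find_longest_orf
from .models import AnnotationSet, SampleSheet, TranscriptModel

CONDITION_ORDER = ("SD1", "SD2", "NB")
_BASES = np.array(list("ACGT"))
_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the toy study; defaults run the whole pipeline in seconds."""

    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length_bp: int = 2_000_000
    n_coding_genes: int = 200
    n_lncrnas_per_class: Mapping[str, int] = field(
        default_factory=lambda: {"lincRNA": 16, "intronic": 8, "sense": 8, "antisense": 8}
    )
    n_planted_positive: int = 5
    n_planted_negative: int = 5
    effect_log2fc: float = 3.0
    nb_dispersion: float = 0.05
    mean_expression_log_range: tuple[float, float] = (1.5, 2.5)
    cis_fraction: float = 0.5
    trans_target_corr: float = 0.99
    trans_targets_per_regulator: int = 8
    #: amplification of the target response relative to its regulator;
    #: compensates count-level noise attenuation of the latent correlation
    trans_response_gain: float = 2.0
    library_size_range: tuple[float, float] = (0.7, 1.4)
    replicates: int = 3
    coding_orf_codons: int = 380
    lncrna_orf_max_nt: int = 300

    def __post_init__(self) -> None:
        if min(self.n_chromosomes, self.n_coding_genes, self.replicates) < 1:
            raise ValueError("chromosomes, genes and replicates must be positive")
        if self.n_planted_positive < 0 or self.n_planted_negative < 0:
            raise ValueError("planted counts must be >= 0")
        if any(v < 0 for v in self.n_lncrnas_per_class.values()):
            raise ValueError("lncRNA class counts must be >= 0")
        if not 0.0 <= self.cis_fraction <= 1.0:
            raise ValueError("cis_fraction must lie in [0, 1]")
        if not -1.0 <= self.trans_target_corr <= 1.0:
            raise ValueError("trans_target_corr must lie in [-1, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted, keyed by the public feature ids."""

    planted_class: dict[str, str]
    planted_cis_pairs: set[tuple[str, str]]
    planted_trans_pairs: set[tuple[str, str]]
    positional_class: dict[str, str]
    coding_gene_ids: tuple[str, ...]


@dataclass
class SimulatedStudy:
    reference: AnnotationSet
    assembled: AnnotationSet
    sequences: dict[str, str]
    counts: pd.DataFrame
    feature_lengths: pd.Series
    samples: SampleSheet
    truth: GroundTruth
    chrom_lengths: dict[str, int]
    config: SimulationConfig

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write every artifact as plain text; byte-stable under a fixed seed."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "reference_gtf": lio.write_gtf(self.reference, outdir / "reference.gtf"),
            "assembled_gtf": lio.write_gtf(self.assembled, outdir / "assembled.gtf"),
            "transcripts_fasta": lio.write_fasta(
                self.sequences, outdir / "transcripts.fa"
            ),
            "counts_tsv": lio.write_counts(self.counts, outdir / "counts.tsv"),
            "samples_tsv": lio.write_sample_sheet(self.samples, outdir / "samples.tsv"),
        }
        truth_dir = outdir / "truth"
        truth_dir.mkdir(exist_ok=True)
        pd.DataFrame(
            sorted(self.truth.planted_class.items()),
            columns=["lncrna_id", "planted_class"],
        ).to_csv(truth_dir / "planted_class.tsv", sep="\t", index=False)
        pd.DataFrame(
            sorted(self.truth.planted_cis_pairs), columns=["lncrna_id", "mrna_id"]
        ).to_csv(truth_dir / "cis_pairs.tsv", sep="\t", index=False)
        pd.DataFrame(
            sorted(self.truth.planted_trans_pairs), columns=["lncrna_id", "mrna_id"]
        ).to_csv(truth_dir / "trans_pairs.tsv", sep="\t", index=False)
        pd.DataFrame(
            sorted(self.truth.positional_class.items()),
            columns=["transcript_id", "positional_class"],
        ).to_csv(truth_dir / "positional_class.tsv", sep="\t", index=False)
        paths["truth_dir"] = truth_dir
        return paths

    @property
    def lncrna_ids(self) -> list[str]:
        return sorted(self.truth.positional_class)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _coding_sequence(rng: np.random.Generator, length: int, orf_codons: int) -> str:
    """Random sequence containing one long ATG..stop reading frame."""
    orf = (
        "ATG"
        + "".join(rng.choice(_NONSTOP_CODONS, size=orf_codons))
        + str(rng.choice(["TAA", "TAG", "TGA"]))
    )
    if len(orf) + 6 > length:
        raise ValueError("coding transcript too short for requested ORF")
    prefix_len = int(rng.integers(0, length - len(orf) + 1))
    prefix = _random_sequence(rng, prefix_len)
    suffix = _random_sequence(rng, length - len(orf) - prefix_len)
    return prefix + orf + suffix


def _noncoding_sequence(
    rng: np.random.Generator, length: int, orf_max_nt: int
) -> str:
    """Rejection-sample until the longest ORF is shorter than orf_max_nt."""
    for _ in range(200):
        seq = _random_sequence(rng, length)
        if find_longest_orf(seq) < orf_max_nt:
            return seq
    raise RuntimeError("could not sample a short-ORF sequence")  # pragma: no cover


def _nb_draws(
    rng: np.random.Generator, mean: np.ndarray, alpha: float
) -> np.ndarray:
    """Gamma-Poisson draws with variance mean + alpha * mean^2."""
    mean = np.asarray(mean, dtype=float)
    if alpha < 1e-12:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / alpha, scale=mean * alpha)
    return rng.poisson(lam)


def _place_genes(cfg: SimulationConfig) -> tuple[list[TranscriptModel], dict[str, int]]:
    """Tile coding genes (3 exons of 500 bp, 1 kb introns, alternating
    strands) over the first 75% of each chromosome."""
    per_chrom = math.ceil(cfg.n_coding_genes / cfg.n_chromosomes)
    gene_region = int(0.75 * cfg.chromosome_length_bp)
    stride = gene_region // max(per_chrom, 1)
    if stride < 7000:
        raise ValueError(
            "chromosomes too short for the requested number of coding genes"
        )
    transcripts = []
    chrom_lengths = {}
    for ci in range(cfg.n_chromosomes):
        chrom = f"chr{ci + 1}"
        chrom_lengths[chrom] = cfg.chromosome_length_bp
    for gi in range(cfg.n_coding_genes):
        ci = gi % cfg.n_chromosomes
        local = gi // cfg.n_chromosomes
        chrom = f"chr{ci + 1}"
        s = 10_000 + local * stride
        exons = ((s, s + 500), (s + 1500, s + 2000), (s + 3000, s + 3500))
        strand = "+" if local % 2 == 0 else "-"
        gene_id = f"gene-{gi:04d}"
        transcripts.append(
            TranscriptModel(f"{gene_id}.t1", gene_id, chrom, strand, exons)
        )
    return transcripts, chrom_lengths


def _place_lncrnas(
    cfg: SimulationConfig, genes: list[TranscriptModel]
) -> tuple[list[TranscriptModel], dict[str, str], dict[str, tuple[str, int] | None]]:
    """Realize each positional class geometrically.

    Returns the lncRNA transcripts, their true positional class, and the
    designated nearest coding gene with its span distance (None for isolated
    lincRNAs placed beyond the cis window).
    """
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for lst in by_chrom.values():
        lst.sort(key=lambda t: t.start)
    chroms = sorted(by_chrom)

    # per-chromosome allocation cursors
    gap_cursor = {c: 0 for c in chroms}        # even gene indices -> gap placement
    host_cursor = {c: 1 for c in chroms}       # odd gene indices -> host genes
    iso_cursor = {c: 0 for c in chroms}

    lncrnas: list[TranscriptModel] = []
    positional: dict[str, str] = {}
    nearest: dict[str, tuple[str, int] | None] = {}
    counter = 0

    def next_id() -> str:
        nonlocal counter
        tid = f"lnc-{counter:04d}.t1"
        counter += 1
        return tid

    def take_host(chrom: str) -> TranscriptModel:
        idx = host_cursor[chrom]
        if idx >= len(by_chrom[chrom]):
            raise ValueError("not enough coding genes to host the requested lncRNAs")
        host_cursor[chrom] = idx + 2
        return by_chrom[chrom][idx]

    order = ["lincRNA", "intronic", "sense", "antisense"]
    for cls in order:
        n = cfg.n_lncrnas_per_class.get(cls, 0)
        for j in range(n):
            chrom = chroms[(len(lncrnas)) % len(chroms)]
            tid = next_id()
            if cls == "lincRNA":
                isolated = j % 2 == 1  # half near genes, half isolated
                if isolated:
                    base = int(0.85 * cfg.chromosome_length_bp) + iso_cursor[chrom] * 2000
                    iso_cursor[chrom] += 1
                    exons = ((base, base + 150), (base + 250, base + 400))
                    strand = "+"
                    near = None
                else:
                    idx = gap_cursor[chrom]
                    if idx >= len(by_chrom[chrom]):
                        raise ValueError("not enough intergenic gaps for lincRNAs")
                    gap_cursor[chrom] = idx + 2
                    gene = by_chrom[chrom][idx]
                    base = gene.end + 2000
                    exons = ((base, base + 150), (base + 250, base + 400))
                    strand = "+"
                    near = (gene.gene_id, 2000)
            elif cls == "intronic":
                host = take_host(chrom)
                s = host.start
                exons = ((s + 600, s + 750), (s + 850, s + 1000))
                strand = host.strand
                near = (host.gene_id, 0)
            elif cls == "sense":
                host = take_host(chrom)
                s = host.start
                exons = ((s - 200, s + 100), (s + 600, s + 800))
                strand = host.strand
                near = (host.gene_id, 0)
            else:  # antisense
                host = take_host(chrom)
                s = host.start
                exons = ((s + 400, s + 600), (s + 700, s + 900))
                strand = "-" if host.strand == "+" else "+"
                near = (host.gene_id, 0)
            gene_id = tid.rsplit(".", 1)[0]
            lncrnas.append(TranscriptModel(tid, gene_id, chrom, strand, exons))
            positional[tid] = cls
            nearest[tid] = near
    return lncrnas, positional, nearest


def simulate_study(config: SimulationConfig | None = None) -> SimulatedStudy:
    """Generate the full toy study; bit-identical for a fixed seed."""
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)

    genes, chrom_lengths = _place_genes(cfg)
    lncrnas, positional, nearest = _place_lncrnas(cfg, genes)
    reference = AnnotationSet(genes)
    assembled = AnnotationSet(genes + lncrnas)

    # --- planted regulators -------------------------------------------------
    n_regulators = cfg.n_planted_positive + cfg.n_planted_negative
    lnc_ids = [t.transcript_id for t in lncrnas]
    if n_regulators > len(lnc_ids):
        raise ValueError("more planted regulators than lncRNAs")
    cis_eligible = [t for t in lnc_ids if nearest[t] is not None]
    n_cis = math.ceil(cfg.cis_fraction * n_regulators)
    if n_cis > len(cis_eligible):
        raise ValueError(
            "config demands more cis placements than gene-proximal lncRNAs exist"
        )
    shuffled_cis = [str(t) for t in rng.permutation(cis_eligible)]
    cis_chosen = shuffled_cis[:n_cis]
    remaining = [t for t in lnc_ids if t not in set(cis_chosen)]
    picked = cis_chosen + [str(t) for t in rng.permutation(remaining)][
        : n_regulators - n_cis
    ]
    picked = [str(t) for t in rng.permutation(picked)]
    positives = set(picked[: cfg.n_planted_positive])
    negatives = set(picked[cfg.n_planted_positive : n_regulators])
    planted_class = {
        t: ("positive" if t in positives else "negative" if t in negatives else "none")
        for t in lnc_ids
    }
    planted_cis = {(t, nearest[t][0]) for t in cis_chosen}

    # --- trans targets ------------------------------------------------------
    regulators = sorted(positives | negatives)
    gene_ids = sorted({g.gene_id for g in genes})
    pool = list(rng.permutation(gene_ids))
    planted_trans: set[tuple[str, str]] = set()
    trans_driver: dict[str, str] = {}
    for reg in regulators:
        for _ in range(cfg.trans_targets_per_regulator):
            if not pool:
                raise ValueError("not enough coding genes for the trans targets")
            target = pool.pop()
            planted_trans.add((reg, target))
            trans_driver[target] = reg

    # --- sequences ----------------------------------------------------------
    sequences: dict[str, str] = {}
    for t in genes:
        sequences[t.transcript_id] = _coding_sequence(
            rng, t.spliced_length, cfg.coding_orf_codons
        )
    for t in lncrnas:
        sequences[t.transcript_id] = _noncoding_sequence(
            rng, t.spliced_length, cfg.lncrna_orf_max_nt
        )

    # --- counts -------------------------------------------------------------
    samples = SampleSheet(
        [
            lio.Sample(f"{cond}_{rep}", cond, rep)
            for cond in CONDITION_ORDER
            for rep in range(1, cfg.replicates + 1)
        ]
    )
    sample_cond = np.array(
        [CONDITION_ORDER.index(s.condition) for s in samples]
    )
    n_samples = len(samples)
    lo, hi = cfg.library_size_range
    lib = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_samples))

    feature_ids = gene_ids + lnc_ids
    lengths = {}
    for g in genes:
        lengths[g.gene_id] = g.spliced_length
    for t in lncrnas:
        lengths[t.transcript_id] = t.spliced_length
    lo_m, hi_m = cfg.mean_expression_log_range
    base_mean = {
        f: 10.0 ** rng.uniform(lo_m, hi_m) for f in feature_ids
    }

    eff = 2.0 ** cfg.effect_log2fc
    cond_mult = {}
    for f in feature_ids:
        if planted_class.get(f) == "positive":
            cond_mult[f] = np.array([1.0, eff, 1.0])
        elif planted_class.get(f) == "negative":
            cond_mult[f] = np.array([eff, 1.0, eff])
        else:
            cond_mult[f] = np.ones(3)

    counts = np.zeros((len(feature_ids), n_samples), dtype=np.int64)
    row_of = {f: i for i, f in enumerate(feature_ids)}
    trans_target_ids = set(trans_driver)
    # plain features (and all lncRNAs) first, trans targets after their drivers
    for f in feature_ids:
        if f in trans_target_ids:
            continue
        mu = base_mean[f] * cond_mult[f][sample_cond] * lib
        counts[row_of[f]] = _nb_draws(rng, mu, cfg.nb_dispersion)

    rho = cfg.trans_target_corr
    gain = cfg.trans_response_gain
    for target in sorted(trans_target_ids):
        driver = trans_driver[target]
        x = np.log(counts[row_of[driver]] / lib + 0.5)
        x = x - x.mean()
        sd = x.std() if x.std() > 0 else 1.0
        eps = rng.standard_normal(n_samples)
        eta = rho * x + math.sqrt(max(0.0, 1.0 - rho * rho)) * sd * eps
        mu = base_mean[target] * np.exp(gain * eta) * lib
        counts[row_of[target]] = _nb_draws(rng, mu, cfg.nb_dispersion)

    counts_df = pd.DataFrame(counts, index=feature_ids, columns=samples.sample_ids)
    counts_df.index.name = "feature_id"

    truth = GroundTruth(
        planted_class=planted_class,
        planted_cis_pairs=planted_cis,
        planted_trans_pairs=planted_trans,
        positional_class=positional,
        coding_gene_ids=tuple(gene_ids),
    )
    return SimulatedStudy(
        reference=reference,
        assembled=assembled,
        sequences=sequences,
        counts=counts_df,
        feature_lengths=pd.Series(lengths, name="length"),
        samples=samples,
        truth=truth,
        chrom_lengths=chrom_lengths,
        config=cfg,
    )


def emit_gene_sets(
    truth: GroundTruth,
    config: SimulationConfig,
    n_random_terms: int = 5,
    random_term_size: int = 20,
) -> dict[str, dict]:
    """Gene-set table with one term enriched among planted trans targets.

    The enriched term is built from the planted trans-target genes padded
    with at most 25% random genes, so at least 80% of its members are
    planted targets by construction; the remaining terms are random draws
    without replacement from the coding universe.
    """
    rng = np.random.default_rng(config.seed + 104729)
    universe = list(truth.coding_gene_ids)
    planted_targets = sorted({m for _, m in truth.planted_trans_pairs})
    terms: dict[str, dict] = {}
    if planted_targets:
        n_extra = len(planted_targets) // 5
        others = [g for g in universe if g not in set(planted_targets)]
        extra = list(rng.choice(others, size=min(n_extra, len(others)), replace=False))
        terms["TERM:0000"] = {
            "name": "planted_regulator_targets",
            "genes": set(planted_targets) | set(extra),
        }
    for i in range(n_random_terms):
        size = min(random_term_size, len(universe))
        genes = set(rng.choice(universe, size=size, replace=False))
        terms[f"TERM:{i + 1:04d}"] = {"name": f"random_term_{i + 1}", "genes": genes}
    return terms


def null_config(cfg: SimulationConfig | None = None, **overrides) -> SimulationConfig:
    """A copy of the config with no planted effect (effect_log2fc = 0)."""
    cfg = cfg or SimulationConfig()
    return replace(cfg, effect_log2fc=0.0, **overrides)
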