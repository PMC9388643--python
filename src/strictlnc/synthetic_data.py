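"""Self-contained toy dataset with planted ground truth.

The generator stands in for a large public RNA-seq cohort: it emits a
toy genome, a reference annotation of multi-exon coding genes, candidate
transcripts with planted positional biotypes (lincRNA, NAT,
sense-exonic, intronic, dual NAT+sense-exonic), coding contaminants and
tRNA/rRNA mimics with matching evidence tables, boundary decoys that sit
exactly on every filter threshold (199 nt, 6001-bp intron, 101-aa ORF,
e-value 1e-6, D-score 0.45, 70% identity), a negative-binomial count
matrix over tissues/stages with planted tissue-specific genes and
planted co-expression modules, and a GO annotation whose module terms
make the planted modules GO-coherent.  A manifest records every planted
answer so each downstream stage can be checked exactly.

Everything is deterministic given the seed; independent substreams are
derived per stage so the stages can also be re-run individually.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation_io import (
    GeneModel,
    GenomicInterval,
    SampleMetadata,
    TranscriptModel,
    extract_sequence,
    write_fasta,
    write_gtf,
)
from .filter_cascade import BLAST6_COLUMNS, EvidenceBundle, find_longest_orf

TISSUES = ("embryo", "root", "leaf", "flower", "seedling", "silique",
           "stem", "seed")
#: one representative age per developmental stage (germination, leaf
#: development, first inflorescence, flowering, silique)
STAGE_AGES = (4, 10, 27, 35, 50)

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
]

RETENTION_DESCRIPTIONS = (
    "hypothetical protein At1g99999",
    "unknown protein, partial",
    "predicted protein",
    "unnamed protein product",
)
INFORMATIVE_DESCRIPTIONS = (
    "60S ribosomal protein L3",
    "photosystem II protein D1",
    "heat shock protein 70",
)


class SizingError(Exception):
    """Requested gene content does not fit the configured chromosomes."""


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chroms: int = 2
    chrom_length_bp: int = 800_000
    n_coding_genes: int = 400
    n_lincrna: int = 12
    n_nat: int = 8
    n_sense_exonic: int = 6
    n_intronic: int = 6
    n_dual: int = 2
    n_coding_contaminants: int = 12
    n_rescuable: int = 4
    n_trna_rrna_mimics: int = 4
    n_tissues: int = 6
    samples_per_tissue: int = 10
    n_modules: int = 3
    module_size: int = 60
    lncrnas_per_module: int = 6
    within_module_correlation: float = 0.8
    noise_sd: float = 0.5
    nb_dispersion: float = 0.02
    fraction_tissue_specific: float = 0.5
    #: probability that an intronic candidate has unknown orientation,
    #: emulating transcripts assembled only from unstranded libraries
    unknown_strand_prob: float = 0.15
    single_end_fraction: float = 0.2

    def __post_init__(self):
        for name in ("n_chroms", "chrom_length_bp", "n_coding_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("n_lincrna", "n_nat", "n_sense_exonic", "n_intronic",
                     "n_dual", "n_coding_contaminants", "n_rescuable",
                     "n_trna_rrna_mimics"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 < self.within_module_correlation < 1):
            raise ValueError("within_module_correlation must be in (0, 1)")
        if not (1 < self.n_tissues <= len(TISSUES)):
            raise ValueError(f"n_tissues must be in [2, {len(TISSUES)}]")
        hosts = self.n_nat + self.n_sense_exonic + self.n_intronic + 2 * self.n_dual
        if hosts + self.n_modules * self.module_size > self.n_coding_genes:
            raise ValueError(
                "n_coding_genes too small for the requested hosts and modules"
            )

    @property
    def chrom_names(self) -> list[str]:
        return [f"Chr{i + 1}" for i in range(self.n_chroms)]

    @property
    def tissues(self) -> list[str]:
        return list(TISSUES[: self.n_tissues])


@dataclass
class GroundTruthManifest:
    transcript_class: dict[str, str] = field(default_factory=dict)
    transcript_biotypes: dict[str, list[str]] = field(default_factory=dict)
    contaminant_fail_step: dict[str, str] = field(default_factory=dict)
    gene_module: dict[str, int] = field(default_factory=dict)
    gene_specific_tissue: dict[str, str | None] = field(default_factory=dict)
    module_terms: dict[int, str] = field(default_factory=dict)

    @property
    def expected_survivors(self) -> set[str]:
        return {
            tid for tid, cls in self.transcript_class.items()
            if cls in ("clean_lncRNA", "rescuable_lncRNA")
        }

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["module_terms"] = {str(k): v for k, v in payload["module_terms"].items()}
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruthManifest":
        payload = json.loads(Path(path).read_text())
        payload["module_terms"] = {int(k): v for k, v in payload["module_terms"].items()}
        return cls(**payload)


# ---------------------------------------------------------------------------
# genome + annotation
# ---------------------------------------------------------------------------

class _Placer:
    """Sequential placement with random gaps, balanced across chromosomes."""

    def __init__(self, cfg: SimulationConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng
        self.cursors = {c: 1000 for c in cfg.chrom_names}

    def alloc(self, length: int) -> tuple[str, int]:
        chrom = min(self.cursors, key=lambda c: (self.cursors[c], c))
        gap = int(self.rng.integers(300, 900))
        start = self.cursors[chrom] + gap
        end = start + length
        if end > self.cfg.chrom_length_bp - 1000:
            raise SizingError(
                "ran out of chromosome space; increase chrom_length_bp or "
                "reduce gene counts"
            )
        self.cursors[chrom] = end
        return chrom, start


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _coding_transcript_seq(rng: np.random.Generator, length: int,
                           n_aa: int = 150, utr5: int = 30) -> str:
    """Random sequence carrying an ORF of n_aa codons starting at utr5."""
    orf = "ATG" + "".join(
        _NON_STOP_CODONS[i] for i in rng.integers(0, len(_NON_STOP_CODONS), n_aa - 1)
    ) + "TAA"
    assert utr5 + len(orf) <= length, "transcript too short for its ORF"
    seq = _random_seq(rng, length)
    return seq[:utr5] + orf + seq[utr5 + len(orf):]


@dataclass
class _GeneRec:
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    tx_seq: str | None = None  # designed spliced sequence (coding genes)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def to_gene_model(self) -> GeneModel:
        tx = TranscriptModel(
            self.gene_id + ".1",
            self.gene_id,
            [GenomicInterval(self.chrom, s, e, self.strand) for s, e in self.exons],
        )
        return GeneModel(self.gene_id, [tx], biotype_label="coding")


def _make_coding_gene(
    gid: str,
    placer: _Placer,
    rng: np.random.Generator,
    strand: str | None = None,
    intron1: int | None = None,
    reserve_after: int = 0,
) -> _GeneRec:
    e_lens = [int(x) for x in rng.integers(220, 351, size=3)]
    i1 = intron1 if intron1 is not None else int(rng.integers(300, 401))
    i2 = int(rng.integers(120, 401))
    total = sum(e_lens) + i1 + i2
    chrom, start = placer.alloc(total + reserve_after)
    exons = []
    pos = start
    for length, gap in zip(e_lens, (i1, i2, 0)):
        exons.append((pos, pos + length))
        pos += length + gap
    if strand is None:
        strand = "+" if rng.integers(0, 2) == 0 else "-"
    seq = _coding_transcript_seq(rng, sum(e_lens))
    return _GeneRec(gid, chrom, strand, exons, seq)


def simulate_genome_and_annotation(
    cfg: SimulationConfig,
) -> tuple[dict[str, str], list[GeneModel], list[TranscriptModel], GroundTruthManifest]:
    """Place genes and candidates, build the genome, fill the manifest.

    Candidate transcript sequences are extracted from the generated
    genome, so exactly the same coordinates/sequence relationship holds
    as for real data; non-ORF candidates are re-drawn (outside any
    reference exon) until their longest ORF is at most 100 aa.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    placer = _Placer(cfg, rng)
    manifest = GroundTruthManifest()

    genes: list[_GeneRec] = []
    candidates: list[dict] = []  # chrom/strand/exons/gene_id/transcript_id/designed
    gene_counter = 0

    def next_gid() -> str:
        nonlocal gene_counter
        gene_counter += 1
        return f"CODG{gene_counter:04d}"

    lnc_counter = 0

    def add_candidate(exons, chrom, strand, cls, biotypes=None, designed=None,
                      prefix="LNC", fail_step=None):
        nonlocal lnc_counter
        lnc_counter += 1
        gid = f"{prefix}G{lnc_counter:04d}"
        tid = f"{gid}.1"
        candidates.append(
            {"transcript_id": tid, "gene_id": gid, "chrom": chrom,
             "strand": strand, "exons": exons, "designed": designed}
        )
        manifest.transcript_class[tid] = cls
        if biotypes is not None:
            manifest.transcript_biotypes[tid] = sorted(biotypes)
        if fail_step is not None:
            manifest.contaminant_fail_step[tid] = fail_step
        return tid

    # --- hosts with attached lncRNA candidates ------------------------------
    for kind, count in (("NAT", cfg.n_nat), ("sense_exonic", cfg.n_sense_exonic)):
        for _ in range(count):
            g = _make_coding_gene(next_gid(), placer, rng)
            genes.append(g)
            lnc_len = 400
            ov = int(rng.integers(120, 201))
            e2 = g.exons[1]
            lnc_start = e2[0] - (lnc_len - ov)
            exons = [(lnc_start, lnc_start + lnc_len)]
            strand = (
                ("-" if g.strand == "+" else "+") if kind == "NAT" else g.strand
            )
            add_candidate(exons, g.chrom, strand, "clean_lncRNA", [kind])

    for _ in range(cfg.n_intronic):
        g = _make_coding_gene(next_gid(), placer, rng, intron1=1400)
        genes.append(g)
        lnc_len = 400
        i1_start = g.exons[0][1]
        lnc_start = i1_start + 300
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        if rng.random() < cfg.unknown_strand_prob:
            strand = "."
        add_candidate([(lnc_start, lnc_start + lnc_len)], g.chrom, strand,
                      "clean_lncRNA", ["intronic"])

    for _ in range(cfg.n_dual):
        ga = _make_coding_gene(next_gid(), placer, rng, strand="+", reserve_after=0)
        genes.append(ga)
        # place the antisense partner right after, with a fixed small gap
        gap_d = 400
        e_lens = [int(x) for x in rng.integers(220, 351, size=3)]
        i1, i2 = int(rng.integers(300, 401)), int(rng.integers(120, 401))
        start_b = ga.end + gap_d
        total_b = sum(e_lens) + i1 + i2
        if start_b + total_b > cfg.chrom_length_bp - 1000:
            raise SizingError("dual-host pair does not fit; increase chrom_length_bp")
        exons_b = []
        pos = start_b
        for length, gap in zip(e_lens, (i1, i2, 0)):
            exons_b.append((pos, pos + length))
            pos += length + gap
        gb = _GeneRec(next_gid(), ga.chrom, "-", exons_b,
                      _coding_transcript_seq(rng, sum(e_lens)))
        placer.cursors[ga.chrom] = gb.end
        genes.append(gb)
        ov = 150
        lnc_start = ga.exons[-1][1] - ov
        lnc_end = gb.exons[0][0] + ov
        add_candidate([(lnc_start, lnc_end)], ga.chrom, "+",
                      "clean_lncRNA", ["NAT", "sense_exonic"])

    # --- plain coding genes -------------------------------------------------
    while gene_counter < cfg.n_coding_genes:
        genes.append(_make_coding_gene(next_gid(), placer, rng))

    # --- standalone candidates ----------------------------------------------
    for i in range(cfg.n_lincrna):
        if i % 3 == 2:
            l1, l2 = int(rng.integers(150, 351)), int(rng.integers(150, 351))
            intron = int(rng.integers(150, 401))
            chrom, start = placer.alloc(l1 + intron + l2)
            exons = [(start, start + l1),
                     (start + l1 + intron, start + l1 + intron + l2)]
        else:
            length = int(rng.integers(250, 701))
            chrom, start = placer.alloc(length)
            exons = [(start, start + length)]
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        add_candidate(exons, chrom, strand, "clean_lncRNA", ["lincRNA"])

    for _ in range(cfg.n_rescuable):
        chrom, start = placer.alloc(500)
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        add_candidate([(start, start + 500)], chrom, strand,
                      "rescuable_lncRNA", ["lincRNA"], prefix="RES")

    contaminant_steps = ("blastp", "blastx", "domain", "signal_peptide",
                         "orf_length", "nr_review")
    for i in range(cfg.n_coding_contaminants):
        step = contaminant_steps[i % len(contaminant_steps)]
        length = 600
        chrom, start = placer.alloc(length)
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        designed = None
        if step == "orf_length":
            # first ORF witness sits exactly at 101 aa, one over the limit
            n_aa = 101 if i < len(contaminant_steps) else 120
            designed = _coding_transcript_seq(rng, length, n_aa=n_aa)
        add_candidate([(start, start + length)], chrom, strand,
                      "coding_contaminant", designed=designed, prefix="CONT",
                      fail_step=step)

    for _ in range(cfg.n_trna_rrna_mimics):
        chrom, start = placer.alloc(300)
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        add_candidate([(start, start + 300)], chrom, strand,
                      "trna_rrna_mimic", prefix="MIM", fail_step="ncrna_family")

    # boundary decoys: 199 nt (one under the length floor) and a 6001-bp
    # intron (one over the intron ceiling)
    chrom, start = placer.alloc(199)
    add_candidate([(start, start + 199)], chrom, "+", "short_decoy",
                  prefix="DEC", fail_step="length_and_chrom")
    chrom, start = placer.alloc(150 + 6001 + 150)
    add_candidate([(start, start + 150), (start + 150 + 6001, start + 6301)],
                  chrom, "+", "long_intron_decoy", prefix="DEC",
                  fail_step="intron_length")

    # --- genome assembly -----------------------------------------------------
    genome_arr = {
        c: _BASES[rng.integers(0, 4, size=cfg.chrom_length_bp)].copy()
        for c in cfg.chrom_names
    }

    def write_seq(chrom, strand, exons, seq):
        from .annotation_io import reverse_complement

        genomic = reverse_complement(seq) if strand == "-" else seq
        offset = 0
        for s, e in exons:
            genome_arr[chrom][s:e] = list(genomic[offset : offset + (e - s)])
            offset += e - s

    for g in genes:
        write_seq(g.chrom, g.strand, g.exons, g.tx_seq)
    for c in candidates:
        if c["designed"] is not None:
            write_seq(c["chrom"], c["strand"], c["exons"], c["designed"])

    # re-draw free bases of non-ORF candidates until the ORF filter passes
    ref_exons_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        ref_exons_by_chrom.setdefault(g.chrom, []).extend(g.exons)

    def free_intervals(c) -> list[tuple[int, int]]:
        out = []
        ref = ref_exons_by_chrom.get(c["chrom"], [])
        for s, e in c["exons"]:
            cuts = [(s, e)]
            for rs, re_ in ref:
                cuts = [
                    piece
                    for lo, hi in cuts
                    for piece in ((lo, min(hi, rs)), (max(lo, re_), hi))
                    if piece[0] < piece[1]
                ]
            out.extend(cuts)
        return out

    genome = {c: "".join(arr) for c, arr in genome_arr.items()}
    for c in candidates:
        if c["designed"] is not None:
            continue
        model = _candidate_model(c)
        for _try in range(40):
            seq = extract_sequence(model, genome)
            orf = find_longest_orf(seq)
            if orf is None or orf.peptide_length_aa <= 100:
                break
            redraw = free_intervals(c)
            if not redraw:
                raise SizingError(f"{c['transcript_id']}: cannot redraw sequence")
            for s, e in redraw:
                genome_arr[c["chrom"]][s:e] = _BASES[rng.integers(0, 4, size=e - s)]
            genome[c["chrom"]] = "".join(genome_arr[c["chrom"]])
        else:
            raise SizingError(f"{c['transcript_id']}: ORF constraint unsatisfiable")

    reference = [g.to_gene_model() for g in genes]
    candidate_models = []
    for c in candidates:
        model = _candidate_model(c)
        model.sequence = extract_sequence(model, genome)
        candidate_models.append(model)

    _assign_modules_and_specificity(cfg, manifest, genes, candidates, rng)
    return genome, reference, candidate_models, manifest


def _candidate_model(c: dict) -> TranscriptModel:
    return TranscriptModel(
        c["transcript_id"],
        c["gene_id"],
        [GenomicInterval(c["chrom"], s, e, c["strand"]) for s, e in c["exons"]],
    )


def _assign_modules_and_specificity(cfg, manifest, genes, candidates, rng):
    """Plant module membership and tissue specificity into the manifest.

    Module hosts are drawn from coding genes not used as overlap hosts;
    tissue-specific genes from the remaining pool.  About half of the
    coding genes are planted tissue-specific so that the mRNA-median Tau
    cutoff falls into the gap between broadly expressed and specific
    genes — matching the near-half specific fraction seen in real
    cohorts.
    """
    host_count = cfg.n_nat + cfg.n_sense_exonic + cfg.n_intronic + 2 * cfg.n_dual
    coding_ids = [g.gene_id for g in genes]
    pool = coding_ids[host_count:]  # overlap hosts stay background
    for gid in coding_ids:
        manifest.gene_module[gid] = 0
        manifest.gene_specific_tissue[gid] = None
    for m in range(1, cfg.n_modules + 1):
        for gid in pool[(m - 1) * cfg.module_size : m * cfg.module_size]:
            manifest.gene_module[gid] = m
    remaining = pool[cfg.n_modules * cfg.module_size :] + coding_ids[:host_count]
    n_specific = round(cfg.fraction_tissue_specific * cfg.n_coding_genes)
    if n_specific > len(remaining):
        raise ValueError(
            "fraction_tissue_specific too high for the non-module coding pool"
        )
    tissues = cfg.tissues
    for i, gid in enumerate(remaining[:n_specific]):
        manifest.gene_specific_tissue[gid] = tissues[i % len(tissues)]

    lnc_gene_ids = [
        c["gene_id"] for c in candidates
        if manifest.transcript_class[c["transcript_id"]]
        in ("clean_lncRNA", "rescuable_lncRNA")
    ]
    for gid in lnc_gene_ids:
        manifest.gene_module[gid] = 0
        manifest.gene_specific_tissue[gid] = None
    i = 0
    for m in range(1, cfg.n_modules + 1):
        for _ in range(cfg.lncrnas_per_module):
            if i < len(lnc_gene_ids):
                manifest.gene_module[lnc_gene_ids[i]] = m
                i += 1
    rest = lnc_gene_ids[i:]
    n_spec_lnc = round(cfg.fraction_tissue_specific * len(rest))
    for j, gid in enumerate(rest[:n_spec_lnc]):
        manifest.gene_specific_tissue[gid] = tissues[j % len(tissues)]


# ---------------------------------------------------------------------------
# evidence
# ---------------------------------------------------------------------------

def _blast_row(qid, sid, pident, evalue, sstrand="plus", **extra):
    row = {c: 0 for c in BLAST6_COLUMNS}
    row.update(
        {"qseqid": qid, "sseqid": sid, "pident": pident, "length": 100,
         "evalue": evalue, "bitscore": 200.0, "sstrand": sstrand}
    )
    row.update(extra)
    return row


def simulate_evidence(
    candidates: Sequence[TranscriptModel],
    manifest: GroundTruthManifest,
    cfg: SimulationConfig,
) -> EvidenceBundle:
    """Evidence tables matching the planted classes.

    Clean lncRNAs get no rows anywhere.  Each contaminant gets evidence
    for exactly the step it is planted to fail, including the boundary
    witnesses (e-value exactly 1e-6, D-score exactly 0.45, identity
    exactly 70).  Rescuable transcripts get only an nr best hit with an
    uninformative description.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    blastp, blastx, domain, signalp, nr, family, blastn = [], [], [], [], [], [], []
    seen_step: dict[str, int] = {}
    n_rescued = 0
    for t in candidates:
        tid = t.transcript_id
        cls = manifest.transcript_class[tid]
        if cls == "rescuable_lncRNA":
            pident = 70.0 if n_rescued == 0 else float(rng.uniform(75, 95))
            desc = RETENTION_DESCRIPTIONS[n_rescued % len(RETENTION_DESCRIPTIONS)]
            nr.append(_blast_row(tid, f"nr|{tid}", round(pident, 3), 1e-9,
                                 description=desc))
            n_rescued += 1
        elif cls == "coding_contaminant":
            step = manifest.contaminant_fail_step[tid]
            k = seen_step.get(step, 0)
            seen_step[step] = k + 1
            if step == "blastp":
                evalue = 1e-6 if k == 0 else 10 ** -float(rng.uniform(8, 40))
                blastp.append(_blast_row(tid, f"sp|{tid}", 85.0, evalue))
            elif step == "blastx":
                blastx.append(
                    _blast_row(tid, f"sp|{tid}", 80.0,
                               10 ** -float(rng.uniform(8, 40)))
                )
            elif step == "domain":
                domain.append(
                    {"query_id": tid, "domain_id": f"PF{int(rng.integers(1, 9999)):05d}",
                     "evalue": 10 ** -float(rng.uniform(7, 30))}
                )
            elif step == "signal_peptide":
                d = 0.45 if k == 0 else float(round(rng.uniform(0.6, 0.95), 3))
                signalp.append({"query_id": tid, "d_score": d})
            elif step == "nr_review":
                pident = 70.0 if k == 0 else float(round(rng.uniform(75, 95), 3))
                desc = INFORMATIVE_DESCRIPTIONS[k % len(INFORMATIVE_DESCRIPTIONS)]
                nr.append(_blast_row(tid, f"nr|{tid}", pident, 1e-9,
                                     description=desc))
            # orf_length contaminants carry their evidence in the sequence
        elif cls == "trna_rrna_mimic":
            fam_class = "tRNA" if len(family) % 2 == 0 else "rRNA"
            fam_id = "RF00005" if fam_class == "tRNA" else "RF00001"
            family.append(
                {"query_id": tid, "family_id": fam_id, "family_class": fam_class,
                 "evalue": 10 ** -float(rng.uniform(7, 20))}
            )
            if len(family) % 2 == 1:
                blastn.append(_blast_row(tid, f"ncrna|{tid}", 98.0, 1e-10))
    return EvidenceBundle(
        blastp_hits=pd.DataFrame(blastp, columns=BLAST6_COLUMNS + ["sstrand"]),
        blastx_hits=pd.DataFrame(blastx, columns=BLAST6_COLUMNS + ["sstrand"]),
        domain_hits=pd.DataFrame(domain, columns=["query_id", "domain_id", "evalue"]),
        signal_peptides=pd.DataFrame(signalp, columns=["query_id", "d_score"]),
        nr_best_hits=pd.DataFrame(nr, columns=BLAST6_COLUMNS + ["sstrand", "description"]),
        ncrna_family_hits=pd.DataFrame(
            family, columns=["query_id", "family_id", "family_class", "evalue"]),
        known_ncrna_blastn_hits=pd.DataFrame(blastn, columns=BLAST6_COLUMNS + ["sstrand"]),
    )


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(
    reference: Sequence[GeneModel],
    candidates: Sequence[TranscriptModel],
    manifest: GroundTruthManifest,
    cfg: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Negative-binomial counts over tissues and stages.

    Module genes share a per-module latent profile (a tissue-level
    component plus per-sample jitter) scaled so the expected pairwise
    within-module correlation on the log scale matches the configured
    target; planted tissue-specific genes have expected expression zero
    outside their tissue (hence Tau exactly 1); ages span the five
    developmental stage bins.  Returns (counts, sample metadata frame,
    effective lengths).
    """
    rng = np.random.default_rng([cfg.seed, 2])
    tissues = cfg.tissues
    samples = []
    for t_i, tissue in enumerate(tissues):
        for j in range(cfg.samples_per_tissue):
            layout = "single-end" if rng.random() < cfg.single_end_fraction else "paired-end"
            condition = ["control", "cold", "drought"][
                int(rng.choice(3, p=[0.7, 0.15, 0.15]))
            ]
            samples.append(
                SampleMetadata(
                    sample_id=f"S{t_i * cfg.samples_per_tissue + j + 1:03d}",
                    tissue=tissue,
                    age_days=STAGE_AGES[(t_i + j) % len(STAGE_AGES)],
                    condition=condition,
                    library_layout=layout,
                )
            )
    sample_ids = [s.sample_id for s in samples]
    tissue_of = np.array([s.tissue for s in samples])

    gene_ids, lengths = [], []
    for g in reference:
        gene_ids.append(g.gene_id)
        lengths.append(g.transcripts[0].exonic_length)
    for t in candidates:
        if manifest.transcript_class[t.transcript_id] in (
            "clean_lncRNA", "rescuable_lncRNA"
        ):
            gene_ids.append(t.gene_id)
            lengths.append(t.exonic_length)
    lengths = pd.Series(lengths, index=gene_ids, name="effective_length")

    n_genes, n_samples = len(gene_ids), len(samples)
    r = cfg.within_module_correlation
    sigma_f = cfg.noise_sd * np.sqrt(r / (1.0 - r))
    sigma_tissue = min(0.3, sigma_f / 2)
    sigma_jitter = np.sqrt(max(sigma_f**2 - sigma_tissue**2, 1e-4))

    module_factor = {}
    for m in range(1, cfg.n_modules + 1):
        profile = dict(zip(tissues, rng.normal(0.0, sigma_tissue, len(tissues))))
        jitter = rng.normal(0.0, sigma_jitter, n_samples)
        module_factor[m] = np.array([profile[t] for t in tissue_of]) + jitter

    log_mu = np.zeros((n_genes, n_samples))
    zero_mask = np.zeros((n_genes, n_samples), dtype=bool)
    baselines = rng.uniform(5.0, 9.0, n_genes)
    for gi, gid in enumerate(gene_ids):
        base = baselines[gi]
        module = manifest.gene_module.get(gid, 0)
        specific = manifest.gene_specific_tissue.get(gid)
        noise = rng.normal(0.0, cfg.noise_sd, n_samples)
        if specific is not None:
            log_mu[gi] = base + 1.0 + noise
            zero_mask[gi] = tissue_of != specific
        elif module:
            log_mu[gi] = base + module_factor[module] + noise
        else:
            effects = dict(zip(tissues, rng.normal(0.0, 0.2, len(tissues))))
            log_mu[gi] = base + np.array([effects[t] for t in tissue_of]) + noise

    mu = np.power(2.0, log_mu)
    mu[zero_mask] = 0.0
    inv_disp = 1.0 / cfg.nb_dispersion
    p = inv_disp / (inv_disp + mu)
    counts = rng.negative_binomial(inv_disp, p)
    counts[zero_mask] = 0

    counts_df = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    meta_df = pd.DataFrame([asdict(s) for s in samples])
    return counts_df, meta_df, lengths


# ---------------------------------------------------------------------------
# GO annotation
# ---------------------------------------------------------------------------

MODULE_TERM_NAMES = (
    "photosynthesis",
    "RNA processing",
    "root system development",
    "cell division",
    "response to cold",
)


def generate_go_annotation(
    manifest: GroundTruthManifest, cfg: SimulationConfig
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Gene -> GO(BP) mapping with one coherent term planted per module.

    Coding genes get three random background terms each; genes of module
    m additionally carry that module's planted term with high
    probability (and a trickle of background genes carry it too, so the
    test is non-trivial).  lncRNAs receive no annotation.
    """
    rng = np.random.default_rng([cfg.seed, 3])
    n_background_terms = 30
    background_terms = [f"GO:10000{i:02d}" for i in range(n_background_terms)]
    term_names = {t: f"background process {i}" for i, t in enumerate(background_terms)}
    module_terms = {}
    for m in range(1, cfg.n_modules + 1):
        term = f"GO:70000{m:02d}"
        module_terms[m] = term
        term_names[term] = MODULE_TERM_NAMES[(m - 1) % len(MODULE_TERM_NAMES)]
    manifest.module_terms = module_terms

    coding = [g for g in manifest.gene_module if g.startswith("CODG")]
    rows = []
    for gid in coding:
        for idx in rng.choice(n_background_terms, size=3, replace=False):
            rows.append({"gene_id": gid, "term_id": background_terms[idx]})
        m = manifest.gene_module[gid]
        if m and rng.random() < 0.85:
            rows.append({"gene_id": gid, "term_id": module_terms[m]})
        elif not m and rng.random() < 0.02:
            any_term = module_terms[int(rng.integers(1, cfg.n_modules + 1))]
            rows.append({"gene_id": gid, "term_id": any_term})
    return pd.DataFrame(rows), term_names


# ---------------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    cfg: SimulationConfig
    genome: dict[str, str]
    reference: list[GeneModel]
    candidates: list[TranscriptModel]
    manifest: GroundTruthManifest
    evidence: EvidenceBundle
    counts: pd.DataFrame
    metadata: pd.DataFrame
    effective_lengths: pd.Series
    gene2go: pd.DataFrame
    term_names: dict[str, str]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome, outdir / "genome.fa")
        write_gtf(
            [t for g in self.reference for t in g.transcripts],
            outdir / "reference.gtf",
        )
        write_gtf(self.candidates, outdir / "candidates.gtf")
        write_fasta(
            {t.transcript_id: t.sequence for t in self.candidates},
            outdir / "candidates.fa",
        )
        self.evidence.write(outdir / "evidence")
        self.counts.to_csv(outdir / "counts.tsv", sep="\t",
                           index_label="gene_id")
        self.effective_lengths.to_frame().to_csv(
            outdir / "lengths.tsv", sep="\t", index_label="gene_id")
        self.metadata.to_csv(outdir / "samples.tsv", sep="\t", index=False)
        self.gene2go.to_csv(outdir / "gene2go.tsv", sep="\t", index=False,
                            header=False)
        self.manifest.to_json(outdir / "manifest.json")


def simulate_dataset(cfg: SimulationConfig | None = None) -> SyntheticDataset:
    """Run the full generator: genome, evidence, expression, GO, manifest."""
    cfg = cfg or SimulationConfig()
    genome, reference, candidates, manifest = simulate_genome_and_annotation(cfg)
    evidence = simulate_evidence(candidates, manifest, cfg)
    counts, metadata, lengths = simulate_expression(
        reference, candidates, manifest, cfg
    )
    gene2go, term_names = generate_go_annotation(manifest, cfg)
    return SyntheticDataset(
        cfg, genome, reference, candidates, manifest, evidence,
        counts, metadata, lengths, gene2go, term_names,
    )
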