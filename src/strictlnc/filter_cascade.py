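"""The strict nine-step lncRNA identification cascade.

A candidate transcript survives as a lncRNA when it is an autosomal
transcript of at least 200 nt that shows no protein homology (blastp,
blastx on the plus strand, protein-domain hits, all at e-value <= 1e-6),
no predicted signal peptide (D-score >= 0.45), no open reading frame
longer than 100 aa, no tRNA/rRNA family evidence, and no intron longer
than 6000 bp.  Transcripts removed only by protein homology whose best
nr hit (identity >= 70%) carries an uninformative description
("hypothetical protein", "unknown", ...) are *rescued*: homology to a
protein nobody has characterized is not treated as evidence of coding
potential.

Every step is evaluated for every transcript (no short-circuiting), so
the returned trail is a complete per-filter audit log; survival is
unaffected because the final status only asks whether any unrescued
fail occurred.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from .annotation_io import TranscriptModel, ValidationError, derive_introns

STEP_NAMES = (
    "length_and_chrom",
    "blastp",
    "blastx",
    "domain",
    "signal_peptide",
    "orf_length",
    "nr_review",
    "ncrna_family",
    "intron_length",
    "manual_review",
)

#: Steps whose fails a step-7 (nr_review) rescue clears: all protein-homology
#: evidence.  Length, signal peptide, ORF size, ncRNA family and intron-size
#: fails are never rescued.
_HOMOLOGY_STEPS = {"blastp", "blastx", "domain", "nr_review"}

BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass
class FilterConfig:
    min_length_nt: int = 200
    homology_evalue_max: float = 1e-6
    signalp_d_cutoff: float = 0.45
    max_orf_aa: int = 100
    rescue_pident_min: float = 70.0
    max_intron_bp: int = 6000
    retention_keywords: tuple[str, ...] = (
        "hypothetical protein",
        "similar to",
        "putative protein",
        "unknown",
        "predicted protein",
        "unnamed protein product",
    )
    allowed_chroms: tuple[str, ...] | None = None  # None = all chroms allowed
    require_plus_strand_for_blastx: bool = True

    def __post_init__(self):
        for name in ("min_length_nt", "homology_evalue_max", "signalp_d_cutoff",
                     "max_orf_aa", "rescue_pident_min", "max_intron_bp"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"FilterConfig.{name} must be positive")
        self.retention_keywords = tuple(k.lower() for k in self.retention_keywords)


def _empty(columns: list[str]) -> pd.DataFrame:
    return pd.DataFrame(columns=columns)


@dataclass
class EvidenceBundle:
    """Tabular homology/domain/signal-peptide/ncRNA-family evidence.

    BLAST-like tables use outfmt-6 column order, extended with ``sstrand``
    and (for nr best hits) ``description``.
    """

    blastp_hits: pd.DataFrame = field(
        default_factory=lambda: _empty(BLAST6_COLUMNS + ["sstrand"]))
    blastx_hits: pd.DataFrame = field(
        default_factory=lambda: _empty(BLAST6_COLUMNS + ["sstrand"]))
    domain_hits: pd.DataFrame = field(
        default_factory=lambda: _empty(["query_id", "domain_id", "evalue"]))
    signal_peptides: pd.DataFrame = field(
        default_factory=lambda: _empty(["query_id", "d_score"]))
    nr_best_hits: pd.DataFrame = field(
        default_factory=lambda: _empty(BLAST6_COLUMNS + ["sstrand", "description"]))
    ncrna_family_hits: pd.DataFrame = field(
        default_factory=lambda: _empty(["query_id", "family_id", "family_class", "evalue"]))
    known_ncrna_blastn_hits: pd.DataFrame = field(
        default_factory=lambda: _empty(BLAST6_COLUMNS + ["sstrand"]))

    _TABLES = (
        "blastp_hits", "blastx_hits", "domain_hits", "signal_peptides",
        "nr_best_hits", "ncrna_family_hits", "known_ncrna_blastn_hits",
    )

    def __post_init__(self):
        for name in self._TABLES:
            df = getattr(self, name)
            if "evalue" in df.columns and len(df) and (df["evalue"] < 0).any():
                raise ValidationError(f"{name}: negative e-value")
            if "pident" in df.columns and len(df) and (
                (df["pident"] < 0) | (df["pident"] > 100)
            ).any():
                raise ValidationError(f"{name}: pident outside [0, 100]")
            if "d_score" in df.columns and len(df) and (
                (df["d_score"] < 0) | (df["d_score"] > 1)
            ).any():
                raise ValidationError(f"{name}: d_score outside [0, 1]")

    @classmethod
    def load(cls, directory: str | Path) -> "EvidenceBundle":
        """Load evidence TSVs from a directory; missing files mean no hits."""
        directory = Path(directory)
        kwargs = {}
        for name in cls._TABLES:
            path = directory / f"{name}.tsv"
            if path.exists():
                kwargs[name] = pd.read_csv(path, sep="\t")
        return cls(**kwargs)

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name in self._TABLES:
            getattr(self, name).to_csv(directory / f"{name}.tsv", sep="\t", index=False)


@dataclass
class OrfCall:
    transcript_id: str
    orf_start: int  # transcript coordinate of the ATG
    orf_end: int    # exclusive; includes the stop codon when present
    frame: int
    peptide_length_aa: int
    peptide: str
    has_stop: bool


@dataclass
class FilterStep:
    step_name: str
    outcome: str  # pass | fail | rescued
    reason: str = ""


@dataclass
class FilterTrail:
    transcript_id: str
    steps: list[FilterStep]
    final_status: str  # lncRNA | removed


_STOPS = frozenset({"TAA", "TAG", "TGA"})


def find_longest_orf(
    sequence: str, require_stop: bool = True, transcript_id: str = ""
) -> OrfCall | None:
    """Longest ATG-initiated ORF over the three forward frames.

    Ties are broken by the 5'-most start.  Codons containing N are neither
    start nor stop and translate to X.  Returns None when no ORF exists
    (or the sequence is empty).
    """
    seq = sequence.upper()
    best: tuple[int, int, int, int, bool] | None = None  # (aa, start, end, frame, has_stop)
    for frame in range(3):
        open_start: int | None = None
        i = frame
        while i + 3 <= len(seq):
            codon = seq[i : i + 3]
            if open_start is None and codon == "ATG":
                open_start = i
            elif open_start is not None and codon in _STOPS:
                aa = (i - open_start) // 3
                cand = (aa, open_start, i + 3, frame, True)
                if best is None or aa > best[0] or (aa == best[0] and open_start < best[1]):
                    best = cand
                open_start = None
            i += 3
        if open_start is not None and not require_stop:
            end = open_start + 3 * ((len(seq) - open_start) // 3)
            aa = (end - open_start) // 3
            cand = (aa, open_start, end, frame, False)
            if best is None or aa > best[0] or (aa == best[0] and open_start < best[1]):
                best = cand
    if best is None:
        return None
    aa, start, end, frame, has_stop = best
    nt = seq[start : end - 3] if has_stop else seq[start:end]
    peptide = str(Seq(nt).translate()).replace("*", "X")
    return OrfCall(transcript_id, start, end, frame, aa, peptide, has_stop)


def _hits_by_query(df: pd.DataFrame, key: str = "qseqid") -> dict:
    if df.empty:
        return {}
    return {qid: sub for qid, sub in df.groupby(key, sort=False)}


def apply_strict_method(
    transcripts: Sequence[TranscriptModel],
    sequences: Mapping[str, str] | None,
    evidence: EvidenceBundle,
    cfg: FilterConfig | None = None,
    allowlist: Iterable[str] = (),
    denylist: Iterable[str] = (),
) -> tuple[set[str], dict[str, FilterTrail]]:
    """Run the full cascade and return (surviving ids, per-transcript trail).

    ``sequences`` may be None when every transcript carries its own
    sequence.  ``allowlist``/``denylist`` are the machine-readable stand-in
    for a final curation pass: denylisted transcripts are removed, and
    allowlisted ones retained, regardless of the cascade outcome.
    """
    cfg = cfg or FilterConfig()
    allowset, denyset = set(allowlist), set(denylist)

    known_ids = {t.transcript_id for t in transcripts}
    tables = {
        "blastp": (_hits_by_query(evidence.blastp_hits), "qseqid"),
        "blastx": (_hits_by_query(evidence.blastx_hits), "qseqid"),
        "domain": (_hits_by_query(evidence.domain_hits, "query_id"), "query_id"),
        "signalp": (_hits_by_query(evidence.signal_peptides, "query_id"), "query_id"),
        "nr": (_hits_by_query(evidence.nr_best_hits), "qseqid"),
        "family": (_hits_by_query(evidence.ncrna_family_hits, "query_id"), "query_id"),
        "blastn": (_hits_by_query(evidence.known_ncrna_blastn_hits), "qseqid"),
    }
    for name, (byq, _k) in tables.items():
        unknown = set(byq) - known_ids
        if unknown:
            import warnings

            warnings.warn(
                f"{name} evidence for {len(unknown)} unknown transcript id(s), "
                f"ignored (e.g. {sorted(unknown)[:3]})"
            )

    survivors: set[str] = set()
    trails: dict[str, FilterTrail] = {}
    emax = cfg.homology_evalue_max

    for t in transcripts:
        tid = t.transcript_id
        seq = t.sequence
        if seq is None and sequences is not None:
            seq = sequences.get(tid)
        if seq is None:
            raise ValidationError(f"{tid}: no sequence available for the cascade")

        steps: list[FilterStep] = []

        # 1. chromosome + length
        ok_chrom = cfg.allowed_chroms is None or t.chrom in cfg.allowed_chroms
        ok_len = len(seq) >= cfg.min_length_nt
        if ok_chrom and ok_len:
            steps.append(FilterStep("length_and_chrom", "pass"))
        else:
            reason = (
                f"length {len(seq)} < {cfg.min_length_nt}" if ok_chrom
                else f"chrom {t.chrom} not allowed"
            )
            steps.append(FilterStep("length_and_chrom", "fail", reason))

        # 2. blastp homology
        hits = tables["blastp"][0].get(tid)
        bad = hits is not None and (hits["evalue"] <= emax).any()
        steps.append(
            FilterStep("blastp", "fail" if bad else "pass",
                       f"blastp hit evalue <= {emax}" if bad else "")
        )

        # 3. blastx homology (plus subject strand)
        hits = tables["blastx"][0].get(tid)
        bad = False
        if hits is not None:
            mask = hits["evalue"] <= emax
            if cfg.require_plus_strand_for_blastx and "sstrand" in hits.columns:
                mask &= hits["sstrand"].eq("plus")
            bad = bool(mask.any())
        steps.append(
            FilterStep("blastx", "fail" if bad else "pass",
                       f"blastx plus-strand hit evalue <= {emax}" if bad else "")
        )

        # 4. protein domains
        hits = tables["domain"][0].get(tid)
        bad = hits is not None and (hits["evalue"] <= emax).any()
        steps.append(
            FilterStep("domain", "fail" if bad else "pass",
                       f"domain hit evalue <= {emax}" if bad else "")
        )

        # 5. signal peptide
        hits = tables["signalp"][0].get(tid)
        bad = hits is not None and (hits["d_score"] >= cfg.signalp_d_cutoff).any()
        steps.append(
            FilterStep("signal_peptide", "fail" if bad else "pass",
                       f"D-score >= {cfg.signalp_d_cutoff}" if bad else "")
        )

        # 6. longest ORF
        orf = find_longest_orf(seq, require_stop=True, transcript_id=tid)
        bad = orf is not None and orf.peptide_length_aa > cfg.max_orf_aa
        steps.append(
            FilterStep(
                "orf_length", "fail" if bad else "pass",
                f"ORF {orf.peptide_length_aa} aa > {cfg.max_orf_aa}" if bad else "",
            )
        )

        # 7. nr best-hit review; rescue on uninformative descriptions
        hits = tables["nr"][0].get(tid)
        outcome, reason = "pass", ""
        if hits is not None:
            sig = hits[hits["evalue"] <= emax]
            if "sstrand" in hits.columns:
                sig = sig[sig["sstrand"].eq("plus")]
            if len(sig):
                best = sig.sort_values(
                    ["evalue", "pident"], ascending=[True, False]
                ).iloc[0]
                if best["pident"] >= cfg.rescue_pident_min:
                    desc = str(best.get("description", "")).lower()
                    if any(k in desc for k in cfg.retention_keywords):
                        outcome = "rescued"
                        reason = f"uninformative best nr hit: {best.get('description', '')!r}"
                    else:
                        outcome = "fail"
                        reason = f"informative best nr hit: {best.get('description', '')!r}"
                # pident < 70: unaffected by this step
        steps.append(FilterStep("nr_review", outcome, reason))

        # 8. tRNA/rRNA families and known-ncRNA blastn
        fam = tables["family"][0].get(tid)
        bad_fam = fam is not None and fam["family_class"].isin(["tRNA", "rRNA"]).any()
        bn = tables["blastn"][0].get(tid)
        bad_bn = False
        if bn is not None:
            mask = bn["evalue"] <= emax
            if "sstrand" in bn.columns:
                mask &= bn["sstrand"].eq("plus")
            bad_bn = bool(mask.any())
        bad = bad_fam or bad_bn
        steps.append(
            FilterStep("ncrna_family", "fail" if bad else "pass",
                       "tRNA/rRNA family or known-ncRNA blastn hit" if bad else "")
        )

        # 9. intron length
        introns = derive_introns(t)
        too_long = [i for i in introns if len(i) > cfg.max_intron_bp]
        steps.append(
            FilterStep(
                "intron_length", "fail" if too_long else "pass",
                f"intron {len(too_long[0])} bp > {cfg.max_intron_bp}" if too_long else "",
            )
        )

        # 10. curation allow/deny lists
        if tid in denyset:
            steps.append(FilterStep("manual_review", "fail", "denylisted"))
        elif tid in allowset:
            steps.append(FilterStep("manual_review", "rescued", "allowlisted"))
        else:
            steps.append(FilterStep("manual_review", "pass"))

        rescued_nr = any(
            s.step_name == "nr_review" and s.outcome == "rescued" for s in steps
        )
        allow_all = any(
            s.step_name == "manual_review" and s.outcome == "rescued" for s in steps
        )
        unrescued_fail = False
        for s in steps:
            if s.outcome != "fail":
                continue
            if allow_all:
                continue
            if rescued_nr and s.step_name in _HOMOLOGY_STEPS:
                continue
            unrescued_fail = True
        status = "removed" if unrescued_fail else "lncRNA"
        trails[tid] = FilterTrail(tid, steps, status)
        if status == "lncRNA":
            survivors.add(tid)

    return survivors, trails


def trails_to_frame(trails: Mapping[str, FilterTrail]) -> pd.DataFrame:
    """One row per transcript per step, plus the final status."""
    rows = []
    for trail in trails.values():
        for s in trail.steps:
            rows.append(
                {
                    "transcript_id": trail.transcript_id,
                    "step_name": s.step_name,
                    "outcome": s.outcome,
                    "reason": s.reason,
                    "final_status": trail.final_status,
                }
            )
    return pd.DataFrame(rows)


def cascade_summary(trails: Mapping[str, FilterTrail]) -> dict:
    """Per-step fail counts and the survivor total."""
    df = trails_to_frame(trails)
    fails = (
        df[df["outcome"] == "fail"].groupby("step_name")["transcript_id"].nunique()
        if len(df) else pd.Series(dtype=int)
    )
    return {
        "n_transcripts": int(df["transcript_id"].nunique()) if len(df) else 0,
        "n_lncrna": int(
            df[df["final_status"] == "lncRNA"]["transcript_id"].nunique()
        ) if len(df) else 0,
        "fails_per_step": {step: int(fails.get(step, 0)) for step in STEP_NAMES},
        "n_rescued": int(
            df[(df["step_name"] == "nr_review") & (df["outcome"] == "rescued")]
            ["transcript_id"].nunique()
        ) if len(df) else 0,
    }


def categorize_coding_potential(scores: pd.DataFrame) -> pd.DataFrame:
    """Four-way coding-potential bins on scores in [0, 1].

    hc_noncoding: score <= 0.1; noncoding: 0.1 < score <= 0.5;
    coding: 0.5 < score < 0.9; hc_coding: score >= 0.9.
    """
    import numpy as np

    s = scores["coding_potential"]
    if ((s < 0) | (s > 1)).any():
        raise ValidationError("coding potential scores must lie in [0, 1]")
    category = np.select(
        [s <= 0.1, s <= 0.5, s < 0.9],
        ["hc_noncoding", "noncoding", "coding"],
        default="hc_coding",
    )
    out = scores.copy()
    out["category"] = category
    return out
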