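"""Strand-aware positional biotype classification of lncRNAs.

A surviving lncRNA is classified against every reference gene it touches,
considering *all* isoforms of that gene:

* **sense_exonic** — same-strand exonic overlap covering at least 10% of
  the lncRNA's exonic length;
* **NAT** (natural antisense transcript) — the same, on the opposite
  strand;
* **intronic** — the whole transcript span lies inside one intron of some
  isoform and the transcript touches no exon of that gene, on either
  strand;
* **lincRNA** — the transcript overlaps zero reference-gene bases (exon
  or intron, any strand).

Labels accumulate over reference genes, so a transcript squeezed between
a sense and an antisense gene can legitimately be both NAT and
sense_exonic.  Overlap fractions are measured between exon *base sets*,
not genomic spans, and the 10% threshold is inclusive.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotation_io import (
    GeneModel,
    GenomicInterval,
    TranscriptModel,
    ValidationError,
    derive_introns,
)

BIOTYPES = ("lincRNA", "NAT", "sense_exonic", "intronic")


@dataclass
class OverlapConfig:
    min_fraction_exonic: float = 0.1
    intronic_containment: float = 1.0
    #: unknown-strand policy: "skip" assigns no strand-dependent label
    #: (the transcript falls through to the intronic/lincRNA tests);
    #: "both" treats the transcript as being on both strands.
    strand_policy: str = "skip"
    #: measure the overlap fraction against exon base sets ("exonic")
    #: or whole transcript spans ("span").
    granularity: str = "exonic"

    def __post_init__(self):
        if not (0 < self.min_fraction_exonic <= 1):
            raise ValidationError("min_fraction_exonic must be in (0, 1]")
        if not (0 < self.intronic_containment <= 1):
            raise ValidationError("intronic_containment must be in (0, 1]")
        if self.strand_policy not in ("skip", "both"):
            raise ValidationError(f"unknown strand_policy {self.strand_policy!r}")
        if self.granularity not in ("exonic", "span"):
            raise ValidationError(f"unknown granularity {self.granularity!r}")


@dataclass
class BiotypeCall:
    transcript_id: str
    gene_id: str
    labels: set[str]
    overlapping_gene_ids: dict[str, set[str]] = field(default_factory=dict)


def merge_intervals(ivs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def overlap_length(a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]) -> int:
    """Total base overlap between two merged, sorted interval lists."""
    total = i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo < hi:
            total += hi - lo
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return total


class _GeneIndex:
    """Per-chromosome reference-gene geometry, precomputed once."""

    def __init__(self, reference: Sequence[GeneModel]):
        self.by_chrom: dict[str, list[dict]] = defaultdict(list)
        for g in reference:
            exons_by_strand: dict[str, list[tuple[int, int]]] = {"+": [], "-": []}
            all_exons: list[tuple[int, int]] = []
            introns: list[tuple[int, int]] = []
            span_lo, span_hi = None, None
            for t in g.transcripts:
                for e in t.exons:
                    if e.strand in exons_by_strand:
                        exons_by_strand[e.strand].append((e.start, e.end))
                    all_exons.append((e.start, e.end))
                for i in derive_introns(t):
                    introns.append((i.start, i.end))
                s = t.span
                span_lo = s.start if span_lo is None else min(span_lo, s.start)
                span_hi = s.end if span_hi is None else max(span_hi, s.end)
            self.by_chrom[g.chrom].append(
                {
                    "gene_id": g.gene_id,
                    "span": (span_lo, span_hi),
                    "exons+": merge_intervals(exons_by_strand["+"]),
                    "exons-": merge_intervals(exons_by_strand["-"]),
                    "exons": merge_intervals(all_exons),
                    "introns": introns,
                    # gene body: union of isoform spans (exons + introns)
                    "body": merge_intervals(
                        [(t.span.start, t.span.end) for t in g.transcripts]
                    ),
                }
            )


def classify_transcript(
    t: TranscriptModel,
    reference: Sequence[GeneModel] | _GeneIndex,
    cfg: OverlapConfig | None = None,
) -> BiotypeCall:
    cfg = cfg or OverlapConfig()
    index = reference if isinstance(reference, _GeneIndex) else _GeneIndex(reference)
    if not index.by_chrom:
        warnings.warn("empty reference annotation: every transcript is lincRNA")

    if cfg.granularity == "exonic":
        t_ivs = merge_intervals([(e.start, e.end) for e in t.exons])
    else:
        t_ivs = [(t.span.start, t.span.end)]
    t_len = sum(e - s for s, e in t_ivs)
    span = (t.span.start, t.span.end)

    labels: set[str] = set()
    overlapping: dict[str, set[str]] = defaultdict(set)
    touches_any_gene = False

    for g in index.by_chrom.get(t.chrom, []):
        glo, ghi = g["span"]
        if ghi <= span[0] or span[1] <= glo:
            continue
        if overlap_length([span], g["body"]) > 0:
            touches_any_gene = True

        if t.strand in ("+", "-") or cfg.strand_policy == "both":
            strands = [t.strand] if t.strand in ("+", "-") else ["+", "-"]
            for ts in strands:
                same = overlap_length(t_ivs, g[f"exons{ts}"])
                anti = overlap_length(t_ivs, g["exons-" if ts == "+" else "exons+"])
                if same >= cfg.min_fraction_exonic * t_len:
                    labels.add("sense_exonic")
                    overlapping["sense_exonic"].add(g["gene_id"])
                if anti >= cfg.min_fraction_exonic * t_len:
                    labels.add("NAT")
                    overlapping["NAT"].add(g["gene_id"])

        # intronic: full span inside one intron of some isoform, touching
        # no exon of this gene on either strand
        if overlap_length(t_ivs, g["exons"]) == 0:
            frac = cfg.intronic_containment
            need = frac * (span[1] - span[0])
            for ilo, ihi in g["introns"]:
                inside = min(span[1], ihi) - max(span[0], ilo)
                if inside >= need and (frac < 1 or (ilo <= span[0] and span[1] <= ihi)):
                    labels.add("intronic")
                    overlapping["intronic"].add(g["gene_id"])
                    break

    if not touches_any_gene:
        labels = {"lincRNA"}
        overlapping = {}
    elif not labels and t.strand == "." and cfg.strand_policy == "skip":
        # unknown-strand transcript overlapping exons: no strand-dependent
        # label can be assigned under the default policy; the label set is
        # left empty (documented edge case).
        pass

    return BiotypeCall(t.transcript_id, t.gene_id, labels, dict(overlapping))


def classify_transcripts(
    transcripts: Sequence[TranscriptModel],
    reference: Sequence[GeneModel],
    cfg: OverlapConfig | None = None,
) -> list[BiotypeCall]:
    index = _GeneIndex(reference)
    return [classify_transcript(t, index, cfg) for t in transcripts]


def calls_to_frame(calls: Sequence[BiotypeCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "transcript_id": [c.transcript_id for c in calls],
            "gene_id": [c.gene_id for c in calls],
            "labels": [";".join(sorted(c.labels)) for c in calls],
            "overlapping_genes": [
                ";".join(
                    f"{lab}:{','.join(sorted(gs))}"
                    for lab, gs in sorted(c.overlapping_gene_ids.items())
                )
                for c in calls
            ],
        }
    )


def aggregate_gene_biotypes(calls: Sequence[BiotypeCall]) -> pd.DataFrame:
    """Gene label set = union over isoforms; |set| > 1 flags ambiguity."""
    by_gene: dict[str, set[str]] = defaultdict(set)
    for c in calls:
        by_gene[c.gene_id] |= c.labels
    rows = [
        {
            "gene_id": gid,
            "labels": ";".join(sorted(labs)),
            "n_labels": len(labs),
            "ambiguous": len(labs) > 1,
        }
        for gid, labs in by_gene.items()
    ]
    return pd.DataFrame(rows)


def gene_biotype_summary(gene_table: pd.DataFrame) -> dict:
    """Per-label gene counts plus the distinct-gene arithmetic.

    distinct genes = sum of per-label counts minus, over each gene,
    (number of labels - 1); single-label annotations make the two equal.
    """
    label_counts: dict[str, int] = {b: 0 for b in BIOTYPES}
    for labs in gene_table["labels"]:
        for lab in labs.split(";"):
            if lab:
                label_counts[lab] = label_counts.get(lab, 0) + 1
    excess = int((gene_table["n_labels"] - 1).clip(lower=0).sum())
    return {
        "per_label_gene_counts": label_counts,
        "n_multi_label_genes": int(gene_table["ambiguous"].sum()),
        "distinct_genes": sum(label_counts.values()) - excess,
    }


# ---------------------------------------------------------------------------
# Annotation-set comparison (reciprocal full overlap)
# ---------------------------------------------------------------------------

def _identity_key(t: TranscriptModel, granularity: str) -> tuple:
    if granularity == "span":
        s = t.span
        return (s.chrom, s.strand, s.start, s.end)
    return (t.chrom, t.strand, tuple((e.start, e.end) for e in t.exons))


@dataclass
class ComparisonResult:
    set_names: list[str]
    membership: pd.DataFrame  # one row per combination, gene counts
    pairwise_shared_genes: pd.DataFrame
    unique_genes: dict[str, int]


def compare_annotations(
    sets: Mapping[str, Sequence[TranscriptModel]],
    granularity: str = "span",
) -> ComparisonResult:
    """Shared/unique counts under reciprocal 100% same-strand overlap.

    A transcript pair is shared iff the overlap covers all of both
    transcripts on the same strand — i.e. identical genomic spans (or
    identical exon chains for granularity="exact").  Gene-level sharing
    means any isoform pair is shared.
    """
    names = list(sets)
    chroms = {n: {t.chrom for t in sets[n]} for n in names}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if chroms[a] and chroms[b] and not (chroms[a] & chroms[b]):
                raise ValidationError(
                    f"no shared chromosome names between {a!r} and {b!r}: "
                    f"{sorted(chroms[a])[:5]} vs {sorted(chroms[b])[:5]}"
                )

    key_sets: dict[tuple, set[str]] = defaultdict(set)
    for name in names:
        for t in sets[name]:
            key_sets[_identity_key(t, granularity)].add(name)

    # gene -> set of annotation names any isoform of the gene matches in
    gene_membership: dict[str, dict[str, set[str]]] = {n: defaultdict(set) for n in names}
    for name in names:
        for t in sets[name]:
            gene_membership[name][t.gene_id] |= key_sets[_identity_key(t, granularity)]

    pair = pd.DataFrame(0, index=names, columns=names)
    unique: dict[str, int] = {}
    for name in names:
        n_unique = 0
        for gid, member_of in gene_membership[name].items():
            if member_of == {name}:
                n_unique += 1
            for other in member_of:
                pair.loc[name, other] += 1
        unique[name] = n_unique

    rows = []
    for name in names:
        per_combo: dict[tuple[str, ...], int] = defaultdict(int)
        for gid, member_of in gene_membership[name].items():
            per_combo[tuple(n for n in names if n in member_of)] += 1
        for combo, count in sorted(per_combo.items()):
            rows.append(
                {"query_set": name, "shared_with": "&".join(combo), "n_genes": count}
            )
    membership = pd.DataFrame(rows)

    return ComparisonResult(names, membership, pair, unique)
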