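"""Expression summaries: TPM, confidence classes, stage bins and the Tau
tissue-specificity index.

Tau for a gene over N groups (tissues or developmental stages) is

    tau = sum_i (1 - x_i / max_j x_j) / (N - 1)

where x_i is the group-level expression — here the mean of log2(TPM + 1)
over the group's samples.  Tau is 0 for perfectly uniform expression and
1 for expression confined to a single group.  A gene counts as tissue-
or stage-specific when its Tau exceeds (strictly) the median Tau of the
supplied mRNA set; the cutoff is recomputed from the data rather than
hard-coded, because the reference median is cohort-dependent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation_io import ValidationError

#: Closed integer day ranges for the five developmental stages:
#: germination, leaf development, first inflorescence, flower production,
#: silique generation.  Ages outside every bin stay unbinned.
DEFAULT_STAGE_BINS: dict[str, tuple[int, int]] = {
    "Stage1": (3, 5),
    "Stage2": (6, 25),
    "Stage3": (26, 29),
    "Stage4": (30, 47),
    "Stage5": (48, 51),
}


@dataclass
class StageBins:
    bins: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_BINS)
    )

    def __post_init__(self):
        spans = sorted(self.bins.values())
        for (a_lo, a_hi), (b_lo, b_hi) in zip(spans, spans[1:]):
            if a_hi >= b_lo:
                raise ValidationError(f"overlapping stage bins {self.bins}")

    def assign(self, age_days: int) -> str | None:
        for label, (lo, hi) in self.bins.items():
            if lo <= age_days <= hi:
                return label
        return None


def assign_stage(age_days: int, bins: StageBins | None = None) -> str | None:
    return (bins or StageBins()).assign(age_days)


def assign_stages(metadata: pd.DataFrame, bins: StageBins | None = None) -> pd.Series:
    """Map each sample's age_days to its stage label (NaN when unbinned)."""
    bins = bins or StageBins()
    out = metadata["age_days"].map(bins.assign)
    n_unbinned = out.isna().sum()
    if n_unbinned:
        warnings.warn(f"{n_unbinned} sample(s) fall outside all stage bins")
    return pd.Series(out.values, index=metadata["sample_id"].values, name="stage")


def counts_to_tpm(counts: pd.DataFrame, effective_lengths: pd.Series) -> pd.DataFrame:
    """Standard TPM: per-sample length-normalized rates scaled to 1e6."""
    lengths = effective_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths[lengths.isna()].index.tolist()[:3]
        raise ValidationError(f"missing effective lengths for {missing} ...")
    if (lengths <= 0).any():
        raise ValidationError("effective lengths must be positive")
    rates = counts.div(lengths, axis=0)
    totals = rates.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tpm = rates.div(totals, axis=1) * 1e6
    tpm[tpm.columns[totals == 0]] = 0.0
    return tpm


def call_confidence(tpm: pd.DataFrame, threshold: float = 3.0) -> pd.DataFrame:
    """HC iff TPM >= threshold in at least one sample, else LC."""
    max_tpm = tpm.max(axis=1)
    return pd.DataFrame(
        {
            "gene_id": tpm.index,
            "status": np.where(max_tpm >= threshold, "HC", "LC"),
            "max_tpm": max_tpm.values,
        }
    ).set_index("gene_id")


def group_expression(
    tpm: pd.DataFrame, grouping: pd.Series, transform: str = "log2"
) -> pd.DataFrame:
    """Per-group mean expression; transform "log2" means log2(TPM+1)."""
    grouping = grouping.reindex(tpm.columns)
    if grouping.isna().any():
        raise ValidationError("grouping missing for some samples")
    values = np.log2(tpm + 1.0) if transform == "log2" else tpm
    return values.T.groupby(grouping).mean().T


def compute_tau(
    tpm: pd.DataFrame, grouping: pd.Series, transform: str = "log2"
) -> pd.DataFrame:
    """Tau profiles; genes with zero expression in every group are dropped."""
    gx = group_expression(tpm, grouping, transform)
    n_groups = gx.shape[1]
    if n_groups < 2:
        raise ValidationError("Tau needs at least two groups")
    maxima = gx.max(axis=1)
    keep = maxima > 0
    gx = gx[keep]
    maxima = maxima[keep]
    xhat = gx.div(maxima, axis=0)
    tau = (1.0 - xhat).sum(axis=1) / (n_groups - 1)
    return pd.DataFrame(
        {
            "tau": tau,
            "argmax_group": gx.idxmax(axis=1),
        },
        index=gx.index,
    )


def call_specific(
    profiles: pd.DataFrame, mrna_profiles: pd.DataFrame
) -> tuple[pd.DataFrame, float]:
    """Flag genes with tau strictly above the mRNA median; return cutoff."""
    if mrna_profiles.empty:
        raise ValidationError("mRNA Tau set is empty; cannot derive cutoff")
    cutoff = float(mrna_profiles["tau"].median())
    out = profiles.copy()
    out["specific"] = out["tau"] > cutoff
    return out, cutoff


def summarize_by_group(
    tpm: pd.DataFrame,
    grouping: pd.Series,
    expressed_threshold: float = 3.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expressed-in-group and unique-to-group summaries.

    A gene is expressed in a group when it reaches the threshold in at
    least one of the group's samples (aligned with the HC definition).
    Returns (boolean gene x group matrix, per-group summary frame).
    """
    grouping = grouping.reindex(tpm.columns)
    expressed = (tpm >= expressed_threshold).T.groupby(grouping).any().T
    n_groups_expressed = expressed.sum(axis=1)
    unique = expressed.loc[n_groups_expressed == 1]
    summary = pd.DataFrame(
        {
            "n_expressed": expressed.sum(axis=0),
            "n_unique": unique.sum(axis=0) if len(unique) else 0,
        }
    )
    summary.index.name = "group"
    return expressed, summary
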