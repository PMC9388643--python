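"""GO over-representation per co-expression module and guilt-by-association
function transfer to lncRNAs.

Each module's annotated coding genes are tested against an annotated
background with a one-sided upper-tail hypergeometric (Fisher) test per
term, Benjamini-Hochberg corrected within the module's term family;
terms with q < 0.01 are significant.  Every lncRNA assigned to a module
then inherits that module's significant terms — its co-expression
neighborhood is the only functional evidence available for a lncRNA.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .annotation_io import ValidationError
from .coexpression import ModuleAssignment


@dataclass
class GoAnnotation:
    gene_to_terms: dict[str, set[str]]
    term_names: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_frame(
        cls,
        mapping: pd.DataFrame,
        term_names: Mapping[str, str] | None = None,
        parents: Mapping[str, Iterable[str]] | None = None,
    ) -> "GoAnnotation":
        """Build from a two-column (gene_id, term_id) frame.

        When a term->parents table is supplied, annotations are closed
        over ancestors (a gene annotated to a term is annotated to all
        the term's ancestors).
        """
        gene_to_terms: dict[str, set[str]] = defaultdict(set)
        for gene, term in zip(mapping.iloc[:, 0], mapping.iloc[:, 1]):
            gene_to_terms[gene].add(term)
        if parents:
            closure: dict[str, set[str]] = {}

            def ancestors(term: str) -> set[str]:
                if term not in closure:
                    closure[term] = set()  # break cycles defensively
                    acc: set[str] = set()
                    for p in parents.get(term, ()):
                        acc.add(p)
                        acc |= ancestors(p)
                    closure[term] = acc
                return closure[term]

            for gene, terms in gene_to_terms.items():
                extra: set[str] = set()
                for t in terms:
                    extra |= ancestors(t)
                terms |= extra
        return cls(dict(gene_to_terms), dict(term_names or {}))

    @classmethod
    def from_tsv(cls, path: str | Path, parents_path: str | Path | None = None):
        mapping = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "term_id"])
        parents = None
        if parents_path is not None:
            pf = pd.read_csv(parents_path, sep="\t", header=None,
                             names=["term_id", "parent_id"])
            parents = defaultdict(list)
            for t, p in zip(pf["term_id"], pf["parent_id"]):
                parents[t].append(p)
        return cls.from_frame(mapping, parents=parents)

    def annotated(self, genes: Iterable[str]) -> list[str]:
        return [g for g in genes if self.gene_to_terms.get(g)]


def hypergeom_enrich(
    module_genes: Sequence[str],
    background_genes: Sequence[str],
    annotation: GoAnnotation,
) -> pd.DataFrame:
    """One-sided hypergeometric p per term present in the module.

    Only annotated genes count: n = annotated module genes, N = annotated
    background genes, K = background carriers of the term, k = module
    carriers.  Terms with k = 0 are skipped.
    """
    background = annotation.annotated(dict.fromkeys(background_genes))
    module = [g for g in dict.fromkeys(module_genes) if g in set(background)]
    if not module:
        warnings.warn("module has no annotated genes; empty enrichment")
        return pd.DataFrame(columns=["term_id", "k", "K", "n", "N", "p_value"])
    if not set(module) <= set(background):
        raise ValidationError("module genes must be a subset of the background")
    N, n = len(background), len(module)
    carriers: dict[str, int] = defaultdict(int)
    module_carriers: dict[str, int] = defaultdict(int)
    module_set = set(module)
    for g in background:
        for t in annotation.gene_to_terms[g]:
            carriers[t] += 1
            if g in module_set:
                module_carriers[t] += 1
    rows = []
    for term, k in sorted(module_carriers.items()):
        K = carriers[term]
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append({"term_id": term, "k": k, "K": K, "n": n, "N": N,
                     "p_value": min(p, 1.0)})
    return pd.DataFrame(rows)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def enrich_modules(
    modules: ModuleAssignment,
    background_genes: Sequence[str],
    annotation: GoAnnotation,
    q_threshold: float = 0.01,
) -> pd.DataFrame:
    """Per-module enrichment with BH applied within each module's terms."""
    frames = []
    for module in sorted(m for m in modules.sizes if m != 0):
        member = [g for g in modules.members(module)]
        res = hypergeom_enrich(member, background_genes, annotation)
        if res.empty:
            continue
        res.insert(0, "module", module)
        res["q_value"] = bh_adjust(res["p_value"].values)
        res["significant"] = res["q_value"] < q_threshold
        frames.append(res)
    if not frames:
        return pd.DataFrame(
            columns=["module", "term_id", "k", "K", "n", "N",
                     "p_value", "q_value", "significant"]
        )
    return pd.concat(frames, ignore_index=True)


def assign_functions_to_lncrnas(
    modules: ModuleAssignment,
    enrichment: pd.DataFrame,
    lncrna_ids: Sequence[str],
) -> pd.DataFrame:
    """Each lncRNA inherits its module's significant terms.

    lncRNAs in module 0, or in modules with no significant term, get an
    empty term list.
    """
    sig_terms: dict[int, list[str]] = defaultdict(list)
    if len(enrichment):
        for module, sub in enrichment[enrichment["significant"]].groupby("module"):
            sig_terms[int(module)] = sorted(sub["term_id"])
    rows = []
    for lnc in lncrna_ids:
        module = int(modules.labels.get(lnc, 0))
        terms = sig_terms.get(module, []) if module != 0 else []
        rows.append(
            {"gene_id": lnc, "module": module, "terms": ";".join(terms),
             "n_terms": len(terms)}
        )
    return pd.DataFrame(rows)
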