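"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately naive (per-base sets, full enumeration,
exact rational arithmetic, triple loops) and shares no code with the
package's algorithmic paths.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np

from strictlnc.annotation_io import GeneModel, TranscriptModel, derive_introns

_STOPS = {"TAA", "TAG", "TGA"}


def brute_force_longest_orf(seq: str, require_stop: bool = True):
    """Enumerate every ATG-initiated ORF; return (aa_len, start) of the
    longest (ties to the 5'-most start), or None."""
    seq = seq.upper()
    candidates = []
    for start in range(len(seq) - 2):
        if seq[start : start + 3] != "ATG":
            continue
        i = start
        stop_at = None
        while i + 3 <= len(seq):
            if i > start and seq[i : i + 3] in _STOPS:
                stop_at = i
                break
            i += 3
        if stop_at is not None:
            candidates.append(((stop_at - start) // 3, start))
        elif not require_stop:
            candidates.append(((len(seq) - start) // 3, start))
    if not candidates:
        return None
    best_aa = max(aa for aa, _ in candidates)
    best_start = min(s for aa, s in candidates if aa == best_aa)
    return best_aa, best_start


def brute_force_biotype(
    t: TranscriptModel, genes: list[GeneModel], min_frac: float = 0.1
) -> set[str]:
    """Per-base reimplementation of the positional biotype rules."""
    t_ex: set[int] = set()
    for e in t.exons:
        t_ex |= set(range(e.start, e.end))
    span = set(range(t.span.start, t.span.end))
    labels: set[str] = set()
    touches = False
    for g in genes:
        if g.chrom != t.chrom:
            continue
        body: set[int] = set()
        ex_plus: set[int] = set()
        ex_minus: set[int] = set()
        for iso in g.transcripts:
            body |= set(range(iso.span.start, iso.span.end))
            for e in iso.exons:
                (ex_plus if e.strand == "+" else ex_minus).update(
                    range(e.start, e.end)
                )
        if span & body:
            touches = True
        if t.strand in ("+", "-"):
            same = ex_plus if t.strand == "+" else ex_minus
            anti = ex_minus if t.strand == "+" else ex_plus
            if len(t_ex & same) >= min_frac * len(t_ex):
                labels.add("sense_exonic")
            if len(t_ex & anti) >= min_frac * len(t_ex):
                labels.add("NAT")
        if not t_ex & (ex_plus | ex_minus):
            for iso in g.transcripts:
                for intron in derive_introns(iso):
                    if intron.start <= t.span.start and t.span.end <= intron.end:
                        labels.add("intronic")
                        break
    if not touches:
        return {"lincRNA"}
    return labels


def brute_force_tom(adj: np.ndarray) -> np.ndarray:
    """Triple-loop topological overlap."""
    n = adj.shape[0]
    a = adj.copy().astype(float)
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    tom = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(n))
            tom[i, j] = (l_ij + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return tom


def exact_hypergeom_upper(k: int, N: int, K: int, n: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeom(N, K, n), by exact enumeration."""
    total = Fraction(0)
    for j in range(k, min(K, n) + 1):
        total += Fraction(comb(K, j) * comb(N - K, n - j), comb(N, n))
    return total


def bh_stepup(p_values) -> list[float]:
    """Hand-rolled BH step-up: q_(i) = min_{j>=i} m*p_(j)/j."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q_sorted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p_values[i] / rank)
        q_sorted[rank - 1] = running
    out = [0.0] * m
    for rank, i in enumerate(order):
        out[i] = q_sorted[rank]
    return out


def random_interval_instance(rng: np.random.Generator, coord_max: int = 4000):
    """A random reference annotation + candidates for oracle comparison.

    Stays under ~200 intervals per instance; candidate strands include
    unknown (".") to exercise the fall-through policy.
    """
    from strictlnc.annotation_io import GenomicInterval

    genes: list[GeneModel] = []
    for gi in range(int(rng.integers(5, 20))):
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        gid = f"G{gi}"
        isoforms = []
        anchor = int(rng.integers(0, coord_max - 600))
        for ti in range(int(rng.integers(1, 3))):
            pos = anchor + int(rng.integers(0, 80))
            exons = []
            for _ in range(int(rng.integers(1, 4))):
                length = int(rng.integers(20, 150))
                exons.append(GenomicInterval("chr", pos, pos + length, strand))
                pos += length + int(rng.integers(25, 160))
            isoforms.append(TranscriptModel(f"{gid}.{ti}", gid, exons))
        genes.append(GeneModel(gid, isoforms))
    candidates: list[TranscriptModel] = []
    for ci in range(int(rng.integers(5, 15))):
        strand = ["+", "-", "."][int(rng.integers(0, 3))]
        pos = int(rng.integers(0, coord_max - 400))
        exons = []
        for _ in range(int(rng.integers(1, 3))):
            length = int(rng.integers(20, 200))
            exons.append(GenomicInterval("chr", pos, pos + length, strand))
            pos += length + int(rng.integers(25, 160))
        candidates.append(TranscriptModel(f"C{ci}.1", f"C{ci}", exons))
    return genes, candidates
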