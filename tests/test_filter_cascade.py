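import numpy as np
import pandas as pd
import pytest

from conftest import make_tx
from oracles import brute_force_longest_orf
from strictlnc.annotation_io import ValidationError
from strictlnc.filter_cascade import (
    BLAST6_COLUMNS,
    EvidenceBundle,
    FilterConfig,
    apply_strict_method,
    categorize_coding_potential,
    find_longest_orf,
)


def blast_row(qid, evalue, pident=85.0, sstrand="plus", description=None):
    row = {c: 0 for c in BLAST6_COLUMNS}
    row.update({"qseqid": qid, "sseqid": "s", "pident": pident, "evalue": evalue,
                "sstrand": sstrand})
    if description is not None:
        row["description"] = description
    return row


def run_one(tx, evidence=None, cfg=None, **kwargs):
    survivors, trails = apply_strict_method(
        [tx], None, evidence or EvidenceBundle(), cfg or FilterConfig(), **kwargs
    )
    return survivors, trails[tx.transcript_id]


def first_fail(trail):
    for s in trail.steps:
        if s.outcome == "fail":
            return s.step_name
    return None


class TestLongestOrf:
    @pytest.mark.parametrize(
        "seq,peptide,aa",
        [
            ("ATGAAATGA", "MK", 2),
            ("CCATGAAATGA", "MK", 2),  # frame 2
            ("ATGGCTGCTGCTTAG", "MAAA", 4),
        ],
    )
    def test_hand_translated_examples(self, seq, peptide, aa):
        orf = find_longest_orf(seq)
        assert orf.peptide == peptide
        assert orf.peptide_length_aa == aa
        assert orf.orf_end - orf.orf_start == 3 * (aa + 1)  # includes stop

    def test_no_atg_returns_none(self):
        assert find_longest_orf("CCCCCC") is None
        assert find_longest_orf("") is None

    def test_longest_of_two_orfs_wins(self):
        seq = "ATG" + "GCT" * 4 + "TAA" + "ATG" + "GCT" * 6 + "TAA"
        orf = find_longest_orf(seq)
        assert orf.peptide_length_aa == 7

    def test_require_stop_false_allows_open_end(self):
        seq = "ATG" + "GCT" * 6
        assert find_longest_orf(seq, require_stop=True) is None
        orf = find_longest_orf(seq, require_stop=False)
        assert orf.peptide_length_aa == 7 and not orf.has_stop

    def test_n_codons_are_neither_start_nor_stop(self):
        orf = find_longest_orf("ATGANATAA")
        assert orf.peptide == "MX"

    def test_matches_enumeration_oracle_on_random_sequences(self):
        rng = np.random.default_rng(42)
        bases = np.array(list("ACGT"))
        for _ in range(120):
            seq = "".join(bases[rng.integers(0, 4, size=int(rng.integers(3, 300)))])
            for require_stop in (True, False):
                expected = brute_force_longest_orf(seq, require_stop)
                got = find_longest_orf(seq, require_stop=require_stop)
                if expected is None:
                    assert got is None
                else:
                    assert (got.peptide_length_aa, got.orf_start) == expected


def no_orf_seq(n):
    return "C" * n


class TestStrictMethodBoundaries:
    def test_length_floor_is_200(self):
        short = make_tx("t.1", "Chr1", "+", [(0, 199)], seq=no_orf_seq(199))
        ok = make_tx("t.2", "Chr1", "+", [(0, 200)], seq=no_orf_seq(200))
        surv, trail = run_one(short)
        assert surv == set() and first_fail(trail) == "length_and_chrom"
        surv, _ = run_one(ok)
        assert surv == {"t.2"}

    def test_disallowed_chromosome_fails_step_one(self):
        cfg = FilterConfig(allowed_chroms=("Chr1",))
        tx = make_tx("t.1", "ChrC", "+", [(0, 300)], seq=no_orf_seq(300))
        surv, trail = run_one(tx, cfg=cfg)
        assert surv == set() and first_fail(trail) == "length_and_chrom"

    def test_orf_limit_is_strictly_greater_than_100(self):
        # the ATG codes the first residue: ATG + 99 codons + stop = 100 aa
        seq100 = "C" * 10 + "ATG" + "GCT" * 99 + "TAA"
        seq101 = "C" * 10 + "ATG" + "GCT" * 100 + "TAA"
        ok = make_tx("t.1", "Chr1", "+", [(0, len(seq100))], seq=seq100)
        bad = make_tx("t.2", "Chr1", "+", [(0, len(seq101))], seq=seq101)
        assert run_one(ok)[0] == {"t.1"}
        surv, trail = run_one(bad)
        assert surv == set() and first_fail(trail) == "orf_length"

    def test_intron_limit_is_strictly_greater_than_6000(self):
        ok = make_tx("t.1", "Chr1", "+", [(0, 150), (6150, 6300)],
                     seq=no_orf_seq(300))
        bad = make_tx("t.2", "Chr1", "+", [(0, 150), (6151, 6301)],
                      seq=no_orf_seq(300))
        assert run_one(ok)[0] == {"t.1"}
        surv, trail = run_one(bad)
        assert surv == set() and first_fail(trail) == "intron_length"

    def test_homology_evalue_boundary_inclusive(self):
        tx = make_tx("t.1", "Chr1", "+", [(0, 300)], seq=no_orf_seq(300))
        at = EvidenceBundle(blastp_hits=pd.DataFrame([blast_row("t.1", 1e-6)]))
        above = EvidenceBundle(blastp_hits=pd.DataFrame([blast_row("t.1", 1.1e-6)]))
        surv, trail = run_one(tx, at)
        assert surv == set() and first_fail(trail) == "blastp"
        assert run_one(tx, above)[0] == {"t.1"}

    def test_blastx_requires_plus_subject_strand(self):
        tx = make_tx("t.1", "Chr1", "+", [(0, 300)], seq=no_orf_seq(300))
        minus = EvidenceBundle(
            blastx_hits=pd.DataFrame([blast_row("t.1", 1e-10, sstrand="minus")]))
        plus = EvidenceBundle(
            blastx_hits=pd.DataFrame([blast_row("t.1", 1e-10, sstrand="plus")]))
        assert run_one(tx, minus)[0] == {"t.1"}
        surv, trail = run_one(tx, plus)
        assert surv == set() and first_fail(trail) == "blastx"

    def test_signal_peptide_d_cutoff_inclusive(self):
        tx = make_tx("t.1", "Chr1", "+", [(0, 300)], seq=no_orf_seq(300))
        at = EvidenceBundle(
            signal_peptides=pd.DataFrame([{"query_id": "t.1", "d_score": 0.45}]))
        below = EvidenceBundle(
            signal_peptides=pd.DataFrame([{"query_id": "t.1", "d_score": 0.4499}]))
        surv, trail = run_one(tx, at)
        assert surv == set() and first_fail(trail) == "signal_peptide"
        assert run_one(tx, below)[0] == {"t.1"}

    def test_ncrna_family_trna_fails_but_other_class_passes(self):
        tx = make_tx("t.1", "Chr1", "+", [(0, 300)], seq=no_orf_seq(300))
        trna = EvidenceBundle(ncrna_family_hits=pd.DataFrame(
            [{"query_id": "t.1", "family_id": "RF00005", "family_class": "tRNA",
              "evalue": 1e-10}]))
        other = EvidenceBundle(ncrna_family_hits=pd.DataFrame(
            [{"query_id": "t.1", "family_id": "RF99999", "family_class": "other",
              "evalue": 1e-10}]))
        surv, trail = run_one(tx, trna)
        assert surv == set() and first_fail(trail) == "ncrna_family"
        assert run_one(tx, other)[0] == {"t.1"}


class TestNrReviewAndRescue:
    def tx(self):
        return make_tx("t.1", "Chr1", "+", [(0, 500)], seq=no_orf_seq(500))

    def test_informative_description_fails(self):
        ev = EvidenceBundle(nr_best_hits=pd.DataFrame(
            [blast_row("t.1", 1e-9, pident=85.0,
                       description="60S ribosomal protein L3")]))
        surv, trail = run_one(self.tx(), ev)
        assert surv == set() and first_fail(trail) == "nr_review"

    def test_retention_keyword_rescues(self):
        ev = EvidenceBundle(nr_best_hits=pd.DataFrame(
            [blast_row("t.1", 1e-9, pident=85.0,
                       description="Hypothetical PROTEIN At1g99999")]))
        surv, trail = run_one(self.tx(), ev)
        assert surv == {"t.1"}
        assert any(s.step_name == "nr_review" and s.outcome == "rescued"
                   for s in trail.steps)

    def test_rescue_clears_earlier_protein_homology_fail(self):
        # homology to an uncharacterized protein is not coding evidence
        ev = EvidenceBundle(
            blastp_hits=pd.DataFrame([blast_row("t.1", 1e-12)]),
            nr_best_hits=pd.DataFrame(
                [blast_row("t.1", 1e-9, pident=85.0,
                           description="hypothetical protein")]),
        )
        surv, trail = run_one(self.tx(), ev)
        assert trail.final_status == "lncRNA"
        assert surv == {"t.1"}

    def test_rescue_never_clears_non_homology_fails(self):
        short = make_tx("t.1", "Chr1", "+", [(0, 150)], seq=no_orf_seq(150))
        ev = EvidenceBundle(nr_best_hits=pd.DataFrame(
            [blast_row("t.1", 1e-9, pident=85.0,
                       description="hypothetical protein")]))
        surv, trail = run_one(short, ev)
        assert surv == set()

    def test_pident_boundary_and_sub70_unaffected(self):
        at = EvidenceBundle(nr_best_hits=pd.DataFrame(
            [blast_row("t.1", 1e-9, pident=70.0, description="ribosomal protein")]))
        below = EvidenceBundle(nr_best_hits=pd.DataFrame(
            [blast_row("t.1", 1e-9, pident=69.9, description="ribosomal protein")]))
        surv, trail = run_one(self.tx(), at)
        assert surv == set() and first_fail(trail) == "nr_review"
        surv, trail = run_one(self.tx(), below)
        assert surv == {"t.1"}  # sub-70% identity: step 7 does not apply

    def test_best_hit_selected_by_evalue_then_pident(self):
        ev = EvidenceBundle(nr_best_hits=pd.DataFrame([
            blast_row("t.1", 1e-9, pident=90.0, description="ribosomal protein"),
            blast_row("t.1", 1e-20, pident=80.0, description="hypothetical protein"),
        ]))
        surv, _ = run_one(self.tx(), ev)
        assert surv == {"t.1"}  # the lowest-evalue hit carries the keyword


class TestCascadeProperties:
    def test_missing_sequence_is_configuration_error(self):
        tx = make_tx("t.1", "Chr1", "+", [(0, 300)])
        with pytest.raises(ValidationError, match="sequence"):
            apply_strict_method([tx], None, EvidenceBundle(), FilterConfig())

    def test_unknown_evidence_ids_warn_and_are_ignored(self):
        tx = make_tx("t.1", "Chr1", "+", [(0, 300)], seq=no_orf_seq(300))
        ev = EvidenceBundle(blastp_hits=pd.DataFrame([blast_row("ghost", 1e-10)]))
        with pytest.warns(UserWarning, match="unknown transcript"):
            surv, _ = apply_strict_method([tx], None, ev, FilterConfig())
        assert surv == {"t.1"}

    def test_order_insensitivity(self, small_dataset):
        ds = small_dataset
        surv_a, trails_a = apply_strict_method(
            ds.candidates, None, ds.evidence, FilterConfig())
        reordered = list(reversed(ds.candidates))
        surv_b, trails_b = apply_strict_method(
            reordered, None, ds.evidence, FilterConfig())
        assert surv_a == surv_b
        for tid in trails_a:
            assert [s.outcome for s in trails_a[tid].steps] == [
                s.outcome for s in trails_b[tid].steps
            ]

    def test_relaxing_thresholds_never_shrinks_survivors(self, small_dataset):
        ds = small_dataset
        strict, _ = apply_strict_method(ds.candidates, None, ds.evidence,
                                        FilterConfig())
        relaxed_cfg = FilterConfig(
            min_length_nt=100, homology_evalue_max=1e-12,
            signalp_d_cutoff=0.99, max_orf_aa=200, max_intron_bp=10_000,
        )
        relaxed, _ = apply_strict_method(ds.candidates, None, ds.evidence,
                                         relaxed_cfg)
        assert strict <= relaxed

    def test_denylist_removes_and_allowlist_retains(self):
        clean = make_tx("t.1", "Chr1", "+", [(0, 300)], seq=no_orf_seq(300))
        short = make_tx("t.2", "Chr1", "+", [(0, 150)], seq=no_orf_seq(150))
        surv, _ = apply_strict_method(
            [clean, short], None, EvidenceBundle(), FilterConfig(),
            allowlist=["t.2"], denylist=["t.1"],
        )
        assert surv == {"t.2"}


class TestCodingPotentialCategories:
    @pytest.mark.parametrize(
        "score,category",
        [
            (0.0, "hc_noncoding"),
            (0.10, "hc_noncoding"),
            (0.11, "noncoding"),
            (0.50, "noncoding"),
            (0.51, "coding"),
            (0.89, "coding"),
            (0.90, "hc_coding"),
            (1.0, "hc_coding"),
        ],
    )
    def test_four_bins(self, score, category):
        out = categorize_coding_potential(
            pd.DataFrame({"transcript_id": ["t"], "coding_potential": [score]})
        )
        assert out["category"].iloc[0] == category

    def test_out_of_range_score_rejected(self):
        with pytest.raises(ValidationError):
            categorize_coding_potential(
                pd.DataFrame({"transcript_id": ["t"], "coding_potential": [1.2]})
            )
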