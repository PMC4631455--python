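"""Alignment ingestion, column statistics and back-to-consensus rules."""

import numpy as np
import pytest

import thermodesign as td
from thermodesign.msa import (
    AlignmentShapeError,
    QueryLookupError,
    column_profile,
    conservation_from_grades,
    pairwise_identity,
    read_profile_tsv,
    write_candidates_tsv,
)

from conftest import random_alignment


FASTA = """>query
MKLV-A
>hom1
MKLLIA
>hom2
MRLL-A
"""


class TestReadAlignment:
    def test_fasta_roundtrip(self, tmp_path):
        p = tmp_path / "aln.fasta"
        p.write_text(FASTA)
        aln = td.read_alignment(p, query_id="query")
        assert aln.n_sequences == 3
        assert aln.length == 6
        assert aln.query_sequence == "MKLVA"
        out = tmp_path / "out.fasta"
        td.write_alignment(aln, out)
        again = td.read_alignment(out, query_id="query")
        assert again.records == aln.records

    def test_clustal_format(self, tmp_path):
        p = tmp_path / "aln.fasta"
        p.write_text(FASTA)
        aln = td.read_alignment(p, query_id="query")
        clu = tmp_path / "aln.aln"
        td.write_alignment(aln, clu, format="clustal")
        again = td.read_alignment(clu, query_id="query", format="clustal")
        assert again.records == aln.records

    def test_unknown_characters_become_wildcard(self, tmp_path):
        p = tmp_path / "aln.fasta"
        p.write_text(">query\nMKB\n>hom1\nMKZ\n")
        aln = td.read_alignment(p, query_id="query")
        assert aln.records[0][1] == "MKX"
        assert aln.records[1][1] == "MKX"

    def test_ragged_rows_error(self):
        with pytest.raises(AlignmentShapeError):
            td.Alignment(records=[("a", "MK"), ("b", "MKL")], query_id="a")

    def test_missing_query_error(self):
        with pytest.raises(QueryLookupError):
            td.Alignment(records=[("a", "MK")], query_id="nope")

    def test_all_gap_query_error(self):
        with pytest.raises(ValueError):
            td.Alignment(records=[("a", "--"), ("b", "MK")], query_id="a")


class TestColumnProfile:
    def _aln(self, *cols):
        rows = ["".join(c) for c in zip(*cols)]
        recs = [(f"s{i}" if i else "query", r) for i, r in enumerate(rows)]
        return td.Alignment(records=recs, query_id="query")

    def test_exclude_gaps_direct_count(self):
        aln = self._aln("LLLV")
        prof = column_profile(aln, 0, "exclude_gaps")
        assert prof.frequencies == {"L": 0.75, "V": 0.25}

    @pytest.mark.parametrize(
        "policy,expected_L", [("exclude_gaps", 1.0), ("count_gaps", 0.5)]
    )
    def test_gap_policies(self, policy, expected_L):
        aln = self._aln("LL--")
        prof = column_profile(aln, 0, policy)
        assert prof.frequencies == {"L": expected_L}
        assert prof.gap_fraction == 0.5

    def test_query_gap_column_rejected(self):
        aln = td.Alignment(
            records=[("query", "-A"), ("s1", "LA")], query_id="query"
        )
        with pytest.raises(ValueError, match="gap in the query"):
            column_profile(aln, 0)

    def test_frequencies_sum_to_one_excluding_gaps(self, rng):
        for _ in range(30):
            aln = random_alignment(rng)
            for qpos, col in aln.query_position_to_column().items():
                prof = column_profile(aln, col, "exclude_gaps")
                if prof.frequencies:
                    assert sum(prof.frequencies.values()) == pytest.approx(1.0, abs=1e-9)


class TestSimpleConsensus:
    def _one_column(self, column):
        recs = [(f"s{i}" if i else "query", c) for i, c in enumerate(column)]
        return td.Alignment(records=recs, query_id="query")

    def test_majority_over_cutoff(self):
        # wt V; L at 0.6 >= 0.5
        aln = self._one_column("VLLLV")
        (cand,) = td.simple_consensus(aln)
        assert (cand.wild_type, cand.proposed) == ("V", "L")
        assert cand.consensus_frequency == 0.6

    def test_inclusive_tie_prefers_non_wildtype(self):
        # exact 50/50 tie: "at least 50%" is inclusive, tie goes to non-wt
        aln = self._one_column("VLLV")
        (cand,) = td.simple_consensus(aln, cutoff=0.5)
        assert cand.proposed == "L"
        assert cand.consensus_frequency == 0.5

    def test_consensus_equals_wildtype_no_candidate(self):
        aln = self._one_column("LLLLV")
        assert td.simple_consensus(aln) == []

    def test_mask_suppresses_candidate(self):
        aln = self._one_column("VLLLV")
        assert td.simple_consensus(aln, mask={1}) == []

    def test_cutoff_monotonicity(self, rng):
        for _ in range(20):
            aln = random_alignment(rng)
            lo = {c.notation for c in td.simple_consensus(aln, cutoff=0.4)}
            hi = {c.notation for c in td.simple_consensus(aln, cutoff=0.6)}
            assert hi <= lo


class TestFrequencyRatio:
    def _freq_aln(self, wt, consensus, wt_n, cons_n, total=20):
        """One-column alignment with controlled wt/consensus counts."""
        fillers = [aa for aa in "GSDENQKRHW" if aa not in (wt, consensus)]
        col = [wt] + [consensus] * cons_n + [wt] * (wt_n - 1)
        col += [fillers[i % len(fillers)] for i in range(total - len(col))]
        recs = [(f"s{i}" if i else "query", c) for i, c in enumerate(col)]
        return td.Alignment(records=recs, query_id="query")

    def test_candidate_forced_by_rule(self):
        # wt 1/20 = 0.05, consensus 9/20 = 0.45: ratio 0.111 <= 0.2, 0.45 >= 0.4
        aln = self._freq_aln("V", "L", wt_n=1, cons_n=9)
        (cand,) = td.frequency_ratio(aln)
        assert cand.proposed == "L"

    def test_ratio_too_high(self):
        # wt 2/20 = 0.10... need ratio > 0.2: wt 0.10/0.45 = 0.222 > 0.2
        aln = self._freq_aln("V", "L", wt_n=2, cons_n=9)
        assert td.frequency_ratio(aln) == []

    def test_consensus_frequency_too_low(self):
        # consensus 7/20 = 0.35 < 0.4
        aln = self._freq_aln("V", "L", wt_n=1, cons_n=7)
        assert td.frequency_ratio(aln) == []


class TestConsensusOracle:
    """Both rules agree with a brute-force per-column reimplementation."""

    @staticmethod
    def _oracle(aln, simple_cutoff=0.5, ratio_cutoff=0.2, min_freq=0.4):
        simple, ratio = set(), set()
        qrow = aln.query_row
        for qpos, col_idx in aln.query_position_to_column().items():
            wt = qrow[col_idx]
            if wt == "X":
                continue
            col = [c for c in aln.column(col_idx) if c in set("ACDEFGHIKLMNPQRSTVWY")]
            if not col:
                continue
            freqs = {aa: col.count(aa) / len(col) for aa in set(col)}
            best = max(freqs.values())
            tied = sorted(aa for aa, f in freqs.items() if f == best)
            non_wt = [aa for aa in tied if aa != wt]
            cons = non_wt[0] if non_wt else tied[0]
            if cons != wt and best >= simple_cutoff:
                simple.add((qpos, wt, cons))
            if cons != wt and best >= min_freq and freqs.get(wt, 0.0) / best <= ratio_cutoff:
                ratio.add((qpos, wt, cons))
        return simple, ratio

    def test_agreement_on_200_random_alignments(self, rng):
        for _ in range(200):
            aln = random_alignment(rng)
            want_simple, want_ratio = self._oracle(aln)
            got_simple = {
                (c.query_position, c.wild_type, c.proposed)
                for c in td.simple_consensus(aln)
            }
            got_ratio = {
                (c.query_position, c.wild_type, c.proposed)
                for c in td.frequency_ratio(aln)
            }
            assert got_simple == want_simple
            assert got_ratio == want_ratio

    def test_no_wildtype_proposals_or_masked_positions(self, rng):
        for _ in range(50):
            aln = random_alignment(rng)
            mask = {1, 2}
            for cand in td.simple_consensus(aln, mask=mask) + td.frequency_ratio(
                aln, mask=mask
            ):
                assert cand.wild_type != cand.proposed
                assert cand.query_position not in mask


class TestConservation:
    def test_nine_evenly_spaced_rates_span_grades(self):
        rates = {i + 1: -2.0 + i * 0.5 for i in range(9)}
        prof = td.grades_from_rates(rates)
        assert [prof.grades[i + 1] for i in range(9)] == [9, 8, 7, 6, 5, 4, 3, 2, 1]

    @pytest.mark.parametrize("rates", [{1: 0.3, 2: 0.3, 3: 0.3}, {1: -1.2}])
    def test_degenerate_range_gives_grade_five(self, rates):
        prof = td.grades_from_rates(rates)
        assert set(prof.grades.values()) == {5}

    def test_grade_non_increasing_in_rate(self, rng):
        rates = {i + 1: float(r) for i, r in enumerate(rng.normal(size=40))}
        prof = td.grades_from_rates(rates)
        ordered = sorted(rates, key=rates.get)
        grades = [prof.grades[p] for p in ordered]
        assert all(a >= b for a, b in zip(grades, grades[1:]))

    def test_empty_rates_error(self):
        with pytest.raises(ValueError):
            td.grades_from_rates({})

    def test_external_grades_imported_verbatim(self):
        prof = conservation_from_grades({10: 8, 11: 3})
        assert prof.grade(10) == 8 and prof.grade(11) == 3
        with pytest.raises(ValueError):
            conservation_from_grades({1: 12})


class TestCorrelation:
    def test_perfectly_covarying_columns_score_one(self):
        rows = ["AC", "DE", "FG", "HI", "KL", "AC"]
        recs = [(f"s{i}" if i else "query", r) for i, r in enumerate(rows)]
        aln = td.Alignment(records=recs, query_id="query")
        prof = td.correlation_scores(aln)
        assert prof.score(1) == pytest.approx(1.0)
        assert prof.score(2) == pytest.approx(1.0)

    def test_constant_column_scores_zero(self):
        rows = ["AA", "AC", "AG", "AW"]
        recs = [(f"s{i}" if i else "query", r) for i, r in enumerate(rows)]
        aln = td.Alignment(records=recs, query_id="query")
        assert td.correlation_scores(aln).score(1) == 0.0

    def test_independent_columns_score_low(self):
        # 500 sequences, two independently shuffled columns
        rng = np.random.default_rng(99)
        a = rng.choice(list("ACDE"), size=500)
        b = rng.choice(list("FGHI"), size=500)
        rows = ["".join(p) for p in zip(a, b)]
        recs = [(f"s{i}" if i else "query", r) for i, r in enumerate(rows)]
        aln = td.Alignment(records=recs, query_id="query")
        assert td.correlation_scores(aln).score(1) < 0.2

    def test_tiny_alignment_degenerates_to_zero(self, caplog):
        recs = [("query", "AC"), ("s1", "DE")]
        aln = td.Alignment(records=recs, query_id="query")
        prof = td.correlation_scores(aln)
        assert set(prof.scores.values()) == {0.0}


class TestReduceRedundancy:
    def test_exact_duplicate_dropped(self):
        recs = [("query", "MKLV"), ("dup", "MKLV"), ("far", "AAAA")]
        aln = td.Alignment(records=recs, query_id="query")
        red = td.reduce_redundancy(aln, identity_cutoff=0.9)
        assert [r[0] for r in red.records] == ["query", "far"]

    def test_cutoff_one_keeps_non_duplicates(self):
        recs = [("query", "MKLV"), ("near", "MKLA")]
        aln = td.Alignment(records=recs, query_id="query")
        red = td.reduce_redundancy(aln, identity_cutoff=1.0)
        assert red.n_sequences == 2

    def test_95_percent_identity_dropped_at_09(self):
        base = "ACDEFGHIKLMNPQRSTVWY"
        variant = "L" + base[1:]  # 19/20 = 0.95 identity
        assert pairwise_identity(base, variant) == pytest.approx(0.95)
        aln = td.Alignment(
            records=[("query", base), ("near", variant)], query_id="query"
        )
        red = td.reduce_redundancy(aln, identity_cutoff=0.9)
        assert [r[0] for r in red.records] == ["query"]

    def test_query_always_kept(self):
        recs = [("other", "MKLV"), ("query", "MKLV")]
        aln = td.Alignment(records=recs, query_id="query")
        red = td.reduce_redundancy(aln, identity_cutoff=0.5)
        assert "query" in [r[0] for r in red.records]


class TestTabularIO:
    def test_candidates_tsv_and_profile_import(self, tmp_path):
        cand = td.ConsensusCandidate(
            query_position=128, wild_type="C", proposed="F",
            method="simple_consensus", consensus_frequency=0.8,
            wild_type_frequency=0.05,
        )
        assert cand.notation == "C128F"
        p = tmp_path / "cands.tsv"
        write_candidates_tsv([cand], p)
        text = p.read_text()
        assert "C\t" in text and "128" in text

        prof = tmp_path / "rates.tsv"
        prof.write_text("position\tvalue\n1\t-1.5\n2\t0.3\n")
        assert read_profile_tsv(prof) == {1: -1.5, 2: 0.3}
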