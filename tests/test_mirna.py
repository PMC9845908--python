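"""miRNA curation rules: filtering, compilation, merging, homology."""

import numpy as np
import pandas as pd
import pytest

import provisio as pv
from provisio import mirna


def _record(precursor, start, end, mature, chrom="chr1", strand="+", sample="S1",
            mature_count=100, star_count=20, randfold_p=0.01, rrna=False):
    return {
        "sample": sample, "precursor": precursor, "chrom": chrom,
        "start": start, "end": end, "strand": strand, "mature_seq": mature,
        "mature_count": mature_count, "star_count": star_count,
        "randfold_p": randfold_p, "rrna_trna": rrna, "novel": True,
    }


class TestFilter:
    def test_read_floor_and_randfold_boundaries(self):
        rows = [
            _record("p1", 0, 80, "A" * 22, mature_count=4, star_count=100),  # reject
            _record("p2", 0, 80, "A" * 22, randfold_p=0.05),                 # reject
            _record("p3", 0, 80, "A" * 22, rrna=True),                       # reject
            _record("p4", 0, 80, "A" * 22, mature_count=5, star_count=5),    # keep
        ]
        out = pv.filter_precursor_pairs(pd.DataFrame(rows))
        assert list(out["precursor"]) == ["p4"]

    def test_fixture_matches_per_record_rule_evaluation(self):
        rng = np.random.default_rng(3)
        rows = []
        for i in range(12):
            rows.append(_record(
                f"p{i}", 0, 80, "ACGU" * 5 + "AC",
                mature_count=int(rng.integers(0, 20)),
                star_count=int(rng.integers(0, 20)),
                randfold_p=float(rng.uniform(0, 0.1)),
                rrna=bool(rng.integers(0, 2) == 0),
            ))
        df = pd.DataFrame(rows)
        out = pv.filter_precursor_pairs(df)
        expected = [
            r["precursor"] for r in rows
            if not r["rrna_trna"] and r["mature_count"] >= 5
            and r["star_count"] >= 5 and r["randfold_p"] < 0.05
        ]
        assert list(out["precursor"]) == expected


class TestCompile:
    def test_no_novel_survivors_returns_known(self):
        assert pv.compile_novel_precursors(pd.Series([], dtype=str), ["K1", "K2"]) == ["K1", "K2"]

    def test_duplicates_collapse_and_known_absorb(self):
        novel = pd.Series(["NOV1", "NOV1", "NOV1", "K1", "NOV2"])
        out = pv.compile_novel_precursors(novel, ["K1", "K2"])
        assert out == ["K1", "K2", "NOV1", "NOV2"]

    def test_fixture_known_plus_three(self):
        novel = pd.Series(["N1", "N2", "N3", "K1", "K2"])
        out = pv.compile_novel_precursors(novel, ["K1", "K2", "K3"])
        assert len(out) == 3 + 3


class TestMergeLoci:
    def test_overlapping_same_mature_merge(self):
        df = pd.DataFrame([
            _record("p1", 100, 180, "A" * 22),
            _record("p2", 150, 230, "A" * 22),
        ])
        loci = pv.merge_loci(df)
        assert len(loci) == 1 and loci[0].members == ("p1", "p2")

    def test_disjoint_same_mature_stay_separate(self):
        df = pd.DataFrame([
            _record("p1", 100, 180, "A" * 22),
            _record("p2", 500, 580, "A" * 22),
        ])
        assert len(pv.merge_loci(df)) == 2

    def test_different_strand_or_chrom_never_merge(self):
        df = pd.DataFrame([
            _record("p1", 100, 180, "A" * 22, strand="+"),
            _record("p2", 120, 200, "A" * 22, strand="-"),
            _record("p3", 120, 200, "A" * 22, chrom="chr2"),
        ])
        assert len(pv.merge_loci(df)) == 3

    def test_transitive_chain_single_locus(self):
        df = pd.DataFrame([
            _record("pA", 0, 100, "G" * 22),
            _record("pB", 80, 200, "G" * 22),
            _record("pC", 180, 300, "G" * 22),  # overlaps B, not A
        ])
        loci = pv.merge_loci(df)
        assert len(loci) == 1 and set(loci[0].members) == {"pA", "pB", "pC"}
        # brute-force connected components agree
        assert loci[0].start == 0 and loci[0].end == 300

    def test_order_invariant_and_idempotent(self):
        rows = [
            _record("p1", 0, 100, "G" * 22),
            _record("p2", 90, 200, "G" * 22),
            _record("p3", 500, 600, "G" * 22),
            _record("p4", 0, 90, "C" * 22),
        ]
        df = pd.DataFrame(rows)
        a = pv.merge_loci(df)
        b = pv.merge_loci(df.iloc[::-1].reset_index(drop=True))
        assert [(l.members, l.mature_seq) for l in a] == [(l.members, l.mature_seq) for l in b]

    def test_counts_conserved_through_merge(self):
        rows = [
            _record("p1", 0, 100, "G" * 22, sample="S1", mature_count=3),
            _record("p2", 90, 200, "G" * 22, sample="S1", mature_count=4),
            _record("p1", 0, 100, "G" * 22, sample="S2", mature_count=7),
            _record("p2", 90, 200, "G" * 22, sample="S2", mature_count=0),
        ]
        df = pd.DataFrame(rows)
        loci = pv.merge_loci(df)
        table = pv.mirna_count_table(loci, df)
        assert table.loc[loci[0].locus_id, "S1"] == 7
        assert table.loc[loci[0].locus_id, "S2"] == 7
        assert table.to_numpy().sum() == df["mature_count"].sum()

    def test_missing_precursor_rejected(self):
        df = pd.DataFrame([_record("p1", 0, 100, "G" * 22)])
        loci = pv.merge_loci(df)
        with pytest.raises(ValueError):
            pv.mirna_count_table(loci, df[df["precursor"] != "p1"])


class TestHomologs:
    def test_identical_sequences_accepted_at_full_identity(self):
        q = {"q": "ACGUACGUACGUACGUACGUAC"}
        out = pv.match_homologs(q, {"s": "ACGUACGUACGUACGUACGUAC"})
        assert out[0].accepted and out[0].identity == 1.0

    def test_seed_region_mismatches_disqualify(self):
        base = list("ACGUACGUACGUACGUACGUAC")
        mut = base.copy()
        mut[1] = "U" if base[1] != "U" else "A"  # position 2
        mut[4] = "U" if base[4] != "U" else "A"  # position 5
        out = pv.match_homologs({"q": "".join(base)}, {"s": "".join(mut)})
        assert not out[0].accepted
        assert set(out[0].mismatch_positions) == {2, 5}

    def test_two_mismatches_outside_seed_accepted(self):
        base = list("ACGUACGUACGUACGUACGUAC")
        mut = base.copy()
        mut[9] = "U" if base[9] != "U" else "A"   # position 10
        mut[19] = "U" if base[19] != "U" else "A"  # position 20
        out = pv.match_homologs({"q": "".join(base)}, {"s": "".join(mut)})
        assert out[0].accepted
        assert out[0].identity == pytest.approx(20 / 22)

    def test_three_mismatches_rejected_even_outside_seed(self):
        base = list("A" * 22)
        for pos in (9, 14, 19):
            base[pos] = "C"
        out = pv.match_homologs({"q": "A" * 22}, {"s": "".join(base)})
        assert not out[0].accepted

    def test_acceptance_symmetric_for_equal_lengths(self):
        rng = np.random.default_rng(12)
        alph = np.array(list("ACGU"))
        for _ in range(20):
            a = "".join(rng.choice(alph, 22))
            b = list(a)
            for pos in rng.choice(22, size=int(rng.integers(0, 4)), replace=False):
                b[pos] = rng.choice([c for c in "ACGU" if c != a[pos]])
            b = "".join(b)
            fwd = pv.match_homologs({"q": a}, {"s": b})[0]
            rev = pv.match_homologs({"q": b}, {"s": a})[0]
            assert fwd.identity == rev.identity and fwd.accepted == rev.accepted

    def test_alphabet_violation_rejected(self):
        with pytest.raises(ValueError):
            pv.match_homologs({"q": "ACGXACGUACGU"}, {"s": "ACGUACGUACGU"})


class TestEndToEndCuration:
    def test_pipeline_reproduces_generator_truth_exactly(self):
        records, truth = pv.generate_mirna_records(n_loci=40, seed=6, n_samples=5)
        passing = pv.filter_precursor_pairs(records)
        assert set(records["precursor"]) - set(passing["precursor"]) == set(
            truth.failing_precursors
        )
        loci = pv.merge_loci(passing)
        assert len(loci) == 40
        got = {frozenset(l.members) for l in loci}
        expected = {frozenset(v) for v in truth.locus_members.values()}
        assert got == expected
        # representative matures agree locus-by-locus
        by_members = {frozenset(v): truth.locus_mature[k]
                      for k, v in truth.locus_members.items()}
        for l in loci:
            assert l.mature_seq == by_members[frozenset(l.members)]
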