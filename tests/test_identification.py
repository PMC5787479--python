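"""Exact peptide matching, presence inference and duplicate-peptide ratios."""

import numpy as np
import pytest

from missingprot import (
    DigestionParams,
    MatchPolicy,
    ObservationSet,
    ReferenceDB,
    ReferenceProtein,
    build_index,
    duplicate_peptide_ratio,
    duplicate_ratio_summary,
    infer_proteins,
    match_peptides,
    uniqueness_from_matches,
)
from missingprot.digestion import UNFILTERED
from missingprot.identification import SubstringCorpus

from conftest import PEP_A1, PEP_B1, PEP_SHARED_ISO, random_protein_db


class TestObservationSet:
    def test_duplicate_rows_collapse_with_a_count(self):
        obs = ObservationSet.from_records(
            [("s1", "WT", 1, "AAAK"), ("s1", "WT", 1, "AAAK"), ("s1", "WT", 2, "CCCK")]
        )
        assert len(obs.frame) == 2
        row = obs.frame[obs.frame["replicate"] == 1].iloc[0]
        assert row["count"] == 2

    def test_lowercase_peptides_are_canonicalised_to_upper(self):
        obs = ObservationSet.from_records([("s1", "WT", 1, "aaak")])
        assert obs.peptides() == {"AAAK"}

    def test_invalid_residue_and_replicate_rejected(self):
        with pytest.raises(ValueError):
            ObservationSet.from_records([("s1", "WT", 1, "AAA1K")])
        with pytest.raises(ValueError):
            ObservationSet.from_records([("s1", "WT", 0, "AAAK")])

    def test_tsv_round_trip(self, tmp_path):
        obs = ObservationSet.from_records(
            [("s1", "WT", 1, "AAAK"), ("s2", "KO_T", 3, "CCCK")]
        )
        path = tmp_path / "obs.tsv"
        obs.to_tsv(path)
        again = ObservationSet.from_tsv(path)
        assert again.frame.equals(obs.frame)


class TestMatchPolicy:
    def test_identity_is_fixed_at_full_match(self):
        with pytest.raises(ValueError):
            MatchPolicy(identity=0.9)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            MatchPolicy(mode="fuzzy")


class TestMatchPeptides:
    def test_singleton_empty_and_x_peptides(self, isoform_db):
        matches = match_peptides(
            [PEP_A1, "WWWWWWW", "AAXAK"], db=isoform_db, policy=MatchPolicy()
        )
        assert matches[PEP_A1] == {"A1"}
        assert matches["WWWWWWW"] == frozenset()
        assert matches["AAXAK"] == frozenset()

    def test_substring_matches_cross_tryptic_boundaries(self, isoform_db):
        # spans the junction of two tryptic peptides: invisible to the index,
        # found by substring matching
        junction = PEP_SHARED_ISO[-3:] + PEP_A1[:3]
        sub = match_peptides([junction], db=isoform_db, policy=MatchPolicy())
        idx = build_index(isoform_db, UNFILTERED)
        tryptic = match_peptides(
            [junction], index=idx, policy=MatchPolicy(mode="tryptic_index")
        )
        assert sub[junction] == {"A1"}
        assert tryptic[junction] == frozenset()

    def test_matches_naive_scan_oracle_on_random_peptides(self):
        rng = np.random.default_rng(5)
        db = random_protein_db(rng, 20, length=300)
        peptides = []
        for _ in range(200):
            if rng.random() < 0.5:  # genuine substring of some protein
                prot = db.proteins[rng.integers(len(db))]
                start = rng.integers(0, len(prot.sequence) - 8)
                peptides.append(prot.sequence[start : start + 8])
            else:  # random string, usually absent
                peptides.append(
                    "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=8))
                )
        matches = match_peptides(peptides, db=db, policy=MatchPolicy())
        for pep in set(peptides):
            oracle = {p.accession for p in db if pep in p.sequence}
            assert matches[pep] == oracle

    def test_every_tryptic_match_is_a_substring_match(self):
        rng = np.random.default_rng(9)
        db = random_protein_db(rng, 10, length=250)
        index = build_index(db, DigestionParams())
        peptides = sorted(index.entries)[:500]
        tryptic = match_peptides(
            peptides, index=index, policy=MatchPolicy(mode="tryptic_index")
        )
        substring = match_peptides(peptides, db=db, policy=MatchPolicy())
        for pep in peptides:
            assert tryptic[pep] <= substring[pep]

    def test_il_policy_must_agree_with_index_and_corpus(self, isoform_db):
        index = build_index(isoform_db, UNFILTERED)
        with pytest.raises(ValueError, match="il_equivalent"):
            match_peptides(
                ["AAAK"],
                index=index,
                policy=MatchPolicy(mode="tryptic_index", il_equivalent=True),
            )
        corpus = SubstringCorpus(isoform_db, il_equivalent=False)
        with pytest.raises(ValueError, match="il_equivalent"):
            match_peptides(
                ["AAAK"], corpus=corpus, policy=MatchPolicy(il_equivalent=True)
            )

    def test_il_equivalent_substring_collapses_isobaric_residues(self):
        db = ReferenceDB([ReferenceProtein("P1", "MKIIIDDDK")])
        matches = match_peptides(
            ["LLLDDDK"], db=db, policy=MatchPolicy(il_equivalent=True)
        )
        assert matches["LLLDDDK"] == {"P1"}


class TestInferProteins:
    def _run(self, matches, db, min_unique=2):
        uniq = uniqueness_from_matches(matches, db)
        return infer_proteins(matches, uniq, min_unique=min_unique)

    def test_one_unique_peptide_is_not_enough(self, isoform_db):
        matches = match_peptides([PEP_B1], db=isoform_db, policy=MatchPolicy())
        (ident,) = self._run(matches, isoform_db)
        assert ident.accession == "B"
        assert ident.n_unique == 1
        assert ident.present is False

    def test_two_unique_peptides_call_presence(self, isoform_db):
        matches = match_peptides(
            [PEP_B1, "MMMNNNR"], db=isoform_db, policy=MatchPolicy()
        )
        (ident,) = self._run(matches, isoform_db)
        assert ident.present is True

    def test_shared_only_evidence_leaves_both_proteins_absent(self):
        seq = "AAAAETKCCCDDDK"
        db = ReferenceDB(
            [ReferenceProtein("P1", seq), ReferenceProtein("P2", seq)]
        )
        matches = match_peptides(
            ["AAAAETK", "CCCDDDK"], db=db, policy=MatchPolicy()
        )
        idents = self._run(matches, db)
        assert {i.accession for i in idents} == {"P1", "P2"}
        assert all(not i.present for i in idents)
        assert all(i.n_shared == 2 and i.n_unique == 0 for i in idents)

    def test_unmatched_peptides_produce_no_identification(self, isoform_db):
        matches = match_peptides(["WWWWWWW"], db=isoform_db, policy=MatchPolicy())
        assert self._run(matches, isoform_db) == []

    def test_min_unique_below_one_rejected(self, isoform_db):
        matches = match_peptides([PEP_B1], db=isoform_db, policy=MatchPolicy())
        with pytest.raises(ValueError):
            self._run(matches, isoform_db, min_unique=0)

    def test_raising_the_threshold_shrinks_the_present_set(self):
        rng = np.random.default_rng(21)
        db = random_protein_db(rng, 12, length=300)
        from missingprot import digest

        peptides = {
            pep
            for prot in db.proteins[:8]
            for pep, _, mc in digest(prot.sequence, DigestionParams())
            if mc == 0
        }
        matches = match_peptides(sorted(peptides), db=db, policy=MatchPolicy())
        uniq = uniqueness_from_matches(matches, db)
        present_by_k = {
            k: {
                i.accession
                for i in infer_proteins(matches, uniq, min_unique=k)
                if i.present
            }
            for k in (1, 2, 3, 4)
        }
        for k in (2, 3, 4):
            assert present_by_k[k] <= present_by_k[k - 1]

    def test_adding_observations_never_flips_present_to_absent(self, isoform_db):
        small = match_peptides([PEP_B1, "MMMNNNR"], db=isoform_db, policy=MatchPolicy())
        larger = match_peptides(
            [PEP_B1, "MMMNNNR", PEP_A1, PEP_SHARED_ISO],
            db=isoform_db,
            policy=MatchPolicy(),
        )
        present_small = {
            i.accession
            for i in self._run(small, isoform_db)
            if i.present
        }
        present_larger = {
            i.accession
            for i in self._run(larger, isoform_db)
            if i.present
        }
        assert present_small <= present_larger

    def test_record_order_does_not_change_the_outcome(self, isoform_db):
        peps = [PEP_B1, "MMMNNNR", PEP_A1, PEP_SHARED_ISO]
        a = self._run(
            match_peptides(peps, db=isoform_db, policy=MatchPolicy()), isoform_db
        )
        b = self._run(
            match_peptides(peps[::-1], db=isoform_db, policy=MatchPolicy()), isoform_db
        )
        assert a == b


class TestDuplicatePeptideRatio:
    def test_hand_enumerated_example(self):
        obs = ObservationSet.from_records(
            [
                ("s1", "WT", 1, "AAAAAA"),
                ("s1", "WT", 1, "CCCCCC"),
                ("s1", "WT", 2, "CCCCCC"),
                ("s1", "WT", 2, "DDDDDD"),
                ("s1", "WT", 3, "CCCCCC"),
            ]
        )
        assert duplicate_peptide_ratio(obs, "s1") == pytest.approx(1 / 3)

    def test_identical_replicates_reach_the_upper_bound(self):
        records = [("s1", "WT", r, pep) for r in (1, 2, 3) for pep in ("AAAAAA", "CCCCCC")]
        obs = ObservationSet.from_records(records)
        assert duplicate_peptide_ratio(obs, "s1") == 1.0

    def test_single_replicate_sample_is_an_error_directing_skip(self):
        obs = ObservationSet.from_records([("s1", "WT", 1, "AAAAAA")])
        with pytest.raises(ValueError, match="skip"):
            duplicate_peptide_ratio(obs, "s1")

    def test_summary_means_are_unweighted_over_samples(self):
        obs = ObservationSet.from_records(
            [
                # s1: ratio 1.0 (both peptides in both replicates)
                ("s1", "WT", 1, "AAAAAA"),
                ("s1", "WT", 2, "AAAAAA"),
                ("s1", "WT", 1, "CCCCCC"),
                ("s1", "WT", 2, "CCCCCC"),
                # s2: ratio 0.0, many more peptides
                *[("s2", "WT", 1, p) for p in ("DDDDDD", "EEEEEE", "FFFFFF", "GGGGGG")],
                *[("s2", "WT", 2, p) for p in ("HHHHHH", "MMMMMM", "NNNNNN", "QQQQQQ")],
            ]
        )
        summary = duplicate_ratio_summary(obs)
        assert summary["per_sample"] == {"s1": 1.0, "s2": 0.0}
        assert summary["per_group"]["WT"] == pytest.approx(0.5)
        assert summary["overall"] == pytest.approx(0.5)
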