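import numpy as np
import pandas as pd
import pytest

from elephkin.core import SampleMeta
from elephkin.kinship import (
    classify_degree,
    degree_counts,
    infer_paternity,
    king_robust,
    kinship_matrix,
    unrelated_subset,
    verify_maternal_links,
)

from conftest import make_matrix


class TestKingRobust:
    def test_hand_counted_worked_example(self):
        G = make_matrix([[1, 1, 2, 0, 1], [1, 0, 2, 2, 1]], sample_ids=["a", "b"])
        r = king_robust(G, "a", "b")
        assert (r.n_both_het, r.n_opp_hom, r.n_het_a, r.n_het_b) == (2, 1, 3, 2)
        assert r.phi == pytest.approx(0.0)
        assert r.n_shared == 5

    def test_duplicate_genotypes_give_half(self):
        g = [0, 1, 2, 1, 0, 1]
        G = make_matrix([g, g], sample_ids=["a", "b"])
        assert king_robust(G, "a", "b").phi == pytest.approx(0.5)

    def test_undefined_when_no_heterozygotes(self):
        G = make_matrix([[0, 0, 2], [0, 0, 2]], sample_ids=["a", "b"])
        r = king_robust(G, "a", "b")
        assert np.isnan(r.phi) and r.degree == "undefined"

    def test_symmetric(self):
        rng = np.random.default_rng(0)
        calls = rng.integers(-1, 3, size=(2, 400))
        G = make_matrix(calls, sample_ids=["a", "b"])
        assert king_robust(G, "a", "b").phi == king_robust(G, "b", "a").phi

    def test_errors(self):
        G = make_matrix([[0, 1], [-1, -1]], sample_ids=["a", "b"])
        with pytest.raises(ValueError, match="differ"):
            king_robust(G, "a", "a")
        with pytest.raises(KeyError):
            king_robust(G, "a", "zz")
        with pytest.raises(ValueError, match="pairwise-complete"):
            king_robust(G, "a", "b")


class TestKinshipMatrix:
    def test_two_samples_one_row(self):
        G = make_matrix([[0, 1, 2], [1, 1, 0]], sample_ids=["a", "b"])
        kin = kinship_matrix(G)
        assert len(kin) == 1
        assert kin.loc[0, "r"] == pytest.approx(2 * kin.loc[0, "phi"])

    def test_matches_single_pair_computation(self, small_sim):
        G = small_sim.genotypes
        kin = kinship_matrix(G)
        rng = np.random.default_rng(1)
        for _ in range(10):
            row = kin.iloc[rng.integers(len(kin))]
            single = king_robust(G, row.id_a, row.id_b)
            assert single.n_shared == row.n_shared
            assert single.n_both_het == row.n_both_het
            assert single.n_opp_hom == row.n_opp_hom
            assert single.phi == pytest.approx(row.phi, abs=1e-12)

    def test_sample_permutation_leaves_pair_phis_unchanged(self, small_sim):
        G = small_sim.genotypes
        perm = list(reversed(G.sample_ids))
        Gp = G.subset_samples(perm)
        k1 = kinship_matrix(G)
        k2 = kinship_matrix(Gp)
        d1 = {frozenset((t.id_a, t.id_b)): t.phi for t in k1.itertuples()}
        d2 = {frozenset((t.id_a, t.id_b)): t.phi for t in k2.itertuples()}
        assert d1.keys() == d2.keys()
        for k in d1:
            assert d1[k] == pytest.approx(d2[k], nan_ok=True, abs=1e-12)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            kinship_matrix(make_matrix([[0, 1]]))


class TestDegreeClassification:
    @pytest.mark.parametrize(
        "r,expected",
        [
            (0.5, "first"),
            (0.46, "first"),
            (0.45, "second"),
            (0.30, "second"),
            (0.25, "second"),
            (0.20, "third_fourth"),
            (0.125, "third_fourth"),
            (0.124, "unrelated"),
            (-0.1, "unrelated"),
            (float("nan"), "undefined"),
        ],
    )
    def test_bins(self, r, expected):
        assert classify_degree(r) == expected

    def test_degree_counts_totals(self, small_sim):
        kin = kinship_matrix(small_sim.genotypes)
        counts = degree_counts(kin)
        assert counts.sum() == len(kin)


def _kin_frame(pairs):
    rows = []
    for a, b, phi in pairs:
        r = 2 * phi
        rows.append(
            {"id_a": a, "id_b": b, "phi": phi, "r": r,
             "n_shared": 100, "n_both_het": 10, "n_opp_hom": 0,
             "n_het_a": 20, "n_het_b": 20, "degree": classify_degree(r)}
        )
    return pd.DataFrame(rows)


class TestUnrelatedSubset:
    def test_no_pairs_above_cutoff_all_retained(self):
        kin = _kin_frame([("A", "B", 0.01), ("A", "C", 0.02), ("B", "C", 0.0)])
        assert unrelated_subset(kin, 0.08) == ["A", "B", "C"]

    def test_three_vertex_path_removes_middle(self):
        kin = _kin_frame([("A", "B", 0.2), ("B", "C", 0.2), ("A", "C", 0.0)])
        assert unrelated_subset(kin, 0.08) == ["A", "C"]

    def test_camp_tie_break_prefers_rare_camps(self):
        kin = _kin_frame([("A", "B", 0.2)])
        meta = [
            SampleMeta("A", camp="Big"), SampleMeta("B", camp="Rare"),
            SampleMeta("C", camp="Big"), SampleMeta("D", camp="Big"),
        ]
        # A and B tie on degree; A's camp is better represented -> A removed
        assert unrelated_subset(kin, 0.08, meta) == ["B", "C", "D"]

    def test_postcondition_on_simulated_data(self, small_sim):
        kin = kinship_matrix(small_sim.genotypes)
        kept = unrelated_subset(kin, 0.08, small_sim.meta)
        kept_set = set(kept)
        bad = kin[
            (kin["phi"] >= 0.08)
            & kin["id_a"].isin(kept_set)
            & kin["id_b"].isin(kept_set)
        ]
        assert bad.empty


def _meta(entries):
    return [SampleMeta(*e) for e in entries]


class TestInferPaternity:
    # sex, birth_year, approx, origin, camp, dam
    BASE = [
        ("SIRE", "male", 1950, False, "wild", "K", None),
        ("DAM", "female", 1955, False, "wild", "K", None),
        ("KID", "male", 1980, False, "captive", "K", "DAM"),
    ]

    def test_valid_pair_emitted_with_counts(self):
        kin = _kin_frame([("SIRE", "KID", 0.25), ("DAM", "KID", 0.25),
                          ("SIRE", "DAM", 0.0)])
        pairs, counts, skipped = infer_paternity(kin, _meta(self.BASE))
        assert list(pairs["sire_id"]) == ["SIRE"]
        assert list(pairs["offspring_id"]) == ["KID"]
        assert counts["SIRE"] == 1 and not skipped

    def test_older_female_not_emitted(self):
        kin = _kin_frame([("DAM", "KID", 0.25)])
        pairs, _, _ = infer_paternity(kin, _meta(self.BASE))
        assert pairs.empty

    def test_exact_18_year_gap_not_emitted(self):
        meta = _meta([
            ("SIRE", "male", 1962, False, "wild", "K", None),
            ("KID", "male", 1980, False, "captive", "K", None),
        ])
        kin = _kin_frame([("SIRE", "KID", 0.25)])
        assert infer_paternity(kin, meta)[0].empty
        meta[0].birth_year = 1961  # gap 19 -> emitted
        assert len(infer_paternity(kin, meta)[0]) == 1

    def test_recorded_maternal_path_not_emitted(self):
        # older male shares the recorded dam with the younger individual
        meta = _meta([
            ("DAM", "female", 1950, False, "wild", "K", None),
            ("BRO", "male", 1968, False, "captive", "K", "DAM"),
            ("KID", "male", 1990, False, "captive", "K", "DAM"),
        ])
        kin = _kin_frame([("BRO", "KID", 0.25)])
        assert infer_paternity(kin, meta)[0].empty

    def test_missing_birth_year_skipped_and_reported(self):
        meta = _meta([
            ("SIRE", "male", None, False, "wild", "K", None),
            ("KID", "male", 1990, False, "captive", "K", None),
        ])
        kin = _kin_frame([("SIRE", "KID", 0.25)])
        pairs, _, skipped = infer_paternity(kin, meta)
        assert pairs.empty and skipped == [("SIRE", "KID")]


class TestVerifyMaternalLinks:
    def test_flags_discordant_and_concordant(self):
        meta = _meta([
            ("DAM", "female", 1950, False, "wild", "K", None),
            ("K1", "female", 1970, False, "captive", "K", "DAM"),
            ("K2", "male", 1975, False, "captive", "K", "DAM"),
        ])
        kin = _kin_frame([("DAM", "K1", 0.25), ("DAM", "K2", 0.01),
                          ("K1", "K2", 0.25)])
        rep = verify_maternal_links(kin, meta)
        assert len(rep) == 2
        assert not rep[rep["offspring_id"] == "K1"]["discordant"].iloc[0]
        assert rep[rep["offspring_id"] == "K2"]["discordant"].iloc[0]

    def test_non_genotyped_dam_reported_not_flagged(self):
        meta = _meta([
            ("K1", "female", 1970, False, "captive", "K", "GHOST"),
        ])
        kin = _kin_frame([("K1", "X", 0.0)])
        rep = verify_maternal_links(kin, meta)
        assert rep["degree"].iloc[0] == "not_genotyped"
        assert not rep["discordant"].iloc[0]

    def test_clean_simulation_has_no_discordant_links(self, small_sim):
        kin = kinship_matrix(small_sim.genotypes_clean)
        rep = verify_maternal_links(kin, small_sim.meta)
        genotyped = rep[rep["degree"] != "not_genotyped"]
        assert len(genotyped) > 10
        assert not genotyped["discordant"].any()
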