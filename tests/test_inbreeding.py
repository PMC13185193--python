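import itertools

import numpy as np
import pytest

from elephkin.core import MISSING, GenomeLayout
from elephkin.inbreeding import (
    RohParams,
    compare_groups,
    dataset_density,
    detect_roh,
    froh,
    observed_heterozygosity,
)

from conftest import make_matrix


class TestObservedHeterozygosity:
    @pytest.mark.parametrize(
        "calls,expected",
        [
            ([1, 1, 1, 1], 1.0),
            ([0, 2, 0, 2], 0.0),
            ([1, 0, 2, MISSING], 1 / 3),
        ],
    )
    def test_worked_examples(self, calls, expected):
        G = make_matrix([calls])
        assert observed_heterozygosity(G)["S0"] == pytest.approx(expected)

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError, match="no non-missing"):
            observed_heterozygosity(make_matrix([[MISSING, MISSING]]))

    def test_het_plus_hom_fractions_sum_to_one(self, small_sim):
        G = small_sim.genotypes
        ho = observed_heterozygosity(G)
        obs = (G.calls != MISSING).sum(axis=1)
        hom = ((G.calls == 0) | (G.calls == 2)).sum(axis=1) / obs
        np.testing.assert_allclose(ho.to_numpy() + hom, 1.0)


def brute_force_roh(calls, pos, layout_total, n_dataset_markers, params):
    """Oracle: every sub-interval, all five criteria, maximality w.r.t.
    the het/missing constraints."""
    m = len(calls)
    out = []
    for a, b in itertools.combinations(range(m + 1), 2):
        b -= 1
        window = calls[a : b + 1]
        if (window == 1).any():
            continue
        if (window == MISSING).sum() > params.max_missing_in_run:
            continue
        # maximal: extending either way violates (i) or (ii)
        for ext in (a - 1, b + 1):
            if 0 <= ext < m:
                grown = calls[min(a, ext) : max(b, ext) + 1]
                if not (
                    (grown == 1).any()
                    or (grown == MISSING).sum() > params.max_missing_in_run
                ):
                    break
        else:
            n_snps = b - a + 1
            length = pos[b] - pos[a] + 1
            density = n_dataset_markers / layout_total
            if (
                n_snps >= params.min_snps
                and length >= params.min_length_bp
                and n_snps / length >= density
            ):
                out.append((int(pos[a]), int(pos[b]), n_snps))
    return sorted(out)


class TestDetectRoh:
    def _detect(self, calls, pos, total_len, params=None):
        params = params or RohParams()
        G = make_matrix([calls], pos=pos)
        layout = GenomeLayout({"chr1": total_len})
        return detect_roh(G, layout, params), G, layout

    def test_fixture_passing_all_five_criteria(self):
        # 25 homozygous calls spanning 120 kb with one missing inside
        calls = [0] * 10 + [MISSING] + [2] * 14
        pos = np.linspace(1, 120_000, 25).astype(int)
        segs, G, layout = self._detect(calls, pos, 200_000)
        assert len(segs) == 1
        row = segs.iloc[0]
        assert (row.n_snps, row.n_missing) == (25, 1)
        assert (row.start, row.end) == (1, 120_000)

    def test_two_missing_calls_reject(self):
        calls = [0] * 10 + [MISSING] + [2] * 6 + [MISSING] + [2] * 7
        pos = np.linspace(1, 120_000, 25).astype(int)
        segs, _, _ = self._detect(calls, pos, 200_000)
        assert segs.empty

    def test_nineteen_snps_reject(self):
        calls = [0] * 19
        pos = np.linspace(1, 120_000, 19).astype(int)
        segs, _, _ = self._detect(calls, pos, 200_000)
        assert segs.empty

    def test_99_kb_reject(self):
        calls = [0] * 25
        pos = np.linspace(1, 99_000, 25).astype(int)
        segs, _, _ = self._detect(calls, pos, 160_000)
        assert segs.empty

    def test_all_heterozygous_chromosome_empty(self):
        calls = [1] * 30
        pos = np.linspace(1, 150_000, 30).astype(int)
        segs, _, _ = self._detect(calls, pos, 200_000)
        assert segs.empty

    def test_density_criterion_uses_dataset_ratio(self):
        calls = [0] * 25
        pos = np.linspace(1, 120_000, 25).astype(int)
        # sparse dataset -> run density easily above the ratio
        segs, _, _ = self._detect(calls, pos, 10_000_000)
        assert len(segs) == 1
        # dense dataset elsewhere -> the same run now falls below the ratio
        G = make_matrix(
            [list(calls) + [1] * 975],
            pos=np.concatenate([pos, 120_001 + np.arange(975)]),
        )
        layout = GenomeLayout({"chr1": 200_000})
        assert detect_roh(G, layout, RohParams()).empty

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(25, 61))
        calls = rng.choice([0, 1, 2, MISSING], size=m, p=[0.42, 0.08, 0.42, 0.08])
        pos = np.sort(rng.choice(500_000, size=m, replace=False)) + 1
        total = 600_000
        params = RohParams(min_snps=10, min_length_bp=50_000)
        G = make_matrix([calls], pos=pos)
        layout = GenomeLayout({"chr1": total})
        got = detect_roh(G, layout, params)
        got_t = sorted(zip(got["start"], got["end"], got["n_snps"]))
        expected = brute_force_roh(calls, pos, total, m, params)
        assert got_t == expected

    def test_monotone_in_min_snps_and_length(self):
        rng = np.random.default_rng(99)
        calls = rng.choice([0, 1, 2, MISSING], size=300, p=[0.45, 0.04, 0.45, 0.06])
        pos = np.sort(rng.choice(3_000_000, size=300, replace=False)) + 1
        G = make_matrix([calls], pos=pos)
        layout = GenomeLayout({"chr1": 3_100_000})
        prev = None
        for min_snps in (5, 10, 20):
            n = len(detect_roh(G, layout, RohParams(min_snps=min_snps,
                                                    min_length_bp=10_000)))
            if prev is not None:
                assert n <= prev
            prev = n
        prev = None
        for min_len in (10_000, 60_000, 200_000):
            n = len(detect_roh(G, layout, RohParams(min_snps=5,
                                                    min_length_bp=min_len)))
            if prev is not None:
                assert n <= prev
            prev = n

    def test_empty_layout_rejected(self, small_sim):
        with pytest.raises(ValueError, match="layout"):
            detect_roh(small_sim.genotypes, GenomeLayout({}), RohParams())


class TestFroh:
    def test_no_segments_zero(self):
        import pandas as pd

        segs = pd.DataFrame(columns=["sample_id", "chrom", "start", "end"])
        layout = GenomeLayout({"chr1": 100_000_000})
        f = froh(segs, layout, sample_ids=["A"])
        assert f["A"] == 0.0

    def test_one_megabase_on_hundred(self):
        import pandas as pd

        segs = pd.DataFrame(
            [{"sample_id": "A", "chrom": "chr1", "start": 1, "end": 1_000_000}]
        )
        layout = GenomeLayout({"chr1": 100_000_000})
        assert froh(segs, layout)["A"] == pytest.approx(0.01, abs=1e-5)

    def test_overlapping_segments_merged(self):
        import pandas as pd

        segs = pd.DataFrame(
            [
                {"sample_id": "A", "chrom": "chr1", "start": 1, "end": 600_000},
                {"sample_id": "A", "chrom": "chr1", "start": 400_000, "end": 1_000_000},
            ]
        )
        layout = GenomeLayout({"chr1": 100_000_000})
        assert froh(segs, layout)["A"] == pytest.approx(0.01, abs=1e-5)

    def test_never_exceeds_marker_covered_span(self, small_sim):
        G = small_sim.genotypes
        layout = small_sim.layout
        segs = detect_roh(G, layout, RohParams(min_snps=5, min_length_bp=1000))
        f = froh(segs, layout, sample_ids=G.sample_ids)
        covered = 0
        for c in G.markers.chromosomes():
            p = G.markers.pos[G.markers.chrom == c]
            covered += int(p.max() - p.min() + 1)
        assert (f <= covered / layout.total_length + 1e-12).all()


class TestCompareGroups:
    def test_identical_groups_wilcoxon_p_near_one(self):
        vals = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        labels = np.array(["a"] * 3 + ["b"] * 3)
        _, p = compare_groups(vals, labels, "wilcoxon")
        assert p > 0.95

    def test_separated_groups_significant(self):
        vals = np.array([1, 2, 3, 101, 102, 103], dtype=float)
        labels = np.array(["a"] * 3 + ["b"] * 3)
        stat, p = compare_groups(vals, labels, "wilcoxon")
        # complete separation: U hits its extreme and p its n=3 floor
        assert stat in (0.0, 9.0) and p < 0.05
        _, p = compare_groups(vals, labels, "anova")
        assert p < 0.01
        # at larger n the rank-sum p goes well below 0.01 too
        vals = np.concatenate([np.arange(10), np.arange(10) + 100.0])
        labels = np.array(["a"] * 10 + ["b"] * 10)
        _, p = compare_groups(vals, labels, "wilcoxon")
        assert p < 0.01

    def test_validation(self):
        with pytest.raises(ValueError, match="two groups"):
            compare_groups([1, 2, 3], ["a", "b", "c"], "wilcoxon")
        with pytest.raises(ValueError, match="per group"):
            compare_groups([1, 2, 3], ["a", "a", "b"], "anova")
        with pytest.raises(ValueError, match="unknown test"):
            compare_groups([1, 2, 3, 4], ["a", "a", "b", "b"], "ttest")
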