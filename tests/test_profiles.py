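"""Detection matrix, survey-fixture integrity, clustering and Mantel test."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.stats import kstest

from ahlscreen import masslib as ml
from ahlscreen import profiles as pr
from ahlscreen.errors import ValidationError
from ahlscreen.screen import ChromPeak, Detection

#: printed per-strain AHL counts of the survey table
PRINTED_COUNTS = {
    "S0188": 9, "S0202": 5, "S0203": 7, "S0207": 4, "S0209": 8, "S0273": 7,
    "S0344": 2, "S0787": 0, "S0821": 6, "S0843": 2, "S0845": 1, "S1073": 0,
    "S1089": 4, "S1106": 4, "S1110": 2, "S1137": 2, "S1162": 8, "S1192": 1,
    "S1194": 2, "S1196": 2, "S1728": 4, "S1729": 7, "S1730": 5, "S1732": 5,
    "S2605": 1, "S2606": 6, "S2719": 2, "S2757": 3, "S3857": 2, "S4497": 3,
    "S4634": 1, "S4738": 1, "90-11-287": 3,
}

REFERENCE = "90-11-287"


class TestFixtureIntegrity:
    def test_strain_counts(self, fixture_strains):
        assert len(fixture_strains) == 33
        assert sum(not s.reference for s in fixture_strains) == 32
        assert [s.strain for s in fixture_strains if s.reference] == [REFERENCE]

    def test_per_strain_counts_match_printed_column(self, fixture_matrix):
        counts = pr.per_strain_counts(fixture_matrix)
        for strain, expected in PRINTED_COUNTS.items():
            assert counts[strain] == expected, strain

    def test_21_distinct_ahls(self, fixture_matrix):
        tallies = pr.tally_occurrences(fixture_matrix, exclude=[REFERENCE])
        assert int((tallies > 0).sum()) == 21

    @pytest.mark.parametrize("ahl,expected", [
        ("OH-C6", 17), ("OH-C10", 12), ("OH-C4", 11), ("O-C10", 10),
    ])
    def test_headline_tallies(self, fixture_matrix, ahl, expected):
        tallies = pr.tally_occurrences(fixture_matrix, exclude=[REFERENCE])
        assert tallies[ahl] == expected

    def test_tallies_and_per_strain_counts_agree(self, fixture_matrix):
        tallies = pr.tally_occurrences(fixture_matrix, exclude=[REFERENCE])
        counts = pr.per_strain_counts(fixture_matrix).drop(REFERENCE)
        assert tallies.sum() == counts.sum()

    def test_reference_profile(self, fixture_matrix):
        row = fixture_matrix.presence.loc[REFERENCE]
        assert set(row.index[row]) == {"OH-C6", "OH-C10", "O-C10"}

    def test_s0344_profile(self, fixture_matrix):
        row = fixture_matrix.presence.loc["S0344"]
        assert set(row.index[row]) == {"C4", "OH-C4"}

    def test_run2_only_detection_counts_as_present(self, fixture_matrix):
        assert fixture_matrix.area1.loc["S4634", "OH-C6"] == 0
        assert fixture_matrix.area2.loc["S4634", "OH-C6"] == 148
        assert fixture_matrix.presence.loc["S4634", "OH-C6"]

    def test_all_absent_rows_retained(self, fixture_matrix):
        for strain in ("S0787", "S1073"):
            assert strain in fixture_matrix.strains
            assert not fixture_matrix.presence.loc[strain].any()


def det(name, tier="b", area=10.0, rt=1.0):
    species = ml.build_library(include_open=True).get(name)
    peak = ChromPeak(rt_apex=rt, height=area, area=area, snr=50.0)
    return Detection(species=species, ions={"[M+H]+": peak}, rt_apex=rt, tier=tier)


class TestBuildMatrix:
    def test_union_of_runs(self):
        m = pr.build_matrix({"X": [[det("OH-C6")], [det("OH-C6"), det("C4")]]},
                            ["X", "Y"])
        assert m.presence.loc["X", "OH-C6"] and m.presence.loc["X", "C4"]
        assert m.area1.loc["X", "C4"] == 0 and m.area2.loc["X", "C4"] == 10.0
        assert not m.presence.loc["Y"].any()

    def test_duplicate_species_areas_summed(self, caplog):
        m = pr.build_matrix({"X": [[det("C4", area=5.0), det("C4", area=7.0)]]},
                            ["X"])
        assert m.area1.loc["X", "C4"] == 12.0
        assert "summed" in caplog.text

    def test_best_tier_kept(self):
        m = pr.build_matrix({"X": [[det("C4", tier="c")], [det("C4", tier="b")]]},
                            ["X"])
        assert m.tier.loc["X", "C4"] == "b"

    def test_unknown_strain_rejected(self):
        with pytest.raises(ValidationError):
            pr.build_matrix({"Z": [[det("C4")]]}, ["X"])


class TestClustering:
    def toy(self, rows):
        strains = sorted(rows)
        ahls = sorted({a for profile in rows.values() for a in profile},
                      key=pr.ahl_sort_key)
        m = pr.DetectionMatrix.empty(strains, ahls)
        for s, profile in rows.items():
            for a in profile:
                m.set_cell(s, a, 1.0, 0.0, "b")
        return m

    def test_identical_profiles_merge_at_zero(self):
        m = self.toy({"A": {"C4"}, "B": {"C4"}, "C": {"OH-C6"}})
        cl = pr.cluster_profiles(m)
        assert (frozenset({"A", "B"}), 0.0) in {(a | b, d) for a, b, d in cl.merges}

    def test_disjoint_profiles_distance_one(self):
        m = self.toy({"A": {"C4"}, "B": {"OH-C6"}})
        cl = pr.cluster_profiles(m)
        assert cl.merges[0][2] == pytest.approx(1.0)

    def test_matches_scipy_average_linkage(self):
        """Brute-force/scipy oracle on a toy matrix with unique distances."""
        m = self.toy({
            "A": {"C4", "C6", "OH-C6"},
            "B": {"C4", "C6"},
            "C": {"O-C10", "O-C12", "C6"},
            "D": {"O-C10", "OH-C10", "OH-C12", "OH-C14"},
        })
        cl = pr.cluster_profiles(m)
        X = m.presence.loc[sorted(m.strains)].to_numpy().astype(bool)
        Z = hierarchy.linkage(pdist(X, metric="jaccard"), method="average")
        scipy_clusters = set()
        labels = sorted(m.strains)
        members = {i: frozenset([labels[i]]) for i in range(len(labels))}
        for k, (i, j, dist, _) in enumerate(Z):
            merged = members[int(i)] | members[int(j)]
            members[len(labels) + k] = merged
            scipy_clusters.add(merged)
        assert cl.clusters() == scipy_clusters

    def test_invariant_to_row_permutation(self, fixture_matrix):
        cl1 = pr.cluster_profiles(fixture_matrix)
        shuffled_strains = list(fixture_matrix.strains)[::-1]
        m2 = pr.DetectionMatrix(
            shuffled_strains, fixture_matrix.ahls,
            fixture_matrix.area1.loc[shuffled_strains],
            fixture_matrix.area2.loc[shuffled_strains],
            fixture_matrix.tier.loc[shuffled_strains])
        cl2 = pr.cluster_profiles(m2)
        assert cl1.clusters() == cl2.clusters()
        assert cl1.newick == cl2.newick

    def test_all_absent_matrix_rejected(self):
        m = pr.DetectionMatrix.empty(["A", "B"], ["C4"])
        with pytest.raises(ValidationError):
            pr.cluster_profiles(m)


class TestFingerprint:
    def test_single_strain_clade_is_its_profile(self, fixture_matrix, fixture_strains):
        fp = pr.clade_fingerprint(fixture_matrix, fixture_strains, ["S0344"], q=1.0)
        assert fp == {"C4", "OH-C4"}

    def test_splendidus_subclade_core(self, fixture_matrix, fixture_strains):
        fp = pr.clade_fingerprint(fixture_matrix, fixture_strains,
                                  ["S0188", "S0203", "S0209", "S0273"], q=1.0)
        assert {"OH-C4", "OH-C6", "OH-C10"} <= fp

    def test_tiny_q_gives_union(self, fixture_matrix, fixture_strains):
        members = ["S0188", "S0203"]
        fp = pr.clade_fingerprint(fixture_matrix, fixture_strains, members, q=1e-4)
        union = set()
        for s in members:
            row = fixture_matrix.presence.loc[s]
            union |= set(row.index[row])
        assert fp == union

    def test_unknown_clade_rejected(self, fixture_matrix, fixture_strains):
        with pytest.raises(ValidationError):
            pr.clade_fingerprint(fixture_matrix, fixture_strains, "Atlantis")


class TestMantel:
    def random_dm(self, n, rng):
        pts = rng.normal(size=(n, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels = [f"s{i}" for i in range(n)]
        return pd.DataFrame(d, index=labels, columns=labels)

    def test_self_correlation(self):
        d = self.random_dm(10, np.random.default_rng(0))
        r, p = pr.mantel_test(d, d, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)
        assert p <= 1 / (99 + 1) + 1e-12

    def test_constant_matrix_rejected(self):
        labels = ["a", "b", "c"]
        c = pd.DataFrame(np.ones((3, 3)) - np.eye(3), index=labels, columns=labels)
        d = self.random_dm(3, np.random.default_rng(1))
        d.index = d.columns = labels
        with pytest.raises(ValidationError):
            pr.mantel_test(c, d, n_perm=99)

    def test_mismatched_labels_rejected(self):
        rng = np.random.default_rng(2)
        d1, d2 = self.random_dm(5, rng), self.random_dm(5, rng)
        d2.index = d2.columns = list("vwxyz")
        with pytest.raises(ValidationError):
            pr.mantel_test(d1, d2, n_perm=99)

    def test_p_uniform_under_null(self):
        """Independent random matrices: p-values approximately uniform
        (KS test over 200 seeds)."""
        ps = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            d1 = self.random_dm(8, rng)
            d2 = self.random_dm(8, rng)
            _, p = pr.mantel_test(d1, d2, n_perm=99, seed=seed)
            ps.append(p)
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_great_circle_sanity(self):
        # quarter meridian ~ 10,008 km on the sphere
        assert pr.great_circle_km(0.0, 0.0, 90.0, 0.0) == pytest.approx(10008, rel=0.01)
        assert pr.great_circle_km(10.0, 20.0, 10.0, 20.0) == 0.0

    def test_geography_uncorrelated_with_fixture_profiles(
            self, fixture_matrix, fixture_strains):
        """The survey's conclusion: AHL profile does not track isolation
        site."""
        pdm = pr.profile_distance_matrix(fixture_matrix)
        gdm = pr.geo_distance_matrix([s for s in fixture_strains if not s.reference])
        common = [s for s in pdm.index if s in gdm.index]
        r, p = pr.mantel_test(pdm.loc[common, common], gdm.loc[common, common],
                              n_perm=999, seed=0)
        assert p > 0.05
        assert abs(r) < 0.3
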