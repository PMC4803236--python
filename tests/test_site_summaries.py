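import numpy as np
import pytest

from traitevo.model import (MISSING, Alignment, BinarizationConfig,
                            BinaryPhyleticMatrix, RegionAnnotation,
                            SiteRateProfile, TraitEvoError)
from traitevo import site_summaries as ss


def _matrix(rows, kind="disorder"):
    return BinaryPhyleticMatrix(
        [f"t{i}" for i in range(len(rows))],
        np.array(rows, dtype=np.int8), kind)


def _profile(z, trait="DOT"):
    z = np.asarray(z, dtype=float)
    return SiteRateProfile(trait, "family", np.full_like(z, np.nan), z,
                           alpha=1.0)


class TestGapFilter:
    @pytest.mark.parametrize("n_rows,n_gaps,kept", [
        (301, 30, True),    # 30/301 ~ 0.0997 < 0.1
        (301, 31, False),   # 0.103
        (10, 1, False),     # exactly 10%: strict "less than" removes it
        (10, 0, True),
    ])
    def test_strict_threshold(self, n_rows, n_gaps, kept):
        col = np.zeros((n_rows, 1), dtype=np.int8)
        col[:n_gaps, 0] = MISSING
        mask = ss.filter_sites_by_gaps(_matrix(col))
        assert bool(mask[0]) is kept

    def test_mask_uses_scope_rows_only(self):
        # column gapped only within the clade: family keeps, clade drops
        data = np.zeros((10, 1), dtype=np.int8)
        data[:3, 0] = MISSING
        m = _matrix(data)
        fam = ss.filter_sites_by_gaps(m)
        clade = ss.filter_sites_by_gaps(m, rows=[f"t{i}" for i in range(3)])
        assert not fam[0] is None
        assert fam[0] == False  # noqa: E712  (3/10 gaps fails family too)
        sub = ss.filter_sites_by_gaps(m, rows=[f"t{i}" for i in range(3, 10)])
        assert sub[0] == True  # noqa: E712

    def test_works_on_alignment(self):
        aln = Alignment(["a", "b"], ["AC", "A-"])
        mask = ss.filter_sites_by_gaps(aln)
        np.testing.assert_array_equal(mask, [True, False])


class TestClassification:
    def test_all_fast_requires_every_trait(self):
        profiles = {t: _profile([z], t) for t, z in
                    zip("ABCD", [0.2, 1.1, 0.3, 2.0])}
        out = ss.classify_site_rates(profiles)
        assert bool(out.loc[0, "ALL_fast"])
        assert not bool(out.loc[0, "ALL_slow"])

    def test_mixed_signs_are_neither(self):
        profiles = {t: _profile([z], t) for t, z in
                    zip("ABCD", [-0.1, 0.1, -0.1, -0.1])}
        out = ss.classify_site_rates(profiles)
        assert not bool(out.loc[0, "ALL_fast"])
        assert not bool(out.loc[0, "ALL_slow"])

    def test_zero_is_excluded_from_both_sides(self):
        profiles = {t: _profile([z], t) for t, z in
                    zip("ABCD", [0.0, -1.0, -1.0, -1.0])}
        out = ss.classify_site_rates(profiles)
        assert not bool(out.loc[0, "ALL_slow"])

    def test_missing_z_excluded_from_all_flags(self):
        profiles = {"A": _profile([np.nan, 1.0], "A"),
                    "B": _profile([1.0, 1.0], "B")}
        out = ss.classify_site_rates(profiles)
        assert not bool(out.loc[0, "ALL_fast"])
        assert bool(out.loc[1, "ALL_fast"])
        assert not bool(out.loc[0, "complete"])


class TestRegionCounts:
    def test_counts_over_kept_columns(self):
        z = np.array([1.0] * 4 + [-1.0] * 6)
        profiles = {"DOT": _profile(z)}
        regions = RegionAnnotation([("D1", 0, 10)], 10)
        mask = np.ones(10, dtype=bool)
        out = ss.count_rapid_by_region(
            ss.classify_site_rates(profiles), regions, mask)
        assert out.table.loc["D1", "DOT"] == 4
        assert out.table.loc["D1", "n_sites"] == 10

    def test_fully_filtered_region_has_zero_counts(self):
        z = np.ones(10)
        profiles = {"DOT": _profile(z)}
        regions = RegionAnnotation([("D1", 0, 5), ("D2", 5, 10)], 10)
        mask = np.array([True] * 5 + [False] * 5)
        out = ss.count_rapid_by_region(
            ss.classify_site_rates(profiles), regions, mask)
        assert out.table.loc["D2", "n_sites"] == 0
        assert out.table.loc["D2", "DOT"] == 0

    def test_region_order_does_not_matter(self):
        z = np.array([1.0, -1.0] * 5)
        profiles = {"DOT": _profile(z)}
        mask = np.ones(10, dtype=bool)
        cls = ss.classify_site_rates(profiles)
        a = ss.count_rapid_by_region(
            cls, RegionAnnotation([("D1", 0, 4), ("D2", 6, 10)], 10), mask)
        b = ss.count_rapid_by_region(
            cls, RegionAnnotation([("D2", 6, 10), ("D1", 0, 4)], 10), mask)
        assert a.table.sort_index().equals(b.table.sort_index())

    def test_kept_sites_partition_across_regions(self, rng):
        z = rng.normal(size=50)
        profiles = {"DOT": _profile(z)}
        mask = rng.random(50) < 0.8
        regions = RegionAnnotation([("D1", 5, 20), ("D2", 30, 40)], 50)
        out = ss.count_rapid_by_region(
            ss.classify_site_rates(profiles), regions, mask)
        assert out.table["n_sites"].sum() == mask.sum()


class TestAccumulated:
    def test_sum_across_traits(self):
        profiles = {t: _profile([z], t) for t, z in
                    zip("ABCD", [1.0, -1.0, 0.5, -0.5])}
        out = ss.accumulate_site_rates(profiles)
        assert out.loc[0, "accumulated"] == pytest.approx(0.0)

    def test_extreme_flag_above_ten(self):
        profiles = {t: _profile([3.0], t) for t in "ABCD"}
        out = ss.accumulate_site_rates(profiles)
        assert out.loc[0, "accumulated"] == pytest.approx(12.0)
        assert bool(out.loc[0, "extreme"])

    def test_single_trait_passthrough(self):
        profiles = {"DOT": _profile([0.7, -0.2])}
        out = ss.accumulate_site_rates(profiles)
        np.testing.assert_allclose(out["accumulated"], [0.7, -0.2])


class TestDisorderConservation:
    def test_gaps_included_denominator(self):
        rows = [[1]] * 6 + [[0]] * 2 + [[MISSING]] * 2
        frac = ss.site_disorder_conservation(_matrix(rows))
        assert frac[0] == pytest.approx(0.6)

    def test_all_missing_is_zero(self):
        frac = ss.site_disorder_conservation(_matrix([[MISSING]] * 4))
        assert frac[0] == 0.0

    def test_all_ones_is_one(self):
        frac = ss.site_disorder_conservation(_matrix([[1]] * 4))
        assert frac[0] == 1.0

    def test_antitone_under_relabeling(self, rng):
        data = rng.integers(-1, 2, size=(12, 30)).astype(np.int8)
        m = _matrix(data)
        relabeled = data.copy()
        relabeled[data == 0] = 1
        relabeled[data == 1] = 0
        f0 = ss.site_disorder_conservation(m)
        f1 = ss.site_disorder_conservation(_matrix(relabeled))
        nonmissing = (data != MISSING).mean(axis=0)
        np.testing.assert_allclose(f1, nonmissing - f0, atol=1e-12)


PDB = (
    "HEADER    TOY STRUCTURE\n"
    "ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 20.00"
    "           N\n"
    "ATOM      2  CA  ALA A   1      11.804   6.934  -6.004  1.00 20.00"
    "           C\n"
    "ATOM      3  N   GLY A   2      12.104   7.134  -5.504  1.00 20.00"
    "           N\n"
    "ATOM      4  N   SER A   3      13.104   8.134  -4.504  1.00 20.00"
    "           N\n"
    "END\n"
)


class TestStructureMapping:
    def test_bfactor_roundtrip(self, tmp_path):
        pdb_in = tmp_path / "in.pdb"
        pdb_in.write_text(PDB)
        out = tmp_path / "out.pdb"
        mapping = {0: ("A", 1), 1: ("A", 2), 2: ("A", 3)}
        ss.map_values_to_structure(np.array([0.1, 0.5, 0.9]), mapping,
                                  pdb_in, out)
        bvals = [float(line[60:66]) for line in out.read_text().splitlines()
                 if line.startswith("ATOM")]
        assert bvals == [0.10, 0.10, 0.50, 0.90]

    def test_non_bfactor_bytes_preserved(self, tmp_path):
        pdb_in = tmp_path / "in.pdb"
        pdb_in.write_text(PDB)
        out = tmp_path / "out.pdb"
        ss.map_values_to_structure(np.array([0.1]), {0: ("A", 1)}, pdb_in,
                                   out)
        for orig, new in zip(PDB.splitlines(), out.read_text().splitlines()):
            if orig.startswith("ATOM"):
                assert new[:60] == orig[:60] and new[66:] == orig[66:]
            else:
                assert new == orig

    def test_empty_mapping_writes_sentinel(self, tmp_path):
        pdb_in = tmp_path / "in.pdb"
        pdb_in.write_text(PDB)
        out = tmp_path / "out.pdb"
        ss.map_values_to_structure(np.array([0.1]), {}, pdb_in, out)
        bvals = {float(line[60:66]) for line in
                 out.read_text().splitlines() if line.startswith("ATOM")}
        assert bvals == {-1.0}

    def test_mapping_to_absent_residue_errors(self, tmp_path):
        pdb_in = tmp_path / "in.pdb"
        pdb_in.write_text(PDB)
        with pytest.raises(TraitEvoError, match="999"):
            ss.map_values_to_structure(np.array([0.1]), {0: ("A", 999)},
                                       pdb_in, tmp_path / "out.pdb")
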