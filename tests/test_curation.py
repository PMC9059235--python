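import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from amprep import (
    AbundanceTable,
    CurationParams,
    MetadataTable,
    apply_depth_filter,
    apply_rare_taxon_filter,
    clean_read_totals,
    flag_foreign_asvs,
    flag_recurrent_water_asvs,
    remove_single_hit_asvs,
    remove_water_only_asvs,
    run_curation,
    tss_normalize,
)
from amprep.curation import (
    KEPT,
    REMOVED_RARE,
    REMOVED_SINGLE_HIT,
    REMOVED_WATER_ONLY,
    SAMPLE_KEPT,
    SAMPLE_REMOVED_LOW_DEPTH,
    CurationError,
)
from amprep.io import TaxonomyTable

from conftest import make_meta, milk_record, water_record


def table_of(counts, prefix_asv="A", prefix_s="s"):
    counts = np.asarray(counts)
    return AbundanceTable(
        [f"{prefix_asv}{i}" for i in range(counts.shape[0])],
        [f"{prefix_s}{j}" for j in range(counts.shape[1])],
        counts,
    )


class TestCleanReads:
    def test_column_sum(self):
        table = table_of([[3], [0], [7]])
        assert clean_read_totals(table) == {"s0": 10}

    def test_zero_column(self):
        table = table_of([[0], [0]])
        assert clean_read_totals(table) == {"s0": 0}

    def test_planted_depth(self, recovery_sim):
        table, _, _, truth = recovery_sim
        totals = clean_read_totals(table)
        for s, prov in truth.provenance.items():
            assert totals[s] == prov.depth


class TestDepthFilter:
    def test_boundary_strictly_less(self):
        table = table_of([[499, 500, 501]])
        filtered, disp = apply_depth_filter(table, None, CurationParams())
        assert filtered.sample_ids == ["s1", "s2"]
        assert disp == {
            "s0": SAMPLE_REMOVED_LOW_DEPTH,
            "s1": SAMPLE_KEPT,
            "s2": SAMPLE_KEPT,
        }

    def test_identity_when_all_deep(self):
        table = table_of([[500, 9000]])
        filtered, disp = apply_depth_filter(table, None, CurationParams())
        assert filtered == table
        assert set(disp.values()) == {SAMPLE_KEPT}

    def test_planted_shallow_samples(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(10, 80, size=(5, 8))
        shallow = {1, 4}  # force column totals below 500 there, above elsewhere
        for j in range(8):
            counts[:, j] = counts[:, j] * (1 if j in shallow else 10)
        table = table_of(counts)
        assert all(t < 500 for s, t in table.sample_totals().items() if int(s[1]) in shallow)
        filtered, disp = apply_depth_filter(table, None, CurationParams())
        removed = {s for s, d in disp.items() if d == SAMPLE_REMOVED_LOW_DEPTH}
        assert removed == {f"s{j}" for j in shallow}


class TestRareTaxonFilter:
    def test_boundary(self):
        # grand total 100,000; 0.01% = 10 reads: 10 kept, 9 removed
        counts = np.array([[10], [9], [100000 - 19]])
        table = table_of(counts)
        filtered, disp = apply_rare_taxon_filter(table, CurationParams())
        assert disp["A0"] == KEPT
        assert disp["A1"] == REMOVED_RARE
        assert "A1" not in filtered.asv_ids

    def test_single_asv_kept(self):
        table = table_of([[5]])
        filtered, disp = apply_rare_taxon_filter(table, CurationParams())
        assert disp == {"A0": KEPT}

    def test_zero_grand_total_errors(self):
        with pytest.raises(CurationError):
            apply_rare_taxon_filter(table_of([[0]]), CurationParams())

    def test_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(42)
        counts = rng.integers(0, 40, size=(100, 12))
        counts[rng.random(size=counts.shape) < 0.6] = 0
        table = table_of(counts)
        params = CurationParams(tau_rel=0.5)
        _, disp = apply_rare_taxon_filter(table, params)
        grand = counts.sum()
        expected = {
            f"A{i}": (REMOVED_RARE if 100.0 * counts[i].sum() / grand < params.tau_rel else KEPT)
            for i in range(100)
        }
        assert disp == expected

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        table = table_of(rng.integers(0, 30, size=(40, 6)))
        params = CurationParams(tau_rel=0.8)
        once, _ = apply_rare_taxon_filter(table, params)
        twice, disp = apply_rare_taxon_filter(once, params)
        assert twice == once
        assert set(disp.values()) == {KEPT}


class TestWaterOnly:
    def test_examples(self, mixed_table):
        table, meta = mixed_table
        filtered, disp = remove_water_only_asvs(table, meta)
        assert disp["A3"] == REMOVED_WATER_ONLY  # water counts only
        assert disp["A2"] == KEPT  # both milk and water
        assert "A3" not in filtered.asv_ids

    def test_milk_totals_unchanged(self, mixed_table):
        table, meta = mixed_table
        before = clean_read_totals(table)
        filtered, _ = remove_water_only_asvs(table, meta)
        after = clean_read_totals(filtered)
        for s in ("m1", "m2", "m3"):
            assert after[s] == before[s]

    def test_no_water_is_noop(self):
        table = table_of([[1, 0], [2, 3]], prefix_s="m")
        meta = make_meta([milk_record("m0", erep=1), milk_record("m1", erep=2)])
        filtered, disp = remove_water_only_asvs(table, meta)
        assert filtered == table
        assert set(disp.values()) == {KEPT}

    def test_planted_contaminants_all_and_only(self, recovery_sim):
        table, meta, _, truth = recovery_sim
        filtered, disp = remove_water_only_asvs(table, meta)
        removed = {a for a, d in disp.items() if d == REMOVED_WATER_ONLY}
        water_totals = {
            a: t for a, t in zip(table.asv_ids, table.counts.sum(axis=1))
        }
        planted_present = {
            a for a in truth.contaminant_asvs if water_totals[a] > 0
        }
        assert removed == planted_present

    def test_idempotent(self, mixed_table):
        table, meta = mixed_table
        once, _ = remove_water_only_asvs(table, meta)
        twice, disp = remove_water_only_asvs(once, meta)
        assert twice == once
        assert set(disp.values()) == {KEPT}


class TestRecurrentWaterFlag:
    @pytest.mark.parametrize(
        "water_counts,expected",
        [
            ((150, 3, 2), True),    # 3 occupied replicates (>2), max 150 (>100)
            ((200, 150, 0), False),  # only 2 occupied replicates
            ((90, 80, 70), False),   # never above 100 reads
        ],
    )
    def test_rule(self, water_counts, expected):
        counts = np.array([[10, 10, *water_counts]])
        table = AbundanceTable(["A0"], ["m1", "m2", "w1", "w2", "w3"], counts)
        meta = make_meta(
            [milk_record("m1", erep=1), milk_record("m2", erep=2)]
            + [water_record(f"w{i}", erep=i) for i in (1, 2, 3)]
        )
        flags = flag_recurrent_water_asvs(table, meta, CurationParams())
        assert (("A0" in flags) is expected)

    def test_flagged_asvs_are_retained(self, recovery_sim):
        table, meta, _, _ = recovery_sim
        flags = flag_recurrent_water_asvs(table, meta, CurationParams())
        assert flags <= set(table.asv_ids)


class TestSingleHit:
    def test_examples(self):
        counts = np.zeros((2, 10), dtype=int)
        counts[0, 3] = 999  # single hit regardless of count
        counts[1, 2] = 1
        counts[1, 7] = 1
        table = table_of(counts)
        filtered, disp = remove_single_hit_asvs(table)
        assert disp["A0"] == REMOVED_SINGLE_HIT
        assert disp["A1"] == KEPT

    def test_matches_occupancy_oracle(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 5, size=(60, 9))
        counts[rng.random(size=counts.shape) < 0.7] = 0
        table = table_of(counts)
        _, disp = remove_single_hit_asvs(table)
        for i in range(60):
            occ = int((counts[i] > 0).sum())
            assert disp[f"A{i}"] == (REMOVED_SINGLE_HIT if occ == 1 else KEPT)

    def test_idempotent(self):
        rng = np.random.default_rng(6)
        counts = rng.integers(0, 3, size=(30, 5))
        once, _ = remove_single_hit_asvs(table_of(counts))
        twice, disp = remove_single_hit_asvs(once)
        assert twice == once
        assert set(disp.values()) <= {KEPT}


class TestForeignFlag:
    def make_tax(self, genera):
        return TaxonomyTable(
            ranks=("genus",), lineages={a: {"genus": g} for a, g in genera.items()}
        )

    def test_empty_list_no_flags(self):
        table = table_of([[5, 5]])
        tax = self.make_tax({"A0": "Aquabacterium"})
        flags, fractions = flag_foreign_asvs(table, tax, CurationParams())
        assert flags == set()

    def test_arithmetic_by_construction(self):
        # flagged ASV carries 3 of 200 milk reads -> 1.5%
        counts = np.array([[1, 2], [99, 98]])
        table = AbundanceTable(["F", "M"], ["m1", "m2"], counts)
        meta = make_meta([milk_record("m1", erep=1), milk_record("m2", erep=2)])
        tax = self.make_tax({"F": "Aquabacterium", "M": "Staphylococcus"})
        params = CurationParams(foreign_taxa=("Aquabacterium",))
        flags, fractions = flag_foreign_asvs(table, tax, params, meta)
        assert flags == {"F"}
        assert fractions["V1V2"] == pytest.approx(1.5)

    def test_missing_taxonomy_not_flagged(self):
        table = table_of([[5]])
        params = CurationParams(foreign_taxa=("Aquabacterium",))
        flags, _ = flag_foreign_asvs(table, None, params)
        assert flags == set()


class TestTss:
    def test_examples(self):
        table = table_of([[3], [1]])
        norm = tss_normalize(table)
        assert norm["s0"].tolist() == [0.75, 0.25]
        assert tss_normalize(table_of([[5]]))["s0"].tolist() == [1.0]

    def test_zero_total_errors(self):
        with pytest.raises(CurationError):
            tss_normalize(table_of([[0, 1], [0, 1]]))

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.integers(0, 1000), min_size=2, max_size=20).filter(lambda v: sum(v) > 0))
    def test_matches_direct_division(self, column):
        table = table_of(np.array(column)[:, None])
        norm = tss_normalize(table)["s0"].to_numpy()
        total = sum(column)
        assert np.allclose(norm, np.array(column) / total)
        assert abs(norm.sum() - 1.0) < 1e-9


class TestRunCuration:
    def test_identity_on_clean_table(self):
        counts = np.array([[600, 700], [800, 900]])
        table = table_of(counts, prefix_s="m")
        meta = make_meta([milk_record("m0", erep=1), milk_record("m1", erep=2)])
        curated, report = run_curation(table, meta)
        assert curated == table
        assert set(report.asv_disposition.values()) == {KEPT}
        assert set(report.sample_disposition.values()) == {SAMPLE_KEPT}

    def test_partition_conservation(self, sim_main):
        table, meta, taxonomy, _ = sim_main
        curated, report = run_curation(table, meta, taxonomy)
        assert set(report.asv_disposition) == set(table.asv_ids)
        assert set(report.sample_disposition) == set(table.sample_ids)
        kept = set(report.kept_asvs())
        removed = set(report.removed_asvs())
        assert kept | removed == set(table.asv_ids)
        assert kept & removed == set()
        assert set(curated.asv_ids) == kept

    def test_planted_truth_recovered(self, recovery_sim):
        table, meta, taxonomy, truth = recovery_sim
        curated, report = run_curation(table, meta, taxonomy)
        water_present = {
            a for a in truth.contaminant_asvs
            if table.counts[table.asv_ids.index(a)].sum() > 0
        }
        assert set(report.removed_asvs(REMOVED_WATER_ONLY)) == water_present
        assert set(report.removed_asvs(REMOVED_SINGLE_HIT)) == truth.singleton_asvs

    def test_drop_flagged_policy(self):
        counts = np.array([[600, 700], [10, 20]])
        table = AbundanceTable(["M", "F"], ["m1", "m2"], counts)
        meta = make_meta([milk_record("m1", erep=1), milk_record("m2", erep=2)])
        tax = TaxonomyTable(ranks=("genus",), lineages={"M": {"genus": "Staphylococcus"},
                                                        "F": {"genus": "Pelomonas"}})
        params = CurationParams(foreign_taxa=("Pelomonas",), tau_depth=0, tau_rel=0.0)
        kept_version, report = run_curation(table, meta, tax, params, drop_flagged=False)
        assert "F" in kept_version.asv_ids
        assert report.asv_flags["F"] == ["flagged:foreign"]
        dropped_version, report2 = run_curation(table, meta, tax, params, drop_flagged=True)
        assert "F" not in dropped_version.asv_ids

    def test_stage_error_names_stage(self):
        table = table_of([[0]])
        meta = make_meta([milk_record("s0")])
        with pytest.raises(CurationError, match="apply_rare_taxon_filter"):
            run_curation(table, meta, params=CurationParams(tau_depth=0))
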