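"""Curation filters, duplicate collapse and structure checks."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from ddgbench import (
    Dataset,
    check_residue_window,
    collapse_duplicates,
    curate_pronab,
    curate_s2648,
    curate_skempi_3d,
    curate_skempi_seq,
    drop_missing_affinity_or_temperature,
    filter_dimers,
    filter_min_chain_length,
    filter_single_point,
    generate_structure_fixture,
    load_structure,
    normalize_nonstandard_residues,
)
from ddgbench.curation import StructureCheckConfig

from conftest import make_record


def structure_from_text(tmp_path, text, name="fix"):
    path = tmp_path / f"{name}.pdb"
    path.write_text(text)
    return load_structure(path)


class TestElementaryFilters:
    def test_missing_temperature_or_kd_dropped(self):
        records = [
            make_record("full"),
            make_record("no_temp", temperature_K=None),
            make_record("no_kd_wt", kd_wt_M=None),
            make_record("no_kd_mut", kd_mut_M=None),
        ]
        kept = drop_missing_affinity_or_temperature(records)
        assert [r.record_id for r in kept] == ["full"]

    def test_empty_input_passes_through(self):
        assert drop_missing_affinity_or_temperature([]) == []

    def test_single_point_filter(self):
        records = [make_record("s1"), make_record("s2"),
                   make_record("s3"), make_record("d1", n_mutations=2),
                   make_record("d2", n_mutations=3)]
        kept = filter_single_point(records)
        assert [r.record_id for r in kept] == ["s1", "s2", "s3"]

    @pytest.mark.parametrize("chains,kept", [
        ("A_B", True),    # one chain per side: dimer
        ("AB_C", False),  # two chains on one side
        ("A_BC", False),
        ("A", False),     # no partner information
        ("", False),
    ])
    def test_dimer_rule(self, chains, kept):
        records = [make_record("x", chains=chains)]
        assert (len(filter_dimers(records)) == 1) is kept


class TestCollapseDuplicates:
    def group(self, values):
        return [make_record(f"g{i}", position="14", ddg_exp=v)
                for i, v in enumerate(values)]

    def test_low_sd_group_collapses_to_mean(self):
        out = collapse_duplicates(self.group([1.0, 1.2, 1.1]))
        assert len(out) == 1
        assert out[0].ddg_exp == pytest.approx(1.1)
        assert out[0].n_measurements == 3

    def test_high_sd_group_purged(self):
        # sample SD of {0.0, 3.0} is ~2.12 > 1
        assert collapse_duplicates(self.group([0.0, 3.0])) == []

    def test_singleton_unchanged(self):
        rec = make_record("solo", ddg_exp=2.4)
        assert collapse_duplicates([rec]) == [rec]

    def test_idempotent(self):
        once = collapse_duplicates(self.group([1.0, 1.2, 1.1]))
        assert collapse_duplicates(once) == once

    @given(st.permutations(list(range(3))))
    @settings(max_examples=10, deadline=None, derandomize=True)
    def test_permutation_invariant(self, order):
        records = (self.group([1.0, 1.3]) +
                   [make_record("other", position="99", ddg_exp=0.5)])
        permuted = collapse_duplicates([records[i] for i in order])
        assert permuted == collapse_duplicates(records)


class TestChainLength:
    def test_short_partner_chain_drops_record(self):
        lengths = {("1ABC", "A"): 120, ("1ABC", "B"): 19}
        assert filter_min_chain_length([make_record("x")], lengths) == []

    def test_long_chains_kept(self):
        lengths = {("1ABC", "A"): 21, ("1ABC", "B"): 300}
        assert len(filter_min_chain_length([make_record("x")], lengths)) == 1

    def test_exactly_twenty_is_kept(self):
        lengths = {("1ABC", "A"): 20, ("1ABC", "B"): 100}
        assert len(filter_min_chain_length([make_record("x")], lengths)) == 1

    def test_unresolvable_chain_drops_record(self):
        assert filter_min_chain_length([make_record("x")], {}) == []

    def test_lengths_from_structure_fixture(self, tmp_path):
        text = generate_structure_fixture({"A": 19, "B": 100})
        st_ = structure_from_text(tmp_path, text)
        kept = filter_min_chain_length([make_record("x")], None,
                                       {"1ABC": st_})
        assert kept == []


class TestResidueWindow:
    def test_gap_inside_window_fails(self, tmp_path):
        text = generate_structure_fixture({"A": 30}, gap_positions={"A": [17]})
        st_ = structure_from_text(tmp_path, text)
        assert check_residue_window(st_, "A", "15") is False

    def test_intact_window_passes(self, tmp_path):
        text = generate_structure_fixture({"A": 30})
        st_ = structure_from_text(tmp_path, text)
        assert check_residue_window(st_, "A", "15") is True

    def test_window_truncates_at_terminus(self, tmp_path):
        text = generate_structure_fixture({"A": 30})
        st_ = structure_from_text(tmp_path, text)
        assert check_residue_window(st_, "A", "3") is True

    def test_absent_site_fails(self, tmp_path):
        text = generate_structure_fixture({"A": 30})
        st_ = structure_from_text(tmp_path, text)
        assert check_residue_window(st_, "A", "99") is False
        assert check_residue_window(st_, "Z", "15") is False


class TestNonstandardResidues:
    def test_selenomethionine_reverted_to_parent(self, tmp_path):
        text = generate_structure_fixture({"A": 12},
                                          nonstandard={"A": {5: "MSE"}})
        st_ = structure_from_text(tmp_path, text)
        st_, purge = normalize_nonstandard_residues(st_)
        names = {r.seqid.num: r.name for r in st_[0]["A"]}
        assert names[5] == "MET"
        assert purge is False

    def test_purge_list_residue_flags_structure(self, tmp_path):
        text = generate_structure_fixture({"A": 12},
                                          nonstandard={"A": {5: "LLP"}})
        st_ = structure_from_text(tmp_path, text)
        _, purge = normalize_nonstandard_residues(st_)
        assert purge is True

    def test_clean_structure_unchanged(self, tmp_path):
        text = generate_structure_fixture({"A": 12})
        st_ = structure_from_text(tmp_path, text)
        st_, purge = normalize_nonstandard_residues(st_)
        assert purge is False
        assert all(r.name == "ALA" for r in st_[0]["A"])


class TestS2648Pipeline:
    def test_obsolete_structure_removed(self):
        records = [make_record(f"r{i}", kind="folding", chains="",
                               kd_wt_M=None, kd_mut_M=None, position=str(i),
                               pdb_id="2A01" if i == 0 else "1XYZ")
                   for i in range(5)]
        raw = Dataset(name="s", dataset_kind="folding", records=records)
        curated, log = curate_s2648(raw)
        assert len(curated) == 4
        assert log.counts() == [(5, 4)]

    def test_empty_obsolete_set_is_identity(self):
        records = [make_record("a", kind="folding", chains="", kd_wt_M=None,
                               kd_mut_M=None)]
        raw = Dataset(name="s", dataset_kind="folding", records=records)
        curated, _ = curate_s2648(raw, obsolete_pdb_ids=())
        assert curated.records == records


class TestSkempiSeqPipeline:
    def test_each_filter_trips_once(self, skempi_filter_fixture):
        raw, chain_lengths = skempi_filter_fixture
        curated, log = curate_skempi_seq(raw, chain_lengths=chain_lengths)
        assert len(log.steps) == 5
        assert log.counts() == [(7, 6), (6, 5), (5, 4), (4, 3), (3, 2)]
        assert all(s.n_out == s.n_in - 1 for s in log.steps)
        assert len(curated) == 2
        collapsed = next(r for r in curated.records if r.position == "14")
        assert collapsed.ddg_exp == pytest.approx(1.1)

    def test_empty_input_logs_five_steps(self):
        raw = Dataset(name="empty", dataset_kind="protein_protein", records=[])
        curated, log = curate_skempi_seq(raw, chain_lengths={})
        assert len(curated) == 0
        assert [s.n_out for s in log.steps] == [0] * 5

    def test_monotone_and_consistent_counts(self, skempi_filter_fixture):
        raw, chain_lengths = skempi_filter_fixture
        curated, log = curate_skempi_seq(raw, chain_lengths=chain_lengths)
        for step in log.steps:
            assert step.n_out <= step.n_in
        assert log.steps[-1].n_out == len(curated)


class TestSkempi3dPipeline:
    @pytest.fixture
    def structures(self, tmp_path):
        good = generate_structure_fixture({"A": 40, "B": 40})
        gapped = generate_structure_fixture({"A": 40, "B": 40},
                                            gap_positions={"A": [22]})
        llp = generate_structure_fixture({"A": 40, "B": 40},
                                         nonstandard={"A": {30: "LLP"}})
        return {
            "GOOD": structure_from_text(tmp_path, good, "good"),
            "GAPY": structure_from_text(tmp_path, gapped, "gapy"),
            "LLPX": structure_from_text(tmp_path, llp, "llpx"),
        }

    def test_window_and_purge_steps(self, structures):
        records = [
            make_record("keep", pdb_id="GOOD", position="20"),
            make_record("gap", pdb_id="GAPY", position="20"),
            make_record("llp", pdb_id="LLPX", position="20"),
            make_record("nostructure", pdb_id="MISS", position="20"),
        ]
        raw = Dataset(name="3d", dataset_kind="protein_protein",
                      records=records)
        curated, log = curate_skempi_3d(raw, structures)
        assert [r.record_id for r in curated.records] == ["keep"]
        names = [s.name for s in log.steps]
        assert names == ["drop_missing_affinity_or_temperature",
                         "filter_single_point", "collapse_duplicates",
                         "check_residue_window", "purge_nonstandard_residues"]


class TestPronabPipeline:
    @pytest.fixture
    def structures(self, tmp_path):
        # chain A of poly-ALA; mutation wt must equal the structure residue
        text = generate_structure_fixture({"A": 30})
        return {"1AAY": structure_from_text(tmp_path, text, "aay")}

    def base(self, record_id, **kw):
        defaults = dict(kind="protein_dna", chains="", na_type="DNA",
                        pdb_id="1AAY", chain="A", position="10", wt_aa="A",
                        mut_aa="G", kd_wt_M=None, kd_mut_M=None)
        defaults.update(kw)
        return make_record(record_id, **defaults)

    def test_full_pipeline(self, structures):
        records = [
            self.base("keep"),
            self.base("rna", na_type="RNA", position="11"),
            self.base("nopdb", pdb_id="", position="12"),
            self.base("multi", n_mutations=2, position="13"),
            self.base("mismatch", wt_aa="R", mut_aa="K", position="14"),
            self.base("offstructure", position="99"),
        ]
        raw = Dataset(name="pn", dataset_kind="protein_dna", records=records)
        curated, log = curate_pronab(raw, structures)
        assert [r.record_id for r in curated.records] == ["keep"]
        assert [s.name for s in log.steps] == [
            "filter_single_point", "keep_dna_only", "require_pdb",
            "collapse_duplicates", "map_mutation_to_structure"]
        assert log.counts() == [(6, 5), (5, 4), (4, 3), (3, 3), (3, 1)]
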