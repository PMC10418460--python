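import pytest

from ddgbench import (
    Dataset,
    MutationRecord,
    build_snv_lookup,
)


@pytest.fixture(scope="session")
def lookup():
    return build_snv_lookup()


def make_record(record_id, kind="protein_protein", **kw):
    defaults = dict(
        record_id=record_id, dataset_kind=kind, pdb_id="1ABC", chains="A_B",
        chain="A", position="31", wt_aa="V", mut_aa="A", ddg_exp=1.0,
        temperature_K=298.0, kd_wt_M=1e-9, kd_mut_M=1e-8,
    )
    defaults.update(kw)
    return MutationRecord(**defaults)


@pytest.fixture
def toy_folding_dataset():
    """Six folding ddG values used for the stability-count example."""
    values = [2.5, 1.5, -0.5, -1.2, -2.1, -3.0]
    records = [
        make_record(f"r{i}", kind="folding", chains="", kd_wt_M=None,
                    kd_mut_M=None, ddg_exp=v, position=str(10 + i))
        for i, v in enumerate(values)
    ]
    return Dataset(name="toy", dataset_kind="folding", records=records)


@pytest.fixture
def skempi_filter_fixture():
    """Engineered pre-curation set tripping each sequence-pipeline filter once.

    Seven records: one survivor, one missing temperature, one double
    mutant, one trimer, one duplicate pair (SD <= 1, collapses 2 -> 1),
    one on a 19-residue chain.  Stepwise counts: 7->6->5->4->3->2.
    """
    records = [
        make_record("ok", pdb_id="P1", position="10"),
        make_record("no_temp", pdb_id="P1", position="11", temperature_K=None),
        make_record("double", pdb_id="P1", position="12", n_mutations=2),
        make_record("trimer", pdb_id="P2", chains="AB_C", position="13"),
        make_record("dup_a", pdb_id="P1", position="14", ddg_exp=1.0),
        make_record("dup_b", pdb_id="P1", position="14", ddg_exp=1.2),
        make_record("short_chain", pdb_id="P3", position="15"),
    ]
    chain_lengths = {
        ("P1", "A"): 120, ("P1", "B"): 140,
        ("P2", "A"): 120, ("P2", "B"): 120, ("P2", "C"): 120,
        ("P3", "A"): 19, ("P3", "B"): 100,
    }
    raw = Dataset(name="engineered", dataset_kind="protein_protein",
                  records=records)
    return raw, chain_lengths
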