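"""Dataset-construction pipelines with per-step audit logging.

Implements the curation recipes behind four benchmark sets:

* a ProTherm-derived folding set (S2648-style) with obsolete-structure
  removal;
* a sequence-level protein-protein binding set: exact affinity +
  temperature -> single-point -> dimers only -> duplicate collapse at
  SD <= 1 kcal/mol -> minimum partner-chain length 20;
* a structure-level protein-protein binding set: exact affinity +
  temperature -> single-point -> duplicate collapse -> intact -5..+5
  residue window around the mutation site -> nonstandard-residue
  normalisation with purging of CGU/LLP-containing structures;
* a protein-DNA binding set: single-point -> DNA only -> PDB required ->
  duplicate collapse -> mutation maps onto the structure.

Every step is recorded in a :class:`CurationLog` with input/output
record and complex counts, so published funnel counts can be compared
step by step.
"""

from __future__ import annotations

import io
import json
import statistics
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional, Sequence

import gemmi

from .dataset_io import Dataset, MutationRecord
from .genetic_code import InputError

__all__ = [
    "CurationLog",
    "StructureCheckConfig",
    "DEFAULT_ANALOG_MAP",
    "load_structure",
    "drop_missing_affinity_or_temperature",
    "filter_single_point",
    "filter_dimers",
    "collapse_duplicates",
    "filter_min_chain_length",
    "check_residue_window",
    "normalize_nonstandard_residues",
    "curate_s2648",
    "curate_skempi_seq",
    "curate_skempi_3d",
    "curate_pronab",
]

#: Common nonstandard-residue analogs mapped back to parent residues.
DEFAULT_ANALOG_MAP: dict[str, str] = {
    "MSE": "MET", "SEP": "SER", "TPO": "THR", "PTR": "TYR",
    "CSO": "CYS", "CME": "CYS", "CSD": "CYS", "OCS": "CYS",
    "MLY": "LYS", "KCX": "LYS", "HYP": "PRO", "PCA": "GLU",
    "FME": "MET", "CMT": "CYS", "M3L": "LYS", "ALY": "LYS",
}

_THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}


@dataclass
class CurationStep:
    name: str
    n_in: int
    n_out: int
    n_complexes_out: int
    notes: str = ""


@dataclass
class CurationLog:
    """Ordered record of filter steps with input/output counts."""

    dataset: str
    steps: list[CurationStep] = field(default_factory=list)

    def add(self, name: str, n_in: int, records: Sequence[MutationRecord],
            notes: str = "") -> None:
        n_out = len(records)
        if n_out > n_in:
            raise AssertionError(f"step {name!r} increased record count")
        complexes = {r.pdb_id for r in records if r.pdb_id}
        self.steps.append(CurationStep(
            name=name, n_in=n_in, n_out=n_out,
            n_complexes_out=len(complexes), notes=notes,
        ))

    def counts(self) -> list[tuple[int, int]]:
        return [(s.n_in, s.n_out) for s in self.steps]

    def to_json(self) -> str:
        return json.dumps({
            "dataset": self.dataset,
            "steps": [vars(s) for s in self.steps],
        }, indent=2)

    def __str__(self) -> str:
        buf = io.StringIO()
        buf.write(f"Curation of {self.dataset}\n")
        for s in self.steps:
            buf.write(f"  {s.name}: {s.n_in} -> {s.n_out}"
                      f" ({s.n_complexes_out} complexes/proteins)")
            if s.notes:
                buf.write(f"  [{s.notes}]")
            buf.write("\n")
        return buf.getvalue()


@dataclass
class StructureCheckConfig:
    """Parameters of the structure-based checks."""

    window_half_width: int = 5
    purge_residues: frozenset[str] = frozenset({"CGU", "LLP"})
    analog_map: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_ANALOG_MAP))
    sd_ddof: int = 1  # sample SD for duplicate groups

    def __post_init__(self) -> None:
        if self.window_half_width < 0:
            raise InputError("window half-width must be >= 0")


def load_structure(source: str | Path | gemmi.Structure) -> gemmi.Structure:
    """Load a PDB/mmCIF file (or pass through a parsed structure)."""
    if isinstance(source, gemmi.Structure):
        return source
    st = gemmi.read_structure(str(source))
    st.setup_entities()
    return st


# ---------------------------------------------------------------------------
# elementary filters

def drop_missing_affinity_or_temperature(
    records: Sequence[MutationRecord],
) -> list[MutationRecord]:
    """Keep only records with a numeric temperature and exact Kd for both
    wild type and mutant (inequality affinities never parse to a value)."""
    return [
        r for r in records
        if r.temperature_K is not None
        and r.kd_wt_M is not None and r.kd_mut_M is not None
    ]


def filter_single_point(records: Sequence[MutationRecord]) -> list[MutationRecord]:
    """Keep only single-point mutations."""
    return [r for r in records if r.n_mutations == 1]


def filter_dimers(records: Sequence[MutationRecord]) -> list[MutationRecord]:
    """Keep only dimeric complexes: exactly one chain in each of the two
    partner groups.  Records without chain-group information are dropped."""
    out = []
    for r in records:
        groups = r.partner_groups
        if len(groups) == 2 and all(len(g) == 1 for g in groups):
            out.append(r)
    return out


def collapse_duplicates(
    records: Sequence[MutationRecord],
    sd_threshold: float = 1.0,
    ddof: int = 1,
) -> list[MutationRecord]:
    """Average replicate measurements of the same mutation; purge noisy ones.

    Records are grouped by (complex, chains, chain, position, wt, mut).
    A group whose ddG standard deviation (``ddof=1``: sample estimator)
    exceeds ``sd_threshold`` is removed entirely; otherwise the group
    collapses to a single record carrying the mean ddG and the group
    size.  Singletons pass through unchanged.  Output order follows the
    first occurrence of each group, so the operation is deterministic
    and insensitive to permutations up to ordering.
    """
    groups: dict[tuple, list[MutationRecord]] = {}
    for r in records:
        groups.setdefault(r.mutation_key, []).append(r)
    out = []
    for key in groups:
        members = groups[key]
        if len(members) == 1:
            out.append(members[0])
            continue
        values = [m.ddg_exp for m in members]
        if any(v is None for v in values):
            continue  # replicates without a value cannot be averaged
        if ddof == 1:
            sd = statistics.stdev(values)
        else:
            sd = statistics.pstdev(values)
        if sd > sd_threshold:
            continue
        lead = min(members, key=lambda m: m.record_id)
        out.append(replace(
            lead,
            ddg_exp=sum(values) / len(values),
            n_measurements=sum(m.n_measurements for m in members),
        ))
    out.sort(key=lambda r: r.record_id)
    return out


def _chain_length(
    chain_lengths: Mapping[tuple[str, str], int] | None,
    structures: Mapping[str, gemmi.Structure] | None,
    pdb_id: str,
    chain: str,
) -> Optional[int]:
    if chain_lengths is not None and (pdb_id, chain) in chain_lengths:
        return chain_lengths[(pdb_id, chain)]
    if structures is not None and pdb_id in structures:
        st = structures[pdb_id]
        # SEQRES (full_sequence) preferred; fall back to resolved residues.
        for entity in st.entities:
            if chain in entity.subchains or chain in entity.name:
                if entity.full_sequence:
                    return len(entity.full_sequence)
        model = st[0]
        ch = model.find_chain(chain)
        if ch is not None:
            return sum(1 for res in ch if res.name in _THREE_TO_ONE
                       or res.name in DEFAULT_ANALOG_MAP)
    return None


def filter_min_chain_length(
    records: Sequence[MutationRecord],
    chain_lengths: Mapping[tuple[str, str], int] | None = None,
    structures: Mapping[str, gemmi.Structure] | None = None,
    min_len: int = 20,
) -> list[MutationRecord]:
    """Keep records only when every partner chain has >= ``min_len``
    residues (a chain of exactly ``min_len`` is kept).  Chains whose
    length cannot be resolved drop the record."""
    out = []
    for r in records:
        chains = [c for group in r.partner_groups for c in group]
        if not chains:
            continue
        lengths = [_chain_length(chain_lengths, structures, r.pdb_id, c)
                   for c in chains]
        if any(ln is None for ln in lengths):
            continue
        if all(ln >= min_len for ln in lengths):
            out.append(r)
    return out


# ---------------------------------------------------------------------------
# structure checks

def _parse_position(position: str) -> tuple[int, str]:
    """Split an author-numbering position into (number, insertion code)."""
    pos = position.strip()
    icode = ""
    if pos and pos[-1].isalpha():
        icode = pos[-1].upper()
        pos = pos[:-1]
    try:
        return int(pos), icode
    except ValueError:
        raise InputError(f"unparsable residue position {position!r}")


def check_residue_window(
    structure: gemmi.Structure | str | Path,
    chain: str,
    position: str,
    half_width: int = 5,
) -> bool:
    """True iff the mutation site and all residues at author numbers
    within +/- ``half_width`` of it are present with coordinates.

    Only positions that exist within the chain's numbering range are
    required, so windows truncate at the termini instead of failing.
    A site absent from the chain returns False.
    """
    st = load_structure(structure)
    model = st[0]
    ch = model.find_chain(chain)
    if ch is None:
        return False
    num, icode = _parse_position(position)
    present = {res.seqid.num for res in ch if len(res) > 0}
    site_found = any(
        res.seqid.num == num and (res.seqid.icode.strip().upper() == icode)
        for res in ch
    )
    if not site_found or not present:
        return False
    lo, hi = min(present), max(present)
    for offset in range(-half_width, half_width + 1):
        target = num + offset
        if target < lo or target > hi:
            continue  # beyond the terminus: not required
        if target not in present:
            return False
    return True


def normalize_nonstandard_residues(
    structure: gemmi.Structure | str | Path,
    config: StructureCheckConfig | None = None,
) -> tuple[gemmi.Structure, bool]:
    """Rename common residue analogs to their parents; flag purge-listed ones.

    Returns the (modified in place) structure and a flag that is True iff
    any residue on the purge list (default CGU, LLP) is present — such
    structures are excluded from structure-based curation.
    """
    config = config or StructureCheckConfig()
    st = load_structure(structure)
    purge = False
    for model in st:
        for chain in model:
            for res in chain:
                if res.name in config.purge_residues:
                    purge = True
                elif res.name in config.analog_map:
                    res.name = config.analog_map[res.name]
    return st, purge


# ---------------------------------------------------------------------------
# pipelines

def curate_s2648(
    raw: Dataset,
    obsolete_pdb_ids: Iterable[str] = ("2A01",),
) -> tuple[Dataset, CurationLog]:
    """Folding-set cleanup: remove records from obsolete PDB entries."""
    log = CurationLog(dataset=raw.name)
    obsolete = {p.upper() for p in obsolete_pdb_ids}
    kept = [r for r in raw.records if r.pdb_id.upper() not in obsolete]
    log.add("drop_obsolete_structures", len(raw.records), kept,
            notes=f"obsolete: {sorted(obsolete)}")
    return Dataset(name=f"{raw.name}-curated", dataset_kind=raw.dataset_kind,
                   records=kept), log


def curate_skempi_seq(
    raw: Dataset,
    chain_lengths: Mapping[tuple[str, str], int] | None = None,
    structures: Mapping[str, gemmi.Structure] | None = None,
    sd_threshold: float = 1.0,
    min_chain_len: int = 20,
) -> tuple[Dataset, CurationLog]:
    """Sequence-level protein-protein pipeline (five ordered filters)."""
    log = CurationLog(dataset=raw.name)
    recs = list(raw.records)

    n = len(recs)
    recs = drop_missing_affinity_or_temperature(recs)
    log.add("drop_missing_affinity_or_temperature", n, recs)

    n = len(recs)
    recs = filter_single_point(recs)
    log.add("filter_single_point", n, recs)

    n = len(recs)
    recs = filter_dimers(recs)
    log.add("filter_dimers", n, recs)

    n = len(recs)
    recs = collapse_duplicates(recs, sd_threshold=sd_threshold)
    log.add("collapse_duplicates", n, recs, notes=f"SD threshold {sd_threshold}")

    n = len(recs)
    recs = filter_min_chain_length(recs, chain_lengths, structures,
                                   min_len=min_chain_len)
    log.add("filter_min_chain_length", n, recs, notes=f"min length {min_chain_len}")

    return Dataset(name=f"{raw.name}-seq", dataset_kind=raw.dataset_kind,
                   records=recs), log


def curate_skempi_3d(
    raw: Dataset,
    structures: Mapping[str, gemmi.Structure | str | Path],
    config: StructureCheckConfig | None = None,
    sd_threshold: float = 1.0,
) -> tuple[Dataset, CurationLog]:
    """Structure-level protein-protein pipeline.

    After the affinity/temperature, single-point and duplicate-collapse
    steps, records are removed when the mutation-site residue window is
    broken or the structure contains purge-listed nonstandard residues.
    Records whose structure file is unavailable are dropped.
    """
    config = config or StructureCheckConfig()
    log = CurationLog(dataset=raw.name)
    recs = list(raw.records)

    n = len(recs)
    recs = drop_missing_affinity_or_temperature(recs)
    log.add("drop_missing_affinity_or_temperature", n, recs)

    n = len(recs)
    recs = filter_single_point(recs)
    log.add("filter_single_point", n, recs)

    n = len(recs)
    recs = collapse_duplicates(recs, sd_threshold=sd_threshold, ddof=config.sd_ddof)
    log.add("collapse_duplicates", n, recs, notes=f"SD threshold {sd_threshold}")

    parsed: dict[str, gemmi.Structure] = {}
    purged_pdbs: set[str] = set()
    for pdb_id, src in structures.items():
        st, purge = normalize_nonstandard_residues(load_structure(src), config)
        parsed[pdb_id.upper()] = st
        if purge:
            purged_pdbs.add(pdb_id.upper())

    n = len(recs)
    kept = []
    for r in recs:
        st = parsed.get(r.pdb_id.upper())
        if st is None:
            continue
        if check_residue_window(st, r.chain, r.position,
                                half_width=config.window_half_width):
            kept.append(r)
    recs = kept
    log.add("check_residue_window", n, recs,
            notes=f"half-width {config.window_half_width}")

    n = len(recs)
    recs = [r for r in recs if r.pdb_id.upper() not in purged_pdbs]
    log.add("purge_nonstandard_residues", n, recs,
            notes=f"purge list {sorted(config.purge_residues)}")

    return Dataset(name=f"{raw.name}-3d", dataset_kind=raw.dataset_kind,
                   records=recs), log


def _mutation_maps_to_structure(
    record: MutationRecord, st: gemmi.Structure
) -> bool:
    """The mutated residue exists with coordinates and matches the listed
    wild-type amino acid."""
    model = st[0]
    ch = model.find_chain(record.chain) if record.chain else None
    chains = [ch] if ch is not None else list(model)
    try:
        num, icode = _parse_position(record.position)
    except InputError:
        return False
    for chain in chains:
        for res in chain:
            if res.seqid.num == num and res.seqid.icode.strip().upper() == icode:
                if len(res) == 0:
                    continue
                one = _THREE_TO_ONE.get(res.name)
                if one is None:
                    parent = DEFAULT_ANALOG_MAP.get(res.name)
                    one = _THREE_TO_ONE.get(parent) if parent else None
                if one == record.wt_aa:
                    return True
    return False


def curate_pronab(
    raw: Dataset,
    structures: Mapping[str, gemmi.Structure | str | Path],
    sd_threshold: float = 1.0,
) -> tuple[Dataset, CurationLog]:
    """Protein-DNA pipeline: single-point -> DNA only -> PDB required ->
    duplicate collapse -> mutation maps onto the structure."""
    log = CurationLog(dataset=raw.name)
    recs = list(raw.records)

    n = len(recs)
    recs = filter_single_point(recs)
    log.add("filter_single_point", n, recs)

    n = len(recs)
    recs = [r for r in recs if r.na_type == "DNA"]
    log.add("keep_dna_only", n, recs)

    n = len(recs)
    recs = [r for r in recs if r.pdb_id]
    log.add("require_pdb", n, recs)

    n = len(recs)
    recs = collapse_duplicates(recs, sd_threshold=sd_threshold)
    log.add("collapse_duplicates", n, recs, notes=f"SD threshold {sd_threshold}")

    parsed = {pid.upper(): load_structure(src) for pid, src in structures.items()}
    n = len(recs)
    recs = [
        r for r in recs
        if r.pdb_id.upper() in parsed
        and _mutation_maps_to_structure(r, parsed[r.pdb_id.upper()])
    ]
    log.add("map_mutation_to_structure", n, recs)

    return Dataset(name=f"{raw.name}-curated", dataset_kind=raw.dataset_kind,
                   records=recs), log
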