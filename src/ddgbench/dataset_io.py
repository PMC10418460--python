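"""Reading and writing mutation datasets and prediction sets.

Supported inputs: the package's canonical comma-delimited CSV, the
semicolon-delimited SKEMPI-2.0 export, a ProNAB-style protein-nucleic
acid export, and predictor output CSVs.  Binding affinities are
converted to free energies with dG = RT ln(Kd); only *exact* (purely
numeric) dissociation constants parse to a value — inequalities such as
``>1e-4`` are retained as missing so the curation stage can purge them.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .genetic_code import AMINO_ACIDS, InputError

__all__ = [
    "GAS_CONSTANT_KCAL",
    "DATASET_KINDS",
    "MutationRecord",
    "Dataset",
    "PredictionSet",
    "read_canonical_csv",
    "write_canonical_csv",
    "read_skempi2",
    "read_pronab_export",
    "read_predictions",
    "dg_from_kd",
    "ddg_binding_from_affinities",
    "parse_mutation_string",
    "parse_temperature",
]

logger = logging.getLogger(__name__)

#: Gas constant in kcal mol^-1 K^-1.
GAS_CONSTANT_KCAL: float = 1.9872e-3

DATASET_KINDS = ("folding", "protein_protein", "protein_dna")

_CANONICAL_COLUMNS = [
    "record_id", "dataset_kind", "pdb_id", "chains", "chain", "position",
    "wt_aa", "mut_aa", "ddg_exp", "temperature_K", "kd_wt_M", "kd_mut_M",
    "n_measurements", "source",
]
_OPTIONAL_COLUMNS = ["n_mutations", "na_type"]


@dataclass
class MutationRecord:
    """One single-point amino-acid substitution with its measurement.

    ``ddg_exp`` is in kcal/mol, in the native sign convention of
    ``dataset_kind`` (folding: stabilizing-positive; binding:
    destabilizing-positive).  ``position`` is the author-numbering
    position string and may carry an insertion code.  ``chains`` holds
    the partner chain groups of a complex as ``"<group1>_<group2>"``.
    """

    record_id: str
    dataset_kind: str
    wt_aa: str
    mut_aa: str
    pdb_id: str = ""
    chains: str = ""
    chain: str = ""
    position: str = ""
    ddg_exp: Optional[float] = None
    temperature_K: Optional[float] = None
    kd_wt_M: Optional[float] = None
    kd_mut_M: Optional[float] = None
    n_measurements: int = 1
    n_mutations: int = 1
    na_type: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if self.dataset_kind not in DATASET_KINDS:
            raise InputError(
                f"record {self.record_id}: unknown dataset_kind {self.dataset_kind!r}"
            )
        if self.wt_aa == self.mut_aa:
            raise InputError(
                f"record {self.record_id}: wild-type and mutant residue are equal"
            )
        for name in ("kd_wt_M", "kd_mut_M", "temperature_K"):
            value = getattr(self, name)
            if value is not None and not value > 0:
                raise InputError(
                    f"record {self.record_id}: {name} must be positive, got {value}"
                )

    @property
    def partner_groups(self) -> tuple[str, ...]:
        """Partner chain groups, e.g. ``"A_BC"`` -> ``("A", "BC")``."""
        if not self.chains:
            return ()
        return tuple(g for g in self.chains.split("_") if g)

    @property
    def mutation_key(self) -> tuple[str, str, str, str, str, str]:
        """Identity of the mutation for duplicate grouping."""
        return (self.pdb_id, self.chains, self.chain, self.position,
                self.wt_aa, self.mut_aa)


@dataclass
class Dataset:
    """A named, homogeneous collection of :class:`MutationRecord`."""

    name: str
    dataset_kind: str
    records: list[MutationRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.record_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise InputError(f"dataset {self.name!r}: duplicate record ids {dupes[:5]}")
        for r in self.records:
            if r.dataset_kind != self.dataset_kind:
                raise InputError(
                    f"dataset {self.name!r}: record {r.record_id} has kind "
                    f"{r.dataset_kind!r}, expected {self.dataset_kind!r}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def ddg_values(self) -> np.ndarray:
        return np.array([r.ddg_exp for r in self.records], dtype=float)


@dataclass
class PredictionSet:
    """Predicted ddG per record id for one predictor.

    ``convention`` declares the predictor's sign convention:
    ``"dataset"`` (already native), ``"stabilizing_positive"`` or
    ``"destabilizing_positive"``.
    """

    predictor: str
    values: dict[str, float]
    convention: str = "dataset"

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.values.items() if not math.isfinite(v)}
        if bad:
            raise InputError(
                f"prediction set {self.predictor!r}: non-finite values for "
                f"{sorted(bad)[:5]}"
            )

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# canonical CSV

def _opt_float(value, *, row: int, column: str) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise InputError(f"row {row}: unparsable numeric in column {column!r}: {value!r}")


def read_canonical_csv(path: str | Path, name: str | None = None) -> Dataset:
    """Read a dataset from the canonical CSV schema."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing mandatory columns {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        try:
            records.append(MutationRecord(
                record_id=d["record_id"],
                dataset_kind=d["dataset_kind"],
                pdb_id=d["pdb_id"],
                chains=d["chains"],
                chain=d["chain"],
                position=d["position"],
                wt_aa=d["wt_aa"],
                mut_aa=d["mut_aa"],
                ddg_exp=_opt_float(d["ddg_exp"], row=i, column="ddg_exp"),
                temperature_K=_opt_float(d["temperature_K"], row=i, column="temperature_K"),
                kd_wt_M=_opt_float(d["kd_wt_M"], row=i, column="kd_wt_M"),
                kd_mut_M=_opt_float(d["kd_mut_M"], row=i, column="kd_mut_M"),
                n_measurements=int(d["n_measurements"] or 1),
                n_mutations=int(d.get("n_mutations") or 1),
                na_type=d.get("na_type", ""),
                source=d["source"],
            ))
        except InputError as exc:
            raise InputError(f"{path}, row {i}: {exc}") from exc
    kinds = {r.dataset_kind for r in records}
    if len(kinds) > 1:
        raise InputError(f"{path}: mixed dataset kinds {sorted(kinds)}")
    kind = records[0].dataset_kind if records else "folding"
    return Dataset(name=name or path.stem, dataset_kind=kind, records=records)


def write_canonical_csv(dataset: Dataset, path: str | Path) -> None:
    """Write a dataset in the canonical CSV schema (lossless round trip)."""
    rows = []
    for r in dataset.records:
        rows.append({
            "record_id": r.record_id, "dataset_kind": r.dataset_kind,
            "pdb_id": r.pdb_id, "chains": r.chains, "chain": r.chain,
            "position": r.position, "wt_aa": r.wt_aa, "mut_aa": r.mut_aa,
            "ddg_exp": "" if r.ddg_exp is None else repr(r.ddg_exp),
            "temperature_K": "" if r.temperature_K is None else repr(r.temperature_K),
            "kd_wt_M": "" if r.kd_wt_M is None else repr(r.kd_wt_M),
            "kd_mut_M": "" if r.kd_mut_M is None else repr(r.kd_mut_M),
            "n_measurements": r.n_measurements,
            "n_mutations": r.n_mutations,
            "na_type": r.na_type,
            "source": r.source,
        })
    df = pd.DataFrame(rows, columns=_CANONICAL_COLUMNS + _OPTIONAL_COLUMNS)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# field parsers

_MUTATION_RE = re.compile(
    r"^(?P<wt>[A-Z])(?P<chain>[A-Za-z0-9]?)(?P<pos>\d+[A-Za-z]?)(?P<mut>[A-Z])$"
)


def parse_mutation_string(text: str) -> tuple[str, str, str, str]:
    """Parse ``{wt}{chain?}{position}{mut}`` into (wt, chain, position, mut).

    The chain character is optional (as in ``V31A``); insertion codes are
    kept as part of the position string.
    """
    text = text.strip()
    m = _MUTATION_RE.match(text)
    if not m:
        raise InputError(f"unparsable mutation string {text!r}")
    wt, chain, pos, mut = m.group("wt"), m.group("chain"), m.group("pos"), m.group("mut")
    # A chain letter is only plausible when followed by digits; the regex
    # already guarantees that.  Bare forms like "V31A" leave chain empty
    # only when the second character is a digit.
    if chain.isdigit():
        pos = chain + pos
        chain = ""
    if wt not in AMINO_ACIDS or mut not in AMINO_ACIDS:
        raise InputError(f"mutation {text!r}: non-canonical residue")
    return wt, chain, pos, mut


_NUMBER_RE = re.compile(r"[-+]?\d+(?:\.\d+)?(?:[eE][-+]?\d+)?")


def parse_temperature(text: str) -> Optional[float]:
    """Extract the leading numeric token of a temperature field.

    Annotated values such as ``"298(assumed)"`` yield 298.0; a field with
    no numeric token is missing.
    """
    if text is None:
        return None
    m = _NUMBER_RE.search(str(text))
    if not m:
        return None
    value = float(m.group(0))
    return value if value > 0 else None


def _parse_exact_kd(text) -> Optional[float]:
    """Parse a Kd only if given as an exact number (no inequality marks)."""
    if text is None:
        return None
    s = str(text).strip()
    if not s or s.lower() in {"nan", "n.b.", "n.b", "nb"}:
        return None
    if any(c in s for c in "<>~"):
        return None
    try:
        value = float(s)
    except ValueError:
        return None
    return value if value > 0 else None


# ---------------------------------------------------------------------------
# SKEMPI-2.0 dialect

_SKEMPI_REQUIRED = [
    "#Pdb", "Mutation(s)_cleaned", "Affinity_mut_parsed",
    "Affinity_wt_parsed", "Temperature",
]


def read_skempi2(path: str | Path, name: str = "skempi2") -> Dataset:
    """Read a SKEMPI-2.0 semicolon-delimited export (pre-curation).

    One record per row; rows listing several comma-separated mutations
    keep the first for the residue fields and carry the total count in
    ``n_mutations`` for the single-point filter.  Unparsable or inexact
    affinities and temperatures are retained as missing — curation, not
    reading, purges them.  ddG is computed as RT ln(Kd_mut/Kd_wt) when
    both affinities and the temperature are available.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=";", dtype=str, keep_default_na=False)
    missing = [c for c in _SKEMPI_REQUIRED if c not in df.columns]
    if missing:
        raise InputError(f"{path}: not a SKEMPI-2.0 export; missing columns {missing}")
    records = []
    for i, row in enumerate(df.to_dict("records"), start=2):
        complex_id = row["#Pdb"].strip()
        parts = complex_id.split("_")
        pdb_id = parts[0].upper()
        chains = "_".join(parts[1:]) if len(parts) > 1 else ""
        mutations = [m for m in row["Mutation(s)_cleaned"].split(",") if m.strip()]
        if not mutations:
            raise InputError(f"{path}, row {i}: empty mutation list")
        try:
            wt, chain, pos, mut = parse_mutation_string(mutations[0])
        except InputError as exc:
            raise InputError(f"{path}, row {i}: {exc}") from exc
        kd_wt = _parse_exact_kd(row["Affinity_wt_parsed"])
        kd_mut = _parse_exact_kd(row["Affinity_mut_parsed"])
        temperature = parse_temperature(row["Temperature"])
        ddg = None
        if kd_wt is not None and kd_mut is not None and temperature is not None:
            ddg = ddg_binding_from_affinities(kd_wt, kd_mut, temperature)
        record_id = f"{pdb_id}:{chain}:{pos}:{wt}>{mut}#{i - 2}"
        records.append(MutationRecord(
            record_id=record_id, dataset_kind="protein_protein",
            pdb_id=pdb_id, chains=chains, chain=chain, position=pos,
            wt_aa=wt, mut_aa=mut, ddg_exp=ddg, temperature_K=temperature,
            kd_wt_M=kd_wt, kd_mut_M=kd_mut, n_mutations=len(mutations),
            source="SKEMPI-2.0",
        ))
    return Dataset(name=name, dataset_kind="protein_protein", records=records)


# ---------------------------------------------------------------------------
# ProNAB-style dialect

_PRONAB_REQUIRED = ["NUCLEIC_ACID", "PDB_ID", "MUTATION"]


def read_pronab_export(path: str | Path, name: str = "pronab") -> Dataset:
    """Read a ProNAB-style protein-nucleic-acid export (pre-curation).

    Expected columns: ``NUCLEIC_ACID`` (DNA/RNA/hybrid), ``PDB_ID``
    (may be empty), ``MUTATION`` (``{wt}{chain?}{pos}{mut}``), optional
    ``CHAIN``, ``DDG`` (kcal/mol, destabilizing-positive), ``KD_WT``,
    ``KD_MUT``, ``TEMPERATURE``, ``N_MUTATIONS``.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _PRONAB_REQUIRED if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing columns {missing}")
    records = []
    for i, row in enumerate(df.to_dict("records"), start=2):
        try:
            wt, chain, pos, mut = parse_mutation_string(row["MUTATION"])
        except InputError as exc:
            raise InputError(f"{path}, row {i}: {exc}") from exc
        chain = row.get("CHAIN", "") or chain
        pdb_id = row["PDB_ID"].strip().upper()
        temperature = parse_temperature(row.get("TEMPERATURE", ""))
        kd_wt = _parse_exact_kd(row.get("KD_WT", ""))
        kd_mut = _parse_exact_kd(row.get("KD_MUT", ""))
        ddg = _opt_float(row.get("DDG", ""), row=i, column="DDG")
        if ddg is None and kd_wt is not None and kd_mut is not None and temperature:
            ddg = ddg_binding_from_affinities(kd_wt, kd_mut, temperature)
        record_id = f"{pdb_id or 'NOPDB'}:{chain}:{pos}:{wt}>{mut}#{i - 2}"
        records.append(MutationRecord(
            record_id=record_id, dataset_kind="protein_dna",
            pdb_id=pdb_id, chain=chain, position=pos,
            wt_aa=wt, mut_aa=mut, ddg_exp=ddg, temperature_K=temperature,
            kd_wt_M=kd_wt, kd_mut_M=kd_mut,
            n_mutations=int(row.get("N_MUTATIONS") or 1),
            na_type=row["NUCLEIC_ACID"].strip().upper(),
            source="ProNAB",
        ))
    return Dataset(name=name, dataset_kind="protein_dna", records=records)


# ---------------------------------------------------------------------------
# predictions

def read_predictions(
    path: str | Path,
    known_ids: Iterable[str] | None = None,
) -> PredictionSet:
    """Read a predictor output CSV: ``record_id,predictor,ddg_pred[,convention]``.

    Predictions for ids not in ``known_ids`` (when given) are excluded
    with a logged warning.  Non-finite predictions are input errors.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("record_id", "ddg_pred"):
        if col not in df.columns:
            raise InputError(f"{path}: missing column {col!r}")
    predictor = str(df["predictor"].iloc[0]) if "predictor" in df.columns and len(df) else path.stem
    convention = "dataset"
    if "convention" in df.columns and len(df):
        conventions = set(df["convention"].astype(str))
        if len(conventions) > 1:
            raise InputError(f"{path}: mixed sign conventions {sorted(conventions)}")
        convention = conventions.pop()
    values: dict[str, float] = {}
    known = set(known_ids) if known_ids is not None else None
    for i, row in enumerate(df.itertuples(index=False), start=2):
        rid = str(row.record_id)
        value = float(row.ddg_pred)
        if not math.isfinite(value):
            raise InputError(f"{path}, row {i}: non-finite prediction for {rid!r}")
        if known is not None and rid not in known:
            logger.warning("%s, row %d: prediction for unknown id %r excluded",
                           path, i, rid)
            continue
        if rid in values:
            raise InputError(f"{path}, row {i}: duplicate prediction for {rid!r}")
        values[rid] = value
    return PredictionSet(predictor=predictor, values=values, convention=convention)


# ---------------------------------------------------------------------------
# affinity -> free energy

def dg_from_kd(kd: float, temperature_K: float) -> float:
    """Binding free energy dG = RT ln(Kd) in kcal/mol.

    Sub-molar dissociation constants give negative (favourable) dG, the
    convention used by the SKEMPI community.
    """
    if not kd > 0:
        raise InputError(f"Kd must be positive, got {kd}")
    if not temperature_K > 0:
        raise InputError(f"temperature must be positive, got {temperature_K}")
    return GAS_CONSTANT_KCAL * temperature_K * math.log(kd)


def ddg_binding_from_affinities(
    kd_wt: float, kd_mut: float, temperature_K: float
) -> float:
    """ddG_binding = RT ln(Kd_mut / Kd_wt); positive means weaker binding."""
    return dg_from_kd(kd_mut, temperature_K) - dg_from_kd(kd_wt, temperature_K)
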