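"""Synthetic datasets, pseudo-predictors and structure fixtures.

The generator reproduces the statistical features that the assessment
pipeline relies on, with ground truth attached:

* the ~50/50 split between substitutions reachable by a single
  nucleotide change and those that are not;
* the destabilization-enriched ddG distribution of experimental
  databases, modelled as a two-component Gaussian mixture (one
  destabilization-shifted component plus a near-neutral one) whose
  defaults put the destabilizing:stabilizing ratio at the 2 kcal/mol
  cutoff inside the empirically reported 8-16 band;
* duplicated measurements with replicate noise, to exercise the
  SD-based duplicate collapse;
* pseudo-predictors pred = beta * ddg_true + eps with configurable
  attenuation beta and noise sigma, including per-stratum overrides.

Everything is driven by a single integer seed through numpy's
Generator, so outputs are byte-for-byte reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .dataset_io import Dataset, MutationRecord, PredictionSet
from .energetics import STABILIZING_DIRECTION
from .genetic_code import (
    CodonTable,
    InputError,
    SNVLookup,
    Substitution,
    build_snv_lookup,
    sense_codons,
    single_nt_neighbors,
)

__all__ = [
    "DdgMixture",
    "SyntheticSpec",
    "GeneratedData",
    "sample_substitution",
    "sample_ddg",
    "generate_dataset",
    "generate_predictions",
    "generate_structure_fixture",
    "theoretical_metrics",
]


@dataclass(frozen=True)
class DdgMixture:
    """Two-component Gaussian mixture over ddG *magnitudes* in the
    destabilizing direction (kcal/mol); the dataset kind orients the sign.

    Defaults give a destabilizing:stabilizing ratio of roughly 12:1 at
    the 2 kcal/mol cutoff, inside the 8-16 band seen in experimental
    databases.
    """

    destab_weight: float = 0.7
    destab_mean: float = 1.6
    destab_sd: float = 2.0
    neutral_mean: float = 0.2
    neutral_sd: float = 0.6

    def __post_init__(self) -> None:
        if not 0 <= self.destab_weight <= 1:
            raise InputError("destab_weight must be in [0, 1]")
        if self.destab_sd < 0 or self.neutral_sd < 0:
            raise InputError("mixture SDs must be >= 0")


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic dataset."""

    n_records: int = 1000
    dataset_kind: str = "folding"
    snv_fraction: float = 0.5
    mixture: DdgMixture = field(default_factory=DdgMixture)
    duplicate_rate: float = 0.0
    replicate_sd: float = 0.3
    seed: int = 0
    name: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_records < 1:
            raise InputError("n_records must be >= 1")
        if not 0 <= self.snv_fraction <= 1:
            raise InputError("snv_fraction must be in [0, 1]")
        if not 0 <= self.duplicate_rate <= 1:
            raise InputError("duplicate_rate must be in [0, 1]")
        if self.replicate_sd < 0:
            raise InputError("replicate_sd must be >= 0")


@dataclass
class GeneratedData:
    """A generated dataset with its pre-collapse raw records and ground truth.

    ``truth`` columns: record_id, is_snv (bool), ddg_true (kcal/mol,
    native convention, before replicate noise).
    """

    dataset: Dataset
    raw_records: list[MutationRecord]
    truth: pd.DataFrame


def sample_substitution(
    want_snv: bool,
    lookup: SNVLookup,
    rng: np.random.Generator,
    table: CodonTable | None = None,
) -> Substitution:
    """Draw a substitution that is (not) single-nucleotide reachable.

    SNV draws pick a random sense codon and a random missense sense
    neighbor, so the result is reachable by construction; non-SNV draws
    sample uniformly from the lookup's false pairs.
    """
    if want_snv:
        table = table or CodonTable.standard()
        codons = sense_codons(table)
        while True:
            codon = codons[rng.integers(len(codons))]
            wt = table.mapping[codon]
            neighbors = [
                nb for nb in single_nt_neighbors(codon)
                if table.mapping[nb] not in ("*", wt)
            ]
            if neighbors:
                nb = neighbors[rng.integers(len(neighbors))]
                return Substitution(wt, table.mapping[nb])
    false_pairs = sorted(p for p, v in lookup.entries.items() if not v)
    if not false_pairs:
        raise InputError("lookup has no non-SNV pairs to sample")
    wt, mut = false_pairs[rng.integers(len(false_pairs))]
    return Substitution(wt, mut)


def sample_ddg(
    mixture: DdgMixture, dataset_kind: str, rng: np.random.Generator
) -> float:
    """One ddG draw, signed for the dataset kind's destabilizing direction."""
    if dataset_kind not in STABILIZING_DIRECTION:
        raise InputError(f"unknown dataset kind {dataset_kind!r}")
    if rng.random() < mixture.destab_weight:
        magnitude = rng.normal(mixture.destab_mean, mixture.destab_sd)
    else:
        magnitude = rng.normal(mixture.neutral_mean, mixture.neutral_sd)
    # magnitude > 0 means destabilizing; orient to the native convention
    return float(-STABILIZING_DIRECTION[dataset_kind] * magnitude)


def generate_dataset(spec: SyntheticSpec) -> GeneratedData:
    """Generate a dataset plus raw (pre-collapse) records and ground truth.

    Each record gets a fake complex/protein identity; with probability
    ``duplicate_rate`` the raw form carries one extra replicate with
    Gaussian replicate noise, so running the duplicate collapse on
    ``raw_records`` recovers approximately the canonical dataset.
    """
    rng = np.random.default_rng(spec.seed)
    lookup = build_snv_lookup()
    table = CodonTable.standard()
    chains = "A_B" if spec.dataset_kind != "folding" else ""
    records: list[MutationRecord] = []
    raw: list[MutationRecord] = []
    truth_rows = []
    for i in range(spec.n_records):
        want_snv = bool(rng.random() < spec.snv_fraction)
        sub = sample_substitution(want_snv, lookup, rng, table)
        ddg_true = sample_ddg(spec.mixture, spec.dataset_kind, rng)
        pdb_id = f"SY{i // 50:02d}"
        position = str(10 + i % 50)
        record_id = f"{pdb_id}:A:{position}:{sub.wt_aa}>{sub.mut_aa}#{i}"
        base = MutationRecord(
            record_id=record_id, dataset_kind=spec.dataset_kind,
            pdb_id=pdb_id, chains=chains, chain="A", position=position,
            wt_aa=sub.wt_aa, mut_aa=sub.mut_aa, ddg_exp=ddg_true,
            temperature_K=298.0, source="synthetic",
        )
        records.append(base)
        n_rep = 2 if rng.random() < spec.duplicate_rate else 1
        for k in range(n_rep):
            noise = rng.normal(0.0, spec.replicate_sd) if n_rep > 1 else 0.0
            raw.append(MutationRecord(
                record_id=f"{record_id}/r{k}", dataset_kind=spec.dataset_kind,
                pdb_id=pdb_id, chains=chains, chain="A", position=position,
                wt_aa=sub.wt_aa, mut_aa=sub.mut_aa,
                ddg_exp=ddg_true + noise,
                temperature_K=298.0, source="synthetic-raw",
            ))
        truth_rows.append({
            "record_id": record_id,
            "is_snv": lookup.is_snv(sub.wt_aa, sub.mut_aa),
            "ddg_true": ddg_true,
        })
    dataset = Dataset(name=spec.name, dataset_kind=spec.dataset_kind,
                      records=records)
    return GeneratedData(dataset=dataset, raw_records=raw,
                         truth=pd.DataFrame(truth_rows))


def generate_predictions(
    dataset: Dataset,
    beta: float = 1.0,
    sigma: float = 0.0,
    stratum_overrides: Mapping[str, tuple[float, float]] | None = None,
    lookup: SNVLookup | None = None,
    seed: int = 0,
    predictor: str = "pseudo",
) -> PredictionSet:
    """Pseudo-predictor pred = beta * ddg_exp + Normal(0, sigma^2).

    ``stratum_overrides`` maps ``"SNV"`` / ``"non-SNV"`` to (beta,
    sigma) pairs; a lookup is then required to resolve each record's
    stratum.  Predictions are emitted in the dataset's native sign
    convention.
    """
    if sigma < 0:
        raise InputError("sigma must be >= 0")
    overrides = dict(stratum_overrides or {})
    if overrides and lookup is None:
        raise InputError("stratum_overrides require an SNV lookup")
    rng = np.random.default_rng(seed)
    values = {}
    for rec in dataset.records:
        b, s = beta, sigma
        if overrides:
            label = "SNV" if lookup.is_snv(rec.wt_aa, rec.mut_aa) else "non-SNV"
            if label in overrides:
                b, s = overrides[label]
        values[rec.record_id] = float(b * rec.ddg_exp + rng.normal(0.0, s))
    return PredictionSet(predictor=predictor, values=values, convention="dataset")


_ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}


def generate_structure_fixture(
    chains: Mapping[str, int],
    gap_positions: Mapping[str, Sequence[int]] | None = None,
    nonstandard: Mapping[str, Mapping[int, str]] | None = None,
    start_number: int = 1,
    sequence_aa: str = "A",
) -> str:
    """Minimal CA-only PDB text for exercising the structure checks.

    ``chains`` maps chain id -> length; ``gap_positions[chain]`` lists
    author residue numbers to omit (simulating unresolved residues);
    ``nonstandard[chain][number]`` replaces the residue name at a
    position (e.g. with ``"MSE"`` or ``"LLP"``).
    """
    gaps = {c: set(v) for c, v in (gap_positions or {}).items()}
    nonstd = {c: dict(v) for c, v in (nonstandard or {}).items()}
    for c in list(gaps) + list(nonstd):
        if c not in chains:
            raise InputError(f"options refer to unknown chain {c!r}")
    for c, numbers in gaps.items():
        rng_ok = range(start_number, start_number + chains[c])
        if any(n not in rng_ok for n in numbers):
            raise InputError(f"gap position outside chain {c!r}")
        if set(numbers) & set(nonstd.get(c, {})):
            raise InputError(f"chain {c!r}: a residue cannot be both gapped "
                             f"and nonstandard")
    lines = []
    serial = 1
    base_res = _ONE_TO_THREE[sequence_aa]
    for chain_id, length in chains.items():
        for num in range(start_number, start_number + length):
            if num in gaps.get(chain_id, set()):
                continue
            resname = nonstd.get(chain_id, {}).get(num, base_res)
            x, y, z = float(num), float(ord(chain_id) % 10), 0.0
            record = "HETATM" if resname in ("LLP", "CGU") else "ATOM  "
            lines.append(
                f"{record}{serial:5d}  CA  {resname:>3s} {chain_id}{num:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
            )
            serial += 1
        lines.append(f"TER   {serial:5d}      {base_res:>3s} {chain_id}"
                     f"{start_number + length - 1:4d}")
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def theoretical_metrics(
    beta: float, sigma: float, sigma_true: float
) -> tuple[float, float]:
    """Closed-form (pcc, slope) of pred = beta*true + eps.

    With Var(true) = sigma_true^2 and Var(eps) = sigma^2, the OLS slope
    of pred on true is beta and the correlation is
    beta * sigma_true / sqrt(beta^2 sigma_true^2 + sigma^2).
    """
    if not sigma_true > 0:
        raise InputError("sigma_true must be positive")
    if sigma < 0:
        raise InputError("sigma must be >= 0")
    denom = math.sqrt(beta**2 * sigma_true**2 + sigma**2)
    pcc = 0.0 if denom == 0 else beta * sigma_true / denom
    return pcc, beta
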