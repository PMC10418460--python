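"""Sign conventions, stabilizing/destabilizing classification, distributions.

Folding and binding free-energy changes use opposite sign conventions:

* folding: ddG = dG_wt - dG_mut, so a *positive* value stabilizes the
  protein;
* binding (protein-protein and protein-DNA): ddG = dG_mut - dG_wt, so a
  *positive* value weakens the interaction (destabilizes).

Classification at a cutoff is strict: |ddG| must exceed the cutoff, ties
are neutral.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .dataset_io import Dataset, MutationRecord
from .genetic_code import InputError, SNVLookup, Substitution

__all__ = [
    "STABILIZING_DIRECTION",
    "StabilityCounts",
    "DistributionSummary",
    "ddg_folding",
    "ddg_binding",
    "classify_stability",
    "count_stability",
    "summarize_distribution",
    "split_snv",
]

#: Sign of ddG that *stabilizes* for each dataset kind.
STABILIZING_DIRECTION: dict[str, int] = {
    "folding": +1,
    "protein_protein": -1,
    "protein_dna": -1,
}


def ddg_folding(dg_wt: float, dg_mut: float) -> float:
    """Folding free energy change: dG_wt - dG_mut (positive stabilizes)."""
    return dg_wt - dg_mut


def ddg_binding(dg_wt: float, dg_mut: float) -> float:
    """Binding free energy change: dG_mut - dG_wt (positive weakens binding)."""
    return dg_mut - dg_wt


def classify_stability(ddg: float, dataset_kind: str, cutoff: float = 2.0) -> str:
    """Classify a ddG as ``stabilizing``, ``destabilizing`` or ``neutral``.

    ``cutoff`` (kcal/mol, > 0) is applied strictly: a |ddG| equal to the
    cutoff is neutral.
    """
    if dataset_kind not in STABILIZING_DIRECTION:
        raise InputError(f"unknown dataset kind {dataset_kind!r}")
    if not cutoff > 0:
        raise InputError(f"cutoff must be positive, got {cutoff}")
    signed = ddg * STABILIZING_DIRECTION[dataset_kind]
    if signed > cutoff:
        return "stabilizing"
    if signed < -cutoff:
        return "destabilizing"
    return "neutral"


@dataclass(frozen=True)
class StabilityCounts:
    """Stabilizing/destabilizing tallies at one cutoff."""

    dataset: str
    cutoff: float
    n_stabilizing: int
    n_destabilizing: int

    @property
    def ratio_destab_to_stab(self) -> Optional[float]:
        """Destabilizing:stabilizing ratio; None when undefined."""
        if self.n_stabilizing == 0:
            return None
        return self.n_destabilizing / self.n_stabilizing


def count_stability(
    dataset: Dataset, cutoffs: Sequence[float] = (1.0, 2.0)
) -> list[StabilityCounts]:
    """Tallies of stabilizing and destabilizing mutations per cutoff."""
    out = []
    for cutoff in cutoffs:
        labels = [
            classify_stability(r.ddg_exp, dataset.dataset_kind, cutoff)
            for r in dataset.records
        ]
        out.append(StabilityCounts(
            dataset=dataset.name,
            cutoff=cutoff,
            n_stabilizing=labels.count("stabilizing"),
            n_destabilizing=labels.count("destabilizing"),
        ))
    return out


@dataclass
class DistributionSummary:
    """Histogram and summary statistics of one stratum's ddG values."""

    stratum: str
    n: int
    bin_edges: np.ndarray
    bin_counts: np.ndarray
    mean: Optional[float]
    median: Optional[float]
    fraction_destabilizing: Optional[float]
    #: cutoff -> destabilizing:stabilizing ratio (None when undefined)
    ratio_at_cutoff: dict[float, Optional[float]] = field(default_factory=dict)


def split_snv(
    dataset: Dataset, lookup: SNVLookup
) -> dict[str, list[MutationRecord]]:
    """Partition records into SNV and non-SNV strata via a lookup."""
    strata: dict[str, list[MutationRecord]] = {"SNV": [], "non-SNV": []}
    for rec in dataset.records:
        key = "SNV" if lookup.is_snv(rec.wt_aa, rec.mut_aa) else "non-SNV"
        strata[key].append(rec)
    return strata


def summarize_distribution(
    dataset: Dataset,
    lookup: SNVLookup | None = None,
    cutoffs: Sequence[float] = (1.0, 2.0),
    n_bins: int = 20,
) -> list[DistributionSummary]:
    """Per-stratum ddG distribution summaries (whole, SNV, non-SNV).

    Without a lookup only the whole-dataset summary is produced.  The
    destabilizing fraction counts records destabilizing at the smallest
    cutoff; ratios are reported per cutoff and are None when no
    stabilizing mutation exists at that cutoff.
    """
    strata: dict[str, list[MutationRecord]] = {"all": list(dataset.records)}
    if lookup is not None:
        strata.update(split_snv(dataset, lookup))
    kind = dataset.dataset_kind
    min_cutoff = min(cutoffs)
    out = []
    for label, records in strata.items():
        values = np.array([r.ddg_exp for r in records], dtype=float)
        if values.size == 0:
            out.append(DistributionSummary(
                stratum=label, n=0,
                bin_edges=np.array([]), bin_counts=np.array([], dtype=int),
                mean=None, median=None, fraction_destabilizing=None,
                ratio_at_cutoff={c: None for c in cutoffs},
            ))
            continue
        counts, edges = np.histogram(values, bins=n_bins)
        labels = [classify_stability(v, kind, min_cutoff) for v in values]
        frac_destab = labels.count("destabilizing") / values.size
        ratios: dict[float, Optional[float]] = {}
        for cutoff in cutoffs:
            cls = [classify_stability(v, kind, cutoff) for v in values]
            n_stab = cls.count("stabilizing")
            n_destab = cls.count("destabilizing")
            ratios[cutoff] = (n_destab / n_stab) if n_stab else None
        out.append(DistributionSummary(
            stratum=label, n=int(values.size),
            bin_edges=edges, bin_counts=counts,
            mean=float(values.mean()), median=float(np.median(values)),
            fraction_destabilizing=frac_destab,
            ratio_at_cutoff=ratios,
        ))
    return out
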