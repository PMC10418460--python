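"""Physicochemical typing of amino acids and substitution categories.

Substitutions are categorized along four independent axes — hydropathy
(hydrophobic/polar), size (small/large), ring character
(aliphatic/aromatic/neither) and charge (positive/negative/neutral).
Categories are ordered pairs of labels (large-small differs from
small-large), so that e.g. destabilizing cavity-creating mutations
(large-to-small) form their own stratum.

The default scheme is a Taylor-style taxonomy; any scheme can be
supplied from a YAML file and is validated for coverage and exclusivity
on load.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping

import yaml

from .genetic_code import AMINO_ACIDS, InputError, Substitution

if TYPE_CHECKING:  # pragma: no cover
    from .dataset_io import Dataset, MutationRecord

__all__ = [
    "AXES",
    "DEFAULT_SCHEME",
    "PropertyScheme",
    "SubstitutionCategory",
    "properties_of",
    "categorize_substitution",
    "stratify_by_category",
    "load_scheme",
]

logger = logging.getLogger(__name__)

#: The four classification axes, in canonical order.
AXES: tuple[str, ...] = ("hydropathy", "size", "ring", "charge")

_DEFAULT_PARTITIONS: dict[str, dict[str, str]] = {
    "hydropathy": {"hydrophobic": "ACFILMVWY", "polar": "DEGHKNPQRST"},
    "size": {"small": "ACDGNPSTV", "large": "EFHIKLMQRWY"},
    "ring": {"aliphatic": "AGILPV", "aromatic": "FHWY", "neither": "CDEKMNQRST"},
    "charge": {"positive": "HKR", "negative": "DE", "neutral": "ACFGILMNPQSTVWY"},
}


@dataclass(frozen=True)
class SubstitutionCategory:
    """An ordered (wild-type label, mutant label) pair on one axis."""

    axis: str
    wt_label: str
    mut_label: str

    def __str__(self) -> str:
        return f"{self.wt_label}-{self.mut_label}"


@dataclass(frozen=True)
class PropertyScheme:
    """Per-axis partitions of the 20 canonical amino acids into labels.

    ``partitions[axis][label]`` is a frozenset of one-letter codes; every
    axis must cover all 20 amino acids with mutually exclusive labels.
    """

    name: str
    partitions: Mapping[str, Mapping[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for axis, labels in self.partitions.items():
            covered: set[str] = set()
            for label, members in labels.items():
                overlap = covered & set(members)
                if overlap:
                    raise InputError(
                        f"scheme {self.name!r}, axis {axis!r}: amino acids "
                        f"{sorted(overlap)} assigned to more than one label"
                    )
                bad = set(members) - set(AMINO_ACIDS)
                if bad:
                    raise InputError(
                        f"scheme {self.name!r}, axis {axis!r}, label {label!r}: "
                        f"unknown amino acids {sorted(bad)}"
                    )
                covered |= set(members)
            missing = set(AMINO_ACIDS) - covered
            if missing:
                raise InputError(
                    f"scheme {self.name!r}, axis {axis!r}: amino acids "
                    f"{sorted(missing)} not covered"
                )

    @property
    def axes(self) -> tuple[str, ...]:
        return tuple(self.partitions)

    def label_of(self, aa: str, axis: str) -> str:
        if aa not in AMINO_ACIDS:
            raise InputError(f"unknown amino acid {aa!r}")
        if axis not in self.partitions:
            raise InputError(f"unknown axis {axis!r}; have {list(self.partitions)}")
        for label, members in self.partitions[axis].items():
            if aa in members:
                return label
        raise AssertionError("unreachable: validated scheme covers all amino acids")


def _freeze(
    partitions: Mapping[str, Mapping[str, Iterable[str]]],
) -> dict[str, dict[str, frozenset[str]]]:
    return {
        axis: {label: frozenset(members) for label, members in labels.items()}
        for axis, labels in partitions.items()
    }


#: Default Taylor-style scheme.  Under it V->A is hydrophobic-hydrophobic
#: and small-small; R->A is polar-hydrophobic and large-small.
DEFAULT_SCHEME = PropertyScheme(name="default", partitions=_freeze(_DEFAULT_PARTITIONS))


def properties_of(
    aa: str, scheme: PropertyScheme = DEFAULT_SCHEME
) -> dict[str, str]:
    """One label per axis for a canonical amino acid."""
    return {axis: scheme.label_of(aa, axis) for axis in scheme.axes}


def categorize_substitution(
    sub: Substitution, scheme: PropertyScheme = DEFAULT_SCHEME, axis: str = "hydropathy"
) -> SubstitutionCategory:
    """The ordered category of ``sub`` on one axis."""
    return SubstitutionCategory(
        axis=axis,
        wt_label=scheme.label_of(sub.wt_aa, axis),
        mut_label=scheme.label_of(sub.mut_aa, axis),
    )


def stratify_by_category(
    dataset: "Dataset | Iterable[MutationRecord]",
    scheme: PropertyScheme = DEFAULT_SCHEME,
    axis: str = "hydropathy",
) -> dict[SubstitutionCategory, list]:
    """Partition a dataset's records by substitution category on one axis.

    Records whose residues are not canonical one-letter codes are
    excluded and logged; every remaining record lands in exactly one
    category, so the category subsets are a partition of the dataset.
    """
    records = getattr(dataset, "records", dataset)
    if axis not in scheme.axes:
        raise InputError(f"unknown axis {axis!r}; have {list(scheme.axes)}")
    out: dict[SubstitutionCategory, list] = {}
    n_excluded = 0
    for rec in records:
        try:
            sub = Substitution(rec.wt_aa, rec.mut_aa)
        except InputError as exc:
            n_excluded += 1
            logger.warning("excluding record %s from stratification: %s",
                           getattr(rec, "record_id", "?"), exc)
            continue
        cat = categorize_substitution(sub, scheme, axis)
        out.setdefault(cat, []).append(rec)
    if n_excluded:
        logger.warning("%d record(s) excluded from %s stratification", n_excluded, axis)
    return out


def load_scheme(path: str | Path) -> PropertyScheme:
    """Load a property scheme from YAML: ``axis -> label -> [amino acids]``."""
    path = Path(path)
    with path.open() as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise InputError(f"{path}: scheme file must map axes to label tables")
    name = raw.pop("name", path.stem)
    partitions: dict[str, dict[str, frozenset[str]]] = {}
    for axis, labels in raw.items():
        if not isinstance(labels, dict):
            raise InputError(f"{path}: axis {axis!r} must map labels to lists")
        partitions[axis] = {
            label: frozenset(
                aa.upper() for aa in (members if isinstance(members, list) else list(members))
            )
            for label, members in labels.items()
        }
    return PropertyScheme(name=str(name), partitions=partitions)
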