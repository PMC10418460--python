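"""Single-nucleotide-variant reachability of amino-acid substitutions.

A missense substitution is *SNV-reachable* if some sense codon of the
wild-type amino acid can be converted into a sense codon of the mutant
amino acid by changing exactly one nucleotide.  Stop codons are never
traversed: reachability is defined over sense->sense single-base changes
only, because nonsense intermediates do not produce missense variants.

The module builds the full 380-entry ordered-pair lookup (20 x 19
missense pairs) from any codon table, and reads/writes lookup files so
that an externally curated table can replace the computed one.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio.Data import CodonTable as _BioCodonTable

__all__ = [
    "AMINO_ACIDS",
    "NUCLEOTIDES",
    "CodonTable",
    "Substitution",
    "SNVLookup",
    "sense_codons",
    "single_nt_neighbors",
    "is_snv_reachable",
    "build_snv_lookup",
    "load_custom_lookup",
    "write_lookup",
]

#: The 20 canonical amino acids, one-letter codes, alphabetical.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: DNA alphabet (coding strand).
NUCLEOTIDES: str = "ACGT"

#: Marker used for stop codons in :class:`CodonTable` mappings.
STOP = "*"


class InputError(ValueError):
    """Raised for malformed user inputs (codons, residues, lookup files)."""


@dataclass(frozen=True)
class CodonTable:
    """A complete codon -> amino-acid (or stop) mapping.

    Parameters
    ----------
    mapping:
        All 64 DNA triplets mapped to a one-letter amino acid or ``"*"``
        for stop.
    name:
        Identifier of the table (e.g. ``"standard"``).
    """

    mapping: Mapping[str, str]
    name: str = "standard"

    def __post_init__(self) -> None:
        if len(self.mapping) != 64:
            raise InputError(
                f"codon table must have 64 entries, got {len(self.mapping)}"
            )
        for codon, aa in self.mapping.items():
            if len(codon) != 3 or any(b not in NUCLEOTIDES for b in codon):
                raise InputError(f"invalid codon {codon!r}")
            if aa != STOP and aa not in AMINO_ACIDS:
                raise InputError(f"invalid amino acid {aa!r} for codon {codon}")
        encoded = set(self.mapping.values()) - {STOP}
        missing = set(AMINO_ACIDS) - encoded
        if missing:
            raise InputError(f"amino acids without codons: {sorted(missing)}")

    @classmethod
    def standard(cls) -> "CodonTable":
        """The standard genetic code (NCBI table 1)."""
        bio = _BioCodonTable.unambiguous_dna_by_id[1]
        mapping = dict(bio.forward_table)
        for stop in bio.stop_codons:
            mapping[stop] = STOP
        return cls(mapping=mapping, name="standard")

    def with_reassignment(self, codon: str, aa: str) -> "CodonTable":
        """Return a copy with one codon reassigned (e.g. a stop to Trp)."""
        _validate_codon(codon)
        if aa != STOP and aa not in AMINO_ACIDS:
            raise InputError(f"invalid amino acid {aa!r}")
        mapping = dict(self.mapping)
        mapping[codon] = aa
        return CodonTable(mapping=mapping, name=f"{self.name}+{codon}->{aa}")

    def codons_for(self, aa: str) -> list[str]:
        """Sense codons encoding ``aa``, sorted."""
        if aa not in AMINO_ACIDS:
            raise InputError(f"unknown amino acid {aa!r}")
        return sorted(c for c, a in self.mapping.items() if a == aa)


@dataclass(frozen=True)
class Substitution:
    """An ordered missense amino-acid substitution (wild type -> mutant)."""

    wt_aa: str
    mut_aa: str

    def __post_init__(self) -> None:
        for aa in (self.wt_aa, self.mut_aa):
            if aa not in AMINO_ACIDS:
                raise InputError(f"unknown amino acid {aa!r}")
        if self.wt_aa == self.mut_aa:
            raise InputError(
                f"substitution must change the residue ({self.wt_aa}->{self.mut_aa})"
            )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.wt_aa}->{self.mut_aa}"


@dataclass
class SNVLookup:
    """Boolean table over all 380 ordered missense substitutions."""

    entries: dict[tuple[str, str], bool]
    provenance: str = "computed"  # "computed" | "user-supplied"

    def __post_init__(self) -> None:
        expected = {
            (a, b)
            for a, b in itertools.product(AMINO_ACIDS, repeat=2)
            if a != b
        }
        if set(self.entries) != expected:
            raise InputError(
                f"lookup must cover exactly the 380 ordered missense pairs, "
                f"got {len(self.entries)} entries"
            )

    def __getitem__(self, pair: tuple[str, str] | Substitution) -> bool:
        if isinstance(pair, Substitution):
            pair = (pair.wt_aa, pair.mut_aa)
        return self.entries[pair]

    def __len__(self) -> int:
        return len(self.entries)

    def is_snv(self, wt_aa: str, mut_aa: str) -> bool:
        return self[Substitution(wt_aa, mut_aa)]

    def true_pairs(self) -> list[tuple[str, str]]:
        """Sorted list of SNV-reachable ordered pairs."""
        return sorted(p for p, v in self.entries.items() if v)

    def is_symmetric(self) -> bool:
        return all(v == self.entries[(b, a)] for (a, b), v in self.entries.items())


def _validate_codon(codon: str) -> None:
    if not isinstance(codon, str) or len(codon) != 3 or any(
        b not in NUCLEOTIDES for b in codon.upper()
    ):
        raise InputError(f"malformed codon {codon!r}")


def sense_codons(table: CodonTable) -> list[str]:
    """All non-stop codons of ``table``, sorted."""
    return sorted(c for c, aa in table.mapping.items() if aa != STOP)


def single_nt_neighbors(codon: str) -> list[str]:
    """The 9 codons differing from ``codon`` at exactly one position."""
    _validate_codon(codon)
    codon = codon.upper()
    out = []
    for i, base in enumerate(codon):
        for b in NUCLEOTIDES:
            if b != base:
                out.append(codon[:i] + b + codon[i + 1 :])
    return out


def is_snv_reachable(sub: Substitution, table: CodonTable | None = None) -> bool:
    """True iff a sense codon of ``sub.wt_aa`` has a single-base sense
    neighbor encoding ``sub.mut_aa``."""
    table = table or CodonTable.standard()
    for codon in table.codons_for(sub.wt_aa):
        for nb in single_nt_neighbors(codon):
            if table.mapping[nb] == sub.mut_aa:
                return True
    return False


def build_snv_lookup(table: CodonTable | None = None) -> SNVLookup:
    """Compute the full 380-pair SNV reachability lookup from a codon table."""
    table = table or CodonTable.standard()
    entries = {
        (a, b): is_snv_reachable(Substitution(a, b), table)
        for a, b in itertools.product(AMINO_ACIDS, repeat=2)
        if a != b
    }
    return SNVLookup(entries=entries, provenance="computed")


def _tokenize_lookup_line(line: str) -> list[str]:
    line = line.split("#", 1)[0].strip()
    if not line:
        return []
    return line.replace(",", " ").split()


def load_custom_lookup(path: str | Path, symmetric: bool = False) -> SNVLookup:
    """Read a lookup from a delimited text file.

    The file lists one pair per line: ``WT_AA MUT_AA [IS_SNV]`` separated
    by whitespace or commas; an optional header line is skipped.  Lines
    without the boolean column form an *inclusion list* (listed pairs are
    SNV, everything else is not).  With ``symmetric=True`` each listed
    pair also sets its reverse.
    """
    path = Path(path)
    seen: dict[tuple[str, str], bool] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            tokens = _tokenize_lookup_line(raw)
            if not tokens:
                continue
            if lineno == 1 and tokens[0].upper() in {"WT_AA", "WT", "WILD_TYPE"}:
                continue
            if len(tokens) not in (2, 3):
                raise InputError(f"{path}:{lineno}: expected 2 or 3 columns")
            wt, mut = tokens[0].upper(), tokens[1].upper()
            for aa in (wt, mut):
                if aa not in AMINO_ACIDS:
                    raise InputError(f"{path}:{lineno}: unknown amino acid {aa!r}")
            if wt == mut:
                raise InputError(f"{path}:{lineno}: identity pair {wt}->{mut}")
            if len(tokens) == 3:
                if tokens[2] not in {"0", "1"}:
                    raise InputError(f"{path}:{lineno}: IS_SNV must be 0 or 1")
                value = tokens[2] == "1"
            else:
                value = True
            targets = [(wt, mut)] + ([(mut, wt)] if symmetric else [])
            for pair in targets:
                if pair in seen and seen[pair] != value:
                    raise InputError(
                        f"{path}:{lineno}: contradictory duplicate entry for "
                        f"{pair[0]}->{pair[1]}"
                    )
                seen[pair] = value
    entries = {
        (a, b): seen.get((a, b), False)
        for a, b in itertools.product(AMINO_ACIDS, repeat=2)
        if a != b
    }
    return SNVLookup(entries=entries, provenance="user-supplied")


def write_lookup(lookup: SNVLookup, path: str | Path) -> None:
    """Export a lookup as ``WT_AA MUT_AA IS_SNV``, deterministically sorted."""
    path = Path(path)
    lines = ["WT_AA MUT_AA IS_SNV"]
    for (wt, mut) in sorted(lookup.entries):
        lines.append(f"{wt} {mut} {int(lookup.entries[(wt, mut)])}")
    path.write_text("\n".join(lines) + "\n")
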