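"""Immunogenetics allele nomenclature and bookkeeping.

Allele names follow the ``LOCUS*F1[:F2[:F3[:F4]]][SUFFIX][#]`` convention,
e.g. ``MICA*008:28``, ``MICA*107N``, ``HLA-B*14:02:01G``. The trailing ``#``
marks an allele that stands in for a whole group of alleles the genotyping
workflow cannot distinguish ("ambiguity group"); it is reporting metadata and
never participates in equality. The reserved label ``NEW`` denotes an
aggregate of not-yet-named alleles and passes unchanged through field
reduction.

This module also carries the arithmetic over sequence-submission ledgers
(novel proteins / synonymous exon / intron variations / confirmations).
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "AlleleName",
    "AlleleParseError",
    "AmbiguityGroup",
    "GroupConfigError",
    "LedgerBatch",
    "SubmissionLedger",
    "default_groups",
    "first_field",
    "group_membership",
    "ledger_totals",
    "load_groups",
    "parse_allele",
    "read_ledger_csv",
    "resolve_group",
]

NEW_LABEL = "NEW"

_NAME_RE = re.compile(
    r"^(?P<locus>[A-Za-z][A-Za-z0-9-]*)"
    r"\*(?P<fields>\d+(?::\d+)*)"
    r"(?P<suffix>[A-Z])?"
    r"(?P<hash>#)?$"
)


class AlleleParseError(ValueError):
    """Raised when an allele name string cannot be parsed."""


class GroupConfigError(ValueError):
    """Raised for ill-formed ambiguity-group configurations."""


@dataclass(frozen=True, eq=False)
class AlleleName:
    """A parsed allele name.

    Equality and hashing ignore :attr:`hash_flag`: an allele and its
    hash-marked form compare equal, so group representatives can be looked
    up regardless of how they were spelled.
    """

    locus: str
    fields: tuple[str, ...] = ()
    suffix: str | None = None
    hash_flag: bool = False

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AlleleName):
            return NotImplemented
        return (self.locus, self.fields, self.suffix) == (
            other.locus,
            other.fields,
            other.suffix,
        )

    def __hash__(self) -> int:
        return hash((self.locus, self.fields, self.suffix))

    def __lt__(self, other: "AlleleName") -> bool:
        return self.sort_key < other.sort_key

    @property
    def sort_key(self) -> tuple:
        return (self.locus, self.fields, self.suffix or "")

    @property
    def is_new(self) -> bool:
        """True for the reserved NEW (unnamed-allele aggregate) label."""
        return self.locus == NEW_LABEL and not self.fields

    @property
    def is_null(self) -> bool:
        """True for expression-suffix N (null) alleles."""
        return self.suffix == "N"

    def render(self) -> str:
        if self.is_new:
            return NEW_LABEL + ("#" if self.hash_flag else "")
        out = f"{self.locus}*{':'.join(self.fields)}"
        if self.suffix:
            out += self.suffix
        if self.hash_flag:
            out += "#"
        return out

    def first_field(self) -> "AlleleName":
        """Reduce to protein (first-field) resolution; suffix and hash kept."""
        if len(self.fields) <= 1:
            return self
        return replace(self, fields=self.fields[:1])

    def strip_hash(self) -> "AlleleName":
        return replace(self, hash_flag=False) if self.hash_flag else self

    def with_hash(self) -> "AlleleName":
        return self if self.hash_flag else replace(self, hash_flag=True)

    def __str__(self) -> str:
        return self.render()

    def __repr__(self) -> str:
        return f"AlleleName({self.render()!r})"


def parse_allele(name: str) -> AlleleName:
    """Parse ``LOCUS*F1[:F2..][SUFFIX][#]`` into an :class:`AlleleName`.

    Raises :class:`AlleleParseError` naming the offending token.
    """
    token = name.strip()
    if token in (NEW_LABEL, NEW_LABEL + "#"):
        return AlleleName(locus=NEW_LABEL, hash_flag=token.endswith("#"))
    m = _NAME_RE.match(token)
    if m is None:
        raise AlleleParseError(_diagnose(token))
    return AlleleName(
        locus=m.group("locus"),
        fields=tuple(m.group("fields").split(":")),
        suffix=m.group("suffix"),
        hash_flag=m.group("hash") is not None,
    )


def _diagnose(token: str) -> str:
    if not token:
        return "empty allele name"
    if "*" not in token:
        return f"allele name {token!r} lacks the '*' locus separator"
    locus, _, rest = token.partition("*")
    if not re.fullmatch(r"[A-Za-z][A-Za-z0-9-]*", locus):
        return f"invalid locus token {locus!r} in {token!r}"
    bad = rest.rstrip("#")
    for field in bad.split(":"):
        if not re.fullmatch(r"\d+[A-Z]?", field):
            return f"invalid field token {field!r} in {token!r}"
    return f"malformed allele name {token!r}"


def first_field(a: AlleleName) -> AlleleName:
    """Functional alias for :meth:`AlleleName.first_field`."""
    return a.first_field()


@dataclass(frozen=True)
class AmbiguityGroup:
    """A set of alleles reported via one hash-marked representative."""

    representative: AlleleName
    members: tuple[AlleleName, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise GroupConfigError("ambiguity group has no members")
        if len(set(self.members)) != len(self.members):
            raise GroupConfigError(
                f"duplicate members in group {self.representative.render()}"
            )
        loci = {m.locus for m in self.members} | {self.representative.locus}
        if len(loci) != 1:
            raise GroupConfigError(f"mixed loci in group: {sorted(loci)}")
        if self.representative not in self.members:
            raise GroupConfigError(
                f"representative {self.representative.render()} is not a member"
            )
        if not self.representative.hash_flag:
            raise GroupConfigError(
                f"representative {self.representative.render()} must be hash-marked"
            )


def group_membership(
    groups: Iterable[AmbiguityGroup],
) -> dict[AlleleName, AlleleName]:
    """Member -> representative map; an allele in two groups is a config error."""
    mapping: dict[AlleleName, AlleleName] = {}
    for g in groups:
        for m in g.members:
            prior = mapping.get(m)
            if prior is not None and prior != g.representative:
                raise GroupConfigError(
                    f"allele {m.render()} appears in groups "
                    f"{prior.render()} and {g.representative.render()}"
                )
            mapping[m] = g.representative
    return mapping


def resolve_group(
    a: AlleleName, groups: Iterable[AmbiguityGroup] | Mapping[AlleleName, AlleleName]
) -> AlleleName:
    """Replace an allele by its group representative, if it belongs to one.

    Idempotent: a representative resolves to itself. Hash flags on the input
    are ignored during lookup (equality already ignores them).
    """
    mapping = (
        groups if isinstance(groups, Mapping) else group_membership(groups)
    )
    return mapping.get(a, a)


def load_groups(path: str | Path) -> tuple[AmbiguityGroup, ...]:
    """Load ambiguity groups from JSON ({rep: [members]}) or two-column TSV."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        raw = json.loads(path.read_text())
        items = raw.items() if isinstance(raw, dict) else (
            (entry["representative"], entry["members"]) for entry in raw
        )
    else:
        items = []
        with path.open() as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                rep, members = line.split("\t")
                items.append((rep, [m.strip() for m in members.split(",")]))
    groups = tuple(
        AmbiguityGroup(
            representative=parse_allele(rep).with_hash(),
            members=tuple(parse_allele(m) for m in members),
        )
        for rep, members in items
    )
    group_membership(groups)  # validates disjointness
    return groups


def default_groups() -> tuple[AmbiguityGroup, ...]:
    """The packaged ambiguity-group fixture used by the genotyping workflow."""
    ref = resources.files("micapop").joinpath("data/ambiguity_groups.json")
    raw = json.loads(ref.read_text())
    groups = tuple(
        AmbiguityGroup(
            representative=parse_allele(rep).with_hash(),
            members=tuple(parse_allele(m) for m in members),
        )
        for rep, members in raw.items()
    )
    group_membership(groups)
    return groups


# --------------------------------------------------------------------------
# Submission ledger


@dataclass(frozen=True)
class LedgerBatch:
    batch_id: str
    novel_proteins: int
    synonymous_exon: int
    intron_variations: int
    confirmations_extensions: int

    def __post_init__(self) -> None:
        for name in (
            "novel_proteins",
            "synonymous_exon",
            "intron_variations",
            "confirmations_extensions",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return (
            self.novel_proteins
            + self.synonymous_exon
            + self.intron_variations
            + self.confirmations_extensions
        )

    @property
    def novel(self) -> int:
        """Total excluding confirmations/sequence extensions."""
        return self.total - self.confirmations_extensions


@dataclass(frozen=True)
class SubmissionLedger:
    batches: tuple[LedgerBatch, ...]


def ledger_totals(ledger: SubmissionLedger) -> dict:
    """Per-batch totals plus grand and novel (non-confirmation) totals."""
    per_batch = {b.batch_id: b.total for b in ledger.batches}
    categories = {
        "novel_proteins": sum(b.novel_proteins for b in ledger.batches),
        "synonymous_exon": sum(b.synonymous_exon for b in ledger.batches),
        "intron_variations": sum(b.intron_variations for b in ledger.batches),
        "confirmations_extensions": sum(
            b.confirmations_extensions for b in ledger.batches
        ),
    }
    grand = sum(per_batch.values())
    return {
        "per_batch": per_batch,
        "category_totals": categories,
        "grand_total": grand,
        "novel_total": grand - categories["confirmations_extensions"],
    }


_LEDGER_COLUMNS = (
    "batch_id",
    "novel_proteins",
    "synonymous_exon",
    "intron_variations",
    "confirmations_extensions",
)


def read_ledger_csv(path: str | Path) -> SubmissionLedger:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in _LEDGER_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise ValueError(f"ledger CSV missing columns: {', '.join(missing)}")
        batches = tuple(
            LedgerBatch(
                batch_id=row["batch_id"],
                novel_proteins=int(row["novel_proteins"]),
                synonymous_exon=int(row["synonymous_exon"]),
                intron_variations=int(row["intron_variations"]),
                confirmations_extensions=int(row["confirmations_extensions"]),
            )
            for row in reader
        )
    return SubmissionLedger(batches=batches)


def write_ledger_csv(ledger: SubmissionLedger, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_LEDGER_COLUMNS)
        for b in ledger.batches:
            writer.writerow(
                [
                    b.batch_id,
                    b.novel_proteins,
                    b.synonymous_exon,
                    b.intron_variations,
                    b.confirmations_extensions,
                ]
            )
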