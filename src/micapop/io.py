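"""Shared readers/writers: cohort TSV, FASTA, frequency CSV, run reports.

Conventions: UTF-8, Unix newlines, '.' decimal separator. Internally all
coordinates are 0-based half-open; user-facing positions are 1-based
mature-protein numbering.
"""

from __future__ import annotations

import csv
import json
import platform
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

from Bio import SeqIO

from .alleles import AlleleName, AlleleParseError, parse_allele
from .cohort import GenotypeCall
from .frequencies import FrequencyTable

__all__ = [
    "CohortFormatError",
    "FastaRecord",
    "read_cohort_tsv",
    "read_fasta",
    "read_frequency_csv",
    "write_cohort_tsv",
    "write_frequency_csv",
    "write_run_report",
]

_COHORT_COLUMNS = ("sample_id", "population", "candidates", "hla_b")


class CohortFormatError(ValueError):
    """Raised for malformed cohort tables; collects row-level messages."""


def _render_ms(ms: Sequence[AlleleName]) -> str:
    return "+".join(a.render() for a in ms)


def write_cohort_tsv(calls: Sequence[GenotypeCall], path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(_COHORT_COLUMNS) + "\n")
        for c in calls:
            cands = ";".join(_render_ms(ms) for ms in c.candidates)
            hla = _render_ms(c.hla_b) if c.hla_b else ""
            fh.write(f"{c.sample_id}\t{c.population}\t{cands}\t{hla}\n")


def read_cohort_tsv(path: str | Path) -> list[GenotypeCall]:
    """Parse a cohort table; malformed rows are reported with line numbers."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = [c for c in _COHORT_COLUMNS if c not in header]
        if missing:
            raise CohortFormatError(
                f"{path.name}: missing columns: {', '.join(missing)}"
            )
        idx = {c: header.index(c) for c in _COHORT_COLUMNS}
        calls = []
        errors = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            try:
                cand_field = parts[idx["candidates"]]
                if not cand_field:
                    raise ValueError("empty candidates field")
                candidates = tuple(
                    tuple(
                        sorted(
                            (parse_allele(tok) for tok in ms.split("+")),
                            key=lambda a: a.render(),
                        )
                    )
                    for ms in cand_field.split(";")
                )
                hla_field = parts[idx["hla_b"]] if idx["hla_b"] < len(parts) else ""
                hla_b = (
                    tuple(
                        sorted(
                            (parse_allele(tok) for tok in hla_field.split("+")),
                            key=lambda a: a.render(),
                        )
                    )
                    if hla_field
                    else None
                )
                calls.append(
                    GenotypeCall(
                        sample_id=parts[idx["sample_id"]],
                        population=parts[idx["population"]],
                        candidates=candidates,
                        hla_b=hla_b,
                    )
                )
            except (ValueError, IndexError, AlleleParseError) as exc:
                errors.append(f"line {lineno}: {exc}")
        if errors:
            raise CohortFormatError(
                f"{path.name}: {len(errors)} malformed row(s):\n" + "\n".join(errors)
            )
    return calls


@dataclass(frozen=True)
class FastaRecord:
    name: AlleleName
    header: str
    seq: str


def read_fasta(path: str | Path) -> list[FastaRecord]:
    """FASTA records with headers parsed as allele names; sequences are
    uppercased. Duplicate headers and empty files are errors."""
    path = Path(path)
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.id
        if header in seen:
            raise ValueError(f"{path.name}: duplicate header {header!r}")
        seen.add(header)
        records.append(
            FastaRecord(
                name=parse_allele(header), header=header, seq=str(rec.seq).upper()
            )
        )
    if not records:
        raise ValueError(f"{path.name}: no FASTA records")
    return records


def write_frequency_csv(table: FrequencyTable, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# population={table.population}\n")
        fh.write(f"# n_samples={table.n_samples}\n")
        fh.write(f"# denominator={table.denominator!r}\n")
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["allele", "count", "frequency"])
        freqs = table.freqs
        for a in sorted(table.counts, key=lambda x: (-table.counts[x], x.render())):
            writer.writerow([a.render(), repr(table.counts[a]), repr(freqs[a])])


def read_frequency_csv(path: str | Path) -> FrequencyTable:
    path = Path(path)
    meta = {}
    rows = []
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, value = line.lstrip("# ").partition("=")
                meta[key] = value
            elif line:
                rows.append(line)
    reader = csv.reader(rows)
    header = next(reader)
    if header[:3] != ["allele", "count", "frequency"]:
        raise ValueError(f"{path.name}: unexpected header {header}")
    counts = {parse_allele(r[0]): float(r[1]) for r in reader}
    denominator = float(meta.get("denominator", sum(counts.values()) or 1.0))
    return FrequencyTable(
        population=meta.get("population", path.stem),
        n_samples=int(meta.get("n_samples", 0)),
        counts=counts,
        denominator=denominator,
    )


def write_run_report(path: str | Path, payload: dict) -> None:
    """Machine-readable run report accompanying every CLI output."""
    report = {
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "python": platform.python_version(),
        **payload,
    }
    Path(path).write_text(json.dumps(report, indent=2, default=str) + "\n")
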