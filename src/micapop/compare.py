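"""Cross-population frequency comparison.

Produces per-allele frequency-ratio rows against a reference population and
flags alleles whose frequency differs by more than twofold (``over``) or by
less than half (``under``); both bounds are strict, so a ratio of exactly
2.0 or 0.5 is unflagged. Display ratios are rounded half-up; flags are
always computed on the unrounded value.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, NamedTuple

from .alleles import AlleleName
from .frequencies import FrequencyTable

__all__ = [
    "RatioRow",
    "RatioTable",
    "PopulationSpecificReport",
    "population_specific_alleles",
    "ratio_table",
    "round_half_up",
]

UNDEFINED_RATIO = "—"  # em dash: reference frequency is zero


def round_half_up(x: float, digits: int = 2) -> float:
    """Decimal round-half-up (0.005 -> 0.01), unlike banker's rounding."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class RatioRow:
    allele: AlleleName
    ref_freq: float
    pop_freq: float
    ratio: float | None  # None when ref_freq == 0
    ratio_display: str
    flag: str  # "over" | "under" | "none"


@dataclass
class RatioTable:
    reference_population: str
    population: str
    rows: list[RatioRow]

    def row(self, allele: AlleleName) -> RatioRow:
        for r in self.rows:
            if r.allele == allele:
                return r
        raise KeyError(allele.render())


def _freqs_of(t: FrequencyTable | Mapping[AlleleName, float]) -> dict[AlleleName, float]:
    if isinstance(t, FrequencyTable):
        return t.freqs
    return dict(t)


def ratio_table(
    ref: FrequencyTable,
    pop: FrequencyTable,
    round_digits: int = 2,
) -> RatioTable:
    """Per-allele pop/ref frequency ratios over the union of both tables.

    Alleles absent from a table count as frequency 0. Rows whose reference
    frequency is zero get ``ratio=None`` and an explicit marker instead of a
    number.
    """
    ref_freqs = _freqs_of(ref)
    pop_freqs = _freqs_of(pop)
    if not ref_freqs:
        raise ValueError("reference frequency table is empty")

    alleles = sorted(
        set(ref_freqs) | set(pop_freqs),
        key=lambda a: (-ref_freqs.get(a, 0.0), a.render()),
    )
    rows = []
    for a in alleles:
        rf = ref_freqs.get(a, 0.0)
        pf = pop_freqs.get(a, 0.0)
        if rf > 0.0:
            ratio = pf / rf
            display = f"{round_half_up(ratio, round_digits):.{round_digits}f}"
            flag = "over" if ratio > 2.0 else "under" if ratio < 0.5 else "none"
        else:
            ratio, display, flag = None, UNDEFINED_RATIO, "none"
        rows.append(
            RatioRow(
                allele=a,
                ref_freq=rf,
                pop_freq=pf,
                ratio=ratio,
                ratio_display=display,
                flag=flag,
            )
        )
    ref_label = ref.population if isinstance(ref, FrequencyTable) else "reference"
    pop_label = pop.population if isinstance(pop, FrequencyTable) else "population"
    return RatioTable(reference_population=ref_label, population=pop_label, rows=rows)


class PopulationSpecificReport(NamedTuple):
    presence: dict[AlleleName, frozenset[str]]
    specific: dict[AlleleName, tuple[str, float]]


def population_specific_alleles(
    counts: Mapping[str, Mapping[AlleleName, float]],
) -> PopulationSpecificReport:
    """Which populations carry each allele; alleles seen in exactly one.

    ``counts`` maps population -> allele -> raw (possibly fractional) count.
    Alleles with zero count everywhere are excluded entirely.
    """
    presence: dict[AlleleName, set[str]] = {}
    for pop, table in counts.items():
        for a, c in table.items():
            if c > 0:
                presence.setdefault(a, set()).add(pop)
    frozen = {a: frozenset(pops) for a, pops in presence.items()}
    specific = {}
    for a, pops in frozen.items():
        if len(pops) == 1:
            (pop,) = pops
            specific[a] = (pop, counts[pop][a])
    return PopulationSpecificReport(presence=frozen, specific=specific)
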