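"""MICA <-> HLA-B haplotype association by co-occurrence.

A MICA allele is declared linked to an HLA-B allele when it was carried by
at least ``min_count`` unambiguously typed samples and every one of those
samples also carried the HLA-B allele (co-occurrence fraction exactly 1,
with a unique maximal partner). Samples with ambiguous MICA candidate sets
are excluded from carrier counts.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Sequence

from .alleles import AlleleName
from .cohort import GenotypeCall

__all__ = ["LinkageResult", "infer_linkage"]

DEFAULT_MIN_COUNT = 10


@dataclass(frozen=True)
class LinkageResult:
    mica_allele: AlleleName
    partners: tuple[AlleleName, ...]  # maximal co-occurring HLA-B allele(s)
    n_carriers: int
    n_co_occurring: int
    linked: bool

    @property
    def fraction(self) -> float:
        return self.n_co_occurring / self.n_carriers

    @property
    def partner(self) -> AlleleName | None:
        return self.partners[0] if len(self.partners) == 1 else None


def infer_linkage(
    calls: Sequence[GenotypeCall],
    min_count: int = DEFAULT_MIN_COUNT,
    alleles: Sequence[AlleleName] | None = None,
) -> list[LinkageResult]:
    """Co-occurrence linkage for every observed MICA allele (or ``alleles``).

    "Positive for" an HLA-B allele means carrying at least one copy;
    homozygous HLA-B genotypes count once.
    """
    if not any(c.hla_b is not None for c in calls):
        raise ValueError("no HLA-B data in the input calls")

    carriers: Counter = Counter()
    partner_counts: dict[AlleleName, Counter] = defaultdict(Counter)
    for call in calls:
        if call.is_ambiguous or call.hla_b is None:
            continue
        mica_alleles = set(call.candidates[0])
        hla_alleles = set(call.hla_b)
        for a in mica_alleles:
            carriers[a] += 1
            for b in hla_alleles:
                partner_counts[a][b] += 1

    wanted = (
        sorted(carriers, key=lambda a: a.render())
        if alleles is None
        else list(alleles)
    )
    results = []
    for a in wanted:
        n = carriers.get(a, 0)
        if n == 0:
            continue
        counts = partner_counts[a]
        best = max(counts.values())
        partners = tuple(
            sorted((b for b, c in counts.items() if c == best), key=lambda b: b.render())
        )
        linked = n >= min_count and best == n and len(partners) == 1
        results.append(
            LinkageResult(
                mica_allele=a,
                partners=partners,
                n_carriers=n,
                n_co_occurring=best,
                linked=linked,
            )
        )
    return results
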