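"""Ambiguity-aware allele-frequency estimation.

The estimator works in two passes. Pass 1 counts alleles of unambiguous
calls and derives base frequencies from them. Pass 2 distributes each
ambiguous call over its candidate allele multisets in proportion to the
Hardy-Weinberg probability of each candidate under the base frequencies
(renormalized within the candidate set), adding fractional counts.
Frequencies are reported at protein (first-field) resolution after
ambiguity-group resolution.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .alleles import AlleleName, AmbiguityGroup, group_membership
from .cohort import CohortConfig, GenotypeCall, simulate_cohort

__all__ = [
    "FrequencyTable",
    "cumulative_new_frequency",
    "deletion_bias_experiment",
    "estimate_frequencies",
]

DEFAULT_MIN_SAMPLES = 1000


@dataclass
class FrequencyTable:
    """Per-population allele counts and frequencies.

    ``counts`` may be fractional (ambiguous calls contribute fractional
    weight); ``denominator`` is the total reported allele count, which equals
    ``2 * n_samples`` in the absence of duplication carriers. ``warnings``
    counts ambiguous calls that had zero total base probability and were
    allocated uniformly.
    """

    population: str
    n_samples: int
    counts: dict[AlleleName, float]
    denominator: float
    warnings: int = 0

    @property
    def freqs(self) -> dict[AlleleName, float]:
        if self.denominator <= 0:
            raise ValueError("empty frequency table")
        return {a: c / self.denominator for a, c in self.counts.items()}

    @classmethod
    def from_freqs(
        cls,
        population: str,
        freqs: Mapping[AlleleName, float],
        n_samples: int = 0,
    ) -> "FrequencyTable":
        """Wrap externally given frequencies (e.g. a published table).

        The values are taken verbatim (denominator 1), so partial tables that
        do not sum to 1 stay untouched.
        """
        return cls(
            population=population,
            n_samples=n_samples,
            counts=dict(freqs),
            denominator=1.0,
        )


def _normalizer(groups: Iterable[AmbiguityGroup] | None):
    membership = group_membership(groups) if groups else {}

    def norm(a: AlleleName) -> AlleleName:
        return membership.get(a.first_field(), a.first_field())

    return norm


def _hwe_weight(ms: tuple[AlleleName, ...], g: Mapping[AlleleName, float]) -> float:
    """Hardy-Weinberg probability of an allele multiset: multiplicity * prod g."""
    mult = Counter(ms)
    weight = math.factorial(len(ms))
    for a, c in mult.items():
        weight /= math.factorial(c)
    for a, c in mult.items():
        weight *= g.get(a, 0.0) ** c
    return weight


def estimate_frequencies(
    calls: Sequence[GenotypeCall],
    population: str,
    min_samples: int = DEFAULT_MIN_SAMPLES,
    smoothing: float = 0.0,
    groups: Iterable[AmbiguityGroup] | None = None,
    em_iterations: int = 0,
) -> FrequencyTable:
    """Estimate first-field allele frequencies for one population.

    Parameters
    ----------
    calls
        Genotype calls (any population; filtered internally).
    population
        Population label to estimate for.
    min_samples
        Minimum population size; smaller populations raise. Pass 1 to lift
        the restriction for small synthetic cohorts.
    smoothing
        Add-epsilon pseudo-count applied to the base frequencies over the
        union of all alleles seen in any candidate set. Default 0.
    groups
        Optional ambiguity groups; candidate alleles are first reduced to
        first field and then replaced by their group representative.
    em_iterations
        Repeat the allocation pass with base frequencies updated from the
        previous result. Default 0 (single pass over unambiguous-call
        frequencies).
    """
    pop_calls = sorted(
        (c for c in calls if c.population == population),
        key=lambda c: c.sample_id,
    )
    if not pop_calls:
        raise ValueError(f"no calls for population {population!r}")
    if len(pop_calls) < min_samples:
        raise ValueError(
            f"population {population!r} has {len(pop_calls)} samples, "
            f"below min_samples={min_samples}"
        )

    norm = _normalizer(groups)
    universe: set[AlleleName] = set()
    base_counts: Counter = Counter()
    ambiguous: list[tuple[tuple[AlleleName, ...], ...]] = []

    for call in pop_calls:
        cands = sorted(
            {
                tuple(sorted((norm(a) for a in ms), key=lambda x: x.render()))
                for ms in call.candidates
            }
        )
        for ms in cands:
            universe.update(ms)
        if len(cands) == 1:
            base_counts.update(cands[0])
        else:
            ambiguous.append(tuple(cands))

    order = sorted(universe, key=lambda a: a.render())

    def base_freqs(counts: Mapping[AlleleName, float]) -> dict[AlleleName, float]:
        raw = {a: counts.get(a, 0.0) + smoothing for a in order}
        total = sum(raw.values())
        if total <= 0:
            return {a: 0.0 for a in order}
        return {a: v / total for a, v in raw.items()}

    g = base_freqs(base_counts)
    warnings = 0
    final: dict[AlleleName, float] = {}
    for iteration in range(em_iterations + 1):
        warnings = 0
        final = {a: float(base_counts.get(a, 0)) for a in order}
        for cands in ambiguous:
            weights = [_hwe_weight(ms, g) for ms in cands]
            total = sum(weights)
            if total <= 0.0:
                weights = [1.0 / len(cands)] * len(cands)
                warnings += 1
            else:
                weights = [w / total for w in weights]
            for ms, w in zip(cands, weights):
                for a, mult in Counter(ms).items():
                    final[a] += w * mult
        if iteration < em_iterations:
            g = base_freqs(final)

    denominator = sum(final.values())
    return FrequencyTable(
        population=population,
        n_samples=len(pop_calls),
        counts=final,
        denominator=denominator,
        warnings=warnings,
    )


def cumulative_new_frequency(table: FrequencyTable) -> float:
    """Summed frequency of NEW-labeled (unnamed) alleles."""
    return sum(f for a, f in table.freqs.items() if a.is_new)


def deletion_bias_experiment(
    cfg: CohortConfig,
    deletion_rates: Sequence[float],
    n_replicates: int = 3,
    base_seed: int | None = None,
) -> list[dict]:
    """Frequency bias induced by homozygous masking of hemizygous deletions.

    For each rate, the cohort is simulated and estimated ``n_replicates``
    times with distinct fixed seeds; reported is the mean over replicates of
    the maximum absolute deviation between estimated and configured
    (group-resolved, first-field) frequencies.
    """
    seed0 = cfg.seed if base_seed is None else base_seed
    norm = _normalizer(cfg.hash_groups)
    rows = []
    for rate in deletion_rates:
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"deletion rate out of [0,1]: {rate}")
        maxima = []
        for rep in range(n_replicates):
            sim_cfg = CohortConfig(
                populations=cfg.populations,
                ambiguity_rate=cfg.ambiguity_rate,
                hash_groups=cfg.hash_groups,
                deletion_rate=rate,
                duplication_rate=cfg.duplication_rate,
                linkage_map=cfg.linkage_map,
                hla_b_background_freqs=cfg.hla_b_background_freqs,
                seed=seed0 + 7919 * rep,
            )
            calls = simulate_cohort(sim_cfg)
            for pop in cfg.populations:
                expected: dict[AlleleName, float] = {}
                for a, f in pop.freqs.items():
                    key = norm(a)
                    expected[key] = expected.get(key, 0.0) + f
                est = estimate_frequencies(
                    calls, pop.label, min_samples=1, groups=cfg.hash_groups
                ).freqs
                alleles = set(expected) | set(est)
                maxima.append(
                    max(
                        abs(est.get(a, 0.0) - expected.get(a, 0.0))
                        for a in alleles
                    )
                )
        rows.append(
            {
                "deletion_rate": rate,
                "mean_max_abs_bias": sum(maxima) / len(maxima),
                "n_replicates": n_replicates,
            }
        )
    return rows
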