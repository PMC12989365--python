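"""Synthetic diploid genotyping cohorts.

Samples are drawn under Hardy-Weinberg equilibrium from per-population
allele-frequency vectors and then pushed through the reporting artifacts of
a high-throughput genotyping workflow:

* hash-group masking (indistinguishable alleles reported via a representative),
* copy-number artifacts (a duplication adds a third reported allele; a
  deletion is reported as a homozygous call for the surviving allele),
* phasing ambiguity (the true allele pair is wrapped into a candidate set
  together with decoy pairs).

Each generated call keeps its pre-masking haplotypes (`truth`) so parameter
recovery can be checked against realized rather than nominal frequencies.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .alleles import (
    AlleleName,
    AmbiguityGroup,
    group_membership,
    parse_allele,
)

__all__ = [
    "CohortConfig",
    "GenotypeCall",
    "PopulationConfig",
    "simulate_cohort",
    "true_frequencies",
]

_FREQ_TOL = 1e-9


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's reported genotype.

    ``candidates`` is the set of candidate allele multisets (each a sorted
    tuple); a single candidate means the call is unambiguous. ``truth`` holds
    the pre-masking haplotypes when the call came from the simulator.
    """

    sample_id: str
    population: str
    candidates: tuple[tuple[AlleleName, ...], ...]
    hla_b: tuple[AlleleName, AlleleName] | None = None
    truth: tuple[AlleleName, ...] | None = None

    def __post_init__(self) -> None:
        if not self.candidates:
            raise ValueError(f"{self.sample_id}: empty candidate set")
        sizes = {len(ms) for ms in self.candidates}
        if len(sizes) != 1:
            raise ValueError(
                f"{self.sample_id}: candidate multisets of unequal cardinality {sizes}"
            )
        if any(len(ms) == 0 for ms in self.candidates):
            raise ValueError(f"{self.sample_id}: empty candidate multiset")

    @property
    def is_ambiguous(self) -> bool:
        return len(self.candidates) > 1

    @property
    def ploidy(self) -> int:
        return len(self.candidates[0])


def _validate_freqs(freqs: Mapping[AlleleName, float], what: str) -> None:
    if not freqs:
        raise ValueError(f"{what}: empty frequency map")
    total = 0.0
    for a, f in freqs.items():
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"{what}: frequency of {a} out of [0,1]: {f}")
        total += f
    if abs(total - 1.0) > _FREQ_TOL:
        raise ValueError(f"{what}: frequencies sum to {total!r}, expected 1")


@dataclass
class PopulationConfig:
    label: str
    n_samples: int
    freqs: dict[AlleleName, float]

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValueError(f"{self.label}: n_samples must be positive")
        _validate_freqs(self.freqs, f"population {self.label}")


@dataclass
class CohortConfig:
    populations: list[PopulationConfig]
    ambiguity_rate: float = 0.0
    hash_groups: tuple[AmbiguityGroup, ...] = ()
    deletion_rate: float = 0.0
    duplication_rate: float = 0.0
    linkage_map: dict[AlleleName, AlleleName] | None = None
    hla_b_background_freqs: dict[AlleleName, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ambiguity_rate", "deletion_rate", "duplication_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} out of [0,1]: {v}")
        if self.deletion_rate + self.duplication_rate > 1.0 + _FREQ_TOL:
            raise ValueError("deletion_rate + duplication_rate must be <= 1")
        if self.hla_b_background_freqs is not None:
            _validate_freqs(self.hla_b_background_freqs, "HLA-B background")
        if self.linkage_map is not None and self.hla_b_background_freqs is None:
            mapped = set(self.linkage_map)
            for pop in self.populations:
                unmapped = set(pop.freqs) - mapped
                if unmapped:
                    raise ValueError(
                        "linkage_map leaves alleles without an HLA-B partner and "
                        "no hla_b_background_freqs is given: "
                        + ", ".join(a.render() for a in sorted(unmapped))
                    )

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortConfig":
        raw = json.loads(Path(path).read_text())
        pops = [
            PopulationConfig(
                label=p["label"],
                n_samples=int(p["n_samples"]),
                freqs={parse_allele(k): float(v) for k, v in p["freqs"].items()},
            )
            for p in raw["populations"]
        ]
        groups = tuple(
            AmbiguityGroup(
                representative=parse_allele(rep).with_hash(),
                members=tuple(parse_allele(m) for m in members),
            )
            for rep, members in raw.get("hash_groups", {}).items()
        )
        linkage = raw.get("linkage_map")
        background = raw.get("hla_b_background_freqs")
        return cls(
            populations=pops,
            ambiguity_rate=float(raw.get("ambiguity_rate", 0.0)),
            hash_groups=groups,
            deletion_rate=float(raw.get("deletion_rate", 0.0)),
            duplication_rate=float(raw.get("duplication_rate", 0.0)),
            linkage_map=(
                {parse_allele(k): parse_allele(v) for k, v in linkage.items()}
                if linkage
                else None
            ),
            hla_b_background_freqs=(
                {parse_allele(k): float(v) for k, v in background.items()}
                if background
                else None
            ),
            seed=int(raw.get("seed", 0)),
        )

    def to_json(self, path: str | Path) -> None:
        raw = {
            "populations": [
                {
                    "label": p.label,
                    "n_samples": p.n_samples,
                    "freqs": {a.render(): f for a, f in p.freqs.items()},
                }
                for p in self.populations
            ],
            "ambiguity_rate": self.ambiguity_rate,
            "hash_groups": {
                g.representative.strip_hash().render(): [
                    m.render() for m in g.members
                ]
                for g in self.hash_groups
            },
            "deletion_rate": self.deletion_rate,
            "duplication_rate": self.duplication_rate,
            "linkage_map": (
                {k.render(): v.render() for k, v in self.linkage_map.items()}
                if self.linkage_map
                else None
            ),
            "hla_b_background_freqs": (
                {k.render(): v for k, v in self.hla_b_background_freqs.items()}
                if self.hla_b_background_freqs
                else None
            ),
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(raw, indent=2) + "\n")


def _sorted_ms(alleles) -> tuple[AlleleName, ...]:
    return tuple(sorted(alleles, key=lambda a: a.render()))


def simulate_cohort(cfg: CohortConfig, seed: int | None = None) -> list[GenotypeCall]:
    """Generate the cohort described by ``cfg``; deterministic per seed.

    The seed defaults to ``cfg.seed``; populations are processed in config
    order and samples are numbered within population.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    membership = group_membership(cfg.hash_groups)

    bg_alleles: list[AlleleName] = []
    bg_probs: np.ndarray | None = None
    if cfg.hla_b_background_freqs:
        bg_alleles = sorted(cfg.hla_b_background_freqs, key=lambda a: a.render())
        bg_probs = np.array([cfg.hla_b_background_freqs[a] for a in bg_alleles])
        bg_probs = bg_probs / bg_probs.sum()
    want_hla = cfg.linkage_map is not None or bg_probs is not None

    calls: list[GenotypeCall] = []
    for pop in cfg.populations:
        alleles = sorted(pop.freqs, key=lambda a: a.render())
        probs = np.array([pop.freqs[a] for a in alleles], dtype=float)
        probs = probs / probs.sum()
        masked = [membership.get(a, a) for a in alleles]
        n = pop.n_samples

        hap_idx = rng.choice(len(alleles), size=(n, 2), p=probs)
        u_event = rng.random(n)
        u_amb = rng.random(n)

        for i in range(n):
            i1, i2 = int(hap_idx[i, 0]), int(hap_idx[i, 1])
            truth = [alleles[i1], alleles[i2]]
            duplicated = u_event[i] < cfg.duplication_rate
            deleted = (
                not duplicated
                and u_event[i] < cfg.duplication_rate + cfg.deletion_rate
            )

            if duplicated:
                extra = int(rng.choice(len(alleles), p=probs))
                truth.append(alleles[extra])
                reported = _sorted_ms(masked[j] for j in (i1, i2, extra))
            elif deleted:
                # caller reports the surviving copy twice (homozygous masking)
                survivor = masked[i2] if rng.integers(2) == 0 else masked[i1]
                reported = (survivor, survivor)
            else:
                reported = _sorted_ms((masked[i1], masked[i2]))

            candidates: tuple[tuple[AlleleName, ...], ...] = (reported,)
            if (
                not duplicated
                and u_amb[i] < cfg.ambiguity_rate
                and len(set(masked)) > 1
            ):
                # Decoys swap one allele of the true pair for a uniformly
                # drawn allele. Uniform (not frequency-weighted) draws keep
                # the candidate-set proposal symmetric between common and
                # rare alleles, so that downstream Hardy-Weinberg weighting
                # of candidates is an unbiased resolution of the ambiguity;
                # frequency-weighted decoys would tilt candidate sets toward
                # common alleles and double-count that tilt at estimation.
                k = 2 + int(rng.integers(2))  # candidate-set size in {2, 3}
                cand = {reported}
                attempts = 0
                while len(cand) < k and attempts < 20 * k:
                    attempts += 1
                    pos = int(rng.integers(2))
                    z = masked[int(rng.integers(len(alleles)))]
                    decoy = list(reported)
                    decoy[pos] = z
                    cand.add(_sorted_ms(decoy))
                candidates = tuple(sorted(cand))

            hla_b = None
            if want_hla:
                partners = []
                for hap in truth[:2]:
                    partner = (
                        cfg.linkage_map.get(hap) if cfg.linkage_map else None
                    )
                    if partner is None:
                        if bg_probs is None:
                            raise ValueError(
                                f"no HLA-B partner for {hap.render()} and no "
                                "background frequencies configured"
                            )
                        partner = bg_alleles[int(rng.choice(len(bg_alleles), p=bg_probs))]
                    partners.append(partner)
                hla_b = _sorted_ms(partners)

            calls.append(
                GenotypeCall(
                    sample_id=f"{pop.label}_{i:06d}",
                    population=pop.label,
                    candidates=candidates,
                    hla_b=hla_b,
                    truth=tuple(truth),
                )
            )
    return calls


def true_frequencies(
    cfg: CohortConfig, realized: Sequence[GenotypeCall]
) -> dict[str, dict[AlleleName, float]]:
    """Realized pre-masking haplotype frequencies per population.

    Requires the calls to carry provenance (``truth``), i.e. to come straight
    from :func:`simulate_cohort` rather than from a round-tripped table.
    """
    counters: dict[str, Counter] = {p.label: Counter() for p in cfg.populations}
    for call in realized:
        if call.truth is None:
            raise ValueError(
                f"{call.sample_id}: haplotype provenance absent; "
                "true frequencies are only defined for simulator output"
            )
        counters.setdefault(call.population, Counter()).update(call.truth)
    out: dict[str, dict[AlleleName, float]] = {}
    for pop, counter in counters.items():
        total = sum(counter.values())
        if total == 0:
            continue
        out[pop] = {
            a: counter[a] / total
            for a in sorted(counter, key=lambda x: x.render())
        }
    return out
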