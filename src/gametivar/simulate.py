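"""Synthetic data plus two independent oracles for the gametic machinery.

The generator draws phased haplotypes allele-wise at stated allele
frequencies (a linkage-equilibrium baseline; an optional copy-with-mutation
mode adds block LD for stress tests), Normal(0, sd) allele-substitution
effects for K traits, and either sorted-uniform cM maps or valid
adjacent-rate vectors.

Two oracles validate the analytic quadratic form independently of it:

* ``enumerate_gametes`` — the exact gamete distribution under the Markov
  (no-interference) crossover model: the starting haplotype is
  equiprobable and each marker interval recombines independently with its
  adjacent rate. Feasible up to ~20 markers (2^N source paths).
* ``sample_gametes`` — a vectorized Monte-Carlo meiosis simulator for
  instances too large to enumerate.

Gamete breeding values are placed on the centered scale sum((allele-1/2) *
alpha) so the exact mean equals GEBV/2 (genotype code -1/0/+1 is the sum of
two +-1/2 gamete codes); the variance is unaffected by the shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import EffectTable, GeneticMap, HaplotypePair

__all__ = [
    "ChromSpec",
    "SimSpec",
    "simulate_dataset",
    "enumerate_gametes",
    "oracle_moments",
    "oracle_variance",
    "sample_gametes",
]

ENUMERATION_CAP = 20


@dataclass(frozen=True)
class ChromSpec:
    """One simulated chromosome: marker count and map extent.

    ``length_cM`` yields a cM-mode map with sorted uniform positions;
    ``rate_range`` yields a rate-mode map with uniform adjacent rates.
    Exactly one of the two must be set.
    """

    name: str
    n_markers: int
    length_cM: float | None = None
    rate_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if (self.length_cM is None) == (self.rate_range is None):
            raise ValueError("set exactly one of length_cM / rate_range")
        if self.n_markers < 0:
            raise ValueError("n_markers must be non-negative")


@dataclass(frozen=True)
class SimSpec:
    n_individuals: int = 10
    chromosomes: tuple[ChromSpec, ...] = (
        ChromSpec("1", n_markers=50, length_cM=100.0),
    )
    maf_range: tuple[float, float] = (0.1, 0.5)
    n_traits: int = 1
    effect_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.n_traits < 1 or self.n_individuals < 0:
            raise ValueError("need >= 1 trait and >= 0 individuals")
        if self.effect_sd <= 0:
            raise ValueError("effect_sd must be positive")


def simulate_dataset(
    spec: SimSpec,
) -> tuple[dict[str, dict[str, HaplotypePair]], dict[str, GeneticMap], EffectTable]:
    """Draw a reproducible dataset: identical spec + seed -> identical data.

    Returns (individual_id -> chromosome -> HaplotypePair, chromosome ->
    GeneticMap, genome-wide EffectTable in map order).
    """
    rng = np.random.default_rng(spec.seed)
    maps: dict[str, GeneticMap] = {}
    all_ids: list[str] = []
    freqs: dict[str, np.ndarray] = {}
    for cs in spec.chromosomes:
        ids = [f"{cs.name}_m{i + 1}" for i in range(cs.n_markers)]
        all_ids.extend(ids)
        if cs.length_cM is not None:
            pos = np.sort(rng.uniform(0.0, cs.length_cM, size=cs.n_markers))
            maps[cs.name] = GeneticMap(cs.name, ids, positions_cM=pos)
        else:
            lo, hi = cs.rate_range
            rates = rng.uniform(lo, hi, size=max(cs.n_markers - 1, 0))
            maps[cs.name] = GeneticMap(cs.name, ids, adjacent_rates=rates)
        freqs[cs.name] = rng.uniform(*spec.maf_range, size=cs.n_markers)

    individuals: dict[str, dict[str, HaplotypePair]] = {}
    for i in range(spec.n_individuals):
        iid = f"ind{i + 1:04d}"
        individuals[iid] = {}
        for cs in spec.chromosomes:
            f = freqs[cs.name]
            hap_a = (rng.random(cs.n_markers) < f).astype(np.int8)
            hap_b = (rng.random(cs.n_markers) < f).astype(np.int8)
            individuals[iid][cs.name] = HaplotypePair(iid, cs.name, hap_a, hap_b)

    traits = [f"trait{k + 1}" for k in range(spec.n_traits)]
    eff = rng.normal(0.0, spec.effect_sd, size=(len(all_ids), spec.n_traits))
    return individuals, maps, EffectTable(all_ids, traits, eff)


def enumerate_gametes(
    pair: HaplotypePair, adjacent_rates: np.ndarray
) -> dict[tuple[int, ...], float]:
    """Exact probability of every distinct gamete haplotype.

    Enumerates all 2^N source-haplotype paths: a path chooses which parental
    haplotype each allele is copied from; its probability is 1/2 times the
    product over intervals of (rate if the source switches else 1-rate).
    Probabilities of paths yielding the same gamete are summed.
    """
    n = pair.n_markers
    if n > ENUMERATION_CAP:
        raise ValueError(
            f"{n} markers exceeds the enumeration cap of {ENUMERATION_CAP}; "
            "use sample_gametes instead"
        )
    rates = np.asarray(adjacent_rates, dtype=float)
    if rates.shape != (max(n - 1, 0),):
        raise ValueError("adjacent_rates length must be n_markers - 1")
    if n == 0:
        return {(): 1.0}
    # source[s, j] in {0, 1}: which parental haplotype path s copies at j
    source = (
        np.arange(2**n)[:, None] >> np.arange(n - 1, -1, -1)[None, :]
    ) & 1
    switch = source[:, 1:] != source[:, :-1]
    probs = 0.5 * np.prod(np.where(switch, rates, 1.0 - rates), axis=1)
    haps = np.stack([pair.hap_a, pair.hap_b])
    gametes = haps[source, np.arange(n)[None, :]]
    dist: dict[tuple[int, ...], float] = {}
    for g, p in zip(map(tuple, gametes.tolist()), probs):
        dist[g] = dist.get(g, 0.0) + float(p)
    return dist


def oracle_moments(
    dist: dict[tuple[int, ...], float], alpha: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Exact mean vector and covariance matrix of gamete breeding values.

    ``alpha`` is n_markers x K; gamete values use the centered allele code
    (allele - 1/2), so the mean equals GEBV/2 per trait and the covariance
    matrix carries the gametic variances (diagonal) and between-trait
    gametic covariances (off-diagonal).
    """
    alpha = np.atleast_2d(np.asarray(alpha, dtype=float))
    if alpha.shape[0] == 1:
        alpha = alpha.T
    gametes = np.array(list(dist.keys()), dtype=float)
    probs = np.array(list(dist.values()))
    vals = (gametes - 0.5) @ alpha  # n_gametes x K
    mean = probs @ vals
    centered = vals - mean
    cov = (centered * probs[:, None]).T @ centered
    return mean, cov


def oracle_variance(
    dist: dict[tuple[int, ...], float], alpha: np.ndarray
) -> tuple[float, np.ndarray]:
    """Exact gamete-value variance of trait 1 plus the full covariance matrix."""
    _, cov = oracle_moments(dist, alpha)
    return float(cov[0, 0]), cov


def sample_gametes(
    pair: HaplotypePair,
    adjacent_rates: np.ndarray,
    n_samples: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw i.i.d. gametes (n_samples x n_markers allele matrix).

    Same Markov model as ``enumerate_gametes``: equiprobable starting
    haplotype, each interval independently recombinant with its rate.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    n = pair.n_markers
    rates = np.asarray(adjacent_rates, dtype=float)
    if rates.shape != (max(n - 1, 0),):
        raise ValueError("adjacent_rates length must be n_markers - 1")
    if n == 0:
        return np.zeros((n_samples, 0), dtype=np.int8)
    start = rng.integers(0, 2, size=n_samples)
    switches = rng.random((n_samples, n - 1)) < rates[None, :]
    source = np.empty((n_samples, n), dtype=np.int64)
    source[:, 0] = start
    if n > 1:
        source[:, 1:] = np.cumsum(switches, axis=1)
        source[:, 1:] = (source[:, 1:] + start[:, None]) & 1
        # cumsum of switches modulo 2 flips the source at each crossover
    haps = np.stack([pair.hap_a, pair.hap_b])
    return haps[source, np.arange(n)[None, :]]
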