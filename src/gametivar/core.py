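"""Core domain types for gametic-diversity analysis.

Conventions used throughout the package:

* Haplotype alleles are coded 0/1, where **1 is the reference allele**.
  The allele-substitution effect ``alpha`` of a marker is the effect of
  that reference allele, and the phase indicator between two heterozygous
  loci is +1 exactly when the reference alleles sit on the same haplotype.
* The genotype code at a locus is ``hap_a + hap_b - 1``, i.e. -1/0/+1 for
  aa / Aa / AA, the coding used for breeding-value dot products.
* Only biallelic loci are representable; readers reject or drop anything
  else.
* Markers are aligned by marker id, never by position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("gametivar")

__all__ = [
    "GeneticMap",
    "HaplotypePair",
    "EffectTable",
    "TransmissionMatrix",
    "GameticReport",
    "AlignmentError",
    "align_effects_to_map",
]


class AlignmentError(ValueError):
    """A marker required by the genetic map is missing from the effect table."""


@dataclass
class GeneticMap:
    """Marker map for one chromosome.

    Exactly one of ``positions_cM`` (cumulative map positions, centimorgans)
    and ``adjacent_rates`` (recombination rate of each adjacent marker
    interval, length ``n_markers - 1``) is populated; ``distance_mode`` is
    ``"cM"`` or ``"rate"`` accordingly.
    """

    chromosome: str
    marker_ids: list[str]
    positions_cM: np.ndarray | None = None
    adjacent_rates: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.marker_ids = list(self.marker_ids)
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError(
                f"duplicate marker ids on chromosome {self.chromosome!r}"
            )
        if (self.positions_cM is None) == (self.adjacent_rates is None):
            raise ValueError(
                "exactly one of positions_cM / adjacent_rates must be given"
            )
        n = len(self.marker_ids)
        if self.positions_cM is not None:
            self.positions_cM = np.asarray(self.positions_cM, dtype=float)
            if self.positions_cM.shape != (n,):
                raise ValueError("positions_cM length must equal n_markers")
            if np.any(self.positions_cM < 0):
                raise ValueError("map positions must be non-negative")
            if np.any(np.diff(self.positions_cM) < 0):
                raise ValueError(
                    f"cM positions not non-decreasing on chromosome "
                    f"{self.chromosome!r}"
                )
        else:
            self.adjacent_rates = np.asarray(self.adjacent_rates, dtype=float)
            if self.adjacent_rates.shape != (max(n - 1, 0),):
                raise ValueError(
                    "adjacent_rates length must equal n_markers - 1"
                )
            if np.any((self.adjacent_rates < 0) | (self.adjacent_rates > 0.5)):
                raise ValueError("adjacent rates must lie in [0, 0.5]")

    @property
    def distance_mode(self) -> str:
        return "cM" if self.positions_cM is not None else "rate"

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def subset(self, indices: np.ndarray | list[int]) -> "GeneticMap":
        """Map restricted to ``indices`` (sorted marker subset).

        In rate mode the intervals spanning dropped markers are merged with
        the odd-crossover composition r + s - 2rs.
        """
        idx = np.asarray(sorted(indices), dtype=int)
        ids = [self.marker_ids[i] for i in idx]
        if self.distance_mode == "cM":
            return GeneticMap(self.chromosome, ids,
                              positions_cM=self.positions_cM[idx])
        merged = []
        for a, b in zip(idx[:-1], idx[1:]):
            r = 0.0
            for i in range(a, b):
                s = self.adjacent_rates[i]
                r = r + s - 2.0 * r * s
            merged.append(r)
        return GeneticMap(self.chromosome, ids,
                          adjacent_rates=np.asarray(merged))


@dataclass
class HaplotypePair:
    """One individual's two phased haplotypes on one chromosome (0/1 alleles)."""

    individual_id: str
    chromosome: str
    hap_a: np.ndarray
    hap_b: np.ndarray

    def __post_init__(self) -> None:
        self.hap_a = np.asarray(self.hap_a, dtype=np.int8)
        self.hap_b = np.asarray(self.hap_b, dtype=np.int8)
        if self.hap_a.shape != self.hap_b.shape or self.hap_a.ndim != 1:
            raise ValueError("haplotypes must be 1-D and of equal length")
        for h in (self.hap_a, self.hap_b):
            if np.any((h != 0) & (h != 1)):
                raise ValueError("haplotype alleles must be 0 or 1")

    @property
    def n_markers(self) -> int:
        return self.hap_a.shape[0]

    @property
    def genotypes(self) -> np.ndarray:
        """Genotype codes -1/0/+1 for aa/Aa/AA."""
        return (self.hap_a + self.hap_b - 1).astype(np.int8)

    def subset(self, indices: np.ndarray | list[int]) -> "HaplotypePair":
        idx = np.asarray(sorted(indices), dtype=int)
        return HaplotypePair(self.individual_id, self.chromosome,
                             self.hap_a[idx], self.hap_b[idx])


@dataclass
class EffectTable:
    """Allele-substitution effects, one row per marker, one column per trait."""

    marker_ids: list[str]
    trait_names: list[str]
    effects: np.ndarray

    def __post_init__(self) -> None:
        self.marker_ids = list(self.marker_ids)
        self.trait_names = list(self.trait_names)
        self.effects = np.asarray(self.effects, dtype=float)
        if self.effects.ndim == 1:
            self.effects = self.effects[:, None]
        if self.effects.shape != (len(self.marker_ids), len(self.trait_names)):
            raise ValueError("effects must be n_markers x n_traits")
        if not np.all(np.isfinite(self.effects)):
            raise ValueError("effects must be finite")

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)


@dataclass
class TransmissionMatrix:
    """Mendelian-transmission (co)variance matrix P over heterozygous loci.

    ``het_indices`` are the positions of the heterozygous loci within the
    chromosome; ``values`` is the symmetric N_het x N_het matrix with
    diagonal 0.25.
    """

    het_indices: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.het_indices = np.asarray(self.het_indices, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        n = self.het_indices.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("values must be square over het_indices")

    @property
    def n_het(self) -> int:
        return self.het_indices.shape[0]

    def validate(self, atol: float = 1e-12) -> None:
        """Assert the structural invariants of P."""
        v = self.values
        if v.size == 0:
            return
        if not np.allclose(np.diag(v), 0.25, atol=atol):
            raise ValueError("P diagonal must be 0.25")
        if not np.allclose(v, v.T, atol=atol):
            raise ValueError("P must be symmetric")
        if np.any(np.abs(v) > 0.25 + atol):
            raise ValueError("|P_jk| must not exceed 0.25")


@dataclass
class GameticReport:
    """All per-individual statistics, per chromosome and genome-wide.

    Per-chromosome dictionaries are keyed trait -> chromosome -> value
    (trait-pair tuples for covariances); totals are simple sums across
    chromosomes. CRV uses genome-wide totals; per-chromosome CRV values are
    an extension beyond the original program's outputs.
    """

    individual_id: str
    chromosomes: list[str] = field(default_factory=list)
    trait_names: list[str] = field(default_factory=list)
    variance: dict = field(default_factory=dict)
    variance_total: dict = field(default_factory=dict)
    covariance: dict = field(default_factory=dict)
    covariance_total: dict = field(default_factory=dict)
    hom: dict = field(default_factory=dict)
    hom_total: dict = field(default_factory=dict)
    gebv: dict = field(default_factory=dict)
    gebv_total: dict = field(default_factory=dict)
    crv: dict = field(default_factory=dict)
    crv_by_chrom: dict = field(default_factory=dict)
    rpta: dict = field(default_factory=dict)
    progeny_n: dict = field(default_factory=dict)
    progeny_n_raw: dict = field(default_factory=dict)


def align_effects_to_map(
    effects: EffectTable, gmap: GeneticMap, strict: bool = True
) -> EffectTable:
    """Reorder ``effects`` rows to the marker order of ``gmap``.

    With ``strict=True`` every map marker must be present in the effect
    table; otherwise missing markers are dropped (with a logged warning)
    and the returned table covers the intersection, in map order.
    Idempotent: aligning an already aligned table is the identity.
    """
    pos = {m: i for i, m in enumerate(effects.marker_ids)}
    rows, ids = [], []
    missing = []
    for m in gmap.marker_ids:
        if m in pos:
            rows.append(pos[m])
            ids.append(m)
        else:
            missing.append(m)
    if missing:
        if strict:
            raise AlignmentError(
                f"marker {missing[0]!r} on chromosome {gmap.chromosome!r} "
                f"is missing from the effect table "
                f"({len(missing)} missing in total)"
            )
        logger.warning(
            "dropping %d map marker(s) absent from the effect table on "
            "chromosome %s (first: %s)",
            len(missing), gmap.chromosome, missing[0],
        )
    return EffectTable(ids, effects.trait_names, effects.effects[rows, :])
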