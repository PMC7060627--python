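"""Per-individual gametic variance, covariance, HOM, GEBV, CRV.

The gametic variance of trait x is the quadratic form

    sigma2_X = alpha_x' P alpha_x

over the individual's heterozygous loci, where P is the Mendelian
transmission (co)variance matrix; the between-trait gametic covariance
uses the same P bilinearly. Homozygous loci contribute nothing to gametic
variance but enter HOM = sum of squared effects at homozygous loci, which
feeds the coefficient of relative variation

    CRV = sigma_gamete / sqrt(0.5 * HOM + sigma2_gamete)

computed from genome-wide totals. Everything is calculated chromosome by
chromosome; totals are simple sums across chromosomes (all chromosomes are
treated as autosomes).
"""

from __future__ import annotations

import logging
from collections.abc import Mapping

import numpy as np

from .core import EffectTable, GameticReport, GeneticMap, HaplotypePair, TransmissionMatrix
from .selection import SelectionParams, progeny_number, progeny_number_raw, rpta
from .transmission import DENSE_THRESHOLD, _p_block, build_P, heterozygous_loci

logger = logging.getLogger("gametivar")

__all__ = [
    "gametic_variance",
    "gametic_covariance",
    "hom_statistic",
    "crv",
    "gebv",
    "cross_products",
    "individual_report",
]


def _p_values(P) -> np.ndarray:
    return P.values if isinstance(P, TransmissionMatrix) else np.asarray(P, float)


def gametic_variance(alpha_het: np.ndarray, P) -> float:
    """Quadratic form alpha' P alpha over heterozygous loci."""
    v = _p_values(P)
    a = np.asarray(alpha_het, dtype=float)
    if a.shape[0] != v.shape[0]:
        raise ValueError("effect vector length does not match P")
    if a.size == 0:
        return 0.0
    return float(a @ v @ a)


def gametic_covariance(alpha_x_het: np.ndarray, alpha_y_het: np.ndarray, P) -> float:
    """Bilinear form alpha_x' P alpha_y; symmetric in the two traits."""
    v = _p_values(P)
    ax = np.asarray(alpha_x_het, dtype=float)
    ay = np.asarray(alpha_y_het, dtype=float)
    if ax.shape[0] != v.shape[0] or ay.shape[0] != v.shape[0]:
        raise ValueError("effect vector length does not match P")
    if ax.size == 0:
        return 0.0
    return float(ax @ v @ ay)


def hom_statistic(pair: HaplotypePair, alpha: np.ndarray) -> float:
    """Sum of squared effects over the homozygous loci of ``pair``."""
    alpha = np.asarray(alpha, dtype=float)
    hom = pair.hap_a == pair.hap_b
    return float(np.sum(alpha[hom] ** 2))


def crv(sigma_gamete: float, hom_total: float) -> float:
    """Coefficient of relative variation from genome-wide totals.

    ``sigma_gamete`` is the gametic standard deviation (not the variance).
    The degenerate 0/0 case (fully homozygous individual with all-zero
    effects) is defined as 0.
    """
    if sigma_gamete < 0 or hom_total < 0:
        raise ValueError("crv inputs must be non-negative")
    denom2 = 0.5 * hom_total + sigma_gamete**2
    if denom2 == 0.0:
        logger.warning("CRV 0/0 (no gametic variance, no homozygous effects); "
                       "defining CRV = 0")
        return 0.0
    return sigma_gamete / float(np.sqrt(denom2))


def gebv(
    pairs: Mapping[str, HaplotypePair],
    effects_by_chrom: Mapping[str, EffectTable],
    trait: str,
) -> tuple[dict[str, float], float]:
    """Genomic breeding value, per chromosome and total.

    GEBV is the dot product of the -1/0/+1 genotype codes with the
    allele-substitution effects of ``trait``; the genome-wide value is the
    sum over chromosomes. Returned un-halved (the transmitting ability is
    GEBV/2).
    """
    per_chrom = {}
    for chrom, pair in pairs.items():
        eff = effects_by_chrom[chrom]
        a = eff.effects[:, eff.trait_names.index(trait)]
        per_chrom[chrom] = float(pair.genotypes.astype(float) @ a)
    return per_chrom, float(sum(per_chrom.values()))


def cross_products(
    pair: HaplotypePair,
    gmap: GeneticMap,
    alpha: np.ndarray,
    pairwise_rates: np.ndarray | None = None,
    dense_threshold: int = DENSE_THRESHOLD,
) -> np.ndarray:
    """K x K matrix A' P A for all traits at once (A = effects at het loci).

    For up to ``dense_threshold`` heterozygous loci, P is materialized and
    the product computed directly; beyond that, P is accumulated in row
    blocks with identical results.
    """
    alpha = np.atleast_2d(np.asarray(alpha, dtype=float))
    if alpha.shape[0] == 1 and alpha.shape[1] == gmap.n_markers:
        alpha = alpha.T
    het = heterozygous_loci(pair)
    A = alpha[het, :]
    K = A.shape[1]
    if het.size == 0:
        return np.zeros((K, K))
    if het.size <= dense_threshold:
        P = build_P(pair, gmap, pairwise_rates=pairwise_rates)
        return A.T @ P.values @ A
    out = np.zeros((K, K))
    step = dense_threshold
    for start in range(0, het.size, step):
        rows = slice(start, min(start + step, het.size))
        if pairwise_rates is not None:
            r = np.asarray(pairwise_rates, float)[np.ix_(het[rows], het)]
            s = (2 * pair.hap_a[het] - 1).astype(float)
            al = np.outer(s[rows], s)
            block = al * (-r / 2.0 + 0.25)
            block[r >= 0.5] = 0.0
            for i in range(block.shape[0]):
                block[i, rows.start + i] = 0.25
        else:
            block = _p_block(pair, gmap, het, rows)
        out += A[rows, :].T @ block @ A
    return out


def individual_report(
    pairs: Mapping[str, HaplotypePair],
    maps: Mapping[str, GeneticMap],
    effects_by_chrom: Mapping[str, EffectTable],
    params: SelectionParams | None = None,
    pairwise_rates: Mapping[str, np.ndarray] | None = None,
) -> GameticReport:
    """Full per-individual report across chromosomes.

    ``pairs`` maps chromosome -> HaplotypePair (one per chromosome);
    ``effects_by_chrom`` holds effect tables already aligned to each map.
    Genome-wide totals are sums across chromosomes; CRV, RPTA and the
    progeny-number estimate are computed from the totals.
    """
    params = params or SelectionParams()
    missing = [c for c in pairs if c not in maps]
    if missing:
        raise ValueError(
            f"chromosome(s) in genotypes but absent from map: {sorted(missing)}"
        )
    chroms = list(pairs.keys())
    first = effects_by_chrom[chroms[0]]
    traits = list(first.trait_names)
    K = len(traits)
    pair_keys = [(traits[i], traits[j]) for i in range(K) for j in range(i + 1, K)]

    rep = GameticReport(
        individual_id=next(iter(pairs.values())).individual_id,
        chromosomes=chroms,
        trait_names=traits,
    )
    rep.variance = {t: {} for t in traits}
    rep.covariance = {pk: {} for pk in pair_keys}
    rep.hom = {t: {} for t in traits}
    rep.gebv = {t: {} for t in traits}
    rep.crv_by_chrom = {t: {} for t in traits}

    for chrom in chroms:
        pair, gmap, eff = pairs[chrom], maps[chrom], effects_by_chrom[chrom]
        pr = pairwise_rates.get(chrom) if pairwise_rates else None
        cp = cross_products(pair, gmap, eff.effects, pairwise_rates=pr)
        g = pair.genotypes.astype(float)
        hom_mask = pair.hap_a == pair.hap_b
        for i, t in enumerate(traits):
            a = eff.effects[:, i]
            rep.variance[t][chrom] = float(cp[i, i])
            rep.hom[t][chrom] = float(np.sum(a[hom_mask] ** 2))
            rep.gebv[t][chrom] = float(g @ a)
            v = max(cp[i, i], 0.0)
            rep.crv_by_chrom[t][chrom] = crv(float(np.sqrt(v)),
                                             rep.hom[t][chrom])
        for i in range(K):
            for j in range(i + 1, K):
                rep.covariance[(traits[i], traits[j])][chrom] = float(cp[i, j])

    for t in traits:
        rep.variance_total[t] = float(sum(rep.variance[t].values()))
        rep.hom_total[t] = float(sum(rep.hom[t].values()))
        rep.gebv_total[t] = float(sum(rep.gebv[t].values()))
    for pk in pair_keys:
        rep.covariance_total[pk] = float(sum(rep.covariance[pk].values()))

    for t in traits:
        v = rep.variance_total[t]
        if v < 0:
            # possible only in cM mode, where P is not guaranteed PSD
            logger.warning(
                "negative total gametic variance %.3g for trait %s of %s; "
                "clamped to 0 for sigma-derived statistics", v, t,
                rep.individual_id,
            )
            v = 0.0
        sigma = float(np.sqrt(v))
        rep.crv[t] = crv(sigma, rep.hom_total[t])
        rep.rpta[t] = rpta(rep.gebv_total[t], sigma, params)
        rep.progeny_n[t] = progeny_number(rep.crv[t], params)
        rep.progeny_n_raw[t] = progeny_number_raw(rep.crv[t], params)
    return rep
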