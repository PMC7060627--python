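"""Mendelian-transmission (co)variance matrix P.

P is the covariance matrix of the transmission indicators of an
individual's heterozygous loci (gamete allele coded +1/2 when the gamete
carries the reference allele, -1/2 otherwise). Each diagonal entry is the
binomial single-draw variance n*p*q = 0.25 (n = 1, p = q = 0.5). The
off-diagonal entry between heterozygous loci j and k is

    cM input:    al_jk * (-d_jk/200 + 0.25),  0 when d_jk > 50 cM
    rate input:  al_jk * (-r_jk/2  + 0.25),   0 when r_jk >= 0.5

where al_jk is +1 when the reference alleles at j and k lie on the same
haplotype (coupling) and -1 otherwise (repulsion). Loci on different
chromosomes never share a P matrix; independence across chromosomes is
structural.
"""

from __future__ import annotations

import numpy as np

from .core import GeneticMap, HaplotypePair, TransmissionMatrix

__all__ = [
    "heterozygous_loci",
    "phase_indicator",
    "p_offdiag_from_cM",
    "p_offdiag_from_rate",
    "pairwise_rate",
    "build_P",
]

#: above this heterozygous-locus count, quadratic forms are accumulated in
#: row blocks instead of materializing the dense P (see gametic.cross_products)
DENSE_THRESHOLD = 8192


def heterozygous_loci(pair: HaplotypePair) -> np.ndarray:
    """Indices (map order) of loci where the two haplotypes differ."""
    return np.flatnonzero(pair.hap_a != pair.hap_b)


def phase_indicator(pair: HaplotypePair, j: int, k: int) -> int:
    """+1 if the haplotype carrying the reference allele at j also carries
    it at k (coupling), -1 otherwise (repulsion). Both loci must be
    heterozygous."""
    if pair.hap_a[j] == pair.hap_b[j] or pair.hap_a[k] == pair.hap_b[k]:
        raise ValueError("phase indicator is defined for heterozygous loci only")
    return 1 if pair.hap_a[j] == pair.hap_a[k] else -1


def p_offdiag_from_cM(al: int, cM: float) -> float:
    """Off-diagonal P entry from a pairwise genetic distance in centimorgans."""
    if cM < 0:
        raise ValueError("genetic distance must be non-negative")
    if cM > 50.0:
        return 0.0
    return al * (-cM / 200.0 + 0.25)


def p_offdiag_from_rate(al: int, rate: float) -> float:
    """Off-diagonal P entry from a pairwise recombination rate."""
    if rate < 0 or rate > 1:
        raise ValueError("recombination rate must lie in [0, 1]")
    if rate >= 0.5:
        return 0.0
    return al * (-rate / 2.0 + 0.25)


def _rate_prefixes(rates: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Prefix statistics for composing adjacent rates into pairwise rates.

    1 - 2*r_jk = prod_{i in [j,k)} (1 - 2*r_i); a factor of exactly 0 (an
    interval at rate 0.5) is absorbing, tracked by a zero count so the log
    prefix sum stays finite.
    """
    c = 1.0 - 2.0 * np.asarray(rates, dtype=float)
    zeros = np.concatenate([[0], np.cumsum(c == 0.0)])
    logs = np.concatenate([[0.0], np.cumsum(np.where(c > 0.0, np.log(
        np.where(c > 0.0, c, 1.0)), 0.0))])
    return zeros, logs


def pairwise_rate(gmap: GeneticMap, j: int, k: int) -> float:
    """Recombination rate between markers j and k (odd-crossover probability)
    under the no-interference Markov model, composed from adjacent rates."""
    if gmap.distance_mode != "rate":
        raise ValueError("pairwise_rate requires a rate-mode map")
    if j > k:
        j, k = k, j
    zeros, logs = _rate_prefixes(gmap.adjacent_rates)
    if zeros[k] != zeros[j]:
        return 0.5
    return 0.5 * (1.0 - np.exp(logs[k] - logs[j]))


def _pairwise_rate_matrix(rates: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Pairwise rate matrix over the marker subset ``idx`` (vectorized)."""
    zeros, logs = _rate_prefixes(rates)
    z, lg = zeros[idx], logs[idx]
    prod = np.exp(-np.abs(lg[None, :] - lg[:, None]))
    prod[z[None, :] != z[:, None]] = 0.0
    r = 0.5 * (1.0 - prod)
    np.fill_diagonal(r, 0.0)
    return r


def _phase_sign(pair: HaplotypePair, het: np.ndarray) -> np.ndarray:
    s = (2 * pair.hap_a[het] - 1).astype(float)
    return s


def build_P(
    pair: HaplotypePair,
    gmap: GeneticMap,
    pairwise_rates: np.ndarray | None = None,
) -> TransmissionMatrix:
    """Build P over the heterozygous loci of ``pair``.

    ``pairwise_rates``, if given, is a full n_markers x n_markers matrix of
    pairwise recombination rates used verbatim (rate mode only); otherwise
    pairwise rates are composed from the map's adjacent interval rates.
    """
    if pair.n_markers != gmap.n_markers:
        raise ValueError("haplotype length does not match the map")
    het = heterozygous_loci(pair)
    n = het.shape[0]
    if n == 0:
        return TransmissionMatrix(het, np.zeros((0, 0)))
    s = _phase_sign(pair, het)
    al = np.outer(s, s)  # +1 coupling, -1 repulsion; +1 on the diagonal
    if gmap.distance_mode == "cM":
        if pairwise_rates is not None:
            raise ValueError("pairwise_rates requires a rate-mode map")
        pos = gmap.positions_cM[het]
        d = np.abs(pos[None, :] - pos[:, None])
        vals = al * (-d / 200.0 + 0.25)
        vals[d > 50.0] = 0.0
    else:
        if pairwise_rates is not None:
            r = np.asarray(pairwise_rates, dtype=float)[np.ix_(het, het)]
        else:
            r = _pairwise_rate_matrix(gmap.adjacent_rates, het)
        vals = al * (-r / 2.0 + 0.25)
        vals[r >= 0.5] = 0.0
    np.fill_diagonal(vals, 0.25)
    return TransmissionMatrix(het, vals)


def _p_block(
    pair: HaplotypePair,
    gmap: GeneticMap,
    het: np.ndarray,
    rows: slice,
) -> np.ndarray:
    """Rows ``rows`` of P over ``het`` without materializing the full matrix."""
    s = _phase_sign(pair, het)
    al = np.outer(s[rows], s)
    if gmap.distance_mode == "cM":
        pos = gmap.positions_cM[het]
        d = np.abs(pos[rows][:, None] - pos[None, :])
        vals = al * (-d / 200.0 + 0.25)
        vals[d > 50.0] = 0.0
    else:
        zeros, logs = _rate_prefixes(gmap.adjacent_rates)
        z, lg = zeros[het], logs[het]
        prod = np.exp(-np.abs(lg[None, :] - lg[rows][:, None]))
        prod[z[None, :] != z[rows][:, None]] = 0.0
        r = 0.5 * (1.0 - prod)
        vals = al * (-r / 2.0 + 0.25)
        vals[r >= 0.5] = 0.0
    i0 = rows.start or 0
    for i in range(vals.shape[0]):
        vals[i, i0 + i] = 0.25
    return vals
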