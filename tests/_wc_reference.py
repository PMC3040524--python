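"""Independent transcription of the Weir & Cockerham (1984) theta estimator.

This module is a deliberately plain, scalar re-derivation of the per-locus
variance components for a biallelic locus, written before and kept separate
from the package implementation so the two can be compared as independent
routes.  Inputs are per-population genotype summaries:

    pops: list of (n_called, count_allele1, n_heterozygotes)

where ``n_called`` is the number of individuals with a genotype call,
``count_allele1`` the number of allele-1 copies among the 2*n_called called
alleles, and ``n_heterozygotes`` the number of heterozygous individuals.

Returns (a, b, c, theta); theta is None when a + b + c == 0.
"""

from __future__ import annotations


def wc_theta_reference(pops):
    pops = [(n, c1, het) for (n, c1, het) in pops if n > 0]
    r = len(pops)
    if r < 2:
        return (0.0, 0.0, 0.0, None)
    n = [float(p[0]) for p in pops]
    p_hat = [p[1] / (2.0 * p[0]) for p in pops]
    h_hat = [p[2] / float(p[0]) for p in pops]

    n_total = sum(n)
    nbar = n_total / r
    if nbar <= 1.0:
        return (0.0, 0.0, 0.0, None)
    nc = (n_total - sum(ni * ni for ni in n) / n_total) / (r - 1.0)
    if nc == 0.0:
        return (0.0, 0.0, 0.0, None)
    pbar = sum(ni * pi for ni, pi in zip(n, p_hat)) / n_total
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p_hat)) / ((r - 1.0) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h_hat)) / n_total

    a = (nbar / nc) * (
        s2 - (pbar * (1.0 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0) / (nbar - 1.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1.0 - pbar)
        - (r - 1.0) / r * s2
        - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
    )
    c = hbar / 2.0
    denom = a + b + c
    theta = a / denom if denom != 0.0 else None
    return (a, b, c, theta)


def multilocus_theta_reference(components):
    """Ratio-of-sums aggregation over per-locus (a, b, c) triples."""
    num = sum(a for a, b, c in components)
    den = sum(a + b + c for a, b, c in components)
    return num / den if den != 0.0 else None
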