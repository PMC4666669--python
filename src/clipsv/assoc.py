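"""Binomial likelihood-ratio association test between target and background.

The null model pools the non-reference allele counts of both cohorts into a
single binomial; the alternative gives each cohort its own success
probability (its allele frequency).  The statistic

    D = -2 ln [ L(pooled) / ( L(target) x L(background) ) ]

is computed on the binomial *kernels*: the combinatorial coefficients of the
pooled numerator do not cancel against the split denominator and would let D
go negative, while the kernel-only form is algebraically identical to the
standard two-sample binomial LRT, so D >= 0 always and D ~ chi-squared with
1 df under the null.  Allelic counts come from the genotype calls: each called
diploid genotype contributes two alleles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional

from scipy.stats import chi2

from .variants import GenotypeCall


@dataclass(slots=True)
class AssocCounts:
    """Non-reference (n) and total (k) allele counts per cohort."""

    n_t: int
    k_t: int
    n_b: int
    k_b: int

    def __post_init__(self) -> None:
        for n, k, name in ((self.n_t, self.k_t, "target"),
                           (self.n_b, self.k_b, "background")):
            if not (0 <= n <= k):
                raise ValueError(f"invalid {name} counts: n={n}, k={k}")
        if self.k_t < 1 or self.k_b < 1:
            raise ValueError("each cohort needs at least one called allele")

    @property
    def n_c(self) -> int:
        return self.n_t + self.n_b

    @property
    def k_c(self) -> int:
        return self.k_t + self.k_b

    @property
    def af_t(self) -> float:
        return self.n_t / self.k_t

    @property
    def af_b(self) -> float:
        return self.n_b / self.k_b

    @property
    def af_c(self) -> float:
        return self.n_c / self.k_c


def counts_from_genotypes(genotypes: Dict[str, GenotypeCall],
                          target_samples: Iterable[str],
                          background_samples: Iterable[str]
                          ) -> Optional[AssocCounts]:
    """Build cohort allele counts from per-sample genotype calls.

    ``./.`` genotypes contribute nothing; a cohort with zero called alleles
    yields ``None`` (the site gets no LRT).  The sample sets must be disjoint.
    """
    target = list(target_samples)
    background = list(background_samples)
    overlap = set(target) & set(background)
    if overlap:
        raise ValueError(f"samples in both cohorts: {sorted(overlap)}")

    def tally(samples):
        n = k = 0
        for s in samples:
            g = genotypes.get(s)
            if g is None:
                continue
            alt = g.n_alt_alleles
            if alt is None:
                continue
            n += alt
            k += 2
        return n, k

    n_t, k_t = tally(target)
    n_b, k_b = tally(background)
    if k_t == 0 or k_b == 0:
        return None
    return AssocCounts(n_t, k_t, n_b, k_b)


def _log_kernel(n: int, k: int, p: float) -> float:
    """Binomial log-kernel n*ln(p) + (k-n)*ln(1-p) with 0*ln(0) == 0."""
    import math
    out = 0.0
    if n > 0:
        out += n * math.log(p)
    if k - n > 0:
        out += (k - n) * math.log(1.0 - p)
    return out


def lrt_statistic(c: AssocCounts) -> float:
    """The D statistic: -2 x (pooled minus split binomial log-likelihood)."""
    ll_null = _log_kernel(c.n_c, c.k_c, c.af_c)
    ll_alt = _log_kernel(c.n_t, c.k_t, c.af_t) + _log_kernel(c.n_b, c.k_b, c.af_b)
    d = -2.0 * (ll_null - ll_alt)
    return max(d, 0.0)             # clip tiny negative rounding noise


def chi2_pvalue(d: float) -> float:
    """Upper-tail chi-squared (1 df) conversion of D to a p-value."""
    if d < 0:
        raise ValueError(f"D must be non-negative, got {d}")
    return float(chi2.sf(d, df=1))
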