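"""Cross-study concordance of per-SNP effect estimates.

Two studies that probe the same true effects should show correlated odds
ratios even when neither reaches significance.  Three complementary views:

* Spearman rank correlation of the paired ORs (invariant to monotone
  rescaling, so OR vs log-OR makes no difference);
* sign concordance — both ORs on the same side of 1 — with ORs exactly 1
  or missing excluded;
* an exact two-sided binomial test of the concordant/discordant split
  against equal proportions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import InsufficientDataError, ValidationError

EXACT_PERMUTATION_MAX_N = 9


@dataclass(frozen=True)
class ConcordanceReport:
    n_concordant: int
    n_discordant: int
    n_excluded: int
    spearman_rho: float | None = None
    spearman_p: float | None = None
    binomial_p: float | None = None

    @property
    def n_pairs(self) -> int:
        return self.n_concordant + self.n_discordant + self.n_excluded


def _paired(or_a, or_b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(or_a, dtype=float)
    b = np.asarray(or_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("paired OR lists must be 1-D and equal length")
    return a, b


def spearman_or(or_a, or_b) -> tuple[float, float]:
    """Spearman rank correlation of paired ORs with two-sided p.

    Pairs with a missing value are dropped; fewer than 3 complete pairs is
    an error.  For n <= 9 the p-value is exact (full permutation
    enumeration); larger n uses the t-approximation.
    """
    a, b = _paired(or_a, or_b)
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    n = a.size
    if n < 3:
        raise InsufficientDataError(f"need >= 3 complete pairs, got {n}")
    ra = sps.rankdata(a)
    rb = sps.rankdata(b)
    rho = _pearson(ra, rb)
    if n <= EXACT_PERMUTATION_MAX_N:
        perms = np.array(list(itertools.permutations(range(n))))
        rhos = _pearson_rows(ra[perms], rb)
        p = float((np.abs(rhos) >= abs(rho) - 1e-12).mean())
    else:
        p = float(sps.spearmanr(a, b).pvalue)
    return float(rho), p


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        raise InsufficientDataError("constant ranks: correlation undefined")
    return float((xc * yc).sum() / denom)


def _pearson_rows(xrows: np.ndarray, y: np.ndarray) -> np.ndarray:
    xc = xrows - xrows.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum())
    return (xc * yc).sum(axis=1) / denom


def sign_concordance(or_a, or_b) -> ConcordanceReport:
    """Count pairs with both ORs on the same/opposite side of 1.

    Concordant iff (a-1)(b-1) > 0, discordant iff < 0; a pair with either
    OR missing or exactly 1 is excluded (the two printed classes are
    "both > 1" and "both < 1", so a null OR belongs to neither).
    """
    a, b = _paired(or_a, or_b)
    missing = np.isnan(a) | np.isnan(b)
    product = (a - 1) * (b - 1)
    concordant = int((~missing & (product > 0)).sum())
    discordant = int((~missing & (product < 0)).sum())
    excluded = int(a.size - concordant - discordant)
    return ConcordanceReport(
        n_concordant=concordant, n_discordant=discordant, n_excluded=excluded
    )


def binomial_sign_test(k: int, n: int) -> float:
    """Exact two-sided binomial test of k successes in n at rate 0.5."""
    if n <= 0:
        raise ValidationError("binomial sign test needs n >= 1")
    if not 0 <= k <= n:
        raise ValidationError(f"k must lie in [0, n], got k={k}, n={n}")
    return float(sps.binomtest(int(k), int(n), 0.5).pvalue)


def concordance_report(or_a, or_b) -> ConcordanceReport:
    """Full concordance summary: sign counts, Spearman rho/p, binomial p."""
    counts = sign_concordance(or_a, or_b)
    rho, sp = spearman_or(or_a, or_b)
    n_signed = counts.n_concordant + counts.n_discordant
    binom_p = binomial_sign_test(counts.n_concordant, n_signed) if n_signed else None
    return ConcordanceReport(
        n_concordant=counts.n_concordant,
        n_discordant=counts.n_discordant,
        n_excluded=counts.n_excluded,
        spearman_rho=rho,
        spearman_p=sp,
        binomial_p=binom_p,
    )
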