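"""Model selection: small-sample AIC, Akaike weights, and nested LRTs.

AIC-c uses the number of alignment columns as the sample size, the
standard phylogenetic convention.  Parameter counts are structured
identically across families (substitution parameters + gamma shape +
branch lengths), so AIC-c differences between models on the same data
reduce to substitution-parameter differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .errors import DomainError

#: Nesting relations (null -> alt) with the LRT degrees of freedom:
#: GTR (5 free exchangeabilities + 3 free frequencies = 8) vs NREV12 (11
#: free rates) gives d = 3; NREV6 (5 free class rates) vs NREV12 gives
#: d = 6; NREV12 vs NREV12+F (3 extra root parameters) gives d = 3.
NESTED_DF = {
    ("GTR", "NREV12"): 3,
    ("NREV6", "NREV12"): 6,
    ("NREV12", "NREV12F"): 3,
    ("GTR", "NREV12F"): 6,
    ("NREV6", "NREV12F"): 9,
}


def aicc(logL: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike information criterion,
    -2 logL + 2k + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise DomainError(f"AIC-c undefined: sample size n={n} must exceed k+1={k + 1}")
    return -2.0 * logL + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_scores) -> np.ndarray:
    """Relative model support w_i = exp(-delta_i/2) / sum_j exp(-delta_j/2)
    with delta_i the AIC-c difference to the best model."""
    s = np.asarray(aicc_scores, float)
    if s.size < 2 or not np.all(np.isfinite(s)):
        raise DomainError("need >= 2 finite AIC-c scores")
    d = s - s.min()
    w = np.exp(-d / 2.0)
    return w / w.sum()


@dataclass(frozen=True)
class LRTRecord:
    null_family: str
    alt_family: str
    stat: float
    df: int
    p: float


def lrt(null_fit, alt_fit) -> LRTRecord:
    """Likelihood-ratio test of nested substitution models.

    stat = 2 (logL_alt - logL_null), clamped at zero; the p-value is the
    upper tail of a chi-squared distribution with d = difference in free
    substitution parameters (branch lengths and the gamma shape cancel).
    """
    key = (null_fit.family, alt_fit.family)
    if key not in NESTED_DF:
        raise DomainError(f"{key[0]} is not nested in {key[1]}")
    stat = 2.0 * (alt_fit.logL - null_fit.logL)
    if stat < -1e-4 * max(1.0, abs(alt_fit.logL)):
        raise DomainError(
            f"alt logL {alt_fit.logL:.4f} below null {null_fit.logL:.4f}: fits inconsistent")
    stat = max(stat, 0.0)
    df = NESTED_DF[key]
    return LRTRecord(null_family=key[0], alt_family=key[1], stat=float(stat),
                     df=df, p=float(chi2.sf(stat, df)))


@dataclass(frozen=True)
class ModelComparison:
    """AIC-c scores, Akaike weights, and LRTs for one dataset."""

    aicc_scores: dict   # family -> AIC-c
    weights: dict       # family -> Akaike weight
    lrts: tuple         # LRTRecord entries

    @property
    def best_family(self) -> str:
        return min(self.aicc_scores, key=self.aicc_scores.get)


def compare_models(fits: dict) -> ModelComparison:
    """Build the full comparison from a {family: FitResult} mapping; LRTs
    are run for every nested pair present."""
    families = list(fits)
    scores = {f: fits[f].aicc for f in families}
    w = akaike_weights([scores[f] for f in families])
    weights = {f: float(x) for f, x in zip(families, w)}
    records = []
    for (null, alt), _df in NESTED_DF.items():
        if null in fits and alt in fits:
            records.append(lrt(fits[null], fits[alt]))
    return ModelComparison(aicc_scores=scores, weights=weights, lrts=tuple(records))
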