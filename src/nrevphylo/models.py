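"""Nucleotide substitution rate matrices and among-site rate heterogeneity.

The state space is the four nucleotides in the fixed order A, C, G, T
(U is treated as a synonym of T on input).  Three model families are
supported:

* ``GTR``    — the general time-reversible model: six exchangeabilities
  combined with equilibrium frequencies so that detailed balance
  pi_i q_ij = pi_j q_ji holds by construction.
* ``NREV6``  — a non-reversible model for double-stranded genomes in which
  each substitution and its strand complement share one rate
  (q_AC = q_TG, q_AG = q_TC, q_AT = q_TA, q_CG = q_GC, q_CT = q_GA,
  q_GT = q_CA), six rate classes in total.
* ``NREV12`` — the fully general (UNREST-style) model with twelve
  independent substitution rates; its equilibrium frequencies are not free
  parameters but the stationary distribution of the generator (pi Q = 0).

All generators are 4x4 matrices with non-negative off-diagonals and zero
row sums.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .errors import DegenerateGeneratorError, DomainError, ReducibleGeneratorError

NUCLEOTIDES = "ACGT"
#: Order of the twelve substitution types used for NREV12 rate vectors.
RATE_ORDER = (
    "AC", "AG", "AT",
    "CA", "CG", "CT",
    "GA", "GC", "GT",
    "TA", "TC", "TG",
)
_IDX = {b: i for i, b in enumerate(NUCLEOTIDES)}

#: Unordered nucleotide pairs, the keys of a DNR report.
PAIRS = ("AC", "AG", "AT", "CG", "CT", "GT")


@dataclass(frozen=True)
class BaseFrequencies:
    """A probability distribution over (A, C, G, T)."""

    pi: np.ndarray

    def __post_init__(self):
        pi = np.asarray(self.pi, dtype=float)
        if pi.shape != (4,):
            raise DomainError("base frequencies must be a 4-vector")
        if np.any(pi < -1e-12) or abs(pi.sum() - 1.0) > 1e-9:
            raise DomainError(f"invalid base frequencies {pi!r}: must be >= 0 and sum to 1")
        object.__setattr__(self, "pi", np.clip(pi, 0.0, None) / np.clip(pi, 0.0, None).sum())

    def __getitem__(self, base: str) -> float:
        return float(self.pi[_IDX[base]])

    @classmethod
    def uniform(cls) -> "BaseFrequencies":
        return cls(np.full(4, 0.25))


@dataclass(frozen=True)
class RateMatrix:
    """A continuous-time generator over {A, C, G, T}.

    ``q`` has rows/columns in A, C, G, T order; units are substitutions per
    site per unit time.  ``family`` records which constructor produced the
    matrix and ``free_rates`` the generating rate parameters in their
    documented order.
    """

    q: np.ndarray
    family: str = "CUSTOM"
    free_rates: tuple = field(default_factory=tuple)

    def __post_init__(self):
        q = np.array(self.q, dtype=float)
        if q.shape != (4, 4):
            raise DomainError("rate matrix must be 4x4")
        off = q[~np.eye(4, dtype=bool)]
        if np.any(off < -1e-12):
            raise DomainError("off-diagonal rates must be non-negative")
        # enforce exact zero row sums
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "free_rates", tuple(float(r) for r in self.free_rates))

    def rate(self, i: str, j: str) -> float:
        """Instantaneous rate of the ``i`` -> ``j`` substitution."""
        return float(self.q[_IDX[i], _IDX[j]])

    def off_diagonal_rates(self) -> np.ndarray:
        """The twelve off-diagonal entries in :data:`RATE_ORDER` order."""
        return np.array([self.q[_IDX[a], _IDX[b]] for a, b in RATE_ORDER])

    def scaled(self, s: float) -> "RateMatrix":
        return RateMatrix(self.q * s, family=self.family,
                          free_rates=tuple(r * s for r in self.free_rates))

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        obj = {"order": "ACGT", "family": self.family,
               "rates": {k: float(v) for k, v in zip(RATE_ORDER, self.off_diagonal_rates())}}
        return json.dumps(obj, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "RateMatrix":
        obj = json.loads(text)
        rates = obj["rates"] if "rates" in obj else obj
        try:
            vec = [float(rates[k]) for k in RATE_ORDER]
        except KeyError as exc:
            raise DomainError(f"rates object is missing key {exc}") from exc
        return build_nrev12_q(vec)

    def to_table(self) -> str:
        lines = ["# 4x4 instantaneous rate matrix; rows/cols in order A C G T"]
        for i, b in enumerate(NUCLEOTIDES):
            lines.append(b + "\t" + "\t".join(f"{v:.10g}" for v in self.q[i]))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_table(cls, text: str) -> "RateMatrix":
        rows = []
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            rows.append([float(x) for x in parts[-4:]])
        if len(rows) != 4:
            raise DomainError(f"expected 4 matrix rows, found {len(rows)}")
        return cls(np.array(rows))


@dataclass(frozen=True)
class GammaRates:
    """Discretized gamma distribution of among-site rate multipliers."""

    alpha: float
    ncat: int
    rates: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        rates = np.asarray(self.rates, float)
        weights = np.asarray(self.weights, float)
        if rates.shape != (self.ncat,) or weights.shape != (self.ncat,):
            raise DomainError("rates/weights length must equal ncat")
        if abs(weights.sum() - 1.0) > 1e-9 or abs(float(weights @ rates) - 1.0) > 1e-9:
            raise DomainError("gamma categories must have unit mean and weights summing to 1")
        object.__setattr__(self, "rates", rates)
        object.__setattr__(self, "weights", weights)

    @classmethod
    def none(cls) -> "GammaRates":
        """A single unit-rate category (no among-site heterogeneity)."""
        return cls(alpha=math.inf, ncat=1, rates=np.ones(1), weights=np.ones(1))


def _check_rates(rates, n) -> np.ndarray:
    r = np.asarray(rates, dtype=float)
    if r.shape != (n,):
        raise DomainError(f"expected {n} rates, got shape {r.shape}")
    if np.any(r < 0) or not np.all(np.isfinite(r)):
        raise DomainError("rates must be finite and non-negative")
    return r


def build_gtr_q(rates, pi: BaseFrequencies) -> RateMatrix:
    """General time-reversible generator from six exchangeabilities.

    The six rates (a..f) pair with target frequencies as
    q_AC = a*pi_C, q_AG = b*pi_G, q_CG = c*pi_G, q_AT = d*pi_T,
    q_CT = e*pi_T, q_GT = f*pi_T (and symmetrically for the reverse
    entries), so detailed balance holds exactly and ``pi`` is the
    stationary distribution.
    """
    a, b, c, d, e, f = _check_rates(rates, 6)
    if not isinstance(pi, BaseFrequencies):
        pi = BaseFrequencies(np.asarray(pi, float))
    p = pi.pi
    ex = np.array([
        [0.0, a, b, d],
        [a, 0.0, c, e],
        [b, c, 0.0, f],
        [d, e, f, 0.0],
    ])
    q = ex * p[None, :]
    return RateMatrix(q, family="GTR", free_rates=(a, b, c, d, e, f))


# NREV6 rate classes in constraint-list order:
# a: A->C = T->G, b: A->G = T->C, c: A->T = T->A,
# d: C->G = G->C, e: C->T = G->A, f: G->T = C->A
_NREV6_CLASSES = (
    (("A", "C"), ("T", "G")),
    (("A", "G"), ("T", "C")),
    (("A", "T"), ("T", "A")),
    (("C", "G"), ("G", "C")),
    (("C", "T"), ("G", "A")),
    (("G", "T"), ("C", "A")),
)


def build_nrev6_q(rates) -> RateMatrix:
    """Six-class non-reversible generator for double-stranded genomes.

    Each substitution shares a rate with its strand complement (e.g. G->A
    with C->T).  The resulting Q is invariant under the simultaneous
    relabelling A<->T, C<->G, which forces a complement-symmetric
    stationary distribution (pi_A = pi_T, pi_C = pi_G).
    """
    r = _check_rates(rates, 6)
    q = np.zeros((4, 4))
    for rate, pairs in zip(r, _NREV6_CLASSES):
        for i, j in pairs:
            q[_IDX[i], _IDX[j]] = rate
    return RateMatrix(q, family="NREV6", free_rates=tuple(r))


def build_nrev12_q(rates) -> RateMatrix:
    """Fully general generator with twelve independent rates.

    ``rates`` follow :data:`RATE_ORDER` (A->C, A->G, A->T, C->A, C->G,
    C->T, G->A, G->C, G->T, T->A, T->C, T->G).  No frequency factors are
    applied: the equilibrium frequencies are whatever stationary
    distribution the generator induces.
    """
    r = _check_rates(rates, 12)
    q = np.zeros((4, 4))
    for rate, (i, j) in zip(r, RATE_ORDER):
        q[_IDX[i], _IDX[j]] = rate
    for row in range(4):
        if q[row].sum() <= 0.0:
            raise DegenerateGeneratorError(
                f"state {NUCLEOTIDES[row]} has no positive outgoing rate")
    return RateMatrix(q, family="NREV12", free_rates=tuple(r))


def stationary_distribution(q: RateMatrix, tol: float = 1e-10) -> BaseFrequencies:
    """Solve pi Q = 0, pi >= 0, sum(pi) = 1 for the unique stationary pi.

    Raises :class:`ReducibleGeneratorError` when the generator's null space
    is not one-dimensional (more than one communicating class).
    """
    Q = q.q if isinstance(q, RateMatrix) else np.asarray(q, float)
    ns = scipy.linalg.null_space(Q.T, rcond=1e-9)
    if ns.shape[1] != 1:
        raise ReducibleGeneratorError(
            f"generator has a {ns.shape[1]}-dimensional null space; no unique stationary distribution")
    pi = ns[:, 0]
    pi = np.abs(pi) / np.abs(pi).sum()
    # one step of power-iteration refinement sharpens the lstsq solution
    resid = float(np.max(np.abs(pi @ Q)))
    if resid > tol:
        # refine via a linear solve with the normalization constraint appended
        A = np.vstack([Q.T, np.ones(4)])
        b = np.concatenate([np.zeros(4), [1.0]])
        pi, *_ = np.linalg.lstsq(A, b, rcond=None)
        pi = np.clip(pi, 0.0, None)
        pi /= pi.sum()
        resid = float(np.max(np.abs(pi @ Q)))
        if resid > tol:
            raise ReducibleGeneratorError(
                f"stationary solve residual {resid:.2e} exceeds {tol:.1e}")
    return BaseFrequencies(pi)


def expected_rate(q: RateMatrix, pi: BaseFrequencies | None = None) -> float:
    """Expected substitutions per site per unit time, -sum_i pi_i q_ii."""
    if pi is None:
        pi = stationary_distribution(q)
    return float(-(pi.pi * np.diag(q.q)).sum())


def normalize_q(q: RateMatrix, pi: BaseFrequencies | None = None) -> RateMatrix:
    """Rescale ``q`` so the expected rate under ``pi`` is one substitution
    per site per unit time (branch lengths then read as expected
    substitutions/site).  ``pi`` defaults to the stationary distribution."""
    mu = expected_rate(q, pi)
    if mu <= 0:
        raise DomainError("cannot normalize a zero generator")
    return q.scaled(1.0 / mu)


def transition_matrix(q: RateMatrix, t: float) -> np.ndarray:
    """Transition probabilities P(t) = exp(Q t); rows sum to one."""
    if t < 0:
        raise DomainError(f"branch length must be >= 0, got {t}")
    Q = q.q if isinstance(q, RateMatrix) else np.asarray(q, float)
    P = scipy.linalg.expm(Q * t)
    P = np.clip(P, 0.0, None)
    P /= P.sum(axis=1, keepdims=True)
    return P


def discretize_gamma(alpha: float, ncat: int) -> GammaRates:
    """Equal-probability discretization of a mean-one gamma distribution.

    Categories are the ``ncat`` equal-probability quantile bins of a
    Gamma(alpha, 1/alpha) density, each represented by its conditional
    mean, so the weighted mean rate is exactly one.
    """
    if alpha <= 0:
        raise DomainError(f"gamma shape must be > 0, got {alpha}")
    if ncat < 1:
        raise DomainError(f"ncat must be >= 1, got {ncat}")
    if ncat == 1:
        return GammaRates(alpha=alpha, ncat=1, rates=np.ones(1), weights=np.ones(1))
    edges = gamma_dist.ppf(np.linspace(0, 1, ncat + 1), a=alpha, scale=1.0 / alpha)
    edges[0], edges[-1] = 0.0, np.inf
    # E[X | bin] * P(bin) = P(alpha+1, alpha*upper) - P(alpha+1, alpha*lower)
    cum = gammainc(alpha + 1.0, np.where(np.isinf(edges), np.inf, alpha * edges))
    cum[-1] = 1.0
    rates = np.diff(cum) * ncat
    rates /= rates.mean()
    weights = np.full(ncat, 1.0 / ncat)
    return GammaRates(alpha=float(alpha), ncat=ncat, rates=rates, weights=weights)


def is_reversible(q: RateMatrix, tol: float = 1e-8) -> bool:
    """Detailed-balance test: max_ij |pi_i q_ij - pi_j q_ji| <= tol with
    pi the stationary distribution of ``q``."""
    pi = stationary_distribution(q).pi
    F = pi[:, None] * q.q
    return bool(np.max(np.abs(F - F.T)) <= tol)
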