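"""Phylogenetic likelihood under reversible and non-reversible models.

Felsenstein pruning over a rooted tree with discrete-gamma rate
categories, with per-node rescaling of partial likelihoods so long
alignments do not underflow.  Because the NREV models are not
time-reversible the likelihood genuinely depends on the root position;
the root state distribution is, by default, the empirical base
composition for GTR, the stationary distribution of the fitted generator
for NREV6/NREV12, and a free parameter for NREV12+F.

Maximization alternates bounded quasi-Newton steps on the substitution
parameters (in log space) with coordinate-wise branch-length refinement.
Branch-length refinement uses the standard up/down decomposition: for a
branch (u, v) the log-likelihood as a function of its length needs only
the partial likelihoods above u and below v, so a full sweep costs little
more than two tree traversals.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.linalg
from scipy.optimize import minimize, minimize_scalar
from scipy.special import logsumexp

from .alignment import NucAlignment, STATE_TABLE, empirical_frequencies
from .errors import ConvergenceError, DomainError, LabellingError, NrevError
from .models import (BaseFrequencies, GammaRates, RateMatrix, build_gtr_q,
                     build_nrev6_q, build_nrev12_q, discretize_gamma,
                     stationary_distribution)
from .selection import aicc
from .trees import RootedTree, nni_neighbors

FAMILIES = ("GTR", "NREV6", "NREV12", "NREV12F")

_MIN_BL = 1e-9
_LOG_RATE_BOUNDS = (np.log(1e-4), np.log(1e4))
_LOG_ALPHA_BOUNDS = (np.log(0.02), np.log(99.0))


@dataclass
class FitOptions:
    """Tunables of the maximum-likelihood fit."""

    gamma_ncat: int = 4          #: discrete-gamma categories; 1 disables +G
    rel_tol: float = 1e-6        #: relative logL improvement stopping rule
    max_rounds: int = 8          #: outer (rates <-> branch lengths) rounds
    bl_sweeps: int = 2           #: branch sweeps per round
    rate_maxiter: int = 60       #: quasi-Newton iterations per rates block
    n_restarts: int = 1          #: jittered optimizer restarts
    seed: int = 0                #: seeds restart jitter (fit is deterministic)
    bl_max: float = 20.0         #: branch-length upper bound, subst/site
    nni_max_rounds: int = 50     #: cap on accepted-rearrangement rounds
    root_freqs: str | None = None  #: override: 'stationary' | 'empirical'
    init_rates: tuple | None = None
    init_alpha: float | None = None


@dataclass
class FitResult:
    """A fitted substitution model on a fixed topology."""

    family: str
    rates: tuple                 #: free rates, family order (reference rate = 1)
    root_freqs: BaseFrequencies
    root_freq_source: str        #: 'empirical' | 'stationary' | 'free'
    alpha: float | None
    tree: RootedTree             #: input topology with optimized branch lengths
    q: RateMatrix
    gamma: GammaRates
    logL: float
    k: int
    n: int
    aicc: float

    @property
    def rates12(self) -> np.ndarray:
        """The fitted generator's twelve off-diagonal rates, normalized so
        the A->G rate is 1 (the DNR reporting convention)."""
        r = self.q.off_diagonal_rates()
        return r / r[1]


# ---------------------------------------------------------------------------
# propagator cache

class _Propagator:
    """exp(Q r t) via a one-off eigendecomposition of Q."""

    def __init__(self, q: np.ndarray):
        self.q = q
        self.use_expm = False
        try:
            w, V = scipy.linalg.eig(q)
            Vinv = np.linalg.inv(V)
            if np.linalg.cond(V) > 1e8:
                raise np.linalg.LinAlgError
            self.w, self.V, self.Vinv = w, V, Vinv
        except np.linalg.LinAlgError:
            self.use_expm = True

    def __call__(self, t: float) -> np.ndarray:
        if t < 0:
            raise DomainError("branch length must be >= 0")
        if self.use_expm:
            P = scipy.linalg.expm(self.q * t)
        else:
            P = ((self.V * np.exp(self.w * t)) @ self.Vinv).real
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def many(self, ts: np.ndarray) -> np.ndarray:
        """Propagators for a whole vector of branch lengths, (n, 4, 4)."""
        if self.use_expm:
            return np.stack([self(float(t)) for t in ts])
        E = np.exp(np.multiply.outer(ts, self.w))  # (n, 4) complex
        P = np.einsum("xj,nj,jy->nxy", self.V, E, self.Vinv).real
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=2, keepdims=True)
        return P


# ---------------------------------------------------------------------------
# engine

try:
    from numba import njit as _njit
except ImportError:  # pragma: no cover - numba is a soft dependency
    _njit = None


def _prune_py(children_flat, child_ptr, Pt, part, slog):
    """Postorder pruning pass filling internal rows of ``part``/``slog``
    in place; tip rows must be pre-filled (their scale logs are zero)."""
    nnodes = child_ptr.shape[0] - 1
    npat = part.shape[1]
    for i in range(nnodes):
        lo, hi = child_ptr[i], child_ptr[i + 1]
        if lo == hi:
            continue  # tip
        for p in range(npat):
            part[i, p, 0] = 1.0
            part[i, p, 1] = 1.0
            part[i, p, 2] = 1.0
            part[i, p, 3] = 1.0
            slog[i, p] = 0.0
        for k in range(lo, hi):
            c = children_flat[k]
            P = Pt[c]
            for p in range(npat):
                s0 = part[c, p, 0]
                s1 = part[c, p, 1]
                s2 = part[c, p, 2]
                s3 = part[c, p, 3]
                for x in range(4):
                    m = (P[x, 0] * s0 + P[x, 1] * s1
                         + P[x, 2] * s2 + P[x, 3] * s3)
                    part[i, p, x] *= m
                slog[i, p] += slog[c, p]
        # rescale to prevent underflow; fold the factor into the scale log
        for p in range(npat):
            m = part[i, p, 0]
            for x in range(1, 4):
                if part[i, p, x] > m:
                    m = part[i, p, x]
            if m <= 0.0:
                m = 1.0
            inv = 1.0 / m
            for x in range(4):
                part[i, p, x] *= inv
            slog[i, p] += np.log(m)


_prune_kernel = _njit(cache=True)(_prune_py) if _njit is not None else _prune_py


class PhyloLikelihood:
    """Pruning likelihood of one alignment on one rooted tree.

    The tree topology is frozen at construction; branch lengths and the
    substitution model are mutable so optimizers can re-evaluate cheaply.
    Alignment columns are compressed to unique site patterns.
    """

    def __init__(self, aln: NucAlignment, tree: RootedTree):
        self.aln = aln
        self.tree = tree.copy()
        nodes = list(self.tree.postorder())
        self.nodes = nodes
        self.index = {id(n): i for i, n in enumerate(nodes)}
        self.root_index = self.index[id(self.tree.root)]
        self.children = [[self.index[id(c)] for c in n.children] for n in nodes]
        self.parent = [self.index[id(n.parent)] if n.parent is not None else -1
                       for n in nodes]
        self.lengths = np.array([max(n.length, 0.0) for n in nodes])

        missing = [n.name for n in nodes if n.is_tip and n.name not in aln.names]
        if missing:
            raise LabellingError(f"tree tips absent from alignment: {missing}")
        patterns, counts = aln.site_patterns()
        self.counts = counts.astype(float)
        self.npat = patterns.shape[1]
        self.tipL = {}
        for i, n in enumerate(nodes):
            if n.is_tip:
                self.tipL[i] = STATE_TABLE[patterns[aln.names.index(n.name)]]
        self.tip_idx = np.array(sorted(self.tipL), dtype=int)
        self.tipL_arr = np.stack([self.tipL[i] for i in self.tip_idx])
        # flat child-index arrays for the compiled pruning kernel
        self._children_flat = np.array(
            [c for kids in self.children for c in kids], dtype=np.int64)
        self._child_ptr = np.zeros(len(self.nodes) + 1, dtype=np.int64)
        np.cumsum([len(k) for k in self.children], out=self._child_ptr[1:])

    # -- model ------------------------------------------------------------
    def set_model(self, q: RateMatrix, root_freqs, gamma: GammaRates) -> None:
        self.qmat = q
        self.root_pi = root_freqs.pi if isinstance(root_freqs, BaseFrequencies) \
            else np.asarray(root_freqs, float)
        self.gamma = gamma
        Q = q.q
        self._props = [_Propagator(Q * r) for r in gamma.rates]
        self._logw = np.log(gamma.weights)

    # -- plain pruning ----------------------------------------------------
    def _down_pass(self, cat: int):
        """Partial likelihoods below every node for one rate category.
        Returns (partials, scalelogs) as (nnodes, npat, 4)/(nnodes, npat)
        arrays; tip rows hold the observation indicators."""
        Pt = np.ascontiguousarray(self._props[cat].many(self.lengths))
        part = np.empty((len(self.nodes), self.npat, 4))
        slog = np.zeros((len(self.nodes), self.npat))
        part[self.tip_idx] = self.tipL_arr
        _prune_kernel(self._children_flat, self._child_ptr, Pt, part, slog)
        return part, slog

    def site_logliks(self) -> np.ndarray:
        """Per-pattern log-likelihoods mixed over rate categories."""
        per_cat = np.empty((self.gamma.ncat, self.npat))
        for c in range(self.gamma.ncat):
            part, slog = self._down_pass(c)
            r = self.root_index
            siteL = part[r] @ self.root_pi
            if np.any(siteL <= 0.0) or not np.all(np.isfinite(siteL)):
                bad = int(np.argmin(siteL))
                raise NrevError(f"non-finite site likelihood at pattern {bad}")
            per_cat[c] = np.log(siteL) + slog[r]
        if self.gamma.ncat == 1:
            return per_cat[0]
        return logsumexp(per_cat + self._logw[:, None], axis=0)

    def loglik(self) -> float:
        return float(self.counts @ self.site_logliks())

    # -- branch-length machinery ------------------------------------------
    def _branch_site_logl(self, Gs, t: float) -> float:
        """logL as a function of one branch length, from precomputed
        per-category outer products G[p, x, y] and their scale logs."""
        per_cat = np.empty((self.gamma.ncat, self.npat))
        for c in range(self.gamma.ncat):
            G, sc = Gs[c]
            v = G @ self._props[c](t).ravel()
            v[v <= 0.0] = 1e-300
            per_cat[c] = np.log(v) + sc
        if self.gamma.ncat == 1:
            site = per_cat[0]
        else:
            site = logsumexp(per_cat + self._logw[:, None], axis=0)
        return float(self.counts @ site)

    def preorder_indices(self) -> list:
        """Engine node indices listed in preorder of the internal tree."""
        return [self.index[id(n)] for n in self.tree.preorder()]

    def optimize_branches(self, sweeps: int = 2, bl_max: float = 20.0,
                          xatol: float = 1e-7, only=None) -> float:
        """Coordinate-wise branch-length refinement; returns the final logL.
        The likelihood never decreases relative to the input lengths.
        ``only`` restricts the scalar optimizations to a set of engine node
        indices (the traversal still visits the whole tree)."""
        nonroot = np.array([p >= 0 for p in self.parent])
        self.lengths[nonroot] = np.maximum(self.lengths[nonroot], _MIN_BL)
        logl = self.loglik()
        if only is not None:
            only = set(only)
        for _ in range(sweeps):
            downs = [self._down_pass(c) for c in range(self.gamma.ncat)]
            self._sweep_node(self.root_index, [
                (np.tile(self.root_pi, (self.npat, 1)), np.zeros(self.npat))
                for _ in range(self.gamma.ncat)], downs, bl_max, xatol, only)
            new = self.loglik()
            if new < logl - 1e-9 * max(1.0, abs(logl)):
                break  # numerical stall; keep previous logl conservatively
            if new - logl < 1e-6 * max(1.0, abs(logl)):
                logl = max(logl, new)
                break
            logl = new
        return max(logl, self.loglik())

    def _subtree_hits(self, only):
        """Per-node flag: does the subtree rooted there intersect ``only``?"""
        hits = [False] * len(self.nodes)
        for i, kids in enumerate(self.children):
            hits[i] = (i in only) or any(hits[c] for c in kids)
        return hits

    def _sweep_node(self, u: int, above, downs, bl_max: float, xatol: float,
                    only=None):
        """Visit children of node ``u`` in preorder; ``above`` holds the
        per-category (partial, scalelog) just above ``u`` including the
        root distribution."""
        hits = self._subtree_hits(only) if only is not None else None
        self._sweep_node_inner(u, above, downs, bl_max, xatol, only, hits)

    def _sweep_node_inner(self, u, above, downs, bl_max, xatol, only, hits):
        kids = self.children[u]
        for v in kids:
            need_opt = only is None or v in only
            need_descend = bool(self.children[v]) and (hits is None or hits[v])
            if not need_opt and not need_descend:
                continue
            if need_opt:
                Gs = []
                for c in range(self.gamma.ncat):
                    A, sa = above[c]
                    part, slog = downs[c]
                    F = A.copy()
                    sf = sa.copy()
                    for s in kids:
                        if s == v:
                            continue
                        F = F * (part[s] @ self._props[c](self.lengths[s]).T)
                        sf = sf + slog[s]
                    m = F.max(axis=1)
                    m[m <= 0.0] = 1.0
                    F = F / m[:, None]
                    sf = sf + np.log(m)
                    sc = sf + slog[v]
                    D = part[v]
                    Gs.append(((F[:, :, None] * D[:, None, :]).reshape(self.npat, 16), sc))
                res = minimize_scalar(lambda t: -self._branch_site_logl(Gs, t),
                                      bounds=(_MIN_BL, bl_max), method="bounded",
                                      options={"xatol": xatol})
                cur = self._branch_site_logl(Gs, self.lengths[v])
                if -res.fun > cur:
                    self.lengths[v] = float(res.x)
            if need_descend:
                # above partial for v: rebuild F with the updated sibling
                # lengths, then propagate through v's (updated) branch
                newA = []
                for c in range(self.gamma.ncat):
                    A, sa = above[c]
                    part, slog = downs[c]
                    F = A.copy()
                    sf = sa.copy()
                    for s in kids:
                        if s == v:
                            continue
                        F = F * (part[s] @ self._props[c](self.lengths[s]).T)
                        sf = sf + slog[s]
                    Av = F @ self._props[c](self.lengths[v])
                    m = Av.max(axis=1)
                    m[m <= 0.0] = 1.0
                    Av = Av / m[:, None]
                    sf = sf + np.log(m)
                    newA.append((Av, sf))
                self._sweep_node_inner(v, newA, downs, bl_max, xatol, only, hits)

    # -- write-back -------------------------------------------------------
    def lengths_to_tree(self) -> RootedTree:
        t = self.tree.copy()
        for orig, new in zip(self.tree.postorder(), t.postorder()):
            new.length = float(self.lengths[self.index[id(orig)]])
        return t


# ---------------------------------------------------------------------------
# public operations

def log_likelihood(aln: NucAlignment, tree: RootedTree, q: RateMatrix,
                   root_freqs: BaseFrequencies, gamma: GammaRates | None = None) -> float:
    """Log-likelihood of ``aln`` on ``tree`` under generator ``q`` with the
    given root-state distribution and optional gamma rate mixture."""
    engine = PhyloLikelihood(aln, tree)
    engine.set_model(q, root_freqs, gamma or GammaRates.none())
    return engine.loglik()


def optimize_branch_lengths(aln: NucAlignment, tree: RootedTree, q: RateMatrix,
                            root_freqs: BaseFrequencies,
                            gamma: GammaRates | None = None,
                            sweeps: int = 5) -> RootedTree:
    """Refine branch lengths under a fixed model; logL never decreases."""
    engine = PhyloLikelihood(aln, tree)
    engine.set_model(q, root_freqs, gamma or GammaRates.none())
    engine.optimize_branches(sweeps=sweeps)
    return engine.lengths_to_tree()


def _n_subst_params(family: str) -> int:
    # GTR: 5 free exchangeabilities + 3 free frequencies; NREV6: 5 free
    # class rates; NREV12: 11 free rates; NREV12F: 11 rates + 3 root freqs.
    return {"GTR": 8, "NREV6": 5, "NREV12": 11, "NREV12F": 14}[family]


def _stationary_fast(Q: np.ndarray) -> np.ndarray:
    """Stationary distribution by direct linear solve (optimizer hot path);
    falls back to the robust null-space route on singular systems."""
    A = np.empty((4, 4))
    A[:3] = Q.T[:3]
    A[3] = 1.0
    b = np.array([0.0, 0.0, 0.0, 1.0])
    try:
        pi = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return stationary_distribution(RateMatrix(Q)).pi
    if np.any(pi < -1e-9) or np.max(np.abs(pi @ Q)) > 1e-9 * max(1.0, np.abs(Q).max()):
        return stationary_distribution(RateMatrix(Q)).pi
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def _softmax4(logits3: np.ndarray) -> np.ndarray:
    z = np.concatenate([[0.0], logits3])
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


class _ModelMap:
    """Maps a flat optimizer vector to (Q, root distribution, gamma)."""

    def __init__(self, family: str, emp_pi: np.ndarray, ncat: int,
                 root_override: str | None):
        self.family = family
        self.emp_pi = emp_pi
        self.ncat = ncat
        self.root_override = root_override
        self.n_rates = {"GTR": 5, "NREV6": 5, "NREV12": 11, "NREV12F": 11}[family]
        self.n_logits = 3 if family == "NREV12F" else 0
        self.free_alpha = ncat > 1
        self.nparams = self.n_rates + self.n_logits + (1 if self.free_alpha else 0)

    def bounds(self):
        b = [_LOG_RATE_BOUNDS] * self.n_rates
        b += [(-10.0, 10.0)] * self.n_logits
        if self.free_alpha:
            b.append(_LOG_ALPHA_BOUNDS)
        return b

    def unpack(self, theta: np.ndarray):
        r = np.exp(theta[:self.n_rates])
        if self.family == "GTR":
            # exchangeabilities (a, b=1 ref, c, d, e, f)
            rates6 = np.array([r[0], 1.0, r[1], r[2], r[3], r[4]])
            q = build_gtr_q(rates6, BaseFrequencies(self.emp_pi))
            stat = self.emp_pi
            root, source = stat, "empirical"
        elif self.family == "NREV6":
            rates6 = np.array([r[0], 1.0, r[1], r[2], r[3], r[4]])
            q = build_nrev6_q(rates6)
            stat = _stationary_fast(q.q)
            root, source = stat, "stationary"
        else:
            rates12 = np.concatenate([[r[0], 1.0], r[1:]])  # A->G fixed at 1
            q = build_nrev12_q(rates12)
            stat = _stationary_fast(q.q)
            if self.family == "NREV12F":
                root = _softmax4(theta[self.n_rates:self.n_rates + 3])
                source = "free"
            else:
                root, source = stat, "stationary"
        if self.family in ("NREV6", "NREV12") and self.root_override == "empirical":
            root, source = self.emp_pi, "empirical"
        # normalize to one expected substitution per unit time so the rate
        # block controls only relative rates; the overall scale lives in the
        # branch lengths.  Without this the optimizer zigzags along the
        # rates-vs-lengths scale ridge.
        mu = float(-(stat * np.diag(q.q)).sum())
        q = q.scaled(1.0 / mu)
        if self.free_alpha:
            alpha = float(np.exp(theta[-1]))
            gamma = discretize_gamma(alpha, self.ncat)
        else:
            alpha, gamma = None, GammaRates.none()
        return q, root, gamma, alpha, source

    def pack_init(self, init_rates, init_alpha):
        theta = np.zeros(self.nparams)
        if init_rates is not None:
            r = np.asarray(init_rates, float)
            if r.shape[0] == self.n_rates:
                theta[:self.n_rates] = np.log(np.clip(r, 1e-4, 1e4))
            else:
                raise DomainError(
                    f"init_rates must have length {self.n_rates} for {self.family}")
        if self.free_alpha:
            theta[-1] = np.log(init_alpha if init_alpha else 1.0)
        return theta


def fit_model(aln: NucAlignment, tree: RootedTree, family: str,
              opts: FitOptions | None = None) -> FitResult:
    """Maximum-likelihood fit of one model family on a fixed topology.

    Free rates (with one reference rate fixed at 1), the gamma shape and
    all branch lengths are optimized; NREV12+F additionally estimates
    three free root-frequency parameters.  GTR uses the alignment's
    empirical base frequencies; NREV6/NREV12 use the stationary
    distribution of the fitted generator as the root distribution.
    """
    if family not in FAMILIES:
        raise DomainError(f"unknown model family {family!r}; expected one of {FAMILIES}")
    opts = opts or FitOptions()
    engine = PhyloLikelihood(aln, tree)
    emp = empirical_frequencies(aln)
    # guard against zero frequencies in tiny alignments
    emp = np.clip(emp, 1e-6, None)
    emp /= emp.sum()
    mmap = _ModelMap(family, emp, opts.gamma_ncat, opts.root_freqs)

    def objective(theta):
        q, root, gamma, _, _ = mmap.unpack(theta)
        engine.set_model(q, BaseFrequencies(root), gamma)
        try:
            return -engine.loglik()
        except NrevError:
            return 1e12

    rng = np.random.default_rng(opts.seed)
    best = None
    theta0 = mmap.pack_init(opts.init_rates, opts.init_alpha)
    for restart in range(max(1, opts.n_restarts)):
        theta = theta0.copy()
        if restart > 0:
            theta = theta + rng.normal(0.0, 0.5, size=theta.shape)
        engine.lengths = np.array([max(n.length, _MIN_BL if n.parent is not None else 0.0)
                                   for n in engine.nodes])
        logl = -objective(theta)
        for _ in range(opts.max_rounds):
            res = minimize(objective, theta, method="L-BFGS-B",
                           bounds=mmap.bounds(),
                           options={"maxiter": opts.rate_maxiter, "ftol": 1e-9})
            theta = res.x
            q, root, gamma, _, _ = mmap.unpack(theta)
            engine.set_model(q, BaseFrequencies(root), gamma)
            new = engine.optimize_branches(sweeps=opts.bl_sweeps, bl_max=opts.bl_max)
            if new - logl < opts.rel_tol * max(1.0, abs(new)):
                logl = max(logl, new)
                break
            logl = new
        if best is None or logl > best[0]:
            best = (logl, theta.copy(), engine.lengths.copy())
    logl, theta, lengths = best
    if not np.isfinite(logl):
        raise ConvergenceError("optimizer failed to reach a finite likelihood",
                               best=best)
    engine.lengths = lengths
    q, root, gamma, alpha, source = mmap.unpack(theta)
    engine.set_model(q, BaseFrequencies(root), gamma)
    logl = engine.loglik()
    fitted_tree = engine.lengths_to_tree()
    k = _n_subst_params(family) + (1 if mmap.free_alpha else 0) + len(fitted_tree.branches())
    n = aln.nsites
    if family == "GTR":
        rates = q.free_rates
    elif family == "NREV6":
        rates = q.free_rates
    else:
        rates = tuple(q.off_diagonal_rates())
    return FitResult(family=family, rates=rates, root_freqs=BaseFrequencies(root),
                     root_freq_source=source, alpha=alpha, tree=fitted_tree, q=q,
                     gamma=gamma, logL=logl, k=k, n=n, aicc=aicc(logl, k, n))


def nni_search(aln: NucAlignment, family: str, start_tree: RootedTree,
               seed: int = 0, opts: FitOptions | None = None):
    """Hill-climbing nearest-neighbour-interchange topology search.

    Candidate rearrangements are scored with the current fitted model and
    a branch-length sweep; the best candidate is accepted (with a full
    refit) while it improves the log-likelihood.  Deterministic given
    ``seed``.  Returns ``(tree, FitResult)`` with logL >= the start fit's.
    """
    if start_tree.n_tips < 4:
        raise DomainError("NNI search requires >= 4 taxa")
    opts = replace(opts or FitOptions(), seed=seed)
    fit = fit_model(aln, start_tree, family, opts)
    # hill climb with the fitted model frozen: candidates are scored by
    # re-optimizing only the branches the interchange touches, the best
    # move gets a full branch sweep, and the free parameters are refitted
    # once on the final topology
    cur_tree, cur_logl = fit.tree, fit.logL
    moved = False
    for _ in range(opts.nni_max_rounds):
        best = None
        for cand, _desc, affected in nni_neighbors(cur_tree):
            engine = PhyloLikelihood(aln, cand)
            engine.set_model(fit.q, fit.root_freqs, fit.gamma)
            pre = engine.preorder_indices()
            local = {pre[i] for i in affected}
            score = engine.optimize_branches(sweeps=1, bl_max=opts.bl_max,
                                             xatol=1e-3, only=local)
            if score > cur_logl + 1e-3 and (best is None or score > best[0]):
                best = (score, engine)
        if best is None:
            break
        engine = best[1]
        new_logl = engine.optimize_branches(sweeps=2, bl_max=opts.bl_max,
                                            xatol=1e-6)
        if new_logl <= cur_logl + 1e-6:
            break
        cur_tree, cur_logl = engine.lengths_to_tree(), new_logl
        moved = True
    if moved:
        refit = fit_model(aln, cur_tree, family,
                          replace(opts, init_rates=_free_rates_for_init(fit),
                                  init_alpha=fit.alpha))
        if refit.logL >= fit.logL:
            return refit.tree, refit
    return fit.tree, fit


def _free_rates_for_init(fit: FitResult) -> np.ndarray:
    """Free-rate vector (reference rate dropped) for warm-starting a fit."""
    if fit.family == "GTR" or fit.family == "NREV6":
        r = np.asarray(fit.rates, float)
        r = r / r[1]
        return np.concatenate([[r[0]], r[2:]])
    r = np.asarray(fit.rates12, float)
    return np.concatenate([[r[0]], r[2:]])
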