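"""Synthetic sequence evolution: the DNR ladder, alignment simulation,
API calibration, and the full simulation design.

The simulation study evolves alignments along fixed 'true' trees under
twelve-rate generators whose degree of non-reversibility (DNR) is dialled
by a ladder construction: starting from a reversible baseline rate set
(relative rates A<->C 0.166, A<->G 1, A<->T 0.14, C<->G 0.131,
G<->T 0.118, C<->T 1.101), an offset d is added to the six designated
forward substitutions C->A, G->A, A->T, G->C, T->G and C->T while the
reverse rates are left untouched, so the mean DNR of the resulting rate
set is exactly d.  Root states are drawn from the generator's stationary
distribution, which makes the process stationary along the whole tree
(pi e^{Qt} = pi).
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import NucAlignment, write_fasta
from .errors import CalibrationError, DomainError
from .models import (GammaRates, RateMatrix, build_nrev12_q, normalize_q,
                     stationary_distribution, transition_matrix)
from .trees import Node, RootedTree, write_newick

#: Reversible baseline relative rates in RATE_ORDER
#: (A->C, A->G, A->T, C->A, C->G, C->T, G->A, G->C, G->T, T->A, T->C, T->G).
BASELINE_RATES = (0.166, 1.0, 0.14, 0.166, 0.131, 1.101,
                  1.0, 0.131, 0.118, 0.14, 1.101, 0.118)

#: Indices (in RATE_ORDER) of the six designated forward substitutions that
#: receive the DNR offset: C->A, G->A, A->T, G->C, T->G, C->T.
_FORWARD = (3, 6, 2, 7, 11, 5)

DEFAULT_DNR_LEVELS = tuple(range(0, 22, 2))
DEFAULT_API_TARGETS = (75.0, 80.0, 85.0, 90.0, 95.0)


def ladder_rates(d: float) -> np.ndarray:
    """Twelve-rate vector of the DNR ladder at offset ``d`` >= 0.

    mean_dnr(ladder_rates(d)) == d exactly, by construction.
    """
    if d < 0:
        raise DomainError(f"DNR offset must be >= 0, got {d}")
    r = np.array(BASELINE_RATES, dtype=float)
    r[list(_FORWARD)] += d
    return r


def ladder_matrix(d: float, normalized: bool = False) -> RateMatrix:
    """Generator of the ladder rate set.

    By default the printed relative rates are used as-is: adding the DNR
    offset raises the overall substitution rate (about 9x the baseline at
    d = 8, 21x at d = 20), so on a fixed true tree higher-DNR datasets
    are genuinely more diverged — the effect the accuracy study measures.
    Pass ``normalized=True`` for a generator rescaled to one expected
    substitution per site per unit time at stationarity.
    """
    q = build_nrev12_q(ladder_rates(d))
    return normalize_q(q) if normalized else q


#: Expected substitutions per site per unit time of the (unnormalized)
#: reversible baseline at its stationary distribution.
_BASELINE_RATE = float(-(0.25 * np.diag(
    build_nrev12_q(BASELINE_RATES).q)).sum())


def study_matrix(d: float) -> RateMatrix:
    """Ladder generator on the study's common time scale.

    All ladder matrices are divided by the baseline's expected rate, so
    branch lengths of the true trees read as expected substitutions per
    site *at DNR = 0* and the d-dependent rate growth (about 3x at d = 2
    up to about 21x at d = 20) is preserved.  With this unit choice the
    DNR = 0 cell gives unbiased branch-length inference, so model
    comparisons there measure pure noise.
    """
    return ladder_matrix(d).scaled(1.0 / _BASELINE_RATE)


def simulate_alignment(tree: RootedTree, q: RateMatrix, nsites: int,
                       gamma: GammaRates | None = None, seed: int = 0) -> NucAlignment:
    """Evolve ``nsites`` independent columns along ``tree`` under ``q``.

    Root states are i.i.d. draws from the stationary distribution of
    ``q``; states propagate down each branch with transition matrix
    exp(Q * r_c * t) where r_c is the site's gamma rate multiplier.
    Deterministic given ``seed``.
    """
    if nsites < 1:
        raise DomainError("nsites must be >= 1")
    rng = np.random.default_rng(seed)
    pi = stationary_distribution(q).pi
    gamma = gamma or GammaRates.none()
    cat = (np.zeros(nsites, dtype=int) if gamma.ncat == 1
           else rng.choice(gamma.ncat, size=nsites, p=gamma.weights))
    states = {id(tree.root): rng.choice(4, size=nsites, p=pi)}
    for node in tree.preorder():
        if node.parent is None:
            continue
        parent_states = states[id(node.parent)]
        out = np.empty(nsites, dtype=int)
        for c in range(gamma.ncat):
            P = transition_matrix(q, gamma.rates[c] * node.length)
            cmask = cat == c
            for s in range(4):
                idx = np.flatnonzero(cmask & (parent_states == s))
                if idx.size:
                    out[idx] = rng.choice(4, size=idx.size, p=P[s])
        states[id(node)] = out
    bases = np.array(list("ACGT"))
    names, seqs = [], []
    for t in tree.tips():
        names.append(t.name)
        seqs.append("".join(bases[states[id(t)]]))
    return NucAlignment(names=names, sequences=seqs)


_GAPS = frozenset("-?")


def measure_api(aln: NucAlignment) -> float:
    """Average pairwise identity (%): mean over unordered sequence pairs of
    matching columns / columns where both sequences are ungapped."""
    if aln.ntaxa < 2:
        raise DomainError("API needs >= 2 sequences")
    arrs = [np.frombuffer(s.encode(), dtype=np.uint8) for s in aln.sequences]
    gap_codes = np.array([ord(c) for c in _GAPS], dtype=np.uint8)
    nongap = [~np.isin(a, gap_codes) for a in arrs]
    vals = []
    for i in range(len(arrs)):
        for j in range(i + 1, len(arrs)):
            both = nongap[i] & nongap[j]
            denom = int(both.sum())
            if denom == 0:
                continue  # all-gap overlap: pair excluded
            match = int(((arrs[i] == arrs[j]) & both).sum())
            vals.append(100.0 * match / denom)
    if not vals:
        raise DomainError("no sequence pair has ungapped overlap")
    return float(np.mean(vals))


def scale_tree_to_api(tree: RootedTree, q: RateMatrix, target_api: float,
                      tol: float = 1.0, seed: int = 0, nsim: int = 5,
                      nsites: int = 2000):
    """Find one scalar s multiplying every branch length so alignments
    simulated on the scaled tree have mean API within ``tol`` percentage
    points of ``target_api``.  Bisection on log s against the mean API of
    ``nsim`` calibration simulations of ``nsites`` sites.

    Returns ``(scaled_tree, achieved_api)``.
    """
    if not 0.0 < target_api < 100.0:
        raise DomainError("target API must be in (0, 100)")

    def mean_api(s: float) -> float:
        t = tree.scale_branches(s)
        vals = [measure_api(simulate_alignment(t, q, nsites, seed=seed * 7919 + k))
                for k in range(nsim)]
        return float(np.mean(vals))

    lo, hi = 1e-3, 1e3  # API decreasing in s: api(lo) high, api(hi) low
    api_lo, api_hi = mean_api(lo), mean_api(hi)
    if target_api > api_lo or target_api < api_hi:
        raise CalibrationError(
            f"target API {target_api}% outside achievable range "
            f"[{api_hi:.1f}, {api_lo:.1f}]%")
    s = 1.0
    for _ in range(40):
        a = mean_api(s)
        if abs(a - target_api) <= tol:
            return tree.scale_branches(s), a
        if a > target_api:
            lo = s
        else:
            hi = s
        s = float(np.sqrt(lo * hi))
    a = mean_api(s)
    if abs(a - target_api) > tol:
        raise CalibrationError(
            f"bisection stalled at API {a:.2f}% for target {target_api}%")
    return tree.scale_branches(s), a


def synthetic_true_tree(ntaxa: int = 20, seed: int = 0) -> RootedTree:
    """Seeded Yule (pure-birth) topology with exponential branch lengths,
    a stand-in for a fixed empirical 'true' tree.  Deterministic given
    ``seed``; all branch lengths strictly positive."""
    if ntaxa < 4:
        raise DomainError("need >= 4 taxa")
    rng = np.random.default_rng(seed)
    root = Node()
    tips = [root.add(Node(length=float(rng.exponential(0.1)) + 1e-3))
            for _ in range(2)]
    while len(tips) < ntaxa:
        split = tips.pop(int(rng.integers(len(tips))))
        for _ in range(2):
            tips.append(split.add(Node(length=float(rng.exponential(0.1)) + 1e-3)))
    for i, t in enumerate([n for n in _preorder(root) if not n.children]):
        t.name = f"t{i + 1}"
    return RootedTree(root)


def _preorder(node):
    stack = [node]
    while stack:
        n = stack.pop()
        yield n
        stack.extend(reversed(n.children))


def dataset_seed(master: int, tree_index: int, dnr_index: int, rep: int) -> int:
    """Stable per-dataset seed derived from the master seed; < 2^31."""
    ss = np.random.SeedSequence([int(master), tree_index, dnr_index, rep])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class SimulationDesign:
    """The full factorial simulation layout: true trees (one per API
    level) x DNR levels x replicates."""

    api_targets: tuple = DEFAULT_API_TARGETS
    dnr_levels: tuple = DEFAULT_DNR_LEVELS
    replicates: int = 100
    nsites: int = 2000
    ntaxa: int = 20
    seed: int = 0
    api_tol: float = 1.0
    trees: dict = field(default_factory=dict)  # api -> (RootedTree, achieved_api)

    def __post_init__(self):
        if self.replicates < 1:
            raise DomainError("replicates must be >= 1")
        if any(d < 0 for d in self.dnr_levels):
            raise DomainError("DNR levels must be >= 0")

    @property
    def size(self) -> int:
        return len(self.api_targets) * len(self.dnr_levels) * self.replicates

    def cells(self):
        """Yield one provenance row per dataset (no simulation performed)."""
        for ti, api in enumerate(self.api_targets):
            for di, d in enumerate(self.dnr_levels):
                for rep in range(self.replicates):
                    yield {
                        "tree_id": f"api{api:g}",
                        "api": api,
                        "dnr": d,
                        "replicate": rep,
                        "seed": dataset_seed(self.seed, ti, di, rep),
                    }

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(list(self.cells()))

    def materialize_trees(self) -> dict:
        """Generate the base synthetic tree and scale it to each API
        target (calibrated with the reversible baseline generator)."""
        if self.trees:
            return self.trees
        base = synthetic_true_tree(self.ntaxa, seed=self.seed)
        q0 = study_matrix(0.0)
        for api in self.api_targets:
            tree, achieved = scale_tree_to_api(base, q0, api, tol=self.api_tol,
                                               seed=self.seed)
            self.trees[api] = (tree, achieved)
        return self.trees

    def config_hash(self) -> str:
        key = repr((self.api_targets, self.dnr_levels, self.replicates,
                    self.nsites, self.ntaxa, self.seed))
        return hashlib.sha256(key.encode()).hexdigest()[:12]


def run_design(design: SimulationDesign, outdir) -> pd.DataFrame:
    """Materialize every dataset of ``design`` to ``outdir`` (one FASTA per
    dataset, one Newick per true tree) and return the manifest, which is
    also written as TSV."""
    os.makedirs(outdir, exist_ok=True)
    design.materialize_trees()
    header = f"nrevphylo design seed={design.seed} config={design.config_hash()}"
    for api, (tree, _a) in design.trees.items():
        write_newick(tree, os.path.join(outdir, f"true_api{api:g}.nwk"), header=header)
    qs = {d: study_matrix(d) for d in design.dnr_levels}
    rows = []
    for cell in design.cells():
        tree = design.trees[cell["api"]][0]
        aln = simulate_alignment(tree, qs[cell["dnr"]], design.nsites,
                                 seed=cell["seed"])
        fname = (f"sim_{cell['tree_id']}_dnr{cell['dnr']:g}_"
                 f"rep{cell['replicate']:03d}.fasta")
        write_fasta(aln, os.path.join(outdir, fname))
        rows.append({**cell, "path": fname})
    manifest = pd.DataFrame(rows)
    mpath = os.path.join(outdir, "manifest.tsv")
    with open(mpath, "w") as fh:
        fh.write(f"# {header}\n")
        manifest.to_csv(fh, sep="\t", index=False)
    return manifest
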