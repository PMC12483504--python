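"""Tree-accuracy scoring and the paired GTR-vs-NREV12 comparison.

Inferred trees are scored against the simulation's true tree with the
weighted Robinson-Foulds (wRF) distance: both trees are unrooted, and the
distance is the sum over the union of their bipartitions of the absolute
branch-length difference (a missing bipartition contributes its full
weight; pendant edges are included).  Because the non-reversible search
returns rooted trees while GTR inference is rooting-agnostic, unrooting
before comparison puts both models on a common footing.

The study itself mirrors a factorial simulation design: for every
simulated dataset a tree is inferred under GTR and under NREV12 from a
common neighbor-joining start, both are scored against the true tree, and
per (API, DNR) cell a two-sided paired t-test compares the two models,
with Holm adjustment across the DNR levels of each API panel.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import ttest_rel
from statsmodels.stats.multitest import multipletests

from .alignment import NucAlignment
from .errors import DomainError, LabellingError
from .likelihood import FitOptions, nni_search
from .simulate import SimulationDesign, simulate_alignment, study_matrix
from .trees import RootedTree, unrooted_splits


def wrf_distance(t1: RootedTree, t2: RootedTree) -> float:
    """Weighted Robinson-Foulds distance between two trees on the same
    tip set (unrooted; pendant edges included)."""
    if set(t1.tip_labels()) != set(t2.tip_labels()):
        raise LabellingError("trees have different tip sets")
    s1, s2 = unrooted_splits(t1), unrooted_splits(t2)
    keys = set(s1) | set(s2)
    return float(sum(abs(s1.get(k, 0.0) - s2.get(k, 0.0)) for k in keys))


def rf_distance(t1: RootedTree, t2: RootedTree) -> int:
    """Unweighted Robinson-Foulds split count (nontrivial splits only)."""
    if set(t1.tip_labels()) != set(t2.tip_labels()):
        raise LabellingError("trees have different tip sets")
    s1 = {k for k in unrooted_splits(t1) if len(k) > 1}
    s2 = {k for k in unrooted_splits(t2) if len(k) > 1}
    return len(s1 ^ s2)


def paired_model_test(wrf_a, wrf_b):
    """Two-sided paired t-test on per-dataset wRF differences.

    Returns ``(t, p)``.  If every difference is zero the test is
    degenerate and ``(0.0, 1.0)`` is returned.
    """
    a = np.asarray(wrf_a, float)
    b = np.asarray(wrf_b, float)
    if a.shape != b.shape or a.size < 3:
        raise DomainError("paired test needs equal-length vectors of >= 3 values")
    d = a - b
    if np.allclose(d, 0.0):
        return 0.0, 1.0
    if np.std(d, ddof=1) == 0.0:
        return float(np.inf * np.sign(d[0])), 0.0
    t, p = ttest_rel(a, b)
    return float(t), float(p)


def adjust_pvalues(raw, method: str = "holm") -> np.ndarray:
    """Holm step-down adjustment (adjusted >= raw, order-preserving)."""
    p = np.asarray(raw, float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise DomainError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    if p.size == 1:
        return p.copy()
    return multipletests(p, method=method)[1]


# ---------------------------------------------------------------------------
# neighbor-joining starting tree

def jc_distance_matrix(aln: NucAlignment) -> np.ndarray:
    """Jukes-Cantor-corrected pairwise distances (saturation capped)."""
    arrs = [np.frombuffer(s.encode(), np.uint8) for s in aln.sequences]
    n = len(arrs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = float(np.mean(arrs[i] != arrs[j]))
            p = min(p, 0.74)
            d = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
            D[i, j] = D[j, i] = d
    return D


def nj_start_tree(aln: NucAlignment) -> RootedTree:
    """Model-neutral neighbor-joining tree (JC distances), midpoint-rooted,
    used as the common starting point for GTR and NREV12 searches."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    dm = DistanceMatrix(jc_distance_matrix(aln), ids=aln.names)
    sk = nj(dm)
    try:
        sk = sk.root_at_midpoint()
    except Exception:
        pass
    tree = RootedTree.from_newick(str(sk))
    for node in tree.preorder():
        if node.length < 0:
            node.length = 0.0
    # force a bifurcating root (wrap extra children under a zero branch)
    root = tree.root
    while len(root.children) > 2:
        extra = root.children.pop()
        root.children[-1] = _merge(root.children[-1], extra)
    return RootedTree(root)


def _merge(a, b):
    from .trees import Node
    m = Node(length=0.0)
    for c in (a, b):
        c.parent = m
        m.children.append(c)
    m.parent = a.parent
    return m


# ---------------------------------------------------------------------------
# the accuracy study

@dataclass
class StudySummary:
    """Per-dataset records plus per-cell aggregates and paired tests."""

    records: pd.DataFrame   # one row per dataset: api, dnr, rep, wrf_GTR, wrf_NREV12
    summary: pd.DataFrame   # one row per (api, dnr, model): mean/quantiles of wRF
    tests: pd.DataFrame     # one row per (api, dnr): t, raw p, adjusted p, flag
    n_failed: int = 0


def accuracy_study(design: SimulationDesign, fit_opts: FitOptions | None = None,
                   families=("GTR", "NREV12")) -> StudySummary:
    """Run the full inference-accuracy experiment over a materialized
    design: simulate each dataset, infer a tree per model family by NNI
    search from a shared NJ start, score with wRF, aggregate, and run the
    paired tests.  Fully deterministic given the design's master seed."""
    design.materialize_trees()
    fit_opts = fit_opts or FitOptions(gamma_ncat=1, max_rounds=4, rate_maxiter=50)
    qs = {d: study_matrix(d) for d in design.dnr_levels}
    rows = []
    n_failed = 0
    for cell in design.cells():
        true_tree = design.trees[cell["api"]][0]
        aln = simulate_alignment(true_tree, qs[cell["dnr"]], design.nsites,
                                 seed=cell["seed"])
        try:
            start = nj_start_tree(aln)
            row = dict(cell)
            opts = fit_opts
            for fam in families:
                tree, fit = nni_search(aln, fam, start, seed=cell["seed"],
                                       opts=opts)
                row[f"wrf_{fam}"] = wrf_distance(tree, true_tree)
                if fam == "GTR" and "NREV12" in families:
                    # warm-start the free-rate search from the GTR fit
                    # (GTR is nested in NREV12, so this seeds near the
                    # reversible submanifold and converges much faster)
                    r12 = fit.rates12
                    opts = replace(fit_opts,
                                   init_rates=np.concatenate([[r12[0]], r12[2:]]))
            rows.append(row)
        except Exception:
            n_failed += 1
    records = pd.DataFrame(rows)

    summaries = []
    tests = []
    for (api, dnr), grp in records.groupby(["api", "dnr"]):
        for fam in families:
            w = grp[f"wrf_{fam}"]
            summaries.append({"api": api, "dnr": dnr, "model": fam,
                              "mean_wrf": w.mean(), "median_wrf": w.median(),
                              "q25": w.quantile(0.25), "q75": w.quantile(0.75),
                              "n": len(w)})
        t, p = paired_model_test(grp[f"wrf_{families[0]}"],
                                 grp[f"wrf_{families[1]}"])
        tests.append({"api": api, "dnr": dnr, "t": t, "p_raw": p})
    tests = pd.DataFrame(tests)
    adj = np.empty(len(tests))
    for api, idx in tests.groupby("api").groups.items():
        adj[np.asarray(idx)] = adjust_pvalues(tests.loc[idx, "p_raw"].values)
    tests["p_adj"] = adj
    tests["significant"] = tests["p_adj"] < 0.05
    return StudySummary(records=records, summary=pd.DataFrame(summaries),
                        tests=tests, n_failed=n_failed)
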