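"""Independent brute-force oracles shared by the test suite."""

import itertools

import numpy as np

import nrevphylo as nv
from nrevphylo.models import transition_matrix

IDX = {b: i for i, b in enumerate("ACGT")}
AMBIG = {"N": (1, 1, 1, 1), "-": (1, 1, 1, 1), "R": (1, 0, 1, 0), "Y": (0, 1, 0, 1)}


def brute_force_loglik(aln, tree, q, pi, gamma=None):
    """Exhaustive enumeration over all internal-state assignments."""
    gamma = gamma or nv.GammaRates.none()
    nodes = list(tree.postorder())
    internal = [n for n in nodes if n.children]
    tips = [n for n in nodes if not n.children]
    total = 0.0
    for site in range(aln.nsites):
        siteL = 0.0
        for c in range(gamma.ncat):
            Ps = {id(n): transition_matrix(q, gamma.rates[c] * n.length)
                  for n in nodes if n.parent is not None}
            s = 0.0
            for assign in itertools.product(range(4), repeat=len(internal)):
                st = {id(n): a for n, a in zip(internal, assign)}
                for term_states in _tip_expansions(tips, aln, site):
                    st.update(term_states)
                    p = pi.pi[st[id(tree.root)]]
                    for n in nodes:
                        if n.parent is not None:
                            p *= Ps[id(n)][st[id(n.parent)], st[id(n)]]
                    s += p
            siteL += gamma.weights[c] * s
        total += np.log(siteL)
    return total


def _tip_expansions(tips, aln, site):
    """Expand ambiguous tip states into all compatible assignments."""
    choices = []
    for t in tips:
        ch = aln.sequence(t.name)[site]
        if ch in AMBIG:
            states = [i for i, ok in enumerate(AMBIG[ch]) if ok]
        else:
            states = [IDX[ch]]
        choices.append([(id(t), s) for s in states])
    for combo in itertools.product(*choices):
        yield dict(combo)


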