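"""Equal-rates two-state Markov model on a phylogeny.

Presence/absence of post-reproductive lifespans is modelled as a
continuous-time Markov chain with a single instantaneous rate q in
both directions.  On a branch of length t the chain stays in its state
with probability (1 + exp(-2 q t)) / 2 and switches with probability
(1 - exp(-2 q t)) / 2.  The tree likelihood uses the pruning
(post-order) algorithm with a uniform root prior — the stationary
distribution of the symmetric chain.  The rate is fitted by bounded
scalar maximum likelihood, and per-node marginal ("proportional")
probabilities of each state are obtained by combining downward
conditional likelihoods with the outside likelihood of the rest of the
tree, equivalent to re-rooting at each node.

Trees are read from newick text (via dendropy); polytomies are handled
natively by the pruning product.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar


@dataclass
class _Node:
    index: int
    label: Optional[str]
    parent: Optional[int]
    edge_length: float
    children: List[int]

    @property
    def is_leaf(self) -> bool:
        return not self.children


class Tree:
    """Rooted tree with branch lengths; nodes stored in postorder."""

    def __init__(self, nodes: List[_Node]):
        self.nodes = nodes
        self.tip_labels = [n.label for n in nodes if n.is_leaf]
        if len(set(self.tip_labels)) != len(self.tip_labels):
            raise ValueError("duplicate tip labels")
        for n in nodes:
            if n.edge_length < 0:
                raise ValueError("negative branch length")

    @property
    def root_index(self) -> int:
        return len(self.nodes) - 1  # postorder: root last

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def postorder(self):
        return self.nodes

    def preorder(self):
        return reversed(self.nodes)

    @property
    def height(self) -> float:
        depth = np.zeros(len(self.nodes))
        for n in self.preorder():
            if n.parent is not None:
                depth[n.index] = depth[n.parent] + n.edge_length
        return float(depth.max()) if len(depth) else 0.0

    def internal_ids(self) -> List[str]:
        return [f"node_{n.index}" for n in self.nodes if not n.is_leaf]


def read_newick(text: str) -> Tree:
    """Parse a rooted newick string; every non-root branch needs a length."""
    if not text or not text.strip():
        raise ValueError("empty newick string")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise ValueError(f"malformed newick: {exc}") from exc
    nodes: List[_Node] = []
    index_of = {}
    for dnode in dtree.postorder_node_iter():
        idx = len(nodes)
        index_of[dnode] = idx
        children = [index_of[c] for c in dnode.child_nodes()]
        if dnode.parent_node is None:
            length = float(dnode.edge.length or 0.0)
            parent = None
        else:
            if dnode.edge.length is None:
                raise ValueError("branch without a length")
            length = float(dnode.edge.length)
            parent = None  # filled below once parents are indexed
        label = None
        if not children:
            if dnode.taxon is None or not dnode.taxon.label:
                raise ValueError("unlabelled tip")
            label = dnode.taxon.label
        nodes.append(_Node(idx, label, parent, length, children))
    for n in nodes:
        for c in n.children:
            nodes[c].parent = n.index
    tree = Tree(nodes)
    if tree.n_tips < 2:
        raise ValueError("tree needs at least 2 tips")
    return tree


def transition_probability(q: float, t: float) -> np.ndarray:
    """2x2 transition matrix of the symmetric two-state chain."""
    if q < 0 or t < 0:
        raise ValueError("rate and branch length must be non-negative")
    same = (1.0 + math.exp(-2.0 * q * t)) / 2.0
    diff = 1.0 - same
    return np.array([[same, diff], [diff, same]])


def _check_states(tree: Tree, states: Dict[str, int]) -> None:
    missing = [lab for lab in tree.tip_labels if lab not in states]
    if missing:
        raise ValueError(f"missing tip states: {missing}")
    bad = {lab: states[lab] for lab in tree.tip_labels if states[lab] not in (0, 1)}
    if bad:
        raise ValueError(f"states must be 0/1, got {bad}")


def _down_pass(tree: Tree, states: Dict[str, int], q: float):
    """Scaled downward conditional likelihoods and the total log-likelihood.

    Returns (down, log_scale) where down[i] is the conditional
    likelihood vector at node i scaled to max 1, and log_scale the sum
    of the removed log factors.
    """
    down = np.zeros((len(tree.nodes), 2))
    log_scale = 0.0
    for n in tree.postorder():
        if n.is_leaf:
            down[n.index, states[n.label]] = 1.0
        else:
            vec = np.ones(2)
            for c in n.children:
                p = transition_probability(q, tree.nodes[c].edge_length)
                vec = vec * (p @ down[c])
            top = vec.max()
            if top == 0.0:
                return down, -math.inf
            down[n.index] = vec / top
            log_scale += math.log(top)
    return down, log_scale


def er_loglik(tree: Tree, states: Dict[str, int], q: float) -> float:
    """Exact log-likelihood under the equal-rates chain, uniform root prior."""
    if q < 0:
        raise ValueError("rate must be non-negative")
    _check_states(tree, states)
    down, log_scale = _down_pass(tree, states, q)
    if log_scale == -math.inf:
        return -math.inf
    root_l = 0.5 * down[tree.root_index].sum()
    if root_l <= 0.0:
        return -math.inf
    return math.log(root_l) + log_scale


@dataclass
class AncestralReconstruction:
    """Fitted rate, log-likelihood, and per-internal-node marginals."""

    tree: Tree = field(repr=False)
    rate: float
    log_likelihood: float
    prob_present: Dict[str, float]  # internal node id -> P(state 1 | data)
    at_bound: bool = False

    def to_dict(self) -> dict:
        nodes = []
        for n in self.tree.nodes:
            if n.is_leaf:
                continue
            children = [
                self.tree.nodes[c].label if self.tree.nodes[c].is_leaf else f"node_{c}"
                for c in n.children
            ]
            nodes.append(
                {
                    "node": f"node_{n.index}",
                    "children": children,
                    "prob_present": self.prob_present[f"node_{n.index}"],
                }
            )
        return {
            "rate": self.rate,
            "log_likelihood": self.log_likelihood,
            "at_bound": self.at_bound,
            "nodes": nodes,
        }


def ancestral_marginals(tree: Tree, states: Dict[str, int], q: float) -> AncestralReconstruction:
    """Marginal state probabilities at internal nodes given tip data and q.

    Combines downward conditional likelihoods with the outside
    likelihood of the remainder of the tree under the uniform root
    prior; per node the two states' probabilities sum to 1.
    """
    _check_states(tree, states)
    down, log_scale = _down_pass(tree, states, q)
    if log_scale == -math.inf:
        raise ValueError("tip configuration impossible under this rate")
    out = np.zeros((len(tree.nodes), 2))
    out[tree.root_index] = 0.5
    for n in tree.preorder():
        if n.is_leaf:
            continue
        # partial products over children seen from the parent state
        child_msgs = {}
        for c in n.children:
            p = transition_probability(q, tree.nodes[c].edge_length)
            child_msgs[c] = p @ down[c]
        for c in n.children:
            sibling_prod = out[n.index].copy()
            for b in n.children:
                if b != c:
                    sibling_prod = sibling_prod * child_msgs[b]
            p = transition_probability(q, tree.nodes[c].edge_length)
            out[c] = p.T @ sibling_prod
    probs: Dict[str, float] = {}
    for n in tree.nodes:
        if n.is_leaf:
            continue
        joint = down[n.index] * out[n.index]
        total = joint.sum()
        if total <= 0:
            raise ValueError("zero marginal normalizer (impossible configuration)")
        probs[f"node_{n.index}"] = float(joint[1] / total)
    loglik = er_loglik(tree, states, q)
    return AncestralReconstruction(tree, float(q), loglik, probs)


def fit_er_rate(tree: Tree, states: Dict[str, int], bounds=None) -> AncestralReconstruction:
    """Maximum-likelihood transition rate plus the reconstruction at it.

    Bounded scalar optimization over [1e-8, 100 / tree height] by
    default.  With all tips in one state the likelihood is monotone
    decreasing in q, so the lower bound is returned with ``at_bound``
    set.
    """
    _check_states(tree, states)
    if bounds is None:
        height = tree.height
        if height <= 0:
            raise ValueError("tree has zero height")
        bounds = (1e-8, 100.0 / height)
    lo, hi = bounds
    observed = {states[lab] for lab in tree.tip_labels}
    if len(observed) == 1:
        recon = ancestral_marginals(tree, states, lo)
        recon.at_bound = True
        return recon
    res = minimize_scalar(
        lambda q: -er_loglik(tree, states, q),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    q_hat = float(res.x)
    recon = ancestral_marginals(tree, states, q_hat)
    recon.at_bound = bool(q_hat <= lo * (1 + 1e-6) or q_hat >= hi * (1 - 1e-6))
    return recon


def simulate_er_states(tree: Tree, q: float, seed: int = 0) -> Dict[str, int]:
    """Simulate tip states under the equal-rates chain (uniform root state)."""
    rng = np.random.default_rng(seed)
    state = np.zeros(len(tree.nodes), dtype=int)
    for n in tree.preorder():
        if n.parent is None:
            state[n.index] = rng.integers(2)
        else:
            p = transition_probability(q, n.edge_length)
            state[n.index] = rng.choice(2, p=p[state[n.parent]])
    return {n.label: int(state[n.index]) for n in tree.nodes if n.is_leaf}
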