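"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's pruning/message-passing code:
transition probabilities come from scipy's matrix exponential and the
likelihood/posteriors from explicit summation over all joint internal
state assignments.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.linalg import expm


def ctmc_matrix(g: float, l: float, t: float) -> np.ndarray:
    return expm(np.array([[-g, g], [l, -l]]) * t)


def _joint_prob(tree, profile, assign, g, l, prior) -> float:
    p = prior[assign[tree.root]]
    for node in tree.postorder():
        if node.parent is None:
            continue
        P = ctmc_matrix(g, l, node.length)
        parent_state = assign[node.parent]
        if node.children:
            p *= P[parent_state, assign[node.name]]
        else:
            obs = profile.states.get(node.name)
            if obs is not None:
                p *= P[parent_state, obs]
    return p


def enum_likelihood(tree, profile, g, l, prior=None) -> float:
    """Total likelihood by summation over all internal-state assignments."""
    if prior is None:
        prior = np.array([l / (g + l), g / (g + l)])
    internal = [n.name for n in tree.postorder() if n.children]
    total = 0.0
    for states in itertools.product([0, 1], repeat=len(internal)):
        total += _joint_prob(tree, profile, dict(zip(internal, states)), g, l, prior)
    return total


def enum_loglik(tree, profile, g, l, prior=None) -> float:
    return math.log(enum_likelihood(tree, profile, g, l, prior))


def enum_posteriors(tree, profile, g, l, prior=None) -> dict[str, float]:
    """Marginal P(node = present | data) by joint enumeration.

    Leaves with observations are clamped; missing leaves are marginalized
    like internal nodes.
    """
    if prior is None:
        prior = np.array([l / (g + l), g / (g + l)])
    free = [n.name for n in tree.postorder()
            if n.children or profile.states.get(n.name) is None]
    num = {n: 0.0 for n in free}
    denom = 0.0
    for states in itertools.product([0, 1], repeat=len(free)):
        assign = dict(zip(free, states))
        full = dict(assign)
        for n in tree.postorder():
            if not n.children and profile.states.get(n.name) is not None:
                full[n.name] = profile.states[n.name]
        p = prior[full[tree.root]]
        for node in tree.postorder():
            if node.parent is None:
                continue
            P = ctmc_matrix(g, l, node.length)
            p *= P[full[node.parent], full[node.name]]
        denom += p
        for n in free:
            if full[n] == 1:
                num[n] += p
    post = {n: num[n] / denom for n in free}
    for n in tree.postorder():
        if not n.children and profile.states.get(n.name) is not None:
            post[n.name] = float(profile.states[n.name])
    return post
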