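"""Two-state (absent/present) gain/loss model on a phylogeny.

The model is a continuous-time Markov chain with gain rate ``g`` (0 -> 1)
and loss rate ``l`` (1 -> 0) running along the branches of a fixed tree
(branch lengths are never re-estimated).  Likelihoods use Felsenstein
pruning; marginal ancestral posteriors use inside-outside (up-down)
message passing.  An optional rate-category mixture is supported: the
per-trait likelihood is the weighted sum of per-category likelihoods, and
posteriors mix with the data-conditional category weights.

Everything is vectorized over traits: a collection of phyletic profiles
on the same tree is processed as one (n_traits, n_leaves) matrix.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .treeio import Phylogeny

logger = logging.getLogger(__name__)

RATE_BOUNDS = (1e-6, 1e3)

__all__ = [
    "PhyleticProfile",
    "GainLossModel",
    "PosteriorProfile",
    "transition_matrix",
    "pruning_loglik",
    "fit_rates",
    "node_posteriors",
    "marginal_ml_states",
    "profiles_to_matrix",
    "read_profiles_tsv",
    "write_profiles_tsv",
    "write_posteriors_tsv",
]


@dataclass
class PhyleticProfile:
    """Presence/absence of one trait over the genomes at the leaves.

    ``states`` maps genome label -> 0 (absent), 1 (present) or None
    (missing; the leaf contributes partial likelihood (1, 1)).
    """

    trait_id: str
    states: dict[str, int | None]

    def validate(self, tree: Phylogeny) -> None:
        leaf_set = tree.leaf_set()
        bad = [k for k in self.states if k not in leaf_set]
        if bad:
            raise ValueError(f"profile {self.trait_id!r} references non-leaf labels: {bad}")
        if not any(v is not None for v in self.states.values()):
            raise ValueError(f"profile {self.trait_id!r} has no observed leaf")


@dataclass
class GainLossModel:
    """Gain/loss rate categories with a root prior.

    ``categories`` is a list of (gain, loss, weight); weights sum to 1.
    ``root_prior`` is "stationary" (pi1 = g/(g+l) per category) or an
    explicit (p0, p1) pair applied to every category.
    """

    categories: list[tuple[float, float, float]]
    root_prior: str | tuple[float, float] = "stationary"
    loglik: float | None = None

    def __post_init__(self) -> None:
        w = sum(c[2] for c in self.categories)
        if not math.isclose(w, 1.0, rel_tol=1e-9):
            raise ValueError("category weights must sum to 1")
        for g, l, _ in self.categories:
            if not (RATE_BOUNDS[0] <= g <= RATE_BOUNDS[1]) or not (
                RATE_BOUNDS[0] <= l <= RATE_BOUNDS[1]
            ):
                raise ValueError(f"rates ({g}, {l}) outside bounds {RATE_BOUNDS}")

    @classmethod
    def single(cls, gain: float, loss: float, root_prior="stationary") -> "GainLossModel":
        return cls(categories=[(gain, loss, 1.0)], root_prior=root_prior)

    def prior(self, gain: float, loss: float) -> np.ndarray:
        if self.root_prior == "stationary":
            r = gain + loss
            return np.array([loss / r, gain / r])
        p0, p1 = self.root_prior
        if not math.isclose(p0 + p1, 1.0, rel_tol=1e-9):
            raise ValueError("explicit root prior must sum to 1")
        return np.array([p0, p1])


@dataclass
class PosteriorProfile:
    """Marginal posterior probability of presence per node for one trait."""

    trait_id: str
    posteriors: dict[str, float]

    def __getitem__(self, node: str) -> float:
        return self.posteriors[node]


def transition_matrix(g: float, l: float, t: float) -> np.ndarray:
    """Closed-form 2x2 transition matrix of the gain/loss chain.

    With r = g + l and pi1 = g/r:  P01(t) = pi1 (1 - e^{-rt}),
    P10(t) = pi0 (1 - e^{-rt}); rows sum to 1.  t = 0 gives the identity.
    """
    if g <= 0 or l <= 0:
        raise ValueError("rates must be positive")
    if t < 0:
        raise ValueError("branch length must be non-negative")
    r = g + l
    decay = 1.0 - math.exp(-r * t)
    p01 = (g / r) * decay
    p10 = (l / r) * decay
    return np.array([[1.0 - p01, p01], [p10, 1.0 - p10]])


# ---------------------------------------------------------------------------
# vectorized core


def profiles_to_matrix(
    profiles: list[PhyleticProfile], tree: Phylogeny
) -> tuple[np.ndarray, list[str], list[str]]:
    """Stack profiles into an (n_traits, n_leaves) float matrix.

    Missing observations become NaN.  Returns (matrix, trait_ids, leaves).
    """
    leaves = tree.leaves()
    idx = {lf: i for i, lf in enumerate(leaves)}
    X = np.full((len(profiles), len(leaves)), np.nan)
    for t, prof in enumerate(profiles):
        prof.validate(tree)
        for label, state in prof.states.items():
            if state is not None:
                X[t, idx[label]] = state
    return X, [p.trait_id for p in profiles], leaves


def _leaf_partials(X: np.ndarray) -> np.ndarray:
    """(n_traits, n_leaves, 2) conditional likelihoods at the leaves."""
    n_traits, n_leaves = X.shape
    L = np.ones((n_traits, n_leaves, 2))
    obs0 = X == 0
    obs1 = X == 1
    L[obs0, 1] = 0.0
    L[obs1, 0] = 0.0
    return L


def _upward(
    tree: Phylogeny, X: np.ndarray, g: float, l: float
) -> tuple[dict[str, np.ndarray], np.ndarray, list[str]]:
    """Felsenstein pruning pass.

    Returns (partials per node (n_traits, 2), per-trait log scale factors,
    node postorder).  Partials are rescaled per node; the dropped factors
    accumulate in the log-scale vector.
    """
    leaves = tree.leaves()
    leaf_idx = {lf: i for i, lf in enumerate(leaves)}
    leafL = _leaf_partials(X)
    n_traits = X.shape[0]
    partials: dict[str, np.ndarray] = {}
    logscale = np.zeros(n_traits)
    order: list[str] = []
    for node in tree.postorder():
        order.append(node.name)
        if node.is_leaf:
            partials[node.name] = leafL[:, leaf_idx[node.name], :]
            continue
        acc = np.ones((n_traits, 2))
        for child in node.children:
            P = transition_matrix(g, l, tree.nodes[child].length)
            acc = acc * (partials[child] @ P.T)
        mx = acc.max(axis=1)
        mx = np.where(mx > 0, mx, 1.0)
        logscale += np.log(mx)
        partials[node.name] = acc / mx[:, None]
    return partials, logscale, order


def _category_logliks(
    tree: Phylogeny, X: np.ndarray, model: GainLossModel
) -> np.ndarray:
    """(n_categories, n_traits) per-category log-likelihoods."""
    out = []
    for g, l, _w in model.categories:
        partials, logscale, _ = _upward(tree, X, g, l)
        prior = model.prior(g, l)
        lik = partials[tree.root] @ prior
        with np.errstate(divide="ignore"):
            out.append(np.log(lik) + logscale)
    return np.vstack(out)


def loglik_matrix(tree: Phylogeny, X: np.ndarray, model: GainLossModel) -> np.ndarray:
    """Per-trait log-likelihood, mixing categories before the log."""
    cat = _category_logliks(tree, X, model)
    logw = np.log([w for _, _, w in model.categories])[:, None]
    m = (cat + logw).max(axis=0)
    return m + np.log(np.exp(cat + logw - m).sum(axis=0))


def pruning_loglik(
    tree: Phylogeny, profile: PhyleticProfile, model: GainLossModel
) -> float:
    """Log-likelihood of one phyletic profile under the model."""
    X, _, _ = profiles_to_matrix([profile], tree)
    return float(loglik_matrix(tree, X, model)[0])


def fit_rates(
    tree: Phylogeny,
    profiles: list[PhyleticProfile],
    n_categories: int = 1,
    root_prior: str | tuple[float, float] = "stationary",
    n_starts: int = 9,
) -> GainLossModel:
    """Maximum-likelihood gain/loss rates over a profile collection.

    Optimizes log-rates (shared across profiles, per category) with
    L-BFGS-B from a fixed grid of starting points; branch lengths are
    untouched.  A rate pinned at its bound (all-present / all-absent
    collections) is returned at the bound with a logged warning.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    X, _, _ = profiles_to_matrix(profiles, tree)
    lo, hi = math.log(RATE_BOUNDS[0]), math.log(RATE_BOUNDS[1])

    if n_categories == 1:
        def objective(theta):
            model = GainLossModel.single(math.exp(theta[0]), math.exp(theta[1]), root_prior)
            return -loglik_matrix(tree, X, model).sum()

        starts = [
            (math.log(a), math.log(b))
            for a in (0.1, 1.0, 10.0)
            for b in (0.1, 1.0, 10.0)
        ][:n_starts]
        best = None
        for s in starts:
            res = minimize(
                objective, s, method="L-BFGS-B",
                bounds=[(lo, hi), (lo, hi)],
                options={"ftol": 1e-10, "gtol": 1e-8},
            )
            if best is None or res.fun < best.fun:
                best = res
        g, l = math.exp(best.x[0]), math.exp(best.x[1])
        for name, v in (("gain", g), ("loss", l)):
            if math.isclose(v, RATE_BOUNDS[0]) or math.isclose(v, RATE_BOUNDS[1]):
                logger.warning("%s rate hit bound %.3g during fitting", name, v)
        model = GainLossModel.single(g, l, root_prior)
        model.loglik = -float(best.fun)
        return model

    # K-category mixture: log-rates per category plus weight logits
    K = n_categories

    def unpack(theta):
        rates = theta[: 2 * K].reshape(K, 2)
        logits = np.concatenate([theta[2 * K:], [0.0]])
        w = np.exp(logits - logits.max())
        w = w / w.sum()
        return [
            (math.exp(rates[k, 0]), math.exp(rates[k, 1]), float(w[k]))
            for k in range(K)
        ]

    def objective(theta):
        model = GainLossModel(unpack(theta), root_prior)
        return -loglik_matrix(tree, X, model).sum()

    rng = np.random.default_rng(0)
    best = None
    for _ in range(n_starts):
        theta0 = np.concatenate([
            rng.uniform(math.log(0.1), math.log(10.0), 2 * K),
            np.zeros(K - 1),
        ])
        bounds = [(lo, hi)] * (2 * K) + [(-10, 10)] * (K - 1)
        res = minimize(objective, theta0, method="L-BFGS-B", bounds=bounds,
                       options={"ftol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
    model = GainLossModel(unpack(best.x), root_prior)
    model.loglik = -float(best.fun)
    return model


def posteriors_matrix(
    tree: Phylogeny, X: np.ndarray, model: GainLossModel
) -> tuple[np.ndarray, list[str]]:
    """Marginal posterior P(state_v = 1 | data) for every node and trait.

    Up-down algorithm: downward messages carry the likelihood of the data
    outside each node's subtree; the posterior at a node is proportional
    to (down message) x (upward partial).  Mixture categories combine with
    data-conditional weights P(category | data).

    Returns (n_traits, n_nodes) array and the node order (postorder).
    """
    n_traits = X.shape[0]
    cat_logliks = []
    cat_posts = []
    order_ref: list[str] = []
    for g, l, _w in model.categories:
        partials, logscale, order = _upward(tree, X, g, l)
        order_ref = order
        prior = model.prior(g, l)
        root_lik = partials[tree.root] @ prior
        with np.errstate(divide="ignore"):
            cat_logliks.append(np.log(root_lik) + logscale)

        # downward messages, normalized per node (constants cancel in the
        # final posterior normalization)
        down: dict[str, np.ndarray] = {tree.root: np.tile(prior, (n_traits, 1))}
        for node in tree.preorder():
            if node.is_leaf:
                continue
            children = node.children
            contribs = {}
            for child in children:
                P = transition_matrix(g, l, tree.nodes[child].length)
                contribs[child] = partials[child] @ P.T  # (n_traits, 2)
            for child in children:
                sib = np.ones((n_traits, 2))
                for other in children:
                    if other != child:
                        sib = sib * contribs[other]
                P = transition_matrix(g, l, tree.nodes[child].length)
                msg = (down[node.name] * sib) @ P  # sum over parent state
                norm = msg.sum(axis=1, keepdims=True)
                norm[norm == 0] = 1.0
                down[child] = msg / norm

        post = np.empty((n_traits, len(order)))
        for j, name in enumerate(order):
            joint = down[name] * partials[name]
            denom = joint.sum(axis=1)
            denom[denom == 0] = 1.0
            post[:, j] = joint[:, 1] / denom
        cat_posts.append(post)

    cat_logliks = np.vstack(cat_logliks)  # (K, n_traits)
    logw = np.log([w for _, _, w in model.categories])[:, None]
    logjoint = cat_logliks + logw
    m = logjoint.max(axis=0)
    resp = np.exp(logjoint - m)
    resp = resp / resp.sum(axis=0)  # P(category | data)
    post = np.zeros_like(cat_posts[0])
    for k, p in enumerate(cat_posts):
        post += resp[k][:, None] * p
    return post, order_ref


def node_posteriors(
    tree: Phylogeny, profile: PhyleticProfile, model: GainLossModel
) -> PosteriorProfile:
    """Marginal posterior of presence at every node for one trait."""
    X, _, _ = profiles_to_matrix([profile], tree)
    post, order = posteriors_matrix(tree, X, model)
    return PosteriorProfile(
        trait_id=profile.trait_id,
        posteriors={name: float(post[0, j]) for j, name in enumerate(order)},
    )


def marginal_ml_states(posteriors: PosteriorProfile) -> dict[str, int]:
    """Maximum-likelihood marginal state per node: 1 iff posterior > 0.5.

    An exact tie (posterior == 0.5) resolves to absent.
    """
    return {n: (1 if p > 0.5 else 0) for n, p in posteriors.posteriors.items()}


# ---------------------------------------------------------------------------
# TSV I/O (rows = traits, columns = genome labels, cells 0/1/NA)


def read_profiles_tsv(path) -> list[PhyleticProfile]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    out = []
    for trait, row in df.iterrows():
        states: dict[str, int | None] = {}
        for genome, val in row.items():
            if val is None or str(val).upper() in ("NA", "NAN", ""):
                states[genome] = None
            else:
                states[genome] = int(float(val))
        out.append(PhyleticProfile(trait_id=str(trait), states=states))
    return out


def write_profiles_tsv(profiles: list[PhyleticProfile], path) -> None:
    import pandas as pd

    genomes = sorted({g for p in profiles for g in p.states})
    rows = {}
    for p in profiles:
        rows[p.trait_id] = {
            g: ("NA" if p.states.get(g) is None else p.states[g]) for g in genomes
        }
    pd.DataFrame.from_dict(rows, orient="index", columns=genomes).rename_axis(
        "trait"
    ).to_csv(path, sep="\t")


def write_posteriors_tsv(posteriors: list[PosteriorProfile], path) -> None:
    import pandas as pd

    rows = [
        {"trait": p.trait_id, "node": n, "posterior": v}
        for p in posteriors
        for n, v in p.posteriors.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
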