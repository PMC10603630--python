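"""Bayesian multistate ancestral-area estimation over a posterior tree sample.

With the maximum range size set to one area, ancestral-area estimation
reduces to a single multistate character evolving under an equal-input
("F81-type") substitution model: q(i -> j) = mu * pi_j for i != j, with
among-branch rate heterogeneity modeled by a discretized Gamma(alpha)
multiplier integrated over equal-probability categories.

The MCMC jointly samples the model parameters (mu, alpha and — optionally —
the stationary frequencies pi) under vague priors while drawing a tree
uniformly from the posterior sample at each generation, so that the node
posteriors are averaged over phylogenetic uncertainty.  Internal nodes are
matched across trees by their descendant-tip sets; a node's posterior is
averaged only over the sampled trees that contain that clade.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import gamma as gamma_dist

from .treeio import CladeKey, TimeTree, TreeSample

__all__ = [
    "BBMSettings",
    "BBMPosterior",
    "single_char_loglik",
    "char_marginals",
    "bbm_mcmc",
    "discrete_gamma_rates",
]


@dataclass
class BBMSettings:
    """MCMC settings; the defaults mirror a typical published protocol
    (10 chains of 1e6 generations, thinned every 100, 25% burn-in).
    Tests and quick runs use the ``fast`` preset."""

    chains: int = 10
    generations: int = 1_000_000
    sample_interval: int = 100
    burnin_fraction: float = 0.25
    gamma_categories: int = 4
    estimate_frequencies: bool = True
    mu_prior_mean: float = 0.1  # Exponential prior on the rate, /Ma
    alpha_prior_mean: float = 1.0  # Exponential prior on the Gamma shape
    seed: int = 0

    def __post_init__(self) -> None:
        if self.generations % self.sample_interval != 0:
            raise ValueError("generations must be divisible by sample_interval")
        if not 0 <= self.burnin_fraction < 1:
            raise ValueError("burnin_fraction must be in [0, 1)")
        if self.gamma_categories < 1:
            raise ValueError("need at least one Gamma category")

    @classmethod
    def preset(cls, name: str, seed: int = 0) -> "BBMSettings":
        if name == "paper":
            return cls(seed=seed)
        if name == "fast":
            return cls(chains=2, generations=20_000, seed=seed)
        raise ValueError(f"unknown preset {name!r}")


@dataclass
class BBMPosterior:
    """Per-clade posterior area probabilities and clade support."""

    areas: Tuple[str, ...]
    probabilities: Dict[CladeKey, np.ndarray]
    support: Dict[CladeKey, float]
    n_samples: int
    parameter_trace: Dict[str, np.ndarray] = field(default_factory=dict)

    def probability(self, clade: Iterable[str], area: str) -> float:
        key = frozenset(clade)
        return float(self.probabilities[key][self.areas.index(area)])


_GAMMA_RATE_CACHE: Dict[Tuple[float, int], np.ndarray] = {}


def discrete_gamma_rates(alpha: float, k: int) -> np.ndarray:
    """Mean rates of k equal-probability categories of Gamma(alpha, mean 1)."""
    if k == 1:
        return np.ones(1)
    cached = _GAMMA_RATE_CACHE.get((alpha, k))
    if cached is not None:
        return cached
    if len(_GAMMA_RATE_CACHE) > 4096:
        _GAMMA_RATE_CACHE.clear()
    edges = gamma_dist.ppf(np.linspace(0, 1, k + 1), alpha, scale=1.0 / alpha)
    # E[X | a < X < b] for Gamma(alpha, 1/alpha) via the shape+1 trick
    cdf1 = gamma_dist.cdf(edges, alpha + 1, scale=1.0 / alpha)
    rates = k * np.diff(cdf1)
    rates = rates / rates.mean()  # guard against tail truncation error
    _GAMMA_RATE_CACHE[(alpha, k)] = rates
    return rates


def _f81_p(pi: np.ndarray, mu: float, t: float) -> np.ndarray:
    """Equal-input transition matrix: P_ij(t) = pi_j + (delta_ij - pi_j) e^{-mu t}."""
    decay = math.exp(-mu * t)
    return pi[None, :] * (1.0 - decay) + np.eye(len(pi)) * decay


def _postorder_partials(
    tree: TimeTree,
    state_of: Mapping[str, int],
    pi: np.ndarray,
    mu: float,
    rate: float,
) -> Tuple[Dict[int, np.ndarray], Dict[int, np.ndarray]]:
    k = len(pi)
    D: Dict[int, np.ndarray] = {}
    Dup: Dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_tip:
            v = np.zeros(k)
            v[state_of[node.label]] = 1.0
        else:
            v = np.ones(k)
            for child in node.children:
                v = v * Dup[child.id]
        D[node.id] = v
        if node.parent is not None:
            Dup[node.id] = _f81_p(pi, mu, rate * node.length) @ v
    return D, Dup


def single_char_loglik(
    tree: TimeTree,
    states: Mapping[str, str],
    areas: Sequence[str],
    pi: np.ndarray,
    mu: float,
    rate_multiplier: float = 1.0,
) -> float:
    """Pruning log-likelihood of one multistate character; root weighted by pi."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    if abs(pi.sum() - 1.0) > 1e-9 or np.any(pi < 0):
        raise ValueError("pi must be a probability vector")
    state_of = _encode_states(states, areas, tree)
    D, _ = _postorder_partials(tree, state_of, pi, mu, rate_multiplier)
    lik = float(pi @ D[tree.root.id])
    return math.log(lik) if lik > 0 else -math.inf


def _encode_states(
    states: Mapping[str, str], areas: Sequence[str], tree: TimeTree
) -> Dict[str, int]:
    idx = {a: i for i, a in enumerate(areas)}
    out = {}
    for label in tree.tip_labels:
        if label not in states:
            raise ValueError(f"tip {label!r} has no area assignment")
        if states[label] not in idx:
            raise ValueError(f"tip {label!r} assigned unknown area {states[label]!r}")
        out[label] = idx[states[label]]
    return out


def char_marginals(
    tree: TimeTree,
    states: Mapping[str, str],
    areas: Sequence[str],
    pi: np.ndarray,
    mu: float,
    alpha: Optional[float] = None,
    gamma_categories: int = 4,
) -> Dict[CladeKey, np.ndarray]:
    """Analytic marginal state posteriors at internal nodes (up-down pass),
    integrated over discrete-Gamma rate categories when *alpha* is given."""
    state_of = _encode_states(states, areas, tree)
    rates = discrete_gamma_rates(alpha, gamma_categories) if alpha else np.ones(1)
    k = len(pi)
    per_cat: List[Dict[int, np.ndarray]] = []
    weights = []
    for r in rates:
        D, Dup = _postorder_partials(tree, state_of, pi, mu, float(r))
        U: Dict[int, np.ndarray] = {tree.root.id: pi.copy()}
        for node in tree.preorder():
            if node.is_tip:
                continue
            for child in node.children:
                msg = U[node.id].copy()
                for sib in node.children:
                    if sib is not child:
                        msg = msg * Dup[sib.id]
                U[child.id] = msg @ _f81_p(pi, mu, float(r) * child.length)
        marg = {nid: U[nid] * D[nid] for nid in U if nid in D}
        per_cat.append(marg)
        weights.append(float(pi @ D[tree.root.id]))
    weights = np.array(weights)
    total = weights.sum()
    if total <= 0:
        raise ValueError("tip data have zero likelihood under every rate category")
    weights = weights / total
    out: Dict[CladeKey, np.ndarray] = {}
    for node in tree.preorder():
        if node.is_tip:
            continue
        m = np.zeros(k)
        for w, marg in zip(weights, per_cat):
            if w == 0.0:
                continue  # numerically impossible category contributes nothing
            v = marg[node.id]
            m += w * v / v.sum()
        out[tree.clade_key(node)] = m / m.sum()
    return out


def _mixture_loglik(tree, states, areas, pi, mu, alpha, k_cat) -> float:
    """Log-likelihood averaged over discrete-Gamma rate categories.

    All categories share one postorder traversal: partials are carried as a
    (categories x states) array and each branch applies the closed-form
    equal-input transition matrix per category."""
    rates = discrete_gamma_rates(alpha, k_cat)
    state_of = _encode_states(states, areas, tree)
    k = len(pi)
    eye = np.eye(k)
    D: Dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_tip:
            v = np.zeros((k_cat, k))
            v[:, state_of[node.label]] = 1.0
        else:
            v = np.ones((k_cat, k))
            for child in node.children:
                v = v * D[child.id]
        if node.parent is not None:
            decay = np.exp(-mu * rates * node.length)  # (k_cat,)
            P = pi[None, None, :] * (1.0 - decay)[:, None, None] + eye[None] * decay[:, None, None]
            v = np.einsum("cij,cj->ci", P, v)
        D[node.id] = v
    liks = D[tree.root.id] @ pi
    mean_lik = float(liks.mean())
    return math.log(mean_lik) if mean_lik > 0 else -math.inf


def bbm_mcmc(
    trees: TreeSample,
    states: Mapping[str, str],
    areas: Sequence[str],
    settings: BBMSettings,
) -> BBMPosterior:
    """Metropolis-Hastings sampler for (mu, alpha[, pi]) with node-state draws.

    At every generation a tree is drawn uniformly from the sample and each
    parameter is updated by a random-walk MH step (log-normal proposals for
    mu and alpha; a Dirichlet-neighborhood proposal for pi when frequencies
    are estimated, otherwise pi is fixed equal).  At each thinning point a
    node state is drawn per internal node from its analytic marginal and
    accumulated per clade; chains are pooled after discarding burn-in.
    """
    areas = tuple(areas)
    k = len(areas)
    for tree in trees:
        _encode_states(states, areas, tree)  # validate every tree's coding

    n_gen = settings.generations
    burnin_gen = int(settings.burnin_fraction * n_gen)
    counts: Dict[CladeKey, np.ndarray] = {}
    clade_seen: Dict[CladeKey, int] = {}
    total_samples = 0
    traces = {"mu": [], "alpha": [], "lnL": []}

    for chain in range(settings.chains):
        rng = np.random.default_rng((settings.seed, chain))
        mu = rng.exponential(settings.mu_prior_mean)
        alpha = rng.exponential(settings.alpha_prior_mean)
        pi = np.full(k, 1.0 / k)
        tree = trees[int(rng.integers(len(trees)))]
        lnp = _log_posterior(tree, states, areas, pi, mu, alpha, settings)

        for gen in range(1, n_gen + 1):
            tree = trees[int(rng.integers(len(trees)))]
            lnp = _log_posterior(tree, states, areas, pi, mu, alpha, settings)
            # mu update (log-normal random walk)
            mu_new = mu * math.exp(0.3 * rng.standard_normal())
            lnp_new = _log_posterior(tree, states, areas, pi, mu_new, alpha, settings)
            # Jacobian of the log-scale walk: q ratio contributes ln(mu_new/mu)
            if math.log(rng.random()) < lnp_new - lnp + math.log(mu_new / mu):
                mu, lnp = mu_new, lnp_new
            # alpha update
            alpha_new = alpha * math.exp(0.3 * rng.standard_normal())
            lnp_new = _log_posterior(tree, states, areas, pi, mu, alpha_new, settings)
            if math.log(rng.random()) < lnp_new - lnp + math.log(alpha_new / alpha):
                alpha, lnp = alpha_new, lnp_new
            # pi update
            if settings.estimate_frequencies:
                conc = 100.0
                pi_new = rng.dirichlet(conc * pi + 1.0)
                if np.all(pi_new > 1e-6):
                    lnp_new = _log_posterior(tree, states, areas, pi_new, mu, alpha, settings)
                    q_fwd = _dirichlet_logpdf(pi_new, conc * pi + 1.0)
                    q_rev = _dirichlet_logpdf(pi, conc * pi_new + 1.0)
                    if math.log(rng.random()) < lnp_new - lnp + q_rev - q_fwd:
                        pi, lnp = pi_new, lnp_new

            if gen > burnin_gen and gen % settings.sample_interval == 0:
                marg = char_marginals(
                    tree, states, areas, pi, mu, alpha, settings.gamma_categories
                )
                for key, probs in marg.items():
                    draw = int(rng.choice(k, p=probs / probs.sum()))
                    if key not in counts:
                        counts[key] = np.zeros(k)
                        clade_seen[key] = 0
                    counts[key][draw] += 1
                    clade_seen[key] += 1
                total_samples += 1
                traces["mu"].append(mu)
                traces["alpha"].append(alpha)
                traces["lnL"].append(lnp)

    if total_samples == 0:
        raise ValueError(
            "no post-burn-in samples; increase generations or lower burnin_fraction"
        )
    probabilities = {key: counts[key] / clade_seen[key] for key in counts}
    support = {key: clade_seen[key] / total_samples for key in counts}
    return BBMPosterior(
        areas=areas,
        probabilities=probabilities,
        support=support,
        n_samples=total_samples,
        parameter_trace={k_: np.array(v) for k_, v in traces.items()},
    )


def _log_posterior(tree, states, areas, pi, mu, alpha, settings: BBMSettings) -> float:
    if mu <= 0 or alpha <= 0:
        return -math.inf
    lnL = _mixture_loglik(tree, states, areas, pi, mu, alpha, settings.gamma_categories)
    ln_prior = (
        -mu / settings.mu_prior_mean - alpha / settings.alpha_prior_mean
    )  # exponential priors; flat Dirichlet(1,..,1) on pi adds a constant
    return lnL + ln_prior


def _dirichlet_logpdf(x: np.ndarray, a: np.ndarray) -> float:
    from scipy.special import gammaln

    return float(gammaln(a.sum()) - gammaln(a).sum() + ((a - 1.0) * np.log(x)).sum())
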