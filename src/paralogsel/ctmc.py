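"""Two-state trait evolution on a phylogeny.

Provides the likelihood (Felsenstein pruning with per-branch-class rates and
optional node fossilization), maximum-likelihood fitting, the nested
dependent-vs-independent likelihood ratio test, Metropolis-Hastings MCMC with
exponential rate priors, stepping-stone marginal-likelihood estimation, and
log Bayes factors.

State coding: 0 = trait absent, 1 = trait present.  ``q01`` is the gain rate,
``q10`` the loss rate, and ``q10_delta`` an optional loss rate applied on
branches whose class label is in ``delta_classes`` (the "dependent" model).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .phylo import Phylogeny
from .traits import ABSENT, PRESENT, UNKNOWN, TraitTable

__all__ = [
    "TraitModel",
    "NodeConstraint",
    "McmcConfig",
    "SteppingStoneConfig",
    "TraitFitResult",
    "SteppingStoneResult",
    "transition_matrix",
    "TraitLikelihood",
    "log_likelihood",
    "fit_ml",
    "lrt_dependent_vs_independent",
    "run_mcmc",
    "stepping_stone_logml",
    "log_bayes_factor",
    "ancestral_constraint_scan",
]

_RATE_BOUNDS = (1e-6, 1e3)


# ---------------------------------------------------------------------------
# model / config types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraitModel:
    """Rate parameters plus the class->rate mapping and root prior.

    ``root_prior`` is ``"stationary"`` (of the default-class rates),
    ``"uniform"``, or ``("fixed", "present"|"absent")``.
    """

    q01: float
    q10: float
    q10_delta: float | None = None
    delta_classes: frozenset = frozenset({"delta"})
    root_prior: object = "stationary"

    def __post_init__(self) -> None:
        rates = [self.q01, self.q10] + ([] if self.q10_delta is None else [self.q10_delta])
        for r in rates:
            if not (r > 0 and math.isfinite(r)):
                raise ValueError(f"rates must be strictly positive and finite, got {r}")

    @property
    def is_dependent(self) -> bool:
        return self.q10_delta is not None

    @property
    def param_names(self) -> tuple[str, ...]:
        return ("q01", "q10", "q10_delta") if self.is_dependent else ("q01", "q10")

    def rates(self) -> np.ndarray:
        vals = [self.q01, self.q10] + ([self.q10_delta] if self.is_dependent else [])
        return np.asarray(vals, dtype=float)

    def replace_rates(self, rates: Sequence[float]) -> "TraitModel":
        rates = list(rates)
        q10d = rates[2] if self.is_dependent else None
        return TraitModel(rates[0], rates[1], q10d, self.delta_classes, self.root_prior)


@dataclass(frozen=True)
class NodeConstraint:
    """Fossilize the node selected as MRCA of ``taxa`` to ``state``."""

    taxa: frozenset
    state: str  # "present" | "absent"

    def __post_init__(self) -> None:
        if self.state not in ("present", "absent"):
            raise ValueError(f"constraint state must be 'present' or 'absent', got {self.state!r}")

    @property
    def state_index(self) -> int:
        return 1 if self.state == "present" else 0


@dataclass
class McmcConfig:
    iterations: int = 1_010_000
    burn_in: int = 10_000
    thinning: int = 1_000
    prior_mean: float = 0.1
    proposal_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations <= self.burn_in:
            raise ValueError("iterations must exceed burn_in")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if self.prior_mean <= 0:
            raise ValueError("prior mean must be > 0")


@dataclass
class SteppingStoneConfig:
    n_stones: int = 100
    iterations_per_stone: int = 10_000
    shape: float = 0.4
    prior_mean: float = 0.1
    proposal_scale: float = 1.0
    seed: int = 0
    burn_in_per_stone: int | None = None

    def __post_init__(self) -> None:
        if self.n_stones < 2:
            raise ValueError("need at least 2 stones")
        if self.shape <= 0:
            raise ValueError("schedule shape must be > 0")

    @property
    def stone_burn_in(self) -> int:
        return self.iterations_per_stone // 10 if self.burn_in_per_stone is None else self.burn_in_per_stone


@dataclass
class TraitFitResult:
    model: TraitModel
    log_likelihood: float
    converged: bool = True
    samples: dict = field(default_factory=dict)
    medians: dict = field(default_factory=dict)
    ratio_medians: dict = field(default_factory=dict)
    acceptance_rate: float | None = None
    ess: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    @property
    def params(self) -> dict:
        return dict(zip(self.model.param_names, self.model.rates()))


@dataclass
class SteppingStoneResult:
    log_marginal_likelihood: float
    per_stone: np.ndarray
    betas: np.ndarray
    warnings: list = field(default_factory=list)

    def __float__(self) -> float:
        return self.log_marginal_likelihood


# ---------------------------------------------------------------------------
# transition matrix
# ---------------------------------------------------------------------------

def transition_matrix(gain: float, loss: float, t: float) -> np.ndarray:
    """Closed-form P(t) = expm(Q t) for Q = [[-gain, gain], [loss, -loss]]."""
    if t < 0:
        raise ValueError(f"branch length must be >= 0, got {t}")
    if gain <= 0 or loss <= 0:
        raise ValueError("rates must be > 0")
    s = gain + loss
    e = math.exp(-s * t)
    return np.array(
        [
            [(loss + gain * e) / s, gain * (1.0 - e) / s],
            [loss * (1.0 - e) / s, (gain + loss * e) / s],
        ]
    )


# ---------------------------------------------------------------------------
# pruning likelihood
# ---------------------------------------------------------------------------

_TIP_PARTIALS = {ABSENT: (1.0, 0.0), PRESENT: (0.0, 1.0), UNKNOWN: (1.0, 1.0)}


class TraitLikelihood:
    """Reusable pruning workspace for one (tree, traits, constraints) triple.

    Nodes are processed in height levels so each likelihood evaluation is a
    handful of vectorized passes rather than a per-node Python loop.
    """

    def __init__(
        self,
        tree: Phylogeny,
        traits: Mapping[str, str],
        constraints: Iterable[NodeConstraint] = (),
        delta_classes: frozenset = frozenset({"delta"}),
    ):
        self.tree = tree
        n = len(tree.nodes)
        missing = [lbl for lbl in tree.tip_labels if lbl not in traits]
        if missing:
            raise ValueError(f"traits missing for tips: {missing[:5]}{'...' if len(missing) > 5 else ''}")

        self._base = np.ones((n, 2))
        for tip in tree.tips():
            self._base[tip] = _TIP_PARTIALS[traits[tree.nodes[tip].label]]

        # constraint masks applied after a node's partial is assembled
        self._mask = np.ones((n, 2))
        for c in constraints:
            node = tree.mrca(c.taxa)
            allowed = np.zeros(2)
            allowed[c.state_index] = 1.0
            self._mask[node] *= allowed
        self._base *= self._mask  # covers tip/root-only trees and constrained tips

        # edge arrays
        child = np.array([i for i in range(n) if tree.nodes[i].parent is not None], dtype=np.intp)
        parent = np.array([tree.nodes[i].parent for i in child], dtype=np.intp)
        length = np.array([tree.nodes[i].length for i in child])
        is_delta = np.array(
            [tree.nodes[i].branch_class in delta_classes for i in child], dtype=bool
        )
        self._child, self._parent, self._length, self._is_delta = child, parent, length, is_delta
        edge_of_child = {int(c): e for e, c in enumerate(child)}

        # height levels (tips = 0); per level: edges feeding that level's nodes
        height = np.zeros(n, dtype=int)
        for i in tree.postorder():
            kids = tree.nodes[i].children
            if kids:
                height[i] = 1 + max(height[k] for k in kids)
        self._levels = []
        for h in range(1, height[tree.root] + 1):
            nodes_h = np.array([i for i in range(n) if height[i] == h], dtype=np.intp)
            edges_h = np.array(
                [edge_of_child[k] for i in nodes_h for k in tree.nodes[i].children], dtype=np.intp
            )
            self._levels.append((nodes_h, edges_h))
        self.root = tree.root
        self._n = n

        # scalar fast path (small trees): edges ordered by child postorder
        post_pos = {node: k for k, node in enumerate(tree.postorder())}
        order = sorted(range(len(child)), key=lambda e: post_pos[int(child[e])])
        self._scalar_edges = [
            (int(child[e]), int(parent[e]), float(length[e]), bool(is_delta[e])) for e in order
        ]
        self._base_list = [tuple(row) for row in self._base]
        self._mask_list = [tuple(row) for row in self._mask]

    # -- transition matrices for all edges, vectorized ----------------------
    def _edge_matrices(self, q01: float, q10: float, q10_delta: float | None) -> np.ndarray:
        loss = np.full(self._length.shape, q10)
        if q10_delta is not None:
            loss[self._is_delta] = q10_delta
        gain = q01
        s = gain + loss
        e = np.exp(-s * self._length)
        P = np.empty((len(loss), 2, 2))
        P[:, 0, 0] = (loss + gain * e) / s
        P[:, 0, 1] = gain * (1.0 - e) / s
        P[:, 1, 0] = loss * (1.0 - e) / s
        P[:, 1, 1] = (gain + loss * e) / s
        return P

    def loglik(self, model: TraitModel) -> float:
        return self.loglik_rates(model.q01, model.q10, model.q10_delta, model.root_prior)

    def loglik_rates(
        self, q01: float, q10: float, q10_delta: float | None = None, root_prior: object = "stationary"
    ) -> float:
        """Log-likelihood from raw rates (skips model-object construction)."""
        if self._n <= 64:
            return self._loglik_scalar(q01, q10, q10_delta, root_prior)
        return self._loglik_vector(q01, q10, q10_delta, root_prior)

    def _loglik_scalar(self, q01, q10, q10_delta, root_prior) -> float:
        p = [list(row) for row in self._base_list]
        for child, parent, t, is_delta in self._scalar_edges:
            loss = q10_delta if (is_delta and q10_delta is not None) else q10
            s = q01 + loss
            e = math.exp(-s * t)
            c0, c1 = p[child]
            mask = self._mask_list[child]
            c0 *= mask[0]
            c1 *= mask[1]
            pp = p[parent]
            pp[0] *= ((loss + q01 * e) * c0 + q01 * (1.0 - e) * c1) / s
            pp[1] *= (loss * (1.0 - e) * c0 + (q01 + loss * e) * c1) / s
        r0, r1 = p[self.root]
        m0, m1 = self._mask_list[self.root]
        pr0, pr1 = self._root_prior_values(q01, q10, root_prior)
        lik = pr0 * r0 * m0 + pr1 * r1 * m1
        return math.log(lik) if lik > 0.0 else -np.inf

    def _loglik_vector(self, q01, q10, q10_delta, root_prior) -> float:
        P = self._edge_matrices(q01, q10, q10_delta)
        partial = self._base.copy()
        logscale = np.zeros(self._n)
        for nodes_h, edges_h in self._levels:
            ch = self._child[edges_h]
            contrib = np.einsum("eij,ej->ei", P[edges_h], partial[ch])
            np.multiply.at(partial, self._parent[edges_h], contrib)
            np.add.at(logscale, self._parent[edges_h], logscale[ch])
            partial[nodes_h] *= self._mask[nodes_h]
            m = partial[nodes_h].max(axis=1)
            if np.any(m <= 0.0):
                return -np.inf
            partial[nodes_h] /= m[:, None]
            logscale[nodes_h] += np.log(m)

        pr0, pr1 = self._root_prior_values(q01, q10, root_prior)
        lik = pr0 * partial[self.root, 0] + pr1 * partial[self.root, 1]
        if lik <= 0.0:
            return -np.inf
        return math.log(lik) + float(logscale[self.root])

    @staticmethod
    def _root_prior_values(q01: float, q10: float, rp: object) -> tuple[float, float]:
        if rp == "stationary":
            s = q01 + q10
            return q10 / s, q01 / s
        if rp == "uniform":
            return 0.5, 0.5
        if isinstance(rp, tuple) and rp[0] == "fixed":
            return (1.0, 0.0) if rp[1] == "absent" else (0.0, 1.0)
        raise ValueError(f"unknown root prior: {rp!r}")


def log_likelihood(
    tree: Phylogeny,
    traits: Mapping[str, str],
    model: TraitModel,
    constraints: Iterable[NodeConstraint] = (),
) -> float:
    """One-shot pruning log-likelihood (builds a workspace and discards it)."""
    return TraitLikelihood(tree, traits, constraints, model.delta_classes).loglik(model)


# ---------------------------------------------------------------------------
# maximum likelihood
# ---------------------------------------------------------------------------

def _template(kind: str, delta_classes: frozenset, root_prior: object) -> TraitModel:
    if kind == "independent":
        return TraitModel(0.1, 0.1, None, delta_classes, root_prior)
    if kind == "dependent":
        return TraitModel(0.1, 0.1, 0.1, delta_classes, root_prior)
    raise ValueError(f"model kind must be 'independent' or 'dependent', got {kind!r}")


def fit_ml(
    tree: Phylogeny,
    traits: Mapping[str, str],
    model: str | TraitModel = "independent",
    constraints: Iterable[NodeConstraint] = (),
    delta_classes: frozenset = frozenset({"delta"}),
    root_prior: object = "stationary",
    n_starts: int = 5,
    seed: int = 0,
    init: Sequence[float] | None = None,
    bounds: tuple[float, float] = _RATE_BOUNDS,
) -> TraitFitResult:
    """Multi-start box-constrained ML over log-rates.

    ``init``, when given, is used as an extra (first) start — e.g. the
    independent-model optimum padded with its own q10, which guarantees the
    dependent fit can never fall below the independent one.
    """
    template = model if isinstance(model, TraitModel) else _template(model, delta_classes, root_prior)
    engine = TraitLikelihood(tree, traits, constraints, template.delta_classes)
    k = len(template.param_names)
    lo, hi = math.log(bounds[0]), math.log(bounds[1])

    dependent = template.is_dependent
    rp = template.root_prior

    def objective(x: np.ndarray) -> float:
        r = np.exp(x)
        ll = engine.loglik_rates(r[0], r[1], r[2] if dependent else None, rp)
        return 1e12 if not math.isfinite(ll) else -ll

    rng = np.random.default_rng(seed)
    starts = [np.log(np.clip(np.asarray(init, dtype=float), bounds[0], bounds[1]))] if init is not None else []
    starts.append(np.full(k, math.log(0.1)))
    while len(starts) < max(n_starts, 1):
        starts.append(np.log(np.clip(rng.exponential(0.1, size=k), bounds[0], bounds[1])))

    # Nelder-Mead first: the log-likelihood plateaus at extreme rates, where
    # quasi-Newton steps can run onto the bound and stall at a worse optimum.
    best = None
    converged = False
    for x0 in starts[: max(n_starts, 1)]:
        res = optimize.minimize(
            objective, x0, method="Nelder-Mead", bounds=[(lo, hi)] * k,
            options={"maxiter": 1000, "xatol": 1e-8, "fatol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
            converged = bool(res.success)
    polish = optimize.minimize(
        objective, best.x, method="L-BFGS-B", bounds=[(lo, hi)] * k,
        options={"maxiter": 200, "ftol": 1e-13},
    )
    if polish.fun < best.fun:
        best = polish
    fitted = template.replace_rates(np.exp(best.x))
    return TraitFitResult(model=fitted, log_likelihood=-best.fun, converged=converged)


def lrt_dependent_vs_independent(ll_indep: float, ll_dep: float) -> tuple[float, float]:
    """LRT statistic 2*(ll_dep - ll_indep) against chi-square with 1 df."""
    if ll_dep < ll_indep - 1e-6:
        raise ValueError(f"dependent log-likelihood {ll_dep} below independent {ll_indep}")
    statistic = max(0.0, 2.0 * (ll_dep - ll_indep))
    p_value = float(stats.chi2.sf(statistic, df=1))
    return statistic, p_value


# ---------------------------------------------------------------------------
# MCMC
# ---------------------------------------------------------------------------

def _log_prior(x: np.ndarray, mean: float) -> float:
    # exponential(mean) prior on natural-scale rates, sampled on log scale
    return float(np.sum(x) - np.sum(np.exp(x)) / mean)


class _Sampler:
    """Per-parameter Gaussian random-walk MH on log-rates."""

    def __init__(self, engine, template, cfg_scale, prior_mean, rng, power=1.0):
        self.engine = engine
        self.template = template
        self.k = len(template.param_names)
        self.scales = np.full(self.k, cfg_scale)
        self.prior_mean = prior_mean
        self.rng = rng
        self.power = power
        self.accepts = np.zeros(self.k)
        self.proposals = np.zeros(self.k)

        self._dependent = template.is_dependent
        self._rp = template.root_prior

    def loglik(self, x: np.ndarray) -> float:
        r = np.exp(x)
        return self.engine.loglik_rates(r[0], r[1], r[2] if self._dependent else None, self._rp)

    def logpost(self, x: np.ndarray, ll: float) -> float:
        return self.power * ll + _log_prior(x, self.prior_mean)

    def sweep(self, x: np.ndarray, ll: float) -> tuple[np.ndarray, float]:
        for i in range(self.k):
            prop = x.copy()
            prop[i] += self.scales[i] * self.rng.standard_normal()
            ll_prop = self.loglik(prop)
            delta = self.logpost(prop, ll_prop) - self.logpost(x, ll)
            self.proposals[i] += 1
            if math.log(self.rng.random()) < delta:
                x, ll = prop, ll_prop
                self.accepts[i] += 1
        return x, ll

    def adapt(self) -> None:
        with np.errstate(invalid="ignore"):
            rate = np.where(self.proposals > 0, self.accepts / np.maximum(self.proposals, 1), 0.44)
        self.scales = np.clip(self.scales * np.exp(rate - 0.44), 1e-3, 1e3)
        self.accepts[:] = 0
        self.proposals[:] = 0

    @property
    def acceptance_rate(self) -> float:
        total = self.proposals.sum()
        return float(self.accepts.sum() / total) if total else float("nan")


def _ess(x: np.ndarray) -> float:
    n = len(x)
    if n < 4 or np.std(x) == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1 :] / (np.arange(n, 0, -1) * np.var(x))
    tau = 1.0
    for k in range(1, min(n // 2, 1000)):
        if acf[k] < 0.0:
            break
        tau += 2.0 * acf[k]
    return float(n / max(tau, 1.0))


def run_mcmc(
    tree: Phylogeny,
    traits: Mapping[str, str],
    model: str | TraitModel = "dependent",
    constraints: Iterable[NodeConstraint] = (),
    cfg: McmcConfig | None = None,
    delta_classes: frozenset = frozenset({"delta"}),
    root_prior: object = "stationary",
    init: Sequence[float] | None = None,
) -> TraitFitResult:
    """Metropolis-Hastings over log-rates with exponential priors.

    Proposal scales adapt during burn-in only; thinned post-burn-in samples,
    medians of each rate, and medians of per-sample rate ratios are reported.
    """
    cfg = cfg or McmcConfig()
    template = model if isinstance(model, TraitModel) else _template(model, delta_classes, root_prior)
    engine = TraitLikelihood(tree, traits, constraints, template.delta_classes)
    rng = np.random.default_rng(cfg.seed)
    sampler = _Sampler(engine, template, cfg.proposal_scale, cfg.prior_mean, rng)

    if init is not None:
        x = np.log(np.asarray(init, dtype=float))
    else:
        x = np.log(rng.exponential(cfg.prior_mean, size=sampler.k))
    ll = sampler.loglik(x)

    names = template.param_names
    n_keep = (cfg.iterations - cfg.burn_in) // cfg.thinning
    kept = np.empty((n_keep, sampler.k))
    kept_ll = np.empty(n_keep)
    j = 0
    for it in range(1, cfg.iterations + 1):
        x, ll = sampler.sweep(x, ll)
        if it <= cfg.burn_in:
            if it % 50 == 0:
                sampler.adapt()
            if it == cfg.burn_in:
                sampler.adapt()  # reset counters; scales frozen hereafter
        elif (it - cfg.burn_in) % cfg.thinning == 0 and j < n_keep:
            kept[j] = x
            kept_ll[j] = ll
            j += 1

    rates = np.exp(kept[:j])
    samples = {name: rates[:, i] for i, name in enumerate(names)}
    samples["log_likelihood"] = kept_ll[:j]
    medians = {name: float(np.median(samples[name])) for name in names}
    ratio_medians = {"q01:q10": float(np.median(samples["q01"] / samples["q10"]))}
    if "q10_delta" in samples:
        ratio_medians["q01:q10_delta"] = float(np.median(samples["q01"] / samples["q10_delta"]))

    warns = []
    acc = sampler.acceptance_rate
    if not (0.1 <= acc <= 0.7):
        warns.append(f"post-burn-in acceptance rate {acc:.3f} outside [0.1, 0.7]")
    ess = {name: _ess(samples[name]) for name in names}
    point = template.replace_rates([medians[n] for n in names])
    return TraitFitResult(
        model=point, log_likelihood=float(np.max(kept_ll[:j])) if j else -np.inf,
        samples=samples, medians=medians, ratio_medians=ratio_medians,
        acceptance_rate=acc, ess=ess, warnings=warns,
    )


# ---------------------------------------------------------------------------
# stepping-stone marginal likelihood
# ---------------------------------------------------------------------------

def stepping_stone_logml(
    tree: Phylogeny,
    traits: Mapping[str, str],
    model: str | TraitModel = "dependent",
    constraints: Iterable[NodeConstraint] = (),
    cfg: SteppingStoneConfig | None = None,
    delta_classes: frozenset = frozenset({"delta"}),
    root_prior: object = "stationary",
) -> SteppingStoneResult:
    """Stepping-stone log marginal likelihood.

    Power schedule beta_k = (k/K)^(1/shape) (Beta(shape, 1) quantiles); each
    stone samples the power posterior prior * L^beta_k and contributes
    log E[L^(beta_{k+1}-beta_k)] via importance ratios.
    """
    cfg = cfg or SteppingStoneConfig()
    template = model if isinstance(model, TraitModel) else _template(model, delta_classes, root_prior)
    engine = TraitLikelihood(tree, traits, constraints, template.delta_classes)
    rng = np.random.default_rng(cfg.seed)

    K = cfg.n_stones
    betas = (np.arange(K + 1) / K) ** (1.0 / cfg.shape)
    contributions = np.empty(K)
    warns: list[str] = []

    x = np.log(rng.exponential(cfg.prior_mean, size=len(template.param_names)))
    sampler = _Sampler(engine, template, cfg.proposal_scale, cfg.prior_mean, rng, power=0.0)
    ll = sampler.loglik(x)
    for k in range(K):
        sampler.power = betas[k]
        for it in range(cfg.stone_burn_in):
            x, ll = sampler.sweep(x, ll)
            if it % 50 == 49:
                sampler.adapt()
        logls = np.empty(cfg.iterations_per_stone)
        for it in range(cfg.iterations_per_stone):
            x, ll = sampler.sweep(x, ll)
            logls[it] = ll
        dbeta = betas[k + 1] - betas[k]
        scaled = dbeta * logls
        m = scaled.max()
        contributions[k] = m + math.log(np.mean(np.exp(scaled - m)))
        if np.allclose(logls, logls[0]) and not np.allclose(logls, 0.0):
            warns.append(f"degenerate stone {k}: all log-likelihood ratios identical")
    return SteppingStoneResult(float(contributions.sum()), contributions, betas, warns)


# ---------------------------------------------------------------------------
# Bayes factors & fossilization scans
# ---------------------------------------------------------------------------

def log_bayes_factor(logml_1: float, logml_2: float) -> tuple[float, str]:
    """2 * (logML_1 - logML_2) with the weak/positive/strong verdict bands."""
    if not (math.isfinite(logml_1) and math.isfinite(logml_2)):
        raise ValueError("log marginal likelihoods must be finite")
    value = 2.0 * (logml_1 - logml_2)
    if value > 5.0:
        verdict = "strong"
    elif value > 2.0:
        verdict = "positive"
    else:
        verdict = "weak"
    return value, verdict


@dataclass
class ConstraintScanResult:
    node: int
    ll_present: float
    ll_absent: float
    ll_unconstrained: float
    identity_ok: bool
    identity_gap: float
    warnings: list = field(default_factory=list)


def ancestral_constraint_scan(
    tree: Phylogeny,
    traits: Mapping[str, str],
    model: TraitModel,
    taxa: Iterable[str],
    rtol: float = 1e-9,
) -> ConstraintScanResult:
    """Likelihoods with the MRCA of ``taxa`` fossilized to each state.

    Checks the partition identity L(present) + L(absent) = L(unconstrained).
    """
    taxa = frozenset(taxa)
    node = tree.mrca(taxa)
    warns = []
    if tree.nodes[node].is_tip and traits.get(tree.nodes[node].label) == UNKNOWN:
        warns.append("constrained node is an uninformative tip")
    ll_unc = log_likelihood(tree, traits, model)
    ll_p = log_likelihood(tree, traits, model, [NodeConstraint(taxa, "present")])
    ll_a = log_likelihood(tree, traits, model, [NodeConstraint(taxa, "absent")])
    combined = np.logaddexp(ll_p, ll_a)
    gap = abs(combined - ll_unc)
    ok = gap <= rtol * max(1.0, abs(ll_unc))
    return ConstraintScanResult(node, ll_p, ll_a, ll_unc, bool(ok), float(gap), warns)
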