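"""Binary latitudinal-affinity evolution: Mk2 and epoch models.

State coding throughout: ``0 = tropical``, ``1 = extratropical``.  A
species is extratropical when the midpoint of its latitudinal range lies
poleward of the tropic boundary (23.43655 degrees; ties are coded
extratropical).

The module implements

* Felsenstein-pruning log-likelihoods for the time-homogeneous Mk2
  model (symmetric and asymmetric) and for a two-epoch symmetric model
  whose transition rate changes at an absolute time ``tau`` (mya);
* maximum-likelihood fitting on the log-rate scale with multistart;
* a likelihood-profile sweep over candidate epoch boundaries (default
  1–120 mya at 1 my steps);
* AIC model comparison (k = 1 symmetric, 2 asymmetric, 3 two-epoch);
* marginal ancestral state reconstruction (down/up pass);
* stochastic character mapping, whose node-state frequencies converge
  to the marginal reconstruction and whose sampled histories carry
  change counts.

All transition probabilities use the closed-form 2x2 solution
``P(t) = Pi + exp(-(q01+q10) t) (I - Pi)`` with ``Pi`` the stationary
projector, so no matrix exponentials are taken in the hot path; an
independent ``scipy.linalg.expm`` oracle is used only in the tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .treeio import Phylogeny, node_ages

__all__ = [
    "TROPIC_BOUNDARY",
    "MkParams",
    "EpochMkParams",
    "classify_affinity",
    "affinity_states",
    "mk_loglik",
    "epoch_loglik",
    "fit_mk",
    "fit_epoch",
    "sweep_epochs",
    "compare_models",
    "marginal_asr",
    "stochastic_maps",
]

#: Latitude (degrees) separating tropical from extratropical affinity.
TROPIC_BOUNDARY = 23.43655

#: Default epoch-boundary sweep grid (mya): 1..120 at 1 my steps.
SWEEP_TAU_MIN = 1.0
SWEEP_TAU_MAX = 120.0
SWEEP_TAU_STEP = 1.0

_RATE_LO, _RATE_HI = 1e-9, 1e3
_LOG_LO, _LOG_HI = math.log(_RATE_LO), math.log(_RATE_HI)
#: Multistart grid for ML fits (per-my rates).
_STARTS = (1e-4, 1e-3, 1e-2, 1e-1, 1.0)


@dataclass
class MkParams:
    """Time-homogeneous Mk2 parameters.

    ``q01`` is the tropical-to-extratropical rate, ``q10`` the reverse,
    both per lineage per my.  ``root_prior`` is the probability pair for
    (tropical, extratropical) at the root; flat by default, with the
    stationary distribution available via :meth:`stationary`.
    """

    q01: float
    q10: float
    symmetric: bool = False
    root_prior: tuple[float, float] = (0.5, 0.5)

    def __post_init__(self) -> None:
        if self.q01 < 0 or self.q10 < 0:
            raise ValueError("transition rates must be >= 0")
        if self.symmetric and not math.isclose(self.q01, self.q10, rel_tol=1e-12):
            raise ValueError("symmetric flag requires q01 == q10")
        s = self.root_prior[0] + self.root_prior[1]
        if abs(s - 1.0) > 1e-9:
            raise ValueError("root prior must sum to 1")

    def stationary(self) -> tuple[float, float]:
        s = self.q01 + self.q10
        if s == 0:
            return (0.5, 0.5)
        return (self.q10 / s, self.q01 / s)


@dataclass
class EpochMkParams:
    """Two-epoch symmetric Mk2: rate ``q_old`` strictly above age ``tau``
    (mya), ``q_young`` at or below it."""

    tau: float
    q_old: float
    q_young: float
    root_prior: tuple[float, float] = (0.5, 0.5)

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.q_old < 0 or self.q_young < 0:
            raise ValueError("transition rates must be >= 0")


# ----------------------------------------------------------------------
# affinity coding


def classify_affinity(midpoint_lat: float, boundary: float = TROPIC_BOUNDARY) -> int:
    """0 (tropical) if |midpoint| < boundary, else 1 (extratropical)."""
    return 1 if abs(midpoint_lat) >= boundary else 0


def affinity_states(ranges: pd.DataFrame, boundary: float = TROPIC_BOUNDARY) -> pd.Series:
    """Binary affinity per species from a ranges table.

    ``ranges`` needs columns ``species, min_lat, max_lat``; the midpoint
    is their average.
    """
    mid = (ranges["min_lat"].to_numpy() + ranges["max_lat"].to_numpy()) / 2.0
    states = (np.abs(mid) >= boundary).astype(int)
    return pd.Series(states, index=ranges["species"].to_numpy(), name="state")


# ----------------------------------------------------------------------
# transition probabilities


def _pmat(q01: float, q10: float, t: float) -> tuple[float, float, float, float]:
    """(P00, P01, P10, P11) for a 2-state chain over duration t."""
    s = q01 + q10
    if s == 0.0 or t == 0.0:
        return (1.0, 0.0, 0.0, 1.0)
    pi1 = q01 / s
    pi0 = 1.0 - pi1
    e = math.exp(-s * t)
    return (pi0 + pi1 * e, pi1 * (1.0 - e), pi0 * (1.0 - e), pi1 + pi0 * e)


def _mat_mul(a, b):
    """Row-stochastic 2x2 product, tuples (p00,p01,p10,p11)."""
    a00, a01, a10, a11 = a
    b00, b01, b10, b11 = b
    return (
        a00 * b00 + a01 * b10,
        a00 * b01 + a01 * b11,
        a10 * b00 + a11 * b10,
        a10 * b01 + a11 * b11,
    )


def _branch_matrices_mk(tree: Phylogeny, q01: float, q10: float) -> list:
    mats = [None] * tree.n_nodes
    for v in range(tree.n_nodes):
        if v != tree.root:
            mats[v] = _pmat(q01, q10, float(tree.length[v]))
    return mats


def _branch_matrices_epoch(tree: Phylogeny, ages: np.ndarray, params: EpochMkParams) -> list:
    """Per-branch transition matrices under the two-epoch model.

    A branch from a parent at age ``a_p`` to a child at ``a_c`` is split
    at ``tau`` when it crosses it; chronological composition is old
    segment first: ``P = P_old(a_p - tau) @ P_young(tau - a_c)``.
    """
    tau, qo, qy = params.tau, params.q_old, params.q_young
    mats = [None] * tree.n_nodes
    for v in range(tree.n_nodes):
        if v == tree.root:
            continue
        a_c = float(ages[v])
        a_p = float(ages[tree.parent[v]])
        if a_p <= tau:
            mats[v] = _pmat(qy, qy, a_p - a_c)
        elif a_c >= tau:
            mats[v] = _pmat(qo, qo, a_p - a_c)
        else:
            mats[v] = _mat_mul(_pmat(qo, qo, a_p - tau), _pmat(qy, qy, tau - a_c))
    return mats


# ----------------------------------------------------------------------
# pruning


def _states_array(tree: Phylogeny, states) -> np.ndarray:
    """Align tip states to tip index order; raises listing missing tips."""
    if isinstance(states, pd.Series):
        mapping = states.to_dict()
    elif isinstance(states, dict):
        mapping = states
    else:
        arr = np.asarray(states, dtype=int)
        if arr.shape != (tree.n_tips,):
            raise ValueError("state array length must equal tip count")
        mapping = dict(zip(tree.tip_labels, arr))
    missing = [lab for lab in tree.tip_labels if lab not in mapping]
    if missing:
        raise ValueError(f"missing tip states for: {missing[:10]}")
    out = np.array([int(mapping[lab]) for lab in tree.tip_labels])
    if not np.isin(out, (0, 1)).all():
        raise ValueError("states must be binary 0/1")
    return out


def _check_tree(tree: Phylogeny) -> None:
    if not tree.is_bifurcating():
        raise ValueError("trait models require a strictly bifurcating tree")
    if not tree.is_ultrametric():
        raise ValueError("trait models require an ultrametric tree")


def _downpass(tree: Phylogeny, tips: np.ndarray, mats: list):
    """Scaled conditional likelihoods.

    Returns (down, logscale) where ``down[v]`` is the 2-vector of
    conditional likelihoods of the data below v given the state at v,
    rescaled per node; ``logscale`` is the accumulated log of the
    scaling factors.
    """
    down = [None] * tree.n_nodes
    logscale = 0.0
    children = tree.children
    for v in tree.postorder:
        ch = children[v]
        if not ch:
            s = tips[v]
            down[v] = (1.0 - s, float(s))
            continue
        l0 = l1 = 1.0
        for c in ch:
            p00, p01, p10, p11 = mats[c]
            d0, d1 = down[c]
            l0 *= p00 * d0 + p01 * d1
            l1 *= p10 * d0 + p11 * d1
        m = l0 if l0 > l1 else l1
        if m <= 0.0:
            return None, -math.inf  # impossible data (e.g. q=0, mixed tips)
        down[v] = (l0 / m, l1 / m)
        logscale += math.log(m)
    return down, logscale


def _loglik_from_mats(tree, tips, mats, prior) -> float:
    down, logscale = _downpass(tree, tips, mats)
    if down is None:
        return -math.inf
    d0, d1 = down[tree.root]
    lik = prior[0] * d0 + prior[1] * d1
    if lik <= 0.0:
        return -math.inf
    return math.log(lik) + logscale


def mk_loglik(tree: Phylogeny, states, params: MkParams) -> float:
    """Felsenstein-pruning log-likelihood of tip states under Mk2.

    Impossible data (zero likelihood, e.g. both rates 0 with mixed tip
    states) is reported as ``-inf`` rather than raising.
    """
    _check_tree(tree)
    tips = _states_array(tree, states)
    mats = _branch_matrices_mk(tree, params.q01, params.q10)
    return _loglik_from_mats(tree, tips, mats, params.root_prior)


def epoch_loglik(tree: Phylogeny, states, params: EpochMkParams) -> float:
    """Log-likelihood under the two-epoch symmetric model."""
    _check_tree(tree)
    ages = node_ages(tree)
    if params.tau >= tree.root_age():
        raise ValueError(
            f"epoch boundary tau={params.tau} must be younger than the root age "
            f"{tree.root_age():.6g}"
        )
    tips = _states_array(tree, states)
    mats = _branch_matrices_epoch(tree, ages, params)
    return _loglik_from_mats(tree, tips, mats, params.root_prior)


# ----------------------------------------------------------------------
# fast symmetric engine (used by the ML fits and the epoch sweep)


class _SymEngine:
    """Vectorized pruning for symmetric models.

    Every branch is decomposed into an old-epoch duration ``t_old``
    (above ``tau``) and a young-epoch duration ``t_young``; the
    homogeneous model is the special case ``tau >= root age`` or
    ``q_old == q_young``.  Branch transition matrices are symmetric, so
    only (P00, P01) per branch are needed and the matrix product of the
    two segments stays closed form.
    """

    def __init__(self, tree: Phylogeny, tips: np.ndarray,
                 prior: tuple[float, float]):
        self.tree = tree
        self.prior = prior
        self.tipdown = [(1.0 - int(s), float(s)) for s in tips]
        self.internal = []
        for v in tree.postorder:
            ch = tree.children[v]
            if ch:
                self.internal.append((v, ch[0], ch[1]))
        self.root = tree.root
        self.n = tree.n_nodes
        self._ages = None
        self.set_tau(None)

    def set_tau(self, tau: float | None) -> None:
        tree = self.tree
        if tau is None:
            self.t_old = np.zeros(self.n)
            self.t_young = tree.length.astype(float).copy()
            self.t_young[self.root] = 0.0
            return
        if self._ages is None:
            self._ages = node_ages(tree)
        ages = self._ages
        par = tree.parent
        a_c = ages.copy()
        a_p = np.where(par >= 0, ages[np.maximum(par, 0)], ages)
        self.t_old = np.maximum(0.0, a_p - np.maximum(a_c, tau))
        self.t_young = np.maximum(0.0, np.minimum(a_p, tau) - a_c)

    def loglik(self, q_old: float, q_young: float) -> float:
        e_o = np.exp(-2.0 * q_old * self.t_old)
        e_y = np.exp(-2.0 * q_young * self.t_young)
        a0 = 0.5 * (1.0 + e_o)
        a1 = 0.5 * (1.0 - e_o)
        b0 = 0.5 * (1.0 + e_y)
        b1 = 0.5 * (1.0 - e_y)
        p00 = (a0 * b0 + a1 * b1).tolist()
        p01 = (a0 * b1 + a1 * b0).tolist()
        down0 = [0.0] * self.n
        down1 = [0.0] * self.n
        for i, (d0, d1) in enumerate(self.tipdown):
            down0[i] = d0
            down1[i] = d1
        logscale = 0.0
        for v, c1, c2 in self.internal:
            pa, pb = p00[c1], p01[c1]
            d0, d1 = down0[c1], down1[c1]
            m0 = pa * d0 + pb * d1
            m1 = pb * d0 + pa * d1
            pa, pb = p00[c2], p01[c2]
            d0, d1 = down0[c2], down1[c2]
            l0 = m0 * (pa * d0 + pb * d1)
            l1 = m1 * (pb * d0 + pa * d1)
            m = l0 if l0 > l1 else l1
            if m <= 0.0:
                return -math.inf
            down0[v] = l0 / m
            down1[v] = l1 / m
            logscale += math.log(m)
        lik = self.prior[0] * down0[self.root] + self.prior[1] * down1[self.root]
        if lik <= 0.0:
            return -math.inf
        return math.log(lik) + logscale


# ----------------------------------------------------------------------
# fitting


@dataclass
class FitResult:
    params: object
    loglik: float
    converged: bool


def fit_mk(
    tree: Phylogeny,
    states,
    symmetric: bool = True,
    root_prior: tuple[float, float] = (0.5, 0.5),
) -> FitResult:
    """ML fit of the time-homogeneous Mk2 model.

    Rates are optimized on the log scale with L-BFGS-B from multistart
    values spanning 1e-4 to 1 per my; with all tips in one state the
    optimum runs to the lower rate bound (rate ~ 0), which is reported,
    not an error.
    """
    _check_tree(tree)
    tips = _states_array(tree, states)

    if symmetric:
        engine = _SymEngine(tree, tips, root_prior)

        def nll(x):
            q = math.exp(x[0])
            return -engine.loglik(q, q)
        x0s = [[math.log(s)] for s in _STARTS]
        bounds = [(_LOG_LO, _LOG_HI)]
    else:
        def nll(x):
            mats = _branch_matrices_mk(tree, math.exp(x[0]), math.exp(x[1]))
            return -_loglik_from_mats(tree, tips, mats, root_prior)
        x0s = [[math.log(s), math.log(s)] for s in _STARTS]
        x0s += [[math.log(1e-3), math.log(1e-1)], [math.log(1e-1), math.log(1e-3)]]
        bounds = [(_LOG_LO, _LOG_HI)] * 2

    best = None
    ok = False
    for x0 in x0s:
        res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                       options={"ftol": 1e-10, "gtol": 1e-8})
        if best is None or res.fun < best.fun:
            best = res
            ok = bool(res.success)
    if symmetric:
        q = math.exp(best.x[0])
        params = MkParams(q, q, symmetric=True, root_prior=root_prior)
    else:
        params = MkParams(math.exp(best.x[0]), math.exp(best.x[1]),
                          symmetric=False, root_prior=root_prior)
    return FitResult(params, -float(best.fun), ok)


def fit_epoch(
    tree: Phylogeny,
    states,
    tau: float,
    root_prior: tuple[float, float] = (0.5, 0.5),
    extra_starts: list | None = None,
) -> FitResult:
    """ML fit of (q_old, q_young) for a fixed epoch boundary ``tau``."""
    _check_tree(tree)
    if tau >= tree.root_age():
        raise ValueError("tau must be younger than the root age")
    tips = _states_array(tree, states)
    engine = _SymEngine(tree, tips, root_prior)
    engine.set_tau(tau)
    x0s = [[math.log(s), math.log(s)] for s in _STARTS]
    if extra_starts:
        x0s = list(extra_starts) + x0s
    return _optimize_epoch(engine, tau, root_prior, x0s)


def _optimize_epoch(engine: _SymEngine, tau, root_prior, starts) -> FitResult:
    def nll(x):
        return -engine.loglik(math.exp(x[0]), math.exp(x[1]))

    bounds = [(_LOG_LO, _LOG_HI)] * 2
    best = None
    ok = False
    for x0 in starts:
        res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                       options={"ftol": 1e-10, "gtol": 1e-8})
        if best is None or res.fun < best.fun:
            best = res
            ok = bool(res.success)
    params = EpochMkParams(tau, math.exp(best.x[0]), math.exp(best.x[1]), root_prior)
    return FitResult(params, -float(best.fun), ok)


@dataclass
class LikelihoodProfile:
    """Epoch-boundary likelihood profile.

    ``delta_lnl[i]`` is the ML log-likelihood gain of the two-epoch
    model with boundary ``taus[i]`` over the time-homogeneous symmetric
    fit; non-negative everywhere because the homogeneous model is
    nested (q_old = q_young).
    """

    taus: np.ndarray
    delta_lnl: np.ndarray
    loglik_homogeneous: float
    best_tau: float
    best_fit: FitResult
    homogeneous_fit: FitResult = None


def sweep_epochs(
    tree: Phylogeny,
    states,
    tau_min: float = SWEEP_TAU_MIN,
    tau_max: float = SWEEP_TAU_MAX,
    step: float = SWEEP_TAU_STEP,
    root_prior: tuple[float, float] = (0.5, 0.5),
    full_multistart_every: int = 20,
) -> LikelihoodProfile:
    """Profile the two-epoch likelihood over a grid of boundary times.

    At each grid point (q_old, q_young) are refit by ML; the
    homogeneous symmetric baseline is refit on the same tree and its
    optimum is always included among the starting points, which
    guarantees delta lnL >= 0.  Neighbouring grid points have similar
    optima, so warm starts from the previous point are used, with the
    full multistart re-run every ``full_multistart_every`` points.
    """
    hom = fit_mk(tree, states, symmetric=True, root_prior=root_prior)
    log_qh = math.log(max(hom.params.q01, _RATE_LO))
    taus = np.arange(tau_min, tau_max + 0.5 * step, step, dtype=float)
    taus = taus[taus < tree.root_age()]
    if len(taus) == 0:
        raise ValueError("empty tau grid after clipping below the root age")

    tips = _states_array(tree, states)
    engine = _SymEngine(tree, tips, root_prior)
    delta = np.empty(len(taus))
    best_fit = None
    best_tau = taus[0]
    warm = None
    for i, tau in enumerate(taus):
        starts = [[log_qh, log_qh]]
        if warm is not None:
            starts.append(warm)
        if warm is None or i % full_multistart_every == 0:
            starts += [[math.log(s), math.log(s)] for s in _STARTS]
        engine.set_tau(float(tau))
        fit = _optimize_epoch(engine, float(tau), root_prior, starts)
        warm = [math.log(max(fit.params.q_old, _RATE_LO)),
                math.log(max(fit.params.q_young, _RATE_LO))]
        delta[i] = max(fit.loglik - hom.loglik, 0.0)
        if best_fit is None or fit.loglik > best_fit.loglik:
            best_fit = fit
            best_tau = float(tau)
    return LikelihoodProfile(taus, delta, hom.loglik, best_tau, best_fit, hom)


@dataclass
class ModelComparison:
    """AIC comparison of the three candidate trait-evolution models."""

    table: pd.DataFrame  # model, lnL, k, AIC, dAIC
    best_model: str
    fits: dict = field(repr=False, default_factory=dict)
    profile: LikelihoodProfile | None = field(repr=False, default=None)


def compare_models(
    tree: Phylogeny,
    states,
    root_prior: tuple[float, float] = (0.5, 0.5),
    tau_min: float = SWEEP_TAU_MIN,
    tau_max: float = SWEEP_TAU_MAX,
    step: float = SWEEP_TAU_STEP,
) -> ModelComparison:
    """Fit symmetric (k=1), asymmetric (k=2), and best-boundary
    two-epoch symmetric (k=3) models and compare by AIC = 2k - 2 lnL.

    The asymmetric epoch model is deliberately not a candidate: its
    likelihood surface is too poorly behaved to fit reliably.
    """
    sym = fit_mk(tree, states, symmetric=True, root_prior=root_prior)
    asym = fit_mk(tree, states, symmetric=False, root_prior=root_prior)
    prof = sweep_epochs(tree, states, tau_min, tau_max, step, root_prior)
    rows = [
        ("symmetric", sym.loglik, 1),
        ("asymmetric", asym.loglik, 2),
        ("epoch", prof.best_fit.loglik, 3),
    ]
    tab = pd.DataFrame(rows, columns=["model", "lnL", "k"])
    tab["AIC"] = 2 * tab["k"] - 2 * tab["lnL"]
    tab["dAIC"] = tab["AIC"] - tab["AIC"].min()
    best = tab.loc[tab["AIC"].idxmin(), "model"]
    fits = {"symmetric": sym, "asymmetric": asym, "epoch": prof.best_fit}
    return ModelComparison(tab, str(best), fits, prof)


# ----------------------------------------------------------------------
# marginal ancestral states


@dataclass
class MarginalReconstruction:
    """Per-node marginal probability of the extratropical state."""

    p_extratropical: np.ndarray  # length n_nodes, tip rows match data
    node_age: np.ndarray
    params: object


def _branch_mats(tree: Phylogeny, params) -> list:
    if isinstance(params, EpochMkParams):
        return _branch_matrices_epoch(tree, node_ages(tree), params)
    return _branch_matrices_mk(tree, params.q01, params.q10)


def marginal_asr(tree: Phylogeny, states, params) -> MarginalReconstruction:
    """Marginal ancestral state probabilities under a fitted model.

    Down-pass conditional likelihoods are combined with an up-pass
    carrying the likelihood of everything outside each node's subtree;
    the root uses the model's root prior.  Works for homogeneous
    (:class:`MkParams`) and epoch (:class:`EpochMkParams`) parameters.
    Tip rows reproduce the observed states exactly.
    """
    _check_tree(tree)
    tips = _states_array(tree, states)
    mats = _branch_mats(tree, params)
    prior = params.root_prior
    down, logscale = _downpass(tree, tips, mats)
    if down is None:
        raise ValueError("data have zero likelihood under these parameters")

    up = [None] * tree.n_nodes
    up[tree.root] = (prior[0], prior[1])
    post = list(tree.postorder)[::-1]  # preorder
    for v in post:
        ch = tree.children[v]
        if not ch:
            continue
        u0, u1 = up[v]
        # partial products of P_c down_c over children, excluding each child
        msgs = []
        for c in ch:
            p00, p01, p10, p11 = mats[c]
            d0, d1 = down[c]
            msgs.append((p00 * d0 + p01 * d1, p10 * d0 + p11 * d1))
        for idx, c in enumerate(ch):
            e0, e1 = u0, u1
            for jdx, m in enumerate(msgs):
                if jdx != idx:
                    e0 *= m[0]
                    e1 *= m[1]
            p00, p01, p10, p11 = mats[c]
            f0 = e0 * p00 + e1 * p10
            f1 = e0 * p01 + e1 * p11
            s = f0 + f1
            up[c] = (f0 / s, f1 / s) if s > 0 else (0.5, 0.5)

    probs = np.empty(tree.n_nodes)
    for v in range(tree.n_nodes):
        u0, u1 = up[v]
        d0, d1 = down[v]
        a0, a1 = u0 * d0, u1 * d1
        s = a0 + a1
        probs[v] = a1 / s if s > 0 else 0.5
    probs[: tree.n_tips] = tips.astype(float)
    return MarginalReconstruction(probs, node_ages(tree), params)


# ----------------------------------------------------------------------
# stochastic character mapping


@dataclass
class StochasticMaps:
    """Summary of sampled trait histories."""

    node_freq_extratropical: np.ndarray  # per node, fraction of maps in state 1
    mean_changes: float
    changes: np.ndarray  # per-map total number of state changes
    n_sims: int


def stochastic_maps(
    tree: Phylogeny,
    states,
    params,
    n_sims: int = 1000,
    seed: int | None = None,
) -> StochasticMaps:
    """Sample full trait histories conditional on the tip data.

    Node states are drawn from the joint posterior by backward
    filtering / forward sampling on the pruning quantities; branch
    paths (and hence change counts) are drawn by rejection sampling of
    endpoint-conditioned trajectories, switching to uniformization when
    rejection would be pathological.  Node-state frequencies converge
    on :func:`marginal_asr` as the number of maps grows.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    _check_tree(tree)
    rng = np.random.default_rng(seed)
    tips = _states_array(tree, states)
    mats = _branch_mats(tree, params)
    prior = params.root_prior
    down, _ = _downpass(tree, tips, mats)
    if down is None:
        raise ValueError("data have zero likelihood under these parameters")

    ages = node_ages(tree)
    if isinstance(params, EpochMkParams):
        segments = _epoch_segments(tree, ages, params)
    else:
        segments = {
            v: [(params.q01, params.q10, float(tree.length[v]))]
            for v in range(tree.n_nodes) if v != tree.root
        }

    preorder = list(tree.postorder)[::-1]
    counts1 = np.zeros(tree.n_nodes)
    changes = np.zeros(n_sims)
    state = np.empty(tree.n_nodes, dtype=np.int64)

    # root sampling weights
    r0 = prior[0] * down[tree.root][0]
    r1 = prior[1] * down[tree.root][1]
    p_root1 = r1 / (r0 + r1)

    for m in range(n_sims):
        u = rng.random(tree.n_nodes)  # one draw per node
        state[tree.root] = 1 if u[tree.root] < p_root1 else 0
        nch = 0
        for v in preorder:
            for c in tree.children[v]:
                p00, p01, p10, p11 = mats[c]
                d0, d1 = down[c]
                i = state[v]
                w1 = (p01 if i == 0 else p11) * d1
                w0 = (p00 if i == 0 else p10) * d0
                j = 1 if u[c] < w1 / (w0 + w1) else 0
                state[c] = j
                nch += _sample_branch_changes(segments[c], i, j, rng)
        counts1 += state
        changes[m] = nch
    return StochasticMaps(counts1 / n_sims, float(changes.mean()), changes, n_sims)


def _epoch_segments(tree, ages, params: EpochMkParams):
    """Chronological (old->young) rate segments per branch."""
    segs = {}
    tau, qo, qy = params.tau, params.q_old, params.q_young
    for v in range(tree.n_nodes):
        if v == tree.root:
            continue
        a_c, a_p = float(ages[v]), float(ages[tree.parent[v]])
        if a_p <= tau:
            segs[v] = [(qy, qy, a_p - a_c)]
        elif a_c >= tau:
            segs[v] = [(qo, qo, a_p - a_c)]
        else:
            segs[v] = [(qo, qo, a_p - tau), (qy, qy, tau - a_c)]
    return segs


def _sample_branch_changes(segments, i: int, j: int, rng) -> int:
    """Number of state changes on a branch conditioned on endpoints."""
    if len(segments) == 1:
        q01, q10, t = segments[0]
        return _sample_path_changes(q01, q10, t, i, j, rng)
    # two segments: sample the state at the epoch boundary first
    (qa01, qa10, ta), (qb01, qb10, tb) = segments
    pa = _pmat(qa01, qa10, ta)
    pb = _pmat(qb01, qb10, tb)
    w0 = pa[i * 2 + 0] * pb[0 * 2 + j]
    w1 = pa[i * 2 + 1] * pb[1 * 2 + j]
    midt = 1 if rng.random() < w1 / (w0 + w1) else 0
    return (_sample_path_changes(qa01, qa10, ta, i, midt, rng)
            + _sample_path_changes(qb01, qb10, tb, midt, j, rng))


_REJECTION_TRIES = 30
_UNIFORMIZATION_LOAD = 10.0  # switch when expected event count is large


def _sample_path_changes(q01, q10, t, i, j, rng) -> int:
    """Endpoint-conditioned change count for a 2-state chain on [0, t]."""
    if t <= 0.0:
        return 0 if i == j else 1  # zero-length branch with a forced flip
    rate = (q01, q10)
    if max(q01, q10) * t <= _UNIFORMIZATION_LOAD:
        for _ in range(_REJECTION_TRIES):
            s = i
            x = 0.0
            n = 0
            while True:
                r = rate[s]
                if r <= 0.0:
                    break
                x += rng.exponential(1.0 / r)
                if x >= t:
                    break
                s = 1 - s
                n += 1
            if s == j:
                return n
    return _uniformization_changes(q01, q10, t, i, j, rng)


def _uniformization_changes(q01, q10, t, i, j, rng) -> int:
    """Uniformization sampler for the endpoint-conditioned change count."""
    lam = max(q01, q10, 1e-12) * 1.05
    # R = I + Q/lam
    r = np.array([[1.0 - q01 / lam, q01 / lam], [q10 / lam, 1.0 - q10 / lam]])
    p = _pmat(q01, q10, t)
    pij = p[i * 2 + j]
    if pij <= 0.0:
        return 0 if i == j else 1
    # sample N | endpoints: P(N=n) prop pois(lam t; n) * R^n[i, j]
    mu = lam * t
    u = rng.random() * pij
    rn = np.eye(2)
    pois = math.exp(-mu)
    acc = 0.0
    n = 0
    powers = [rn.copy()]
    while True:
        acc += pois * rn[i, j]
        if u <= acc or n > 10000 + 10 * mu:
            break
        n += 1
        pois *= mu / n
        rn = rn @ r
        powers.append(rn.copy())
    # sample the uniformized chain backwards and count real changes
    s = i
    nch = 0
    for k in range(1, n + 1):
        back = powers[n - k]
        w = np.array([r[s, 0] * back[0, j], r[s, 1] * back[1, j]])
        tot = w.sum()
        nxt = s if tot <= 0 else (1 if rng.random() < w[1] / tot else 0)
        if nxt != s:
            nch += 1
        s = nxt
    return nch
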