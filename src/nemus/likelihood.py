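"""Branch-heterogeneous phylogenetic likelihood and ML fitting.

The pruning recursion runs over compressed site patterns with per-node
rescaling (accumulated log factors) to avoid underflow.  Every branch uses
the transition matrix of its *own* mutation-selection model, so shift
configurations in which the fitness profile changes along the tree are
handled natively; root frequencies are either the stationary distribution of
the root (base) model or a free 61-vector.

Caching: each node's partial likelihood depends only on the parameters of
the models used in its subtree.  The engine tracks a version number per
fitness profile (and one for the shared mutation parameters) and recomputes
a node only when something below it changed.  During the greedy shift
search, provisional fits perturb a single clade profile, so only that clade
and its root-ward path are recomputed.

Free root frequencies are not handed to the outer optimiser: for fixed
substitution parameters the log-likelihood is concave in the root
frequencies (a per-site mixture over 61 root states), so they are profiled
out by EM to a tight tolerance inside each objective evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.optimize

from . import mutsel_core as mc
from .mutsel_core import (
    CODON_SPACE,
    FitnessProfile,
    FixationForm,
    MutationParams,
    MutSelModel,
)
from .phylo_data import CodonAlignment, Phylogeny, ShiftConfiguration, assign_models

__all__ = [
    "LikelihoodEngine",
    "FreeMask",
    "FitSettings",
    "FitResult",
    "log_likelihood",
    "fit",
    "fit_root_frequencies",
]

#: Fitness coordinates are optimised as (f - 1) / FITNESS_SCALE so a unit
#: step is a realistic selection-coefficient increment.
FITNESS_SCALE = 1e-5


@dataclass
class FreeMask:
    """Which parameter groups a fit may move.

    ``profiles`` is one flag per profile in ``config.profiles`` (base first);
    ``None`` frees all of them.  ``root`` applies only in free-root mode
    (``None`` = free them iff the configuration is in free-root mode).
    """

    kappa: bool = True
    theta: bool = True
    profiles: tuple[bool, ...] | None = None
    root: bool | None = None

    @classmethod
    def nothing(cls) -> "FreeMask":
        return cls(kappa=False, theta=False, profiles=(), root=False)

    def resolved(self, engine: "LikelihoodEngine") -> "FreeMask":
        profs = self.profiles
        if profs is None:
            profs = (True,) * len(engine.profiles)
        elif len(profs) < len(engine.profiles):
            profs = tuple(profs) + (False,) * (len(engine.profiles) - len(profs))
        root = self.root
        if root is None:
            root = engine.free_root
        return FreeMask(self.kappa, self.theta, tuple(profs), bool(root))


@dataclass
class FitSettings:
    """Optimiser contract: bounded, derivative-free from the caller's view,
    deterministic given identical starts."""

    method: str = "lbfgs"  # "lbfgs" (finite-difference) or "powell"
    maxfev: int = 40000
    maxiter: int = 200
    ftol: float = 1e-9
    gtol: float = 1e-7
    fd_step: float = 1e-4
    kappa_bounds: tuple[float, float] = (0.05, 50.0)
    theta_alr_bound: float = 8.0
    em_tol: float = 1e-10
    em_max_iter: int = 2000


@dataclass
class FitResult:
    kappa: float
    theta: tuple[float, float, float, float]
    profiles: list[FitnessProfile]
    root_frequencies: object
    log_likelihood: float
    k_params: int
    converged: bool
    n_iter: int
    n_fev: int


class LikelihoodEngine:
    """Pruning likelihood for one (tree, alignment, shift configuration)."""

    def __init__(
        self,
        tree: Phylogeny,
        alignment: CodonAlignment,
        config: ShiftConfiguration,
        mutation: MutationParams | None = None,
        fixation_form: FixationForm | str = FixationForm.non_reversible,
        s_max: float = mc.DEFAULT_S_MAX,
    ) -> None:
        self.tree = tree
        self.alignment = alignment
        self.fixation_form = FixationForm(fixation_form)
        self.s_max = s_max
        leaf_names = {tree.leaf_labels[v] for v in tree.leaves}
        if not leaf_names <= set(alignment.taxa):
            missing = sorted(leaf_names - set(alignment.taxa))
            raise ValueError(f"taxa missing from alignment: {missing}")

        # site pattern compression
        rows = np.stack(
            [alignment.row(tree.leaf_labels[v]) for v in tree.leaves], axis=0
        )
        patterns, inverse, counts = np.unique(
            rows, axis=1, return_inverse=True, return_counts=True
        )
        self.patterns = patterns  # (n_leaves, n_patterns)
        self.pattern_weights = counts.astype(float)
        self.pattern_index = inverse
        self.n_sites = alignment.codes.shape[1]
        self.leaf_row = {v: i for i, v in enumerate(tree.leaves)}

        # mutable parameter state
        self.mutation = mutation or MutationParams()
        self.profiles: list[FitnessProfile] = list(config.profiles)
        self.shift_branches = [b for b, _ in config.shifts]
        self.free_root = config.free_root
        if self.free_root:
            self.root_frequencies = np.asarray(config.root_frequencies, float).copy()
        else:
            self.root_frequencies = None
        self.branch_profile = assign_models(tree, config)

        # version bookkeeping
        self._profile_version = [0] * len(self.profiles)
        self._mutation_version = 0
        self._root_version = 0
        # profiles present at or below each node (via branches under it)
        self._subtree_profiles: list[tuple[int, ...]] = [()] * tree.n_nodes
        for v in tree.postorder:
            s: set[int] = set()
            for c in tree.children[v]:
                s.add(int(self.branch_profile[c]))
                s.update(self._subtree_profiles[c])
            self._subtree_profiles[v] = tuple(sorted(s))

        self._Q_cache: dict[int, tuple[tuple, np.ndarray]] = {}
        self._eig_cache: dict[int, tuple[tuple, object]] = {}
        self._P_cache: dict[int, tuple[tuple, np.ndarray]] = {}
        self._partial_cache: dict[int, tuple[tuple, np.ndarray, np.ndarray]] = {}
        self._pi_cache: tuple[tuple, np.ndarray] | None = None
        self.n_evaluations = 0

    # -- parameter setters (version-bumping, diff-checked) -----------------

    def set_mutation(self, mutation: MutationParams) -> None:
        if mutation != self.mutation:
            self.mutation = mutation
            self._mutation_version += 1

    def set_profile(self, i: int, profile: FitnessProfile) -> None:
        if profile.f != self.profiles[i].f:
            self.profiles[i] = profile
            self._profile_version[i] += 1

    def set_root_frequencies(self, rho: np.ndarray) -> None:
        if not self.free_root:
            raise ValueError("engine is in equilibrium-root mode")
        rho = np.asarray(rho, dtype=float)
        self.root_frequencies = rho / rho.sum()
        self._root_version += 1

    # -- model matrices ----------------------------------------------------

    def _model(self, i: int) -> MutSelModel:
        return MutSelModel(
            mutation=self.mutation,
            fitness=self.profiles[i],
            fixation_form=self.fixation_form,
            s_max=self.s_max,
        )

    def scaled_Q(self, i: int) -> np.ndarray:
        key = (self._profile_version[i], self._mutation_version)
        hit = self._Q_cache.get(i)
        if hit is None or hit[0] != key:
            Q = mc.scaled_generator(self._model(i))
            self._Q_cache[i] = (key, Q)
            return Q
        return hit[1]

    def _propagator(self, i: int):
        """Spectral decomposition of profile ``i``'s generator, shared by all
        branches carrying that profile; ``None`` when the eigenbasis is too
        ill-conditioned, in which case branches fall back to Pade expm."""
        key = (self._profile_version[i], self._mutation_version)
        hit = self._eig_cache.get(i)
        if hit is None or hit[0] != key:
            Q = self.scaled_Q(i)
            try:
                w, V = np.linalg.eig(Q)
                Vinv = np.linalg.inv(V)
                decomp = (w, V, Vinv) if np.linalg.cond(V) < 1e8 else None
            except np.linalg.LinAlgError:
                decomp = None
            self._eig_cache[i] = (key, decomp)
            return decomp
        return hit[1]

    def branch_matrix(self, b: int) -> np.ndarray:
        """Transition matrix exp(Q_b * t_b) for the branch above node ``b``."""
        i = int(self.branch_profile[b])
        key = (self._profile_version[i], self._mutation_version)
        hit = self._P_cache.get(b)
        if hit is None or hit[0] != key:
            t = float(self.tree.branch_length[b])
            decomp = self._propagator(i)
            if decomp is None:
                P = mc.transition_probabilities(self.scaled_Q(i), t)
            else:
                w, V, Vinv = decomp
                P = np.real((V * np.exp(w * t)) @ Vinv)
                np.clip(P, 0.0, None, out=P)
                P /= P.sum(axis=1, keepdims=True)
            self._P_cache[b] = (key, P)
            return P
        return hit[1]

    def root_distribution(self) -> np.ndarray:
        """Root codon frequencies: free vector or stationary of the base model."""
        if self.free_root:
            return self.root_frequencies
        key = (self._profile_version[0], self._mutation_version)
        if self._pi_cache is None or self._pi_cache[0] != key:
            self._pi_cache = (key, mc.stationary_distribution(self.scaled_Q(0)))
        return self._pi_cache[1]

    # -- pruning -----------------------------------------------------------

    def _partial_key(self, v: int) -> tuple:
        return (
            self._mutation_version,
            tuple(self._profile_version[i] for i in self._subtree_profiles[v]),
        )

    def node_partials(self, v: int) -> tuple[np.ndarray, np.ndarray]:
        """Partial likelihoods (n_patterns, 61) and per-pattern log scale
        factors for the subtree below node ``v``, conditional on the state
        at ``v``."""
        key = self._partial_key(v)
        hit = self._partial_cache.get(v)
        if hit is not None and hit[0] == key:
            return hit[1], hit[2]
        npat = self.patterns.shape[1]
        part = np.ones((npat, 61))
        scale = np.zeros(npat)
        for c in self.tree.children[v]:
            P = self.branch_matrix(c)
            if self.tree.is_leaf(c):
                codes = self.patterns[self.leaf_row[c]]
                contrib = np.where(
                    (codes >= 0)[:, None], P[:, np.clip(codes, 0, 60)].T, 1.0
                )
            else:
                cpart, cscale = self.node_partials(c)
                contrib = cpart @ P.T
                scale = scale + cscale
            part = part * contrib
        m = part.max(axis=1)
        m = np.where(m > 0, m, 1.0)
        part = part / m[:, None]
        scale = scale + np.log(m)
        self._partial_cache[v] = (key, part, scale)
        return part, scale

    def root_partials(self) -> tuple[np.ndarray, np.ndarray]:
        return self.node_partials(self.tree.root)

    def site_log_likelihoods(self) -> np.ndarray:
        """Per-pattern log-likelihoods (use ``pattern_weights`` to expand)."""
        part, scale = self.root_partials()
        rho = self.root_distribution()
        lik = part @ rho
        if np.any(lik <= 0):
            return np.full(scale.shape, -np.inf)
        return np.log(lik) + scale

    def log_likelihood(self) -> float:
        self.n_evaluations += 1
        site_ll = self.site_log_likelihoods()
        return float(self.pattern_weights @ site_ll)

    # -- EM profiling of free root frequencies -----------------------------

    def optimise_root_frequencies(
        self, tol: float = 1e-10, max_iter: int = 2000
    ) -> float:
        """Maximise the likelihood over the free root frequencies by EM.

        The objective is concave in the root frequencies, so EM converges to
        the global profile maximum from any interior start (the current
        vector is used as the warm start).  Returns the profiled logL.
        """
        if not self.free_root:
            raise ValueError("engine is in equilibrium-root mode")
        part, scale = self.root_partials()
        w = self.pattern_weights
        floor = 1e-16  # keeps every pattern's mixture likelihood positive
        rho = np.clip(self.root_frequencies, floor, None)
        rho = rho / rho.sum()
        const = float(w @ scale)
        last = -np.inf
        for _ in range(max_iter):
            lik = np.maximum(part @ rho, 1e-300)  # (npat,)
            ll = float(w @ np.log(lik)) + const
            resp = (part * rho[None, :]) / lik[:, None]
            rho = np.clip((w @ resp) / w.sum(), floor, None)
            rho = rho / rho.sum()
            if ll - last <= tol * (1.0 + abs(ll)):
                last = ll
                break
            last = ll
        self.root_frequencies = rho
        self._root_version += 1
        lik = np.maximum(part @ rho, 1e-300)
        return float(w @ np.log(lik)) + const


def log_likelihood(engine: LikelihoodEngine) -> float:
    """Module-level convenience wrapper."""
    return engine.log_likelihood()


# ---------------------------------------------------------------------------
# Parameter packing


def _pack(engine: LikelihoodEngine, mask: FreeMask, settings: FitSettings):
    x0: list[float] = []
    lo: list[float] = []
    hi: list[float] = []
    if mask.kappa:
        x0.append(np.log(engine.mutation.kappa))
        lo.append(np.log(settings.kappa_bounds[0]))
        hi.append(np.log(settings.kappa_bounds[1]))
    if mask.theta:
        th = np.asarray(engine.mutation.theta)
        x0.extend(np.log(th[:3] / th[3]))
        lo.extend([-settings.theta_alr_bound] * 3)
        hi.extend([settings.theta_alr_bound] * 3)
    for i, free in enumerate(mask.profiles):
        if not free:
            continue
        prof = engine.profiles[i]
        b = prof.bound / FITNESS_SCALE
        x0.extend((prof.free - 1.0) / FITNESS_SCALE)
        lo.extend([-b] * 19)
        hi.extend([b] * 19)
    return np.array(x0), list(zip(lo, hi))


def _unpack(engine: LikelihoodEngine, mask: FreeMask, x: np.ndarray) -> None:
    k = 0
    mut = engine.mutation
    kappa, theta = mut.kappa, mut.theta
    if mask.kappa:
        kappa = float(np.exp(x[k]))
        k += 1
    if mask.theta:
        z = np.concatenate([np.exp(x[k : k + 3]), [1.0]])
        theta = tuple(z / z.sum())
        k += 3
    if mask.kappa or mask.theta:
        engine.set_mutation(replace(mut, kappa=kappa, theta=theta))
    for i, free in enumerate(mask.profiles):
        if not free:
            continue
        f = 1.0 + x[k : k + 19] * FITNESS_SCALE
        k += 19
        engine.set_profile(
            i, FitnessProfile.from_free(f, bound=engine.profiles[i].bound)
        )


def _count_free(mask: FreeMask) -> int:
    n = 0
    if mask.kappa:
        n += 1
    if mask.theta:
        n += 3
    n += 19 * sum(mask.profiles)
    if mask.root:
        n += 60
    return n


def fit(
    engine: LikelihoodEngine,
    free: FreeMask | None = None,
    settings: FitSettings | None = None,
) -> FitResult:
    """Bounded maximisation of the log-likelihood over the masked parameters.

    Fitnesses move inside their configured band, theta on the simplex via an
    additive log-ratio transform, kappa on a log scale; free root frequencies
    are profiled out by EM inside each evaluation.  Optimisation failure is
    reported through ``converged`` rather than raised, so a shift search can
    treat it as an outcome.
    """
    settings = settings or FitSettings()
    mask = (free or FreeMask()).resolved(engine)
    x0, bounds = _pack(engine, mask, settings)

    best = {"ll": -np.inf, "x": x0.copy() if x0.size else x0}

    def objective(x: np.ndarray) -> float:
        try:
            _unpack(engine, mask, x)
            if mask.root:
                ll = engine.optimise_root_frequencies(
                    tol=settings.em_tol, max_iter=settings.em_max_iter
                )
                engine.n_evaluations += 1
            else:
                ll = engine.log_likelihood()
        except (ValueError, np.linalg.LinAlgError):
            # numerically pathological corner of the box (e.g. a reducible
            # generator from a degenerate theta); steer the optimiser away
            return 1e300
        if not np.isfinite(ll):
            return 1e300
        if ll > best["ll"]:
            best["ll"] = ll
            best["x"] = x.copy()
        return -ll

    if x0.size == 0:
        if mask.root:
            ll = engine.optimise_root_frequencies(
                tol=settings.em_tol, max_iter=settings.em_max_iter
            )
            n_iter = 1
        else:
            ll = engine.log_likelihood()
            n_iter = 0
        return _result(engine, mask, ll, True, n_iter, 1)

    if settings.method == "powell":
        res = scipy.optimize.minimize(
            objective,
            x0,
            method="Powell",
            bounds=bounds,
            options={
                "maxfev": settings.maxfev,
                "maxiter": settings.maxiter,
                "ftol": settings.ftol,
                "xtol": 1e-6,
            },
        )
    else:
        res = scipy.optimize.minimize(
            objective,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={
                "maxfun": settings.maxfev,
                "maxiter": settings.maxiter,
                "ftol": settings.ftol,
                "gtol": settings.gtol,
                "eps": settings.fd_step,
            },
        )
    # leave the engine at the best point seen (the optimiser's terminal point
    # can be worse after a failed line search)
    ll = -objective(res.x)
    if best["ll"] > ll:
        ll = -objective(best["x"])
    # a fit "fails" only when no finite likelihood was ever found; hitting
    # the iteration cap still yields a usable (recorded) optimum
    converged = np.isfinite(ll) and ll > -1e299
    return _result(engine, mask, ll, converged, int(res.nit), int(res.nfev))


def _result(
    engine: LikelihoodEngine,
    mask: FreeMask,
    ll: float,
    converged: bool,
    n_iter: int,
    n_fev: int,
) -> FitResult:
    return FitResult(
        kappa=engine.mutation.kappa,
        theta=tuple(engine.mutation.theta),
        profiles=list(engine.profiles),
        root_frequencies=(
            None if not engine.free_root else engine.root_frequencies.copy()
        ),
        log_likelihood=ll,
        k_params=_count_free(mask),
        converged=converged,
        n_iter=n_iter,
        n_fev=n_fev,
    )


def fit_root_frequencies(
    engine: LikelihoodEngine, settings: FitSettings | None = None
) -> FitResult:
    """Fit with the 60 free root frequencies included (free-root mode)."""
    if not engine.free_root:
        raise ValueError("configuration must be in free-root mode")
    return fit(engine, FreeMask(root=True), settings)
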