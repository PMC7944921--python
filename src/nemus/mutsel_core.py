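"""Mutation-selection codon models with a non-reversible fixation probability.

The substitution process acts on the 61 sense codons of the universal genetic
code.  Rates factor into a mutation layer (an HKY nucleotide process restricted
to single-nucleotide codon changes) and a Wright-Fisher fixation probability
driven by 20 amino-acid Darwinian fitnesses::

    q_ab = 2 N_p mu * HKY(a -> b) * P_fix(s_ab),   s_ab = f_b / f_a - 1

The fixation probability is used in its full diffusion form

    P_fix = (1 - exp(-2 s)) / (1 - exp(-4 N_p s))

*without* log-linearisation of the numerator, which makes the generator
asymmetric and the process non-time-reversible.  A standard reversible
approximation, 2 s / (1 - exp(-4 N_p s)), is provided behind the same
interface for comparison.  Both reduce to 1 / (2 N_p) for neutral changes.

Codons are ordered lexicographically with the alphabetical base order
A < C < G < T; all matrices, alignments and frequency vectors in the package
use this fixed ordering.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

__all__ = [
    "CodonSpace",
    "FitnessProfile",
    "MutationParams",
    "MutSelModel",
    "FixationForm",
    "AMINO_ACIDS",
    "DEFAULT_S_MAX",
    "DEFAULT_FITNESS_BOUND",
    "NEUTRAL_EPS",
    "selection_coefficient",
    "fixation_probability",
    "build_generator",
    "scale_generator",
    "stationary_distribution",
    "transition_probabilities",
    "detailed_balance_residual",
]

BASES = "ACGT"
STOP_CODONS = ("TAA", "TAG", "TGA")
#: Canonical amino acids, alphabetical one-letter order; the last (Y) anchors
#: the fitness scale at 1.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Universal genetic code, codon triplet -> one-letter amino acid.
_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

#: Selection coefficients with |s| above this default are rejected; the
#: diffusion formula itself is evaluated stably far beyond it, but fitness
#: differences of this size are outside the weak-selection regime the model
#: is meant for.
DEFAULT_S_MAX = 2.5e-4
#: Default ceiling on |f - 1| for fitness profiles.
DEFAULT_FITNESS_BOUND = 1e-4
#: |s| below this uses the exact neutral limit 1/(2 N_p) (the formula is 0/0).
NEUTRAL_EPS = 1e-12

_PURINES = frozenset("AG")


def _is_transition(b1: str, b2: str) -> bool:
    return (b1 in _PURINES) == (b2 in _PURINES)


class FixationForm(str, enum.Enum):
    """Which fixation probability the model uses."""

    non_reversible = "non_reversible"
    reversible = "reversible"


class CodonSpace:
    """The 61-codon state space with its single-nucleotide neighbour relation.

    Attributes
    ----------
    codons : list of str
        Sense codons, lexicographic in A<C<G<T base order.
    aa_index : ndarray of shape (61,)
        Index into :data:`AMINO_ACIDS` for each codon.
    neighbor_mask : ndarray of shape (61, 61), bool
        True where two codons differ at exactly one nucleotide position.
    target_base : ndarray of shape (61, 61), int
        For neighbour pairs (a, b), the index in ``ACGT`` of the base that
        codon ``b`` carries at the differing position; -1 elsewhere.
    transition_mask : ndarray of shape (61, 61), bool
        True for neighbour pairs whose differing bases are both purines or
        both pyrimidines.
    """

    def __init__(self) -> None:
        self.codons = [
            b1 + b2 + b3
            for b1 in BASES
            for b2 in BASES
            for b3 in BASES
            if b1 + b2 + b3 not in STOP_CODONS
        ]
        self.index = {c: i for i, c in enumerate(self.codons)}
        self.n = len(self.codons)
        self.aa_index = np.array(
            [AMINO_ACIDS.index(_CODON_TABLE[c]) for c in self.codons], dtype=np.intp
        )
        n = self.n
        self.neighbor_mask = np.zeros((n, n), dtype=bool)
        self.target_base = np.full((n, n), -1, dtype=np.intp)
        self.diff_position = np.full((n, n), -1, dtype=np.intp)
        self.transition_mask = np.zeros((n, n), dtype=bool)
        for i, ci in enumerate(self.codons):
            for j, cj in enumerate(self.codons):
                diffs = [p for p in range(3) if ci[p] != cj[p]]
                if len(diffs) != 1:
                    continue
                (p,) = diffs
                self.neighbor_mask[i, j] = True
                self.diff_position[i, j] = p
                self.target_base[i, j] = BASES.index(cj[p])
                self.transition_mask[i, j] = _is_transition(ci[p], cj[p])

    def translate(self, codon: str) -> str:
        """One-letter amino acid for a sense codon."""
        return AMINO_ACIDS[self.aa_index[self.index[codon]]]

    def neighbors(self, codon: str) -> list[str]:
        i = self.index[codon]
        return [self.codons[j] for j in np.nonzero(self.neighbor_mask[i])[0]]


#: Shared immutable instance; the space never changes.
CODON_SPACE = CodonSpace()


@dataclass(frozen=True)
class FitnessProfile:
    """20 amino-acid Darwinian fitnesses; the last entry is anchored at 1.

    The 19 free parameters are the fitnesses of the first 19 amino acids in
    alphabetical order relative to the 20th (tyrosine).  All values must stay
    within ``1 +/- bound``: the fixation formula is only meaningful in the
    weak-selection regime.
    """

    f: tuple[float, ...]
    bound: float = DEFAULT_FITNESS_BOUND

    def __post_init__(self) -> None:
        if len(self.f) != 20:
            raise ValueError(f"fitness profile needs 20 entries, got {len(self.f)}")
        arr = np.asarray(self.f, dtype=float)
        if np.any(arr <= 0):
            raise ValueError("fitnesses must be strictly positive")
        if arr[-1] != 1.0:
            raise ValueError("anchored (last) fitness must equal 1 exactly")
        if np.any(np.abs(arr - 1.0) > self.bound + 1e-15):
            worst = float(np.max(np.abs(arr - 1.0)))
            raise ValueError(
                f"fitness deviates from 1 by {worst:.3g}, beyond bound {self.bound:.3g}"
            )

    @classmethod
    def neutral(cls) -> "FitnessProfile":
        return cls(f=(1.0,) * 20)

    @classmethod
    def from_free(cls, free: np.ndarray, bound: float = DEFAULT_FITNESS_BOUND) -> "FitnessProfile":
        """Build from the 19 free fitnesses (anchor appended)."""
        free = np.asarray(free, dtype=float)
        if free.shape != (19,):
            raise ValueError("expected 19 free fitnesses")
        return cls(f=tuple(free) + (1.0,), bound=bound)

    @property
    def free(self) -> np.ndarray:
        """The 19 free fitnesses (anchor excluded)."""
        return np.asarray(self.f[:19], dtype=float)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.f, dtype=float)


@dataclass(frozen=True)
class MutationParams:
    """Tree-wide mutation layer: HKY rates plus population size.

    Parameters
    ----------
    kappa : transition/transversion rate ratio.
    theta : nucleotide frequencies (A, C, G, T), summing to 1.
    mu : per-individual mutation rate; cancels under the neutral-rate scaling.
    N_p : effective diploid population size, fixed across the tree.
    """

    kappa: float = 1.0
    theta: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    mu: float = 1e-6
    N_p: int = 100_000

    def __post_init__(self) -> None:
        th = np.asarray(self.theta, dtype=float)
        if th.shape != (4,) or np.any(th <= 0):
            raise ValueError("theta must be 4 positive frequencies")
        if abs(th.sum() - 1.0) > 1e-8:
            raise ValueError(f"theta must sum to 1, got {th.sum()!r}")
        if self.kappa <= 0 or self.mu <= 0 or self.N_p < 1:
            raise ValueError("kappa, mu must be > 0 and N_p >= 1")


@dataclass(frozen=True)
class MutSelModel:
    """One mutation-selection model: mutation layer + fitness profile + form."""

    mutation: MutationParams = field(default_factory=MutationParams)
    fitness: FitnessProfile = field(default_factory=FitnessProfile.neutral)
    fixation_form: FixationForm = FixationForm.non_reversible
    s_max: float = DEFAULT_S_MAX

    def neutral_counterpart(self) -> "MutSelModel":
        return MutSelModel(
            mutation=self.mutation,
            fitness=FitnessProfile.neutral(),
            fixation_form=self.fixation_form,
            s_max=self.s_max,
        )


def selection_coefficient(f_a: float, f_b: float) -> float:
    """Selection coefficient of a mutant with fitness ``f_b`` against wild type
    ``f_a``: ``f_b / f_a - 1``."""
    if f_a <= 0 or f_b <= 0:
        raise ValueError(f"fitnesses must be positive, got ({f_a}, {f_b})")
    return f_b / f_a - 1.0


def _check_s_range(s: np.ndarray, s_max: float) -> None:
    bad = np.abs(s) > s_max
    if np.any(bad):
        worst = float(np.asarray(s)[bad].flat[np.argmax(np.abs(np.asarray(s)[bad]))])
        raise ValueError(
            f"selection coefficient s={worst:.6g} outside supported range "
            f"|s| <= {s_max:.3g}"
        )


def fixation_probability(
    s,
    N_p: int,
    form: FixationForm | str = FixationForm.non_reversible,
    s_max: float = DEFAULT_S_MAX,
    neutral_eps: float = NEUTRAL_EPS,
):
    """Probability that a new mutant with selection coefficient ``s`` fixes.

    ``non_reversible`` evaluates the diffusion result
    ``(1 - exp(-2 s)) / (1 - exp(-4 N_p s))``; ``reversible`` the standard
    population-scaled approximation ``2 s / (1 - exp(-4 N_p s))``.  Both are
    computed with ``expm1`` so the tiny exponents of the weak-selection regime
    lose no precision, and both return exactly ``1 / (2 N_p)`` when
    ``|s| < neutral_eps``.  Accepts scalars or arrays.
    """
    form = FixationForm(form)
    if N_p < 1:
        raise ValueError("N_p must be >= 1")
    s_arr = np.asarray(s, dtype=float)
    _check_s_range(s_arr, s_max)
    neutral = np.abs(s_arr) < neutral_eps
    # placeholder 1.0 on neutral entries keeps the division finite
    s_safe = np.where(neutral, 1.0, s_arr)
    if form is FixationForm.non_reversible:
        numer = -np.expm1(-2.0 * s_safe)
        denom = -np.expm1(-4.0 * N_p * s_safe)
    else:
        # Antisymmetric (log) selection coefficient: makes the resulting
        # process exactly time-reversible (classical linearised-numerator
        # form); agrees with the ratio form to O(s^2).
        s_log = np.log1p(s_safe)
        numer = 2.0 * s_log
        denom = -np.expm1(-4.0 * N_p * s_log)
    out = np.where(neutral, 1.0 / (2.0 * N_p), numer / denom)
    if np.isscalar(s) or np.ndim(s) == 0:
        return float(out)
    return out


def build_generator(model: MutSelModel, space: CodonSpace = CODON_SPACE) -> np.ndarray:
    """61x61 unscaled generator ``q_ab = 2 N_p mu HKY(a->b) P_fix(s_ab)``.

    Only single-nucleotide neighbours get positive rates; the HKY factor is
    ``theta[target base] * kappa^[transition]``; the diagonal closes each row
    to zero.
    """
    mp = model.mutation
    theta = np.asarray(mp.theta, dtype=float)
    f = model.fitness.as_array()
    fa = f[space.aa_index][:, None]
    fb = f[space.aa_index][None, :]
    s = fb / fa - 1.0
    nb = space.neighbor_mask
    _check_s_range(s[nb], model.s_max)
    pfix = fixation_probability(
        np.where(nb, s, 0.0), mp.N_p, model.fixation_form, s_max=model.s_max
    )
    hky = theta[space.target_base] * np.where(space.transition_mask, mp.kappa, 1.0)
    Q = np.where(nb, 2.0 * mp.N_p * mp.mu * hky * pfix, 0.0)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _hky_codon_stationary(mp: MutationParams, space: CodonSpace) -> np.ndarray:
    """Stationary distribution of the neutral (pure HKY) codon process:
    product of base frequencies restricted to sense codons, renormalised."""
    theta = np.asarray(mp.theta, dtype=float)
    base_idx = {b: i for i, b in enumerate(BASES)}
    pi = np.array(
        [theta[base_idx[c[0]]] * theta[base_idx[c[1]]] * theta[base_idx[c[2]]]
         for c in space.codons]
    )
    return pi / pi.sum()


def neutral_expected_rate(model: MutSelModel, space: CodonSpace = CODON_SPACE) -> float:
    """Expected substitutions/site/time of the neutral counterpart model at
    its own stationary distribution."""
    neutral = model.neutral_counterpart()
    Qn = build_generator(neutral, space)
    pi = _hky_codon_stationary(model.mutation, space)
    return float(pi @ (-np.diag(Qn)))


def scale_generator(
    Q: np.ndarray, model: MutSelModel, space: CodonSpace = CODON_SPACE
) -> np.ndarray:
    """Rescale ``Q`` so one unit of time is one expected substitution per site
    under the *neutral* counterpart (all fitnesses 1) of ``model``.

    The per-individual mutation rate ``mu`` multiplies both ``Q`` and the
    neutral rate, so it cancels here.
    """
    rate = neutral_expected_rate(model, space)
    if rate <= 0 or not np.isfinite(rate):
        raise ValueError("neutral expected rate is degenerate; check parameters")
    return Q / rate


def scaled_generator(model: MutSelModel, space: CodonSpace = CODON_SPACE) -> np.ndarray:
    """Convenience: :func:`build_generator` followed by :func:`scale_generator`."""
    return scale_generator(build_generator(model, space), model, space)


def stationary_distribution(Q: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Stationary distribution of a (possibly non-reversible) generator.

    Solves the null left-eigenvector problem ``pi Q = 0`` directly by replacing
    one column of the singular system with the normalisation constraint; no
    reversibility shortcut is used.
    """
    n = Q.shape[0]
    A = Q.T.copy()
    A[-1, :] = 1.0
    b = np.zeros(n)
    b[-1] = 1.0
    scale = max(1.0, float(np.max(np.abs(Q))))
    try:
        pi = np.linalg.solve(A, b)
        pi = pi + np.linalg.solve(A, b - A @ pi)  # one refinement step
    except np.linalg.LinAlgError:
        pi = None
    if pi is None or float(np.max(np.abs(pi @ Q))) > tol * scale or pi.min() < -1e-9:
        # stationary mass can span many orders of magnitude when selection is
        # strong; fall back to propagating the chain for a long time, which
        # keeps the vector non-negative by construction
        P = scipy.linalg.expm(Q * (64.0 / scale))
        for _ in range(10):
            P = P @ P
            P /= P.sum(axis=1, keepdims=True)
        pi = P.mean(axis=0)
        if float(np.max(np.abs(pi @ Q))) > 1e-6 * scale:
            raise ValueError(
                f"stationary solve failed: residual {np.max(np.abs(pi @ Q)):.3g} "
                "(chain may be reducible or numerically singular)"
            )
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def transition_probabilities(Q: np.ndarray, t: float) -> np.ndarray:
    """``exp(Q t)`` by scaling-and-squaring Pade (safe for asymmetric,
    possibly non-diagonalisable generators).  Tiny negative entries from
    round-off are clamped to zero and rows renormalised."""
    if t < 0:
        raise ValueError(f"branch length must be >= 0, got {t}")
    if t == 0:
        return np.eye(Q.shape[0])
    P = scipy.linalg.expm(Q * t)
    P[(P < 0) & (P > -1e-12)] = 0.0
    if np.any(P < 0):
        raise ValueError("matrix exponential produced significant negative entries")
    return P / P.sum(axis=1, keepdims=True)


def detailed_balance_residual(Q: np.ndarray, pi: np.ndarray | None = None) -> float:
    """Max over codon pairs of ``|pi_a q_ab - pi_b q_ba|``; zero iff the chain
    satisfies detailed balance at its stationary distribution."""
    if pi is None:
        pi = stationary_distribution(Q)
    flux = pi[:, None] * Q
    return float(np.max(np.abs(flux - flux.T)))
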