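"""End-to-end simulation of the ASHIFT and RFREQ study designs.

Trees come from a pure-birth process with a balance knob: each lineage
speciates at ``birth_rate * exp(-balance * splits)`` where ``splits`` counts
the speciation events on its root-ward path.  ``balance = 0`` is the
constant-rate Yule process; positive values slow much-split lineages down
(more balanced trees), negative values speed them up (more imbalanced,
caterpillar-like trees).  Only these qualitative regimes are meaningful;
the scale of the knob is this package's own.

Fitness profiles are drawn Uniform(1 - 5e-5, 1 + 5e-5) on the 19 free
entries; a single selective shift is placed by first drawing a node level
(edge distance from the root) uniformly, then a node uniformly within that
level.  Root codon frequencies for the RFREQ design come from a symmetric
Dirichlet over the 61 sense codons.

Sequences evolve site-independently down the tree under each branch's own
scaled generator, by exact CTMC (Gillespie) simulation by default, or by
sampling from exp(Qt) rows.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import mutsel_core as mc
from .mutsel_core import (
    FitnessProfile,
    FixationForm,
    MutationParams,
    MutSelModel,
)
from .phylo_data import (
    CodonAlignment,
    Phylogeny,
    ShiftConfiguration,
    assign_models,
    node_time_depth,
    read_newick,
    write_codon_fasta,
    write_newick,
)

__all__ = [
    "SimulationSpec",
    "SimulatedReplicate",
    "BALANCE_CONDITIONS",
    "FITNESS_DRAW_HALF_WIDTH",
    "simulate_tree",
    "draw_fitness_profile",
    "place_shift",
    "draw_root_frequencies",
    "simulate_alignment",
    "simulate_replicate",
    "run_block",
]

#: Half-width of the uniform fitness draw around 1.
FITNESS_DRAW_HALF_WIDTH = 5e-5

#: Balance-knob values backing the three named tree-shape regimes.
BALANCE_CONDITIONS = {"BAL": 0.5, "BDP": 0.0, "IMB": -0.5}


@dataclass
class SimulationSpec:
    """One treatment block of the simulation study.

    ``series`` is "ASHIFT" (shift detection; equilibrium root) or "RFREQ"
    (free Dirichlet root, no shifts).  ``balance`` is one of the named
    regimes in :data:`BALANCE_CONDITIONS` or a numeric knob value.
    """

    series: str = "ASHIFT"
    taxa: int = 10
    codons: int = 300
    n_shifts: int = 0
    free_root: bool = False
    balance: object = "BDP"
    birth_rate: float = 0.5
    replicates: int = 20
    seed: int = 0
    dirichlet_concentration: float = 1.0
    kappa: float = 1.0
    N_p: int = 100_000

    def __post_init__(self) -> None:
        if self.series not in ("ASHIFT", "RFREQ"):
            raise ValueError(f"unknown series {self.series!r}")
        if self.n_shifts not in (0, 1):
            raise ValueError("n_shifts must be 0 or 1")
        if self.series == "RFREQ":
            self.free_root = True

    @property
    def balance_value(self) -> float:
        if isinstance(self.balance, str):
            return BALANCE_CONDITIONS[self.balance]
        return float(self.balance)


@dataclass
class SimulatedReplicate:
    tree: Phylogeny
    config: ShiftConfiguration
    alignment: CodonAlignment
    mutation: MutationParams
    seed: int
    shift_branch: int | None = None
    shift_time_depth: float | None = None


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_tree(
    taxa: int, birth_rate: float, balance: float = 0.0, seed=None
) -> Phylogeny:
    """Rooted ultrametric pure-birth tree with a tree-shape balance knob.

    The clock runs until the ``taxa``-th lineage appears, then continues for
    one further exponential waiting time (the time to the next, discarded,
    speciation) so pendant branches have positive length; tree age is not
    fixed.
    """
    if taxa < 3:
        raise ValueError("need at least 3 taxa")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be > 0")
    rng = _as_rng(seed)

    basal = [_Lineage(birth=0.0, splits=1), _Lineage(birth=0.0, splits=1)]
    active = list(basal)
    t = 0.0
    while True:
        rates = np.array([birth_rate * np.exp(-balance * ln.splits) for ln in active])
        total = rates.sum()
        t += rng.exponential(1.0 / total)
        if len(active) == taxa:
            # one extra waiting time already elapsed: the present sits just
            # before the (discarded) next speciation, so pendant branches
            # have positive length and tree age is not fixed
            break
        i = int(rng.choice(len(active), p=rates / total))
        node = active[i]
        node.end = t
        node.children = [
            _Lineage(birth=t, splits=node.splits + 1),
            _Lineage(birth=t, splits=node.splits + 1),
        ]
        active[i : i + 1] = node.children
    for ln in active:
        ln.end = t

    counter = [0]

    def render(node: "_Lineage") -> str:
        if node.children:
            inner = ",".join(render(c) for c in node.children)
            core = f"({inner})"
        else:
            counter[0] += 1
            core = f"t{counter[0]}"
        return f"{core}:{node.end - node.birth:.12g}"

    newick = "(" + ",".join(render(b) for b in basal) + ");"
    return read_newick(newick)


class _Lineage:
    __slots__ = ("birth", "end", "splits", "children")

    def __init__(self, birth: float, splits: int):
        self.birth = birth
        self.end = birth
        self.splits = splits
        self.children: list["_Lineage"] = []


def draw_fitness_profile(
    seed=None, half_width: float = FITNESS_DRAW_HALF_WIDTH,
    bound: float = mc.DEFAULT_FITNESS_BOUND,
) -> FitnessProfile:
    """19 free fitnesses i.i.d. Uniform(1 - half_width, 1 + half_width);
    the anchored 20th entry is exactly 1."""
    rng = _as_rng(seed)
    free = 1.0 + rng.uniform(-half_width, half_width, size=19)
    return FitnessProfile.from_free(free, bound=bound)


def place_shift(tree: Phylogeny, seed=None, exclude: set[int] | None = None) -> int:
    """Pick a shift branch by the two-stage uniform scheme: draw a node level
    (edge distance from the root, >= 1) uniformly among occupied levels, then
    a node uniformly within that level.  The branch above the chosen node is
    returned.  Nodes in ``exclude`` (e.g. a basal branch whose sibling is
    already shifted) are resampled away."""
    rng = _as_rng(seed)
    exclude = exclude or set()
    by_level: dict[int, list[int]] = {}
    for v in range(tree.n_nodes):
        if v == tree.root:
            continue
        by_level.setdefault(tree.node_level(v), []).append(v)
    levels = sorted(by_level)
    if len(levels) < 2:
        raise ValueError("tree has fewer than 2 depth levels")
    for _ in range(10_000):
        level = levels[int(rng.integers(len(levels)))]
        nodes = sorted(by_level[level])
        node = nodes[int(rng.integers(len(nodes)))]
        if node not in exclude:
            return node
    raise RuntimeError("could not place shift outside the excluded set")


def draw_root_frequencies(seed=None, concentration: float = 1.0) -> np.ndarray:
    """Symmetric Dirichlet(concentration) draw over the 61 sense codons."""
    if concentration <= 0:
        raise ValueError("concentration must be > 0")
    rng = _as_rng(seed)
    return rng.dirichlet(np.full(61, concentration))


def _gillespie_branch(
    states: np.ndarray, Q: np.ndarray, t: float, rng: np.random.Generator
) -> np.ndarray:
    """Exact CTMC simulation of all sites along one branch."""
    exit_rate = -np.diag(Q)
    jump_cum = np.cumsum(
        np.where(np.eye(61, dtype=bool), 0.0, Q) / np.where(exit_rate > 0, exit_rate, 1.0)[:, None],
        axis=1,
    )
    out = states.copy()
    for i in range(out.size):
        s = out[i]
        remaining = t
        while True:
            rate = exit_rate[s]
            if rate <= 0:
                break
            dt = rng.exponential(1.0 / rate)
            if dt > remaining:
                break
            remaining -= dt
            s = int(np.searchsorted(jump_cum[s], rng.random() * jump_cum[s, -1]))
        out[i] = s
    return out


def _matrix_branch(
    states: np.ndarray, Q: np.ndarray, t: float, rng: np.random.Generator
) -> np.ndarray:
    P = mc.transition_probabilities(Q, t)
    out = np.empty_like(states)
    for s in np.unique(states):
        idx = np.nonzero(states == s)[0]
        out[idx] = rng.choice(61, size=idx.size, p=P[s])
    return out


def simulate_alignment(
    tree: Phylogeny,
    config: ShiftConfiguration,
    codons: int,
    seed=None,
    mutation: MutationParams | None = None,
    fixation_form: FixationForm | str = FixationForm.non_reversible,
    method: str = "ctmc",
) -> CodonAlignment:
    """Simulate a codon alignment under a branch-heterogeneous model.

    Root codons are drawn from the configuration's root frequencies (the
    base model's stationary distribution in equilibrium mode); each branch
    then evolves every site under its own scaled generator.  ``method`` is
    ``"ctmc"`` (exact Gillespie jumps) or ``"matrix"`` (sample from exp(Qt)).
    """
    rng = _as_rng(seed)
    mutation = mutation or MutationParams(kappa=1.0)
    form = FixationForm(fixation_form)
    profile_idx = assign_models(tree, config)
    Qs = [
        mc.scaled_generator(
            MutSelModel(mutation=mutation, fitness=p, fixation_form=form)
        )
        for p in config.profiles
    ]
    if config.free_root:
        rho = np.asarray(config.root_frequencies, dtype=float)
    else:
        rho = mc.stationary_distribution(Qs[0])
    evolve = _gillespie_branch if method == "ctmc" else _matrix_branch
    if method not in ("ctmc", "matrix"):
        raise ValueError(f"unknown simulation method {method!r}")

    states: dict[int, np.ndarray] = {
        tree.root: rng.choice(61, size=codons, p=rho / rho.sum())
    }
    for v in reversed(range(tree.n_nodes)):  # pre-order (parents before kids)
        if v == tree.root:
            continue
        parent_states = states[tree.parent[v]]
        Q = Qs[int(profile_idx[v])]
        states[v] = evolve(parent_states, Q, float(tree.branch_length[v]), rng)
    taxa = [tree.leaf_labels[v] for v in tree.leaves]
    codes = np.stack([states[v] for v in tree.leaves], axis=0)
    return CodonAlignment(taxa, codes)


def simulate_replicate(spec: SimulationSpec, seed) -> SimulatedReplicate:
    """Draw one replicate of a treatment block: tree, truth, alignment."""
    rng = _as_rng(seed)
    tree = simulate_tree(
        spec.taxa, spec.birth_rate, spec.balance_value, seed=rng
    )
    mutation = MutationParams(kappa=spec.kappa, N_p=spec.N_p)
    base = draw_fitness_profile(rng)
    shift_branch = None
    depth = None
    shifts: list[tuple[int, FitnessProfile]] = []
    if spec.series == "ASHIFT" and spec.n_shifts == 1:
        shift_branch = place_shift(tree, rng)
        shifts = [(shift_branch, draw_fitness_profile(rng))]
        depth = node_time_depth(tree, shift_branch)
    if spec.free_root:
        root = draw_root_frequencies(rng, spec.dirichlet_concentration)
    else:
        root = "equilibrium"
    config = ShiftConfiguration(base, shifts, root)
    aln = simulate_alignment(
        tree, config, spec.codons, seed=rng, mutation=mutation
    )
    return SimulatedReplicate(
        tree=tree,
        config=config,
        alignment=aln,
        mutation=mutation,
        seed=-1,
        shift_branch=shift_branch,
        shift_time_depth=depth,
    )


def run_block(spec: SimulationSpec, out_dir: str | Path) -> list[Path]:
    """Simulate a full treatment block and archive it as text files.

    Per replicate: ``rep_NNN.fasta`` (alignment), ``rep_NNN.nwk`` (tree),
    ``rep_NNN.truth.json`` (true configuration, mutation parameters, shift
    position and time depth, per-replicate seed); plus ``manifest.tsv``.
    Fully reproducible from (spec, seed).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(spec.seed).spawn(spec.replicates)
    written: list[Path] = []
    manifest = ["replicate\tseed_entropy\ttaxa\tcodons\tn_shifts\tshift_branch\tshift_time_depth"]
    for r, ss in enumerate(seeds):
        rep = simulate_replicate(spec, np.random.default_rng(ss))
        stem = out / f"rep_{r:03d}"
        (stem.with_suffix(".fasta")).write_text(write_codon_fasta(rep.alignment))
        (stem.with_suffix(".nwk")).write_text(write_newick(rep.tree) + "\n")
        truth = {
            "spec": {k: (v if not isinstance(v, Path) else str(v)) for k, v in asdict(spec).items()},
            "replicate": r,
            "configuration": json.loads(rep.config.to_json()),
            "mutation": {
                "kappa": rep.mutation.kappa,
                "theta": list(rep.mutation.theta),
                "N_p": rep.mutation.N_p,
            },
            "shift_branch": rep.shift_branch,
            "shift_time_depth": rep.shift_time_depth,
        }
        (stem.parent / (stem.name + ".truth.json")).write_text(
            json.dumps(truth, indent=1)
        )
        manifest.append(
            f"{r}\t{ss.entropy}\t{spec.taxa}\t{spec.codons}\t{spec.n_shifts}"
            f"\t{rep.shift_branch}\t{rep.shift_time_depth}"
        )
        written.append(stem)
    (out / "manifest.tsv").write_text("\n".join(manifest) + "\n")
    return written
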