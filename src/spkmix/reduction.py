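"""The slow-promoter-kinetics limit: reduced promoter chain and Poisson
mixture.

As the promoter/protein timescale ratio epsilon goes to zero, the countable
master equation collapses onto an L-state Markov chain over global promoter
configurations.  A binding transition of gene i in global state d carries
rate alpha * E[TF | D = d] (alpha alone for constitutive switching) and an
unbinding transition carries alpha_minus; the conditional TF expectations
come from the product-Poisson conditional laws.  The stationary law of this
chain gives the mixture weights lambda, and the stationary PMF of the full
network is the lambda-weighted mixture of the conditional product-Poisson
components.

Generator orientation: columns sum to zero, entry (d', d) is the rate of
the transition d -> d' (the pdot = Lambda p convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.linalg import expm, null_space

from .conditional import ConditionalPoisson, conditional_law, expected_tf
from .grn import CONSTITUTIVE, GRNSpec, GeneState, enumerate_states, \
    require_valid, state_index

DEFAULT_WEIGHT_FLOOR = 1e-6


@dataclass
class ReducedGenerator:
    """L x L infinitesimal generator over promoter configurations."""

    matrix: np.ndarray
    states: list[GeneState]

    @property
    def n_states(self) -> int:
        return len(self.states)


def build_reduced_generator(spec: GRNSpec) -> ReducedGenerator:
    """Assemble the reduced chain transition-by-transition.

    Only one promoter site changes per transition.  TF-driven binding of
    gene i's site s gets rate alpha_s * E[TF_s | D = d]; constitutive
    activation gets alpha_s; every unbinding gets alpha_minus_s.
    """
    require_valid(spec)
    states = enumerate_states(spec)
    L = len(states)
    M = np.zeros((L, L))
    laws = [conditional_law(spec, s) for s in states]
    for d in states:
        law = laws[d.index]
        for i, g in enumerate(spec.genes):
            for j, jp, s in g.site_transitions():
                site = g.binding_sites[s] if g.binding_sites else CONSTITUTIVE
                alpha, alpha_ = g.binding_rates[s]
                if d.config[i] == j:  # binding j -> jp
                    if site == CONSTITUTIVE:
                        rate = alpha
                    else:
                        tf = spec.resolve_tf(site).output_species
                        rate = alpha * law.species_means[tf]
                    target = d.config[:i] + (jp,) + d.config[i + 1 :]
                    M[state_index(spec, target), d.index] += rate
                elif d.config[i] == jp:  # unbinding jp -> j
                    target = d.config[:i] + (j,) + d.config[i + 1 :]
                    M[state_index(spec, target), d.index] += alpha_
    np.fill_diagonal(M, M.diagonal() - M.sum(axis=0))
    return ReducedGenerator(matrix=M, states=states)


class NonUniqueStationaryError(RuntimeError):
    """The reduced chain has several closed communicating classes and no
    initial promoter distribution was given to split the weight."""

    def __init__(self, kernel_dim: int):
        super().__init__(
            f"stationary law is not unique: the generator kernel has "
            f"dimension {kernel_dim}; pass an initial promoter distribution"
        )
        self.kernel_dim = kernel_dim


def _closed_classes(M: np.ndarray):
    """Strongly connected components with no outgoing rate, plus the set of
    transient states."""
    L = M.shape[0]
    g = nx.DiGraph()
    g.add_nodes_from(range(L))
    src, dst = np.nonzero((M > 0) & ~np.eye(L, dtype=bool))
    g.add_edges_from(zip(dst, src))  # column = from, row = to
    closed, transient = [], []
    for comp in nx.strongly_connected_components(g):
        comp = sorted(comp)
        outside = set(range(L)) - set(comp)
        if any(M[j, i] > 0 for i in comp for j in outside):
            transient += comp
        else:
            closed.append(comp)
    return closed, sorted(transient)


def _class_stationary(M: np.ndarray, comp: list[int]) -> np.ndarray:
    sub = M[np.ix_(comp, comp)].copy()
    np.fill_diagonal(sub, 0.0)
    np.fill_diagonal(sub, -sub.sum(axis=0))
    ns = null_space(sub)
    if ns.shape[1] != 1:  # irreducible class: kernel must be 1-D
        raise RuntimeError("degenerate closed class in reduced generator")
    v = ns[:, 0]
    v = np.abs(v)
    return v / v.sum()


def stationary_weights(gen: ReducedGenerator,
                       initial: np.ndarray | None = None) -> np.ndarray:
    """Mixture weights lambda: the normalized nonnegative kernel vector of
    the reduced generator.

    For an irreducible chain this is the principal eigenvector.  The chain
    becomes reducible for non-leaky networks (binding rates vanish with the
    conditional TF means); then the stationary law of the unique closed
    communicating class is returned, and with several closed classes the
    weight is split by absorption probabilities from ``initial``.
    """
    M = gen.matrix
    L = gen.n_states
    closed, transient = _closed_classes(M)
    lam = np.zeros(L)
    if len(closed) == 1:
        comp = closed[0]
        lam[comp] = _class_stationary(M, comp)
        return lam
    if initial is None:
        raise NonUniqueStationaryError(len(closed))
    initial = np.asarray(initial, float)
    if initial.shape != (L,) or initial.min() < 0 or initial.sum() <= 0:
        raise ValueError("initial must be a probability vector of length L")
    initial = initial / initial.sum()
    # absorption probabilities: split transient mass among closed classes
    absorbed = {tuple(c): initial[c].sum() for c in closed}
    if transient:
        T = M[np.ix_(transient, transient)]
        for comp in closed:
            R = M[np.ix_(comp, transient)]  # rates transient -> this class
            # h = P(absorb in comp | start at transient state): T^T h = -r
            r = R.sum(axis=0)
            h = np.linalg.solve(T.T, -r)
            absorbed[tuple(comp)] += float(initial[transient] @ h)
    for comp in closed:
        lam[comp] = absorbed[tuple(comp)] * _class_stationary(M, comp)
    return lam / lam.sum()


def transition_matrix(gen: ReducedGenerator, t: float) -> np.ndarray:
    """Q(t) = exp(t * Lambda_r): column-stochastic transition probabilities
    of the reduced promoter chain."""
    if t < 0:
        raise ValueError("t must be nonnegative")
    return expm(t * gen.matrix)


# ---------------------------------------------------------------------------
# the mixture


@dataclass
class PoissonMixture:
    """SPK-limit stationary PMF: lambda-weighted Poisson-mixture."""

    spec: GRNSpec
    components: list[ConditionalPoisson]
    weights: np.ndarray
    generator: ReducedGenerator = field(repr=False)

    @property
    def gene_ids(self) -> list[str]:
        return [g.id for g in self.spec.genes]

    def locations(self) -> np.ndarray:
        """(L, N) per-gene monomer means of each component."""
        return np.array([c.location(self.spec) for c in self.components])

    def pmf_marginal(self, x) -> float:
        """Mixture PMF of the monomer copy-number vector x (gene order)."""
        from scipy import stats

        x = np.asarray(x)
        locs = self.locations()
        comp = np.prod(stats.poisson.pmf(x[None, :], locs), axis=1)
        return float(self.weights @ comp)

    def pmf_joint(self, counts: dict[str, int]) -> float:
        return float(
            sum(w * c.pmf(counts)
                for w, c in zip(self.weights, self.components))
        )

    def grid_marginal(self, box: dict[str, int] | None = None) -> np.ndarray:
        """Dense mixture PMF over the monomer lattice box (gene-order
        axes)."""
        species = [g.protein_species for g in self.spec.genes]
        if box is None:
            box = self.default_box()
        out = None
        for w, c in zip(self.weights, self.components):
            if w == 0:
                continue
            g = w * c.pmf_grid(species, box)
            out = g if out is None else out + g
        return out

    def default_box(self, weight_floor: float = DEFAULT_WEIGHT_FLOOR,
                    pad: float = 10.0, floor: int = 20) -> dict[str, int]:
        species = [g.protein_species for g in self.spec.genes]
        box = {s: floor for s in species}
        for w, c in zip(self.weights, self.components):
            if w > weight_floor:
                cb = c.truncation_box(species, pad=pad, floor=floor)
                for s in species:
                    box[s] = max(box[s], cb[s])
        return box

    def component_table(self):
        import pandas as pd

        rows = []
        for w, c in zip(self.weights, self.components):
            rows.append(
                {
                    "state": c.gene_state.index,
                    "config": c.gene_state.label(),
                    **{f"mean_{gid}": m
                       for gid, m in c.monomer_means.items()},
                    "weight": w,
                }
            )
        return pd.DataFrame(rows)


def mixture_pmf(spec: GRNSpec,
                initial: np.ndarray | None = None) -> PoissonMixture:
    """Assemble the SPK-limit stationary mixture for a validated spec."""
    gen = build_reduced_generator(spec)
    lam = stationary_weights(gen, initial=initial)
    comps = [conditional_law(spec, s) for s in gen.states]
    return PoissonMixture(spec=spec, components=comps, weights=lam,
                          generator=gen)


# ---------------------------------------------------------------------------
# modes


@dataclass
class ModeReport:
    """Poisson components above the weight floor (coincident locations
    merged) and, when scanned, the strict local maxima of the mixture on
    the integer lattice."""

    component_modes: list[tuple[tuple[float, ...], float]]
    lattice_maxima: list[tuple[int, ...]] | None
    weight_floor: float

    @property
    def n_component_modes(self) -> int:
        return len(self.component_modes)


def _local_maxima(grid: np.ndarray) -> list[tuple[int, ...]]:
    """Lattice points >= all axis neighbors and > at least one."""
    ge_all = np.ones(grid.shape, bool)
    gt_any = np.zeros(grid.shape, bool)
    for ax in range(grid.ndim):
        for shift in (1, -1):
            nb = np.roll(grid, shift, axis=ax)
            # edges: missing neighbor imposes no constraint
            idx = [slice(None)] * grid.ndim
            idx[ax] = 0 if shift == 1 else -1
            nb[tuple(idx)] = -np.inf
            ge_all &= grid >= nb
            gt_any |= grid > nb
    return [tuple(map(int, p)) for p in np.argwhere(ge_all & gt_any)]


def find_modes(mix: PoissonMixture,
               weight_floor: float = DEFAULT_WEIGHT_FLOOR,
               box: dict[str, int] | None = None,
               scan_lattice: bool | str = "auto",
               max_lattice: int = 5_000_000) -> ModeReport:
    """Modes of the mixture.

    Component modes: distinct component locations with merged weight above
    ``weight_floor``.  Lattice maxima: exhaustive scan of the mixture PMF
    on the truncation box (skipped when the box exceeds ``max_lattice``
    points and ``scan_lattice`` is ``"auto"``).
    """
    if not 0 <= weight_floor < 1:
        raise ValueError("weight_floor must be in [0, 1)")
    merged: dict[tuple[float, ...], float] = {}
    for w, c in zip(mix.weights, mix.components):
        loc = tuple(round(v, 9) for v in c.location(mix.spec))
        merged[loc] = merged.get(loc, 0.0) + float(w)
    component_modes = sorted(
        ((loc, w) for loc, w in merged.items() if w > weight_floor),
        key=lambda lw: -lw[1],
    )
    maxima = None
    if scan_lattice:
        if box is None:
            box = mix.default_box(weight_floor=weight_floor)
        n_points = int(np.prod([b + 1 for b in box.values()]))
        if scan_lattice == "auto" and n_points > max_lattice:
            maxima = None
        else:
            grid = mix.grid_marginal(box)
            maxima = _local_maxima(grid)
    return ModeReport(component_modes=component_modes,
                      lattice_maxima=maxima, weight_floor=weight_floor)


def dominant_components(mix: PoissonMixture, concentration: float = 0.99):
    """Smallest set of components whose cumulative weight reaches the
    concentration threshold; returns (indices, cumulative weight)."""
    order = np.argsort(mix.weights)[::-1]
    cum = np.cumsum(mix.weights[order])
    k = int(np.searchsorted(cum, concentration) + 1)
    k = min(k, len(order))
    return list(order[:k]), float(cum[k - 1])


# ---------------------------------------------------------------------------
# synchronized populations of identical toggle switches


@dataclass
class SynchronizedReport:
    """High-diffusion (synchronized) analysis of N identical
    diffusion-coupled toggle switches."""

    n_switches: int
    full_component_count: int  # positive-weight components, finite Omega
    macro_modes: list[tuple[tuple[int, int], tuple[float, float], float]]
    # (unbound X count i, unbound Y count j), synchronized location, weight
    boundary_modes: list[tuple[float, float]]
    interior_modes: list[tuple[float, float]]
    interior_suppressed: bool
    multimerization_ratio: float | None
    omega_min: float
    omega: float

    @property
    def n_modes(self) -> int:
        return len(self.macro_modes)


def _toggle_pairs(spec: GRNSpec):
    """Group genes of a coupled-toggle population into (X_i, Y_i) pairs and
    check the switches are identical mutual repressors."""
    genes = spec.genes
    if len(genes) % 2:
        raise ValueError("expected an even number of genes (toggle pairs)")
    pairs = [(genes[2 * i], genes[2 * i + 1]) for i in range(len(genes) // 2)]
    for x, y in pairs:
        for g, partner in ((x, y), (y, x)):
            if g.n_sites != 1:
                raise ValueError("toggle genes must have one binding site")
            if spec.resolve_tf(g.binding_sites[0]).id != partner.id:
                raise ValueError(
                    f"gene {g.id!r} is not repressed by its partner"
                )
    ref = pairs[0]

    def signature(g):
        return (g.binding_rates, tuple(sorted(g.production_rates.items())),
                g.decay_rate, g.cooperativity, g.multimerization_rates)

    for x, y in pairs:
        if signature(x) != signature(ref[0]) or signature(y) != signature(
            ref[1]
        ) or signature(x) != signature(y):
            raise ValueError("coupled toggle switches must be identical")
    return pairs


def synchronized_limit(
    coupled_spec: GRNSpec,
    weight_floor: float = DEFAULT_WEIGHT_FLOOR,
    suppression_ratio: float = 10.0,
) -> SynchronizedReport:
    """Mode structure of N identical diffusion-coupled toggle switches in
    the high-diffusion (synchronized) limit.

    The synchronized state depends only on the number of unbound promoters
    per gene family: macro-state (i, j) with i unbound X-promoters and j
    unbound Y-promoters places every cell's component at
    (i k0 / (N k_-), j k0 / (N k_-)).  The all-bound macro-state has zero
    weight (no production means no TF to bind the last free site), so
    (N+1)^2 - 1 macro modes remain; the full finite-Omega chain likewise
    drops its all-bound configuration, leaving 4^N - 1 components.

    The reported synchronization threshold omega_min = (k0 - k_-)/N makes
    the per-cell component spread at most one copy number; it is reported,
    never applied.
    """
    pairs = _toggle_pairs(coupled_spec)
    N = len(pairs)
    gen = build_reduced_generator(coupled_spec)
    lam = stationary_weights(gen)
    # structural count: states outside the closed class carry exactly zero
    full_count = int(np.sum(lam > 0))

    x0 = pairs[0][0]
    k0 = max(x0.production_rates.values())
    km = x0.decay_rate
    unit = k0 / (N * km)

    # aggregate the finite-Omega weights over macro-states (i, j)
    macro_weight: dict[tuple[int, int], float] = {}
    for s, w in zip(gen.states, lam):
        i = sum(1 for x, _ in pairs
                if s.config[coupled_spec.genes.index(x)] == "0")
        j = sum(1 for _, y in pairs
                if s.config[coupled_spec.genes.index(y)] == "0")
        macro_weight[(i, j)] = macro_weight.get((i, j), 0.0) + float(w)

    macro_modes, boundary, interior = [], [], []
    for (i, j), w in sorted(macro_weight.items()):
        if w <= 0:
            continue
        loc = (i * unit, j * unit)
        macro_modes.append(((i, j), loc, w))
        if i == 0 or j == 0:
            boundary.append(loc)
        else:
            interior.append(loc)

    ratio = None
    if x0.cooperativity > 1:
        beta, beta_ = x0.multimerization_rates
        ratio = beta / beta_
    omega = coupled_spec.diffusion_couplings[0][2] \
        if coupled_spec.diffusion_couplings else 0.0
    return SynchronizedReport(
        n_switches=N,
        full_component_count=full_count,
        macro_modes=macro_modes,
        boundary_modes=boundary,
        interior_modes=interior,
        interior_suppressed=bool(ratio is not None
                                 and ratio >= suppression_ratio),
        multimerization_ratio=ratio,
        omega_min=(k0 - km) / N,
        omega=omega,
    )
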