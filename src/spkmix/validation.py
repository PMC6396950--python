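"""Finite-epsilon ground truth: truncated CME, FSP stationary solver,
Gillespie sampling, and deterministic steady states.

The truncated master-equation generator is assembled in explicit fast-slow
form, Lambda_eps = Lambda_fast + eps * Lambda_slow, where the fast part is
block-diagonal over promoter configurations (each block is the conditional
protein chain) and the slow part holds the promoter binding/unbinding
terms.  These backends exist to check the SPK-limit mixture against exact
finite-epsilon solutions, simulated sample paths, and the mass-action ODE.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, sparse
from scipy.sparse.linalg import spsolve

from .conditional import conditional_law
from .grn import (
    GRNSpec,
    GeneState,
    Reaction,
    SLOW_GENE,
    enumerate_states,
    expand_reactions,
    propensity_coeff,
    state_index,
)


def tv_distance(p: np.ndarray, q: np.ndarray) -> float:
    """Total-variation distance between two (broadcastable) PMF arrays."""
    return 0.5 * float(np.abs(np.asarray(p) - np.asarray(q)).sum())


def _falling(x: np.ndarray, n: int) -> np.ndarray:
    """Binomial propensity factor C(x, n)."""
    out = np.ones_like(x, dtype=float)
    for i in range(n):
        out *= x - i
    return out / math.factorial(n)


def default_box(spec: GRNSpec, pad: float = 10.0, floor: int = 20,
                cap: int | None = None) -> dict[str, int]:
    """Truncation box covering every conditional component: per species,
    max conditional mean + pad*sqrt(mean) + floor."""
    laws = [conditional_law(spec, s) for s in enumerate_states(spec)]
    species = list(laws[0].species_means)
    box = {}
    for s in species:
        m = max(law.species_means[s] for law in laws)
        b = int(math.ceil(m + pad * math.sqrt(m) + floor))
        box[s] = min(b, cap) if cap else b
    return box


@dataclass
class TruncatedCME:
    """Sparse truncated master-equation generator in fast-slow form."""

    spec: GRNSpec
    species: list[str]  # protein-side species, axis order of the box
    box: dict[str, int]
    states: list[GeneState]
    fast: sparse.csc_matrix = field(repr=False)  # block-diag over d
    slow: sparse.csc_matrix = field(repr=False)  # promoter transitions
    epsilon: float = 1e-3

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(self.box[s] + 1 for s in self.species)

    @property
    def n_x(self) -> int:
        return int(np.prod(self.shape))

    @property
    def n_states(self) -> int:
        return len(self.states) * self.n_x

    def generator(self, epsilon: float | None = None) -> sparse.csc_matrix:
        eps = self.epsilon if epsilon is None else epsilon
        return (self.fast + eps * self.slow).tocsc()

    def fast_block(self, d: int) -> sparse.csc_matrix:
        """Conditional generator Lambda_d (one diagonal block of the fast
        part)."""
        lo, hi = d * self.n_x, (d + 1) * self.n_x
        return self.fast[lo:hi, lo:hi]


def assemble_cme(spec: GRNSpec, box: dict[str, int] | None = None,
                 epsilon: float | None = None) -> TruncatedCME:
    """Assemble the truncated CME generator on ``box``.

    Column sums are zero for interior states and negative where probability
    would flow out of the box (the leak is kept on the diagonal so it can
    be reported).  Emits a warning when the box is tight (a conditional
    mean beyond half the box), with a Poisson tail estimate of the mass at
    risk.
    """
    net = expand_reactions(spec)
    states = enumerate_states(spec)
    species = list(conditional_law(spec, states[0]).species_means)
    if box is None:
        box = default_box(spec)
    # tightness check
    from scipy import stats

    for s in species:
        m = max(conditional_law(spec, st).species_means[s] for st in states)
        if m > box[s] / 2:
            tail = float(stats.poisson.sf(box[s], m))
            warnings.warn(
                f"box for {s!r} (max {box[s]}) is below twice the largest "
                f"conditional mean {m:.3g}; Poisson tail mass beyond the "
                f"box is about {tail:.2e}",
                stacklevel=2,
            )

    shape = tuple(box[s] + 1 for s in species)
    n_x = int(np.prod(shape))
    spos = {s: i for i, s in enumerate(species)}
    strides = np.array(
        [int(np.prod(shape[i + 1 :])) for i in range(len(shape))], dtype=int
    )
    grids = np.indices(shape).reshape(len(shape), -1)  # (S, n_x)
    flat = np.arange(n_x)
    L = len(states)
    n_tot = L * n_x

    gene_pos = {g.id: i for i, g in enumerate(spec.genes)}

    def promoter_parts(rxn: Reaction):
        """Split reactants/products into (gene config requirement,
        target config) and protein stoichiometry."""
        req = tgt = None
        nu = np.zeros(len(species), int)
        delta = np.zeros(len(species), int)
        for s, n in rxn.reactants:
            if s.startswith("D_"):
                _, gid, code = s.split("_", 2)
                req = (gene_pos[gid], code)
            else:
                nu[spos[s]] += n
                delta[spos[s]] -= n
        for s, n in rxn.products:
            if s.startswith("D_"):
                _, gid, code = s.split("_", 2)
                tgt = (gene_pos[gid], code)
            else:
                delta[spos[s]] += n
        return req, tgt, nu, delta

    acc = {SLOW_GENE: ([], [], []), "fast": ([], [], [])}

    for rxn in net.reactions:
        req, tgt, nu, delta = promoter_parts(rxn)
        w = np.full(n_x, rxn.rate)
        for si, n in enumerate(nu):
            if n:
                w = w * _falling(grids[si], n)
        active = w > 0
        if not active.any():
            continue
        xv = grids[:, active]
        wv = w[active]
        cols_x = flat[active]
        if delta.any():
            tgt_x = xv + delta[:, None]
            ok = np.ones(tgt_x.shape[1], bool)
            for si in range(len(species)):
                ok &= (tgt_x[si] >= 0) & (tgt_x[si] <= box[species[si]])
            rows_x = (tgt_x * strides[:, None]).sum(axis=0)
        else:
            ok = np.ones(len(cols_x), bool)
            rows_x = cols_x

        if req is None:
            d_pairs = [(d.index, d.index) for d in states]
        else:
            gi, code = req
            d_pairs = []
            for d in states:
                if d.config[gi] == code:
                    if tgt is not None and tgt[1] != code:
                        cfg = (
                            d.config[:gi] + (tgt[1],) + d.config[gi + 1 :]
                        )
                        d_pairs.append((d.index, state_index(spec, cfg)))
                    else:
                        d_pairs.append((d.index, d.index))

        key = SLOW_GENE if rxn.klass == SLOW_GENE else "fast"
        rows, cols, vals = acc[key]
        for d_from, d_to in d_pairs:
            off = d_from * n_x
            off_to = d_to * n_x
            # off-diagonal flow (in-box targets only)
            rows.append(off_to + rows_x[ok])
            cols.append(off + cols_x[ok])
            vals.append(wv[ok])
            # diagonal: full outflow, including the leaking part
            rows.append(off + cols_x)
            cols.append(off + cols_x)
            vals.append(-wv)

    def build(key):
        rows, cols, vals = acc[key]
        if not rows:
            return sparse.csc_matrix((n_tot, n_tot))
        return sparse.csc_matrix(
            (
                np.concatenate(vals),
                (np.concatenate(rows), np.concatenate(cols)),
            ),
            shape=(n_tot, n_tot),
        )

    return TruncatedCME(
        spec=spec,
        species=species,
        box=dict(box),
        states=states,
        fast=build("fast"),
        slow=build(SLOW_GENE),
        epsilon=spec.epsilon if epsilon is None else float(epsilon),
    )


# ---------------------------------------------------------------------------
# stationary solve (finite state projection with reflecting closure)


@dataclass
class StationaryPMF:
    """Dense stationary PMF on the truncated (d, x) lattice."""

    cme: TruncatedCME
    values: np.ndarray  # shape (L, *box shape)
    residual: float
    leak_rate: float  # stationary probability outflow rate of the open box
    epsilon: float

    def joint_protein(self) -> np.ndarray:
        """Marginal over promoter configurations: PMF on the protein box."""
        return self.values.sum(axis=0)

    def marginal(self, keep: list[str]) -> np.ndarray:
        """Marginal PMF over a subset of protein species (axes ordered as
        ``keep``)."""
        arr = self.joint_protein()
        axes = tuple(
            i for i, s in enumerate(self.cme.species) if s not in keep
        )
        arr = arr.sum(axis=axes)
        order = [s for s in self.cme.species if s in keep]
        perm = [order.index(s) for s in keep]
        return np.transpose(arr, perm)

    def monomer_marginal(self) -> np.ndarray:
        """PMF over the monomer copy numbers, gene order (the observable
        the mixture's marginal form predicts)."""
        return self.marginal([g.protein_species for g in self.cme.spec.genes])

    def promoter_weights(self) -> np.ndarray:
        return self.values.reshape(len(self.cme.states), -1).sum(axis=1)


def fsp_stationary(cme: TruncatedCME,
                   epsilon: float | None = None) -> StationaryPMF:
    """Stationary solve of the truncated generator with reflecting closure
    (outflow discarded, columns re-closed to zero), normalized to one."""
    eps = cme.epsilon if epsilon is None else float(epsilon)
    A = cme.generator(eps).tocsc()
    n = A.shape[0]
    colsum = np.asarray(A.sum(axis=0)).ravel()  # <= 0: leak rates
    closed = (A - sparse.diags(colsum)).tocsr()
    # replace the normalization: solve [closed[:-1]; 1^T] pi = e_n
    M = sparse.vstack(
        [closed[:-1, :], sparse.csr_matrix(np.ones((1, n)))]
    ).tocsc()
    rhs = np.zeros(n)
    rhs[-1] = 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", sparse.SparseEfficiencyWarning)
        pi = spsolve(M, rhs)
    if not np.all(np.isfinite(pi)):
        raise RuntimeError("FSP stationary solve failed (singular system)")
    neg = pi.min()
    if neg < -1e-8:
        warnings.warn(f"FSP solution has negative mass {neg:.2e}; clipping",
                      stacklevel=2)
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    residual = float(np.abs(closed @ pi).max())
    leak = float(-(colsum @ pi))
    return StationaryPMF(
        cme=cme,
        values=pi.reshape((len(cme.states),) + cme.shape),
        residual=residual,
        leak_rate=leak,
        epsilon=eps,
    )


def reduced_generator_direct(cme: TruncatedCME) -> np.ndarray:
    """Direct projection construction of the reduced generator: sandwich
    the slow part between the stacked conditional PMFs (columns) and the
    block summation matrix (rows).  Used as the independent cross-check of
    the transition-by-transition build."""
    L = len(cme.states)
    n_x = cme.n_x
    out = np.zeros((L, L))
    slow = cme.slow.tocsc()
    for d in cme.states:
        law = conditional_law(cme.spec, d)
        v = law.pmf_grid(cme.species, cme.box).ravel()
        vfull = np.zeros(L * n_x)
        vfull[d.index * n_x : (d.index + 1) * n_x] = v
        u = slow @ vfull
        out[:, d.index] = u.reshape(L, n_x).sum(axis=1)
    return out


# ---------------------------------------------------------------------------
# Gillespie sampling


@dataclass
class Trajectory:
    """A sample path (piecewise-constant copy numbers)."""

    times: np.ndarray
    states: np.ndarray  # (n_records, n_species)
    species: list[str]
    seed: int
    epsilon: float
    t_max: float
    sampled: bool  # True: regular grid samples; False: every event

    def column(self, species: str) -> np.ndarray:
        return self.states[:, self.species.index(species)]

    def occupancy(self, keep: list[str],
                  box: dict[str, int]) -> np.ndarray:
        """Time-weighted occupancy histogram over the given species on the
        box (out-of-box samples are dropped; the result is renormalized)."""
        cols = [self.species.index(s) for s in keep]
        vals = self.states[:, cols]
        if self.sampled:
            w = np.ones(len(vals))
        else:
            w = np.diff(np.append(self.times, self.t_max))
        shape = tuple(box[s] + 1 for s in keep)
        ok = np.all(
            (vals >= 0) & (vals <= np.array([box[s] for s in keep])), axis=1
        )
        hist = np.zeros(shape)
        np.add.at(hist, tuple(vals[ok].T), w[ok])
        total = hist.sum()
        if total <= 0:
            raise RuntimeError("no in-box occupancy mass")
        return hist / total


def ssa_simulate(spec: GRNSpec, epsilon: float | None = None,
                 t_max: float = 100.0, seed: int = 0,
                 record_dt: float | None = None,
                 init: dict[str, int] | None = None,
                 burn_in: float = 0.0) -> Trajectory:
    """Exact stochastic simulation (direct method) of the expanded network.

    The initial condition defaults to all promoters unbound and zero
    proteins; ``init`` overrides individual species.  With ``record_dt``
    the path is sampled on a regular grid (memory-friendly for long runs),
    otherwise every event is recorded.  ``burn_in`` drops the initial
    transient from the record.
    """
    net = expand_reactions(spec)
    eps = spec.epsilon if epsilon is None else float(epsilon)
    species = net.species
    spos = {s: i for i, s in enumerate(species)}
    S = len(species)
    R = len(net.reactions)

    x0 = np.zeros(S, dtype=np.int64)
    for g in spec.genes:
        x0[spos[g.promoter_species(g.binding_set[0])]] = 1
    if init:
        for s, v in init.items():
            x0[spos[s]] = v
            if s.startswith("D_"):
                gid = s.split("_", 2)[1]
                g = spec.gene(gid)
                for j in g.binding_set:  # exactly one configuration set
                    if g.promoter_species(j) != s:
                        x0[spos[g.promoter_species(j)]] = 0

    rates = np.array([r.effective_rate(eps) for r in net.reactions])
    delta = np.zeros((R, S), dtype=np.int64)
    react = []  # per reaction: list of (species index, order)
    for ri, r in enumerate(net.reactions):
        terms = []
        for s, n in r.reactants:
            delta[ri, spos[s]] -= n
            terms.append((spos[s], n))
        for s, n in r.products:
            delta[ri, spos[s]] += n
        react.append(terms)

    max_order = 3
    # propensity factor tables: factor[k] lists (reaction, species, order)
    fact_r, fact_s, fact_n = [], [], []
    for ri, terms in enumerate(react):
        for si, n in terms:
            fact_r.append(ri)
            fact_s.append(si)
            fact_n.append(n)
            if n > max_order:
                raise ValueError("reactant order above 3 not supported")
    fact_r = np.array(fact_r, int)
    fact_s = np.array(fact_s, int)
    fact_n = np.array(fact_n, int)

    rng = np.random.default_rng(seed)
    x = x0.copy()
    t = 0.0
    sampled = record_dt is not None
    if sampled:
        grid = np.arange(burn_in, t_max + 1e-12, record_dt)
        rec = np.empty((len(grid), S), dtype=np.int64)
        gi = 0
    else:
        times, recs = [], []

    while True:
        xf = x[fact_s].astype(float)
        f = xf.copy()
        for i in range(1, max_order):
            mask = fact_n > i
            f[mask] *= (xf[mask] - i) / (i + 1)
        f[fact_n > xf] = 0.0
        prop = rates.copy()
        np.multiply.at(prop, fact_r, f)
        # reactions with no listed reactants keep their base rate
        total = prop.sum()
        if not sampled and t >= burn_in:
            times.append(t)
            recs.append(x.copy())
        if total <= 0:
            t_next = np.inf
        else:
            t_next = t + rng.exponential(1.0 / total)
        if sampled:
            while gi < len(grid) and grid[gi] < min(t_next, t_max):
                rec[gi] = x
                gi += 1
        if t_next >= t_max:
            break
        t = t_next
        ri = np.searchsorted(np.cumsum(prop), rng.uniform(0, total),
                             side="right")
        ri = min(ri, R - 1)
        x = x + delta[ri]

    if sampled:
        rec = rec[:gi]
        return Trajectory(
            times=grid[:gi], states=rec, species=species, seed=seed,
            epsilon=eps, t_max=t_max, sampled=True,
        )
    return Trajectory(
        times=np.array(times), states=np.array(recs), species=species,
        seed=seed, epsilon=eps, t_max=t_max, sampled=False,
    )


def dominant_switch_sequence(traj: Trajectory, gene_ids: list[str],
                             min_run: int = 5,
                             dominance_factor: float = 2.0) -> list[int]:
    """Sequence of dominant genes along a sample path.

    A sample is labelled with the gene holding the largest protein count
    when that count exceeds ``dominance_factor`` times the runner-up;
    a dominance episode must last at least ``min_run`` consecutive samples
    to count.  Consecutive duplicate labels are collapsed, so transitions
    in the returned sequence are the metastable switches.
    """
    counts = np.stack([traj.column(g) for g in gene_ids], axis=1).astype(
        float
    )
    order = np.argsort(counts, axis=1)
    top = order[:, -1]
    second = counts[np.arange(len(counts)), order[:, -2]]
    best = counts[np.arange(len(counts)), top]
    labels = np.where(best > dominance_factor * np.maximum(second, 1.0),
                      top, -1)
    seq: list[int] = []
    run_label, run_len = -1, 0
    for lab in labels:
        if lab == run_label:
            run_len += 1
        else:
            run_label, run_len = int(lab), 1
        if run_label >= 0 and run_len == min_run:
            if not seq or seq[-1] != run_label:
                seq.append(run_label)
    return seq


def cyclic_fraction(sequence: list[int], successor: dict[int, int]) -> float:
    """Fraction of switches in a dominance sequence that follow the given
    successor map (e.g. the cyclic order predicted by the reduced
    chain)."""
    if len(sequence) < 2:
        raise RuntimeError("fewer than two dominance episodes observed")
    hits = sum(
        1 for a, b in zip(sequence, sequence[1:]) if successor[a] == b
    )
    return hits / (len(sequence) - 1)


# ---------------------------------------------------------------------------
# deterministic steady states


@dataclass
class Equilibrium:
    species: dict[str, float]
    stable: bool
    hits: int  # number of starts converging here


def _ode_system(spec: GRNSpec, epsilon: float):
    """Reduced-coordinate mass-action ODE: per gene the first promoter
    fraction is eliminated by conservation.  Deterministic rate constants
    carry the combinatorial 1/nu! so equilibria match the stochastic
    product-form means."""
    net = expand_reactions(spec)
    species = net.species
    spos = {s: i for i, s in enumerate(species)}
    first = {}
    reduced: list[int] = []
    for g in spec.genes:
        gene_all = [spos[g.promoter_species(j)] for j in g.binding_set]
        first[gene_all[0]] = gene_all
        reduced += gene_all[1:]
    protein_idx = [spos[s] for s in species if not s.startswith("D_")]
    reduced += protein_idx
    reduced = list(reduced)

    rates = np.array(
        [r.effective_rate(epsilon) * propensity_coeff(r.reactants)
         for r in net.reactions]
    )
    nu = np.zeros((len(net.reactions), len(species)))
    delta = np.zeros_like(nu)
    for ri, r in enumerate(net.reactions):
        for s, n in r.reactants:
            nu[ri, spos[s]] += n
            delta[ri, spos[s]] -= n
        for s, n in r.products:
            delta[ri, spos[s]] += n

    def full_state(z):
        c = np.zeros(len(species))
        c[reduced] = z
        for f, members in first.items():
            c[f] = 1.0 - c[members[1:]].sum() if len(members) > 1 else 1.0
        return c

    def rhs(z):
        c = full_state(z)
        v = rates * np.prod(np.power(np.maximum(c, 0.0)[None, :], nu),
                            axis=1)
        return (delta.T @ v)[reduced]

    return reduced, species, first, full_state, rhs


def ode_steady_states(spec: GRNSpec, n_starts: int = 200, seed: int = 0,
                      epsilon: float | None = None,
                      t_relax: float | None = None) -> list[Equilibrium]:
    """Deterministic equilibria of the mass-action ODE (promoter
    conservation eliminated), found by multi-start relaxation.

    Each random start is integrated towards its attractor and polished
    with a Newton solve whose promoter residuals are rescaled by 1/epsilon
    (the slow-fast imbalance otherwise defeats the root finder); a direct
    Newton attempt from the raw start is kept as well, which is what picks
    up unstable equilibria.  Stability is judged from the eigenvalues of
    the reduced Jacobian (all real parts < -1e-9).
    """
    from scipy.integrate import solve_ivp

    eps = spec.epsilon if epsilon is None else float(epsilon)
    reduced, species, first, full_state, rhs = _ode_system(spec, eps)
    rng = np.random.default_rng(seed)
    n_red = len(reduced)
    n_prom = sum(len(m) - 1 for m in first.values())
    scale = np.ones(n_red)
    scale[:n_prom] = eps  # promoter balances are O(eps)
    prot_hi = 10.0 * max(
        max(g.production_rates.values()) / g.decay_rate for g in spec.genes
    )
    prot_hi = max(prot_hi, 1.0)
    if t_relax is None:
        # promoter kinetics are the slowest relaxing directions
        slowest = eps * min(
            min(a for pair in g.binding_rates for a in pair if a > 0)
            for g in spec.genes
        )
        t_relax = 50.0 / max(slowest, 1e-12)

    def scaled(z):
        return rhs(z) / scale

    def polish(z0):
        sol = optimize.root(scaled, z0, method="hybr", tol=1e-12)
        if sol.success and np.abs(rhs(sol.x)).max() < 1e-8:
            c = full_state(sol.x)
            if c.min() > -1e-6 and c[list(first)].max() < 1 + 1e-6:
                return np.clip(sol.x, 0.0, None)
        return None

    found: list[tuple[np.ndarray, int]] = []
    failures = 0

    def record(z):
        for i, (zf, h) in enumerate(found):
            if np.allclose(z, zf, rtol=1e-3, atol=1e-4):
                found[i] = (zf, h + 1)
                return
        found.append((z, 1))

    for start in range(n_starts):
        z0 = np.empty(n_red)
        pos = 0
        for f, members in first.items():
            k = len(members)
            if k > 1:
                z0[pos : pos + k - 1] = rng.dirichlet(np.ones(k))[1:]
                pos += k - 1
        z0[pos:] = np.exp(
            rng.uniform(np.log(1e-2), np.log(prot_hi), size=n_red - pos)
        )
        if start == 0:
            z0[:] = 0.0  # the origin is an equilibrium of non-leaky nets
        hit = False
        direct = polish(z0)
        if direct is not None:
            record(direct)
            hit = True
        ivp = solve_ivp(lambda t, z: rhs(z), (0.0, t_relax), z0,
                        method="LSODA", rtol=1e-8, atol=1e-9,
                        dense_output=False)
        if ivp.success:
            z_end = ivp.y[:, -1]
            relaxed = polish(z_end)
            if relaxed is not None:
                record(relaxed)
                hit = True
        if not hit:
            failures += 1

    def jacobian(z):
        n = len(z)
        J = np.empty((n, n))
        f0 = rhs(z)
        for i in range(n):
            h = 1e-7 * (1.0 + abs(z[i]))
            zp = z.copy()
            zp[i] += h
            J[:, i] = (rhs(zp) - f0) / h
        return J

    if failures:
        warnings.warn(
            f"{failures}/{n_starts} starts did not converge to an "
            "equilibrium",
            stacklevel=2,
        )
    out = []
    for z, hits in found:
        eig = np.linalg.eigvals(jacobian(z))
        stable = bool(np.all(eig.real < -1e-9))
        c = full_state(z)
        out.append(
            Equilibrium(
                species={s: float(v) for s, v in zip(species, c)},
                stable=stable,
                hits=hits,
            )
        )
    return out
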