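"""Stationary protein statistics conditioned on a frozen promoter state.

With every promoter frozen in configuration d, the protein side of the
network decouples into independent birth-death (plus reversible
n-merization / linear transport) chains.  These conditional chains are
weakly reversible and deficiency zero, so their stationary law is a product
of Poisson distributions whose means solve the conditional deterministic
equilibrium:

* monomer of gene i:      a_i = k_{i,d_i} / k_{-i}
* n-mer of gene i (n>1):  b_i = (beta_i / (n_i! beta_{-i})) * a_i**n_i

For diffusion-coupled networks the monomer means instead solve the linear
production/decay/transport balance, and the multimer means follow from the
n-merization detailed balance at those monomer levels.

Promoter rates (alpha, alpha_minus) and epsilon never enter: conditional
laws depend only on the fast protein reactions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .grn import GRNSpec, GeneState, require_valid, state_config


@dataclass(frozen=True)
class ConditionalPoisson:
    """Product-Poisson stationary law of the protein process given a fixed
    promoter configuration."""

    gene_state: GeneState
    monomer_means: dict[str, float]  # gene id -> mean monomer copy number
    multimer_means: dict[str, float]  # gene id -> mean n-mer copy number
    species_means: dict[str, float]  # every protein-side species -> mean

    def mean_vector(self, species: list[str]) -> np.ndarray:
        return np.array([self.species_means[s] for s in species], float)

    def location(self, spec: GRNSpec) -> tuple[float, ...]:
        """Per-gene monomer means: the component location of the marginal
        (non-multimerized) mixture."""
        return tuple(self.monomer_means[g.id] for g in spec.genes)

    # -- evaluation ----------------------------------------------------
    def pmf(self, counts: dict[str, int]) -> float:
        """Joint probability of the given species copy numbers (species not
        listed are marginalized out, which for a product law means simply
        omitted)."""
        p = 1.0
        for s, x in counts.items():
            p *= stats.poisson.pmf(x, self.species_means[s])
        return float(p)

    def pmf_grid(self, species: list[str], box: dict[str, int]) -> np.ndarray:
        """Product-Poisson values on the lattice box
        ``{0..box[s]}`` for each requested species; axes follow ``species``
        order."""
        axes = [
            stats.poisson.pmf(np.arange(box[s] + 1), self.species_means[s])
            for s in species
        ]
        out = axes[0]
        for a in axes[1:]:
            out = np.multiply.outer(out, a)
        return out

    def truncation_box(self, species: list[str],
                       pad: float = 10.0, floor: int = 20) -> dict[str, int]:
        """Per-species bound mean + pad*sqrt(mean) + floor (Poisson tails
        beyond this carry negligible mass)."""
        return {
            s: int(math.ceil(self.species_means[s]
                             + pad * math.sqrt(self.species_means[s])
                             + floor))
            for s in species
        }

    def to_tsv(self, path, species: list[str], box: dict[str, int]) -> None:
        import pandas as pd

        grid = self.pmf_grid(species, box)
        idx = np.indices(grid.shape).reshape(len(species), -1).T
        df = pd.DataFrame(idx, columns=species)
        df["probability"] = grid.ravel()
        df.to_csv(path, sep="\t", index=False)


def _as_state(spec: GRNSpec, d) -> GeneState:
    if isinstance(d, GeneState):
        return d
    if isinstance(d, int):
        return GeneState(config=state_config(spec, d), index=d)
    from .grn import state_index

    cfg = tuple(d)
    return GeneState(config=cfg, index=state_index(spec, cfg))


def _multimer_mean(gene, a: float) -> float:
    beta, beta_ = gene.multimerization_rates
    n = gene.cooperativity
    return (beta / beta_) * a**n / math.factorial(n)


def conditional_pmf_joint(spec: GRNSpec, d) -> ConditionalPoisson:
    """Exact joint (protein, multimer) conditional stationary law for a
    block-structured network (no diffusion couplings)."""
    require_valid(spec)
    if spec.diffusion_couplings:
        raise ValueError(
            "network has diffusion couplings; use "
            "conditional_equilibrium_extended"
        )
    state = _as_state(spec, d)
    monomer, multimer, species = {}, {}, {}
    for g, di in zip(spec.genes, state.config):
        a = g.production_rates.get(di, 0.0) / g.decay_rate
        monomer[g.id] = a
        species[g.protein_species] = a
        if g.cooperativity > 1:
            b = _multimer_mean(g, a)
            multimer[g.id] = b
            species[g.multimer_species] = b
    return ConditionalPoisson(state, monomer, multimer, species)


def conditional_pmf_marginal(spec: GRNSpec, d) -> dict[str, float]:
    """Per-gene Poisson means of the marginal (monomer-only) conditional
    law: k_{i,d_i} / k_{-i}."""
    return conditional_pmf_joint(spec, d).monomer_means


def conditional_equilibrium_extended(spec: GRNSpec, d) -> ConditionalPoisson:
    """Conditional product-Poisson law for networks whose conditional
    chains include linear diffusion transport.

    The conditional network at fixed d must consist of constant production,
    first-order decay, first-order reversible transport between monomers,
    and reversible n-merization: this is structurally weakly reversible and
    deficiency zero, so the stationary law is product-Poisson around the
    conditional deterministic equilibrium.  The monomer means solve the
    linear balance (decay diagonal plus transport Laplacian); multimer
    means follow from n-merization detailed balance.
    """
    require_valid(spec)
    state = _as_state(spec, d)
    monomers = [g.protein_species for g in spec.genes]
    pos = {s: i for i, s in enumerate(monomers)}
    for a, b, _ in spec.diffusion_couplings:
        if a not in pos or b not in pos:
            raise ValueError(
                f"diffusion coupling ({a}, {b}) touches a non-monomer "
                "species; the conditional chain is not in the supported "
                "weakly-reversible deficiency-zero form"
            )
    n = len(monomers)
    A = np.zeros((n, n))
    rhs = np.zeros(n)
    for i, g in enumerate(spec.genes):
        A[i, i] = g.decay_rate
        rhs[i] = g.production_rates.get(state.config[i], 0.0)
    for a, b, w in spec.diffusion_couplings:
        i, j = pos[a], pos[b]
        A[i, i] += w
        A[j, j] += w
        A[i, j] -= w
        A[j, i] -= w
    if min(g.decay_rate for g in spec.genes) <= 0:
        raise ValueError("zero decay rate: conditional balance is singular")
    means = np.linalg.solve(A, rhs)
    monomer, multimer, species = {}, {}, {}
    for g, a in zip(spec.genes, means):
        monomer[g.id] = float(a)
        species[g.protein_species] = float(a)
        if g.cooperativity > 1:
            b = _multimer_mean(g, float(a))
            multimer[g.id] = b
            species[g.multimer_species] = b
    return ConditionalPoisson(state, monomer, multimer, species)


def conditional_law(spec: GRNSpec, d) -> ConditionalPoisson:
    """Dispatch: closed-form product-Poisson without diffusion, conditional
    deterministic equilibrium with it."""
    if spec.diffusion_couplings:
        return conditional_equilibrium_extended(spec, d)
    return conditional_pmf_joint(spec, d)


def expected_tf(spec: GRNSpec, d, tf_species: str) -> float:
    """E[TF | D = d]: the mean copy number of a gene's output species under
    the conditional stationary law (k/k_ for a monomer TF,
    (beta/beta_)(k/k_)**n / n! for an n-merized TF)."""
    law = conditional_law(spec, d)
    if tf_species not in law.species_means:
        raise KeyError(f"unknown TF species {tf_species!r}")
    return law.species_means[tf_species]
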