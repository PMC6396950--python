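"""Canonical network fixtures.

Each builder returns a validated :class:`~spkmix.grn.GRNSpec` with default
rates taken from the published figure captions where available
(``provenance: paper``); fixtures whose full numeric rates were never
printed ship with parameters chosen to satisfy every published qualitative
statement about them (``provenance: reconstructed``).  Any rate can be
overridden by keyword.
"""

from __future__ import annotations

from .grn import CONSTITUTIVE, GeneBlock, GRNSpec, require_valid

PROVENANCE = {
    "bursting_gene": "paper",
    "self_regulating_gene": "paper",
    "toggle_switch": "paper",
    "coupled_toggles": "reconstructed",
    "repressilator": "paper",
    "cellfate_independent": "reconstructed",
    "cellfate_pu1_gata1": "reconstructed",
}


def bursting_gene(alpha: float = 1.0, alpha_: float = 0.1, k: float = 20.0,
                  k_minus: float = 2.0, epsilon: float = 1e-3) -> GRNSpec:
    """Constitutively switching gene: inactive/active promoter, production
    only when active.  Defaults: alpha_ = 0.1, alpha = 1, k_ = 2, k = 20."""
    gene = GeneBlock(
        id="X",
        binding_sites=(CONSTITUTIVE,),
        binding_rates=((alpha, alpha_),),
        production_rates={"0": 0.0, "1": k},
        decay_rate=k_minus,
    )
    spec = GRNSpec(genes=(gene,), epsilon=epsilon)
    require_valid(spec)
    return spec


def self_regulating_gene(
    leaky: bool = True,
    cooperative: bool = True,
    activating: bool = True,
    alpha: float = 1.0,
    alpha_: float = 1.0,
    k0: float = 20.0,
    k1: float = 100.0,
    k_minus: float = 10.0,
    beta: float = 10.0,
    beta_minus: float = 50.0,
    epsilon: float = 1e-3,
) -> GRNSpec:
    """One gene whose own output (dimer when cooperative) binds its single
    promoter site.  Defaults: alpha = alpha_ = 1 (slow units), k0 = 20,
    k1 = 100, k_ = 10, beta = 10, beta_ = 50, cooperativity 2.  Non-leaky
    sets the unbound production to zero; ``activating=False`` swaps the
    production rates."""
    lo, hi = (k0, k1) if activating else (k1, k0)
    if not leaky:
        lo = 0.0
    n = 2 if cooperative else 1
    gene = GeneBlock(
        id="X",
        binding_sites=("X",),
        binding_rates=((alpha, alpha_),),
        production_rates={"0": lo, "1": hi},
        decay_rate=k_minus,
        cooperativity=n,
        multimerization_rates=(beta, beta_minus) if n > 1 else None,
    )
    spec = GRNSpec(genes=(gene,), epsilon=epsilon)
    require_valid(spec)
    return spec


def toggle_switch(
    n: int = 1,
    alpha: float = 1.0,
    alpha_: float = 200.0,
    k0: float = 80.0,
    k_minus: float = 2.0,
    beta: float = 1.0,
    beta_minus: float = 1.0,
    epsilon: float = 1e-3,
) -> GRNSpec:
    """Two identical mutually repressing genes X, Y (non-leaky: production
    only while unbound).  Defaults follow alpha/alpha_ = 1/200 and
    k0/k_ = 40."""

    def gene(gid, other):
        return GeneBlock(
            id=gid,
            binding_sites=(other,),
            binding_rates=((alpha, alpha_),),
            production_rates={"0": k0, "1": 0.0},
            decay_rate=k_minus,
            cooperativity=n,
            multimerization_rates=(beta, beta_minus) if n > 1 else None,
        )

    spec = GRNSpec(genes=(gene("X", "Y"), gene("Y", "X")), epsilon=epsilon)
    require_valid(spec)
    return spec


def coupled_toggles(
    N: int = 3,
    omega: float = 100.0,
    n: int = 2,
    alpha: float = 1.0,
    alpha_: float = 200.0,
    k0: float = 300.0,
    k_minus: float = 2.0,
    beta: float = 1.0,
    beta_minus: float = 1.0,
    epsilon: float = 1e-3,
) -> GRNSpec:
    """N identical cooperative toggle switches coupled by all-pairs protein
    diffusion at rate omega.  With k0/(N k_) = 50 for N = 3 the
    synchronized mode locations sit at multiples of 50 copies."""
    genes = []
    for i in range(1, N + 1):
        for fam, other in (("X", "Y"), ("Y", "X")):
            genes.append(
                GeneBlock(
                    id=f"{fam}{i}",
                    binding_sites=(f"{other}{i}",),
                    binding_rates=((alpha, alpha_),),
                    production_rates={"0": k0, "1": 0.0},
                    decay_rate=k_minus,
                    cooperativity=n,
                    multimerization_rates=(beta, beta_minus) if n > 1
                    else None,
                )
            )
    couplings = []
    for fam in ("X", "Y"):
        for i in range(1, N + 1):
            for j in range(i + 1, N + 1):
                couplings.append((f"{fam}{i}", f"{fam}{j}", omega))
    spec = GRNSpec(genes=tuple(genes), diffusion_couplings=tuple(couplings),
                   epsilon=epsilon)
    require_valid(spec)
    return spec


def repressilator(
    n: int = 1,
    alpha: float = 5.0,
    alpha_: float = 1.0,
    k: float = 2000.0,
    k_minus: float = 20.0,
    beta: float = 1.0,
    beta_minus: float = 1.0,
    epsilon: float = 0.1,
) -> GRNSpec:
    """Three identical genes in a repression ring (X represses Y, Y
    represses Z, Z represses X).  Defaults: alpha = 5, alpha_ = 1 (slow
    units; the published slow-kinetics runs use epsilon = 0.1, the fast
    ones epsilon = 1000), k = 2000, k_ = 20, beta = beta_ = 1."""

    def gene(gid, repressor):
        return GeneBlock(
            id=gid,
            binding_sites=(repressor,),
            binding_rates=((alpha, alpha_),),
            production_rates={"0": k, "1": 0.0},
            decay_rate=k_minus,
            cooperativity=n,
            multimerization_rates=(beta, beta_minus) if n > 1 else None,
        )

    spec = GRNSpec(
        genes=(gene("X", "Z"), gene("Y", "X"), gene("Z", "Y")),
        epsilon=epsilon,
    )
    require_valid(spec)
    return spec


def cellfate_independent(
    alpha: float = 1.0,
    alpha_: float = 1.0,
    k_base: float = 5.0,
    k_max: float = 40.0,
    k_both: float = 5.0,
    k_minus: float = 1.0,
    beta: float = 1.0,
    beta_minus: float = 1.0,
    epsilon: float = 1e-3,
) -> GRNSpec:
    """Cell-fate circuit with independent cooperative binding: two genes
    X, Y, each promoter carrying one self-activation site (site 1, bound by
    the gene's own dimer) and one cross-repression site (site 2, bound by
    the partner's dimer).  The singly-repressed configurations (01 for X,
    10 for Y) are silent; the singly-self-activated ones (10 for X, 01 for
    Y) are maximal.  16 global promoter configurations."""

    def gene(gid, hi_cfg, zero_cfg):
        # site 1 is bound by Xc and site 2 by Yc on both promoters, so the
        # self-activated configurations are 10 for X and 01 for Y
        prod = {"00": k_base, "11": k_both, hi_cfg: k_max, zero_cfg: 0.0}
        return GeneBlock(
            id=gid,
            binding_sites=("Xc", "Yc"),
            binding_rates=((alpha, alpha_), (alpha, alpha_)),
            production_rates=prod,
            decay_rate=k_minus,
            cooperativity=2,
            multimerization_rates=(beta, beta_minus),
        )

    spec = GRNSpec(
        genes=(gene("X", "10", "01"), gene("Y", "01", "10")),
        epsilon=epsilon,
    )
    require_valid(spec)
    return spec


def cellfate_pu1_gata1(
    alpha: float = 1.0,
    alpha_: float = 1.0,
    alpha_cross: float = 1.0,
    alpha_cross_: float = 1.0,
    k_low: float = 2.0,
    k_high: float = 50.0,
    k_minus: float = 1.0,
    epsilon: float = 1e-3,
) -> GRNSpec:
    """PU.1/GATA.1 lineage-determinant circuit: non-cooperative, with
    ordered binding.  The partner TF can bind a promoter only after the
    gene's own TF is bound, so each gene keeps three of the four two-site
    configurations (9 global promoter configurations).  Production is high
    with self-activation alone and low in the unbound and doubly-bound
    configurations."""
    x = GeneBlock(
        id="X",  # PU.1: site 1 self (X), site 2 partner (Y)
        binding_sites=("X", "Y"),
        binding_rates=((alpha, alpha_), (alpha_cross, alpha_cross_)),
        production_rates={"00": k_low, "10": k_high, "11": k_low},
        decay_rate=k_minus,
        excluded_configs=("01",),
    )
    y = GeneBlock(
        id="Y",  # GATA.1: site 1 partner (X), site 2 self (Y)
        binding_sites=("X", "Y"),
        binding_rates=((alpha_cross, alpha_cross_), (alpha, alpha_)),
        production_rates={"00": k_low, "01": k_high, "11": k_low},
        decay_rate=k_minus,
        excluded_configs=("10",),
    )
    spec = GRNSpec(genes=(x, y), epsilon=epsilon)
    require_valid(spec)
    return spec


BUILDERS = {
    "bursting_gene": bursting_gene,
    "self_regulating_gene": self_regulating_gene,
    "toggle_switch": toggle_switch,
    "coupled_toggles": coupled_toggles,
    "repressilator": repressilator,
    "cellfate_independent": cellfate_independent,
    "cellfate_pu1_gata1": cellfate_pu1_gata1,
}


def build_fixture(name: str, **overrides) -> GRNSpec:
    """Build a named fixture with default rates; keywords override the
    builder's parameters."""
    try:
        builder = BUILDERS[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(BUILDERS)}"
        ) from None
    return builder(**overrides)


def list_fixtures() -> list[dict]:
    import inspect

    out = []
    for name, b in BUILDERS.items():
        sig = inspect.signature(b)
        out.append(
            {
                "name": name,
                "provenance": PROVENANCE[name],
                "parameters": {
                    p.name: p.default for p in sig.parameters.values()
                },
            }
        )
    return out
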