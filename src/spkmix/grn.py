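"""Declarative gene-regulatory-network model with slow promoter kinetics.

A network is a set of *gene expression blocks*.  Each block owns a promoter
with up to two transcription-factor (TF) binding sites, a per-configuration
protein production rate, first-order decay, and (optionally) an n-merization
reaction turning the expressed protein into the multimer that acts as the
block's TF output.  Promoter binding/unbinding is *slow*: its rates are
scaled by the small parameter ``epsilon`` relative to the protein reactions.

Structural assumptions enforced by :func:`validate`:

A1. each promoter has at most two binding sites;
A2. each gene's TF output has a single, fixed cooperativity index;
A3. each gene is present in a single copy;
A4. the graph of gene expression blocks (wiring plus diffusion couplings)
    is connected.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import networkx as nx
import yaml

CONSTITUTIVE = "constitutive"

FORMAT_TAG = "spkmix/1"

#: reaction classes
SLOW_GENE = "slow_gene"
FAST_PROTEIN = "fast_protein"
FAST_DIFFUSION = "fast_diffusion"


@dataclass(frozen=True)
class GeneBlock:
    """One gene expression block.

    Parameters
    ----------
    id:
        Gene identifier; also the name of the expressed protein species.
    binding_sites:
        Ordered list of 0, 1 or 2 entries.  Each entry names the regulating
        gene (the TF is that gene's output, i.e. its protein or multimer) or
        is the string ``"constitutive"`` for autonomous on/off switching
        that consumes no TF.  The first site is the first digit of the
        promoter configuration code.
    binding_rates:
        One ``(association, dissociation)`` pair per site, in slow time
        units (they are multiplied by ``epsilon`` when reactions are
        expanded).  The association rate is per TF copy for TF-driven
        sites and a plain switching rate for constitutive ones.
    production_rates:
        Map from configuration code (e.g. ``"0"``, ``"10"``) to the protein
        production rate in that configuration (fast time units).
    decay_rate:
        Protein decay/dilution rate (fast time units, > 0).
    cooperativity:
        Number of protein copies forming the TF multimer (n >= 1).
    multimerization_rates:
        ``(beta, beta_minus)`` for ``n X <-> Xc``; required iff
        ``cooperativity > 1``.
    competitive:
        For two-site promoters: the two TFs compete for one location, so
        the doubly-bound configuration ``"11"`` is excluded.
    excluded_configs:
        Configurations structurally removed from the binding set (together
        with every transition in or out of them).  Generalizes
        ``competitive`` (which is shorthand for excluding ``"11"``) to
        ordered-binding promoters where a singly-bound configuration does
        not exist.
    """

    id: str
    binding_sites: tuple[str, ...] = ()
    binding_rates: tuple[tuple[float, float], ...] = ()
    production_rates: dict[str, float] = field(default_factory=dict)
    decay_rate: float = 1.0
    cooperativity: int = 1
    multimerization_rates: tuple[float, float] | None = None
    competitive: bool = False
    excluded_configs: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "binding_sites", tuple(self.binding_sites))
        object.__setattr__(
            self, "binding_rates", tuple(tuple(r) for r in self.binding_rates)
        )
        excluded = set(self.excluded_configs)
        if self.competitive:
            excluded.add("11")
        object.__setattr__(self, "excluded_configs", tuple(sorted(excluded)))

    # -- species naming ------------------------------------------------
    @property
    def protein_species(self) -> str:
        return self.id

    @property
    def multimer_species(self) -> str | None:
        return f"{self.id}c" if self.cooperativity > 1 else None

    @property
    def output_species(self) -> str:
        """The species acting as this gene's TF (multimer if cooperative)."""
        return self.multimer_species or self.protein_species

    def promoter_species(self, code: str) -> str:
        return f"D_{self.id}_{code}"

    # -- binding set ---------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.binding_sites)

    @property
    def binding_set(self) -> tuple[str, ...]:
        """Ordered configuration codes, one binary digit per site."""
        if self.n_sites <= 1:
            codes = ("0", "1")
        else:
            codes = ("00", "01", "10", "11")
        return tuple(c for c in codes if c not in self.excluded_configs)

    def site_transitions(self):
        """Yield ``(j, j_prime, site)`` for every allowed single-site
        binding transition (site flips 0 -> 1); unbinding is the reverse."""
        B = set(self.binding_set)
        for j in self.binding_set:
            for s in range(max(self.n_sites, 1)):
                if j[s] == "0":
                    jp = j[:s] + "1" + j[s + 1 :]
                    if jp in B:
                        yield j, jp, s


@dataclass(frozen=True)
class GRNSpec:
    """A full network: gene blocks, optional diffusion couplings between
    protein species (e.g. cells exchanging proteins at rate omega), and the
    promoter/protein timescale ratio epsilon."""

    genes: tuple[GeneBlock, ...]
    diffusion_couplings: tuple[tuple[str, str, float], ...] = ()
    epsilon: float = 1e-3

    def __post_init__(self):
        object.__setattr__(self, "genes", tuple(self.genes))
        object.__setattr__(
            self,
            "diffusion_couplings",
            tuple((a, b, float(w)) for a, b, w in self.diffusion_couplings),
        )

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def gene(self, gene_id: str) -> GeneBlock:
        for g in self.genes:
            if g.id == gene_id:
                return g
        raise KeyError(f"no gene {gene_id!r}")

    def output_map(self) -> dict[str, GeneBlock]:
        """Map TF output species name -> producing gene."""
        return {g.output_species: g for g in self.genes}

    def resolve_tf(self, name: str) -> GeneBlock | None:
        """Resolve a binding-site entry (gene id or output species name) to
        the regulating gene; ``None`` for constitutive sites."""
        if name == CONSTITUTIVE:
            return None
        for g in self.genes:
            if name in (g.id, g.output_species):
                return g
        raise KeyError(f"binding site references unknown TF {name!r}")

    @property
    def n_states(self) -> int:
        out = 1
        for g in self.genes:
            out *= len(g.binding_set)
        return out

    def protein_species_list(self) -> list[str]:
        """All protein-side species (monomers, then the multimers that
        exist), gene order."""
        out = [g.protein_species for g in self.genes]
        out += [g.multimer_species for g in self.genes if g.multimer_species]
        return out

    def with_epsilon(self, epsilon: float) -> "GRNSpec":
        return replace(self, epsilon=float(epsilon))


@dataclass(frozen=True)
class GeneState:
    """One global promoter configuration d = (d_1, ..., d_N) together with
    its mixed-radix integer index in 0..L-1 (first gene = most significant
    digit)."""

    config: tuple[str, ...]
    index: int

    def label(self) -> str:
        return "|".join(self.config)


def state_index(spec: GRNSpec, config) -> int:
    idx = 0
    for g, c in zip(spec.genes, config):
        B = g.binding_set
        idx = idx * len(B) + B.index(c)
    return idx


def state_config(spec: GRNSpec, index: int) -> tuple[str, ...]:
    digits = []
    for g in reversed(spec.genes):
        B = g.binding_set
        index, r = divmod(index, len(B))
        digits.append(B[r])
    return tuple(reversed(digits))


def enumerate_states(spec: GRNSpec) -> list[GeneState]:
    """All L promoter configurations, sorted by index."""
    out = []
    for i, cfg in enumerate(
        itertools.product(*(g.binding_set for g in spec.genes))
    ):
        out.append(GeneState(config=cfg, index=i))
    return out


# ---------------------------------------------------------------------------
# validation


def validate(spec: GRNSpec) -> list[str]:
    """Check the structural assumptions; returns a list of human-readable
    violations (empty iff the spec is valid)."""
    v: list[str] = []
    seen: set[str] = set()
    for g in spec.genes:
        if g.id in seen:
            v.append(f"A3: gene {g.id!r} declared more than once "
                     "(each gene must be present in a single copy)")
        seen.add(g.id)
        if g.n_sites > 2:
            v.append(f"A1: gene {g.id!r} has {g.n_sites} binding sites; "
                     "each promoter can have up to two TFs binding to it")
            continue
        if len(g.binding_rates) != max(g.n_sites, 1):
            v.append(f"gene {g.id!r}: need one (association, dissociation) "
                     f"rate pair per site, got {len(g.binding_rates)}")
        if g.n_sites == 2 and CONSTITUTIVE in g.binding_sites:
            v.append(f"gene {g.id!r}: a two-site promoter cannot mix "
                     "constitutive switching with TF binding")
        bad = set(g.excluded_configs) - {"01", "10", "11"}
        if g.n_sites <= 1 and g.excluded_configs:
            v.append(f"gene {g.id!r}: configuration exclusions require a "
                     "two-site promoter")
        elif bad:
            v.append(f"gene {g.id!r}: cannot exclude configuration(s) "
                     f"{sorted(bad)} (the all-unbound state must exist)")
        for j in g.binding_set:
            if j not in g.production_rates:
                v.append(f"gene {g.id!r}: configuration {j!r} has no "
                         "production rate (use 0 for silent configurations)")
            elif g.production_rates[j] < 0:
                v.append(f"gene {g.id!r}: negative production rate for {j!r}")
        for j in g.production_rates:
            if j not in g.binding_set:
                v.append(f"gene {g.id!r}: production rate given for "
                         f"configuration {j!r} outside the binding set")
        if not g.decay_rate > 0:
            v.append(f"gene {g.id!r}: decay rate must be positive")
        if g.cooperativity < 1 or int(g.cooperativity) != g.cooperativity:
            v.append(f"A2: gene {g.id!r}: cooperativity index must be an "
                     "integer >= 1")
        if g.cooperativity > 1:
            if g.multimerization_rates is None:
                v.append(f"gene {g.id!r}: cooperativity {g.cooperativity} "
                         "requires multimerization_rates (beta, beta_minus)")
            elif not all(r > 0 for r in g.multimerization_rates):
                v.append(f"gene {g.id!r}: multimerization rates must be "
                         "positive")
        elif g.multimerization_rates is not None:
            v.append(f"gene {g.id!r}: multimerization rates given but "
                     "cooperativity is 1")
        for s in g.binding_sites:
            if s == CONSTITUTIVE:
                continue
            try:
                spec.resolve_tf(s)
            except KeyError:
                v.append(f"gene {g.id!r}: binding site references TF {s!r} "
                         "which is not the output of any gene in the network")
    if not spec.epsilon > 0:
        v.append("epsilon must be positive")

    known = {g.protein_species for g in spec.genes}
    known |= {g.multimer_species for g in spec.genes if g.multimer_species}
    for a, b, w in spec.diffusion_couplings:
        for s in (a, b):
            if s not in known:
                v.append(f"diffusion coupling references unknown species "
                         f"{s!r}")
        if w < 0:
            v.append(f"diffusion coupling ({a}, {b}) has negative rate")

    # A4: connectivity of the block graph (wiring edges plus diffusion).
    if spec.n_genes > 1:
        graph = nx.Graph()
        graph.add_nodes_from(g.id for g in spec.genes)
        for g in spec.genes:
            for s in g.binding_sites:
                if s != CONSTITUTIVE:
                    try:
                        src = spec.resolve_tf(s)
                    except KeyError:
                        continue
                    graph.add_edge(src.id, g.id)
        by_species = {}
        for g in spec.genes:
            by_species[g.protein_species] = g.id
            if g.multimer_species:
                by_species[g.multimer_species] = g.id
        for a, b, _ in spec.diffusion_couplings:
            if a in by_species and b in by_species:
                graph.add_edge(by_species[a], by_species[b])
        if not nx.is_connected(graph):
            v.append("A4: the graph of gene expression blocks is not "
                     "connected; analyze each connected component separately")
    return v


def require_valid(spec: GRNSpec) -> None:
    problems = validate(spec)
    if problems:
        raise ValueError("invalid GRN spec:\n" + "\n".join(problems))


# ---------------------------------------------------------------------------
# reaction expansion


@dataclass(frozen=True)
class Reaction:
    """One mass-action reaction.  ``rate`` is the base rate constant; slow
    gene reactions are additionally multiplied by epsilon (the propensity
    convention is combinatorial: rate * prod_s C(x_s, nu_s))."""

    name: str
    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    rate: float
    klass: str

    def effective_rate(self, epsilon: float) -> float:
        return self.rate * epsilon if self.klass == SLOW_GENE else self.rate


@dataclass
class ReactionNetwork:
    """Explicit stochastic reaction network expanded from a GRNSpec."""

    spec: GRNSpec
    species: list[str]
    reactions: list[Reaction]

    @property
    def epsilon(self) -> float:
        return self.spec.epsilon

    def to_tsv(self, path) -> None:
        import pandas as pd

        rows = []
        for r in self.reactions:
            rows.append(
                {
                    "name": r.name,
                    "reactants": " + ".join(
                        f"{n} {s}" if n > 1 else s for s, n in r.reactants
                    ) or "0",
                    "products": " + ".join(
                        f"{n} {s}" if n > 1 else s for s, n in r.products
                    ) or "0",
                    "rate": r.rate,
                    "class": r.klass,
                }
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _counts(*pairs) -> tuple[tuple[str, int], ...]:
    return tuple((s, n) for s, n in pairs if n)


def expand_reactions(spec: GRNSpec) -> ReactionNetwork:
    """Expand a validated spec into the explicit reaction list.

    Per gene: one binding and one unbinding reaction per allowed single-site
    promoter transition (class ``slow_gene``; TF-driven binding consumes one
    copy of the TF output species), one production reaction per configuration
    with a nonzero rate, one decay reaction, and the n-merization pair when
    the gene is cooperative.  Diffusion couplings add a reversible transport
    pair per coupling.
    """
    require_valid(spec)
    species: list[str] = []
    for g in spec.genes:
        species += [g.promoter_species(j) for j in g.binding_set]
    for g in spec.genes:
        species.append(g.protein_species)
    for g in spec.genes:
        if g.multimer_species:
            species.append(g.multimer_species)

    reactions: list[Reaction] = []
    for g in spec.genes:
        for j, jp, s in g.site_transitions():
            site = g.binding_sites[s] if g.binding_sites else CONSTITUTIVE
            alpha, alpha_ = g.binding_rates[s]
            tf_gene = spec.resolve_tf(site)
            tf = () if tf_gene is None else ((tf_gene.output_species, 1),)
            reactions.append(
                Reaction(
                    name=f"bind:{g.id}:{j}->{jp}",
                    reactants=tf + ((g.promoter_species(j), 1),),
                    products=((g.promoter_species(jp), 1),),
                    rate=alpha,
                    klass=SLOW_GENE,
                )
            )
            reactions.append(
                Reaction(
                    name=f"unbind:{g.id}:{jp}->{j}",
                    reactants=((g.promoter_species(jp), 1),),
                    products=((g.promoter_species(j), 1),) + tf,
                    rate=alpha_,
                    klass=SLOW_GENE,
                )
            )
        for j in g.binding_set:
            k = g.production_rates.get(j, 0.0)
            if k > 0:
                reactions.append(
                    Reaction(
                        name=f"produce:{g.id}:{j}",
                        reactants=((g.promoter_species(j), 1),),
                        products=(
                            (g.promoter_species(j), 1),
                            (g.protein_species, 1),
                        ),
                        rate=k,
                        klass=FAST_PROTEIN,
                    )
                )
        reactions.append(
            Reaction(
                name=f"decay:{g.id}",
                reactants=((g.protein_species, 1),),
                products=(),
                rate=g.decay_rate,
                klass=FAST_PROTEIN,
            )
        )
        if g.cooperativity > 1:
            beta, beta_ = g.multimerization_rates
            n = g.cooperativity
            reactions.append(
                Reaction(
                    name=f"nmerize:{g.id}",
                    reactants=((g.protein_species, n),),
                    products=((g.multimer_species, 1),),
                    rate=beta,
                    klass=FAST_PROTEIN,
                )
            )
            reactions.append(
                Reaction(
                    name=f"denmerize:{g.id}",
                    reactants=((g.multimer_species, 1),),
                    products=((g.protein_species, n),),
                    rate=beta_,
                    klass=FAST_PROTEIN,
                )
            )
    for a, b, w in spec.diffusion_couplings:
        reactions.append(
            Reaction(
                name=f"diffuse:{a}->{b}",
                reactants=((a, 1),),
                products=((b, 1),),
                rate=w,
                klass=FAST_DIFFUSION,
            )
        )
        reactions.append(
            Reaction(
                name=f"diffuse:{b}->{a}",
                reactants=((b, 1),),
                products=((a, 1),),
                rate=w,
                klass=FAST_DIFFUSION,
            )
        )
    return ReactionNetwork(spec=spec, species=species, reactions=reactions)


def propensity_coeff(reactants: tuple[tuple[str, int], ...]) -> float:
    """Combinatorial normalization: prod 1/nu! (used by the deterministic
    backend so its equilibria match the stochastic product-form means)."""
    out = 1.0
    for _, n in reactants:
        out /= math.factorial(n)
    return out


# ---------------------------------------------------------------------------
# file round-trip


def spec_to_dict(spec: GRNSpec) -> dict:
    genes = []
    for g in spec.genes:
        d = {
            "id": g.id,
            "binding_sites": list(g.binding_sites),
            "binding_rates": [list(r) for r in g.binding_rates],
            "production_rates": {str(k): float(v)
                                 for k, v in g.production_rates.items()},
            "decay_rate": float(g.decay_rate),
            "cooperativity": int(g.cooperativity),
        }
        if g.multimerization_rates is not None:
            d["multimerization_rates"] = list(g.multimerization_rates)
        if g.competitive:
            d["competitive"] = True
        extra = set(g.excluded_configs) - ({"11"} if g.competitive else set())
        if extra:
            d["excluded_configs"] = sorted(extra)
        genes.append(d)
    out = {"format": FORMAT_TAG, "epsilon": float(spec.epsilon),
           "genes": genes}
    if spec.diffusion_couplings:
        out["diffusion"] = [
            {"species": [a, b], "rate": float(w)}
            for a, b, w in spec.diffusion_couplings
        ]
    return out


def spec_from_dict(data: dict) -> GRNSpec:
    tag = data.get("format", FORMAT_TAG)
    if tag != FORMAT_TAG:
        raise ValueError(f"unsupported model format {tag!r} "
                         f"(expected {FORMAT_TAG!r})")
    genes = []
    for d in data["genes"]:
        genes.append(
            GeneBlock(
                id=str(d["id"]),
                binding_sites=tuple(d.get("binding_sites", ())),
                binding_rates=tuple(
                    tuple(map(float, r)) for r in d.get("binding_rates", ())
                ),
                production_rates={
                    str(k): float(v)
                    for k, v in d.get("production_rates", {}).items()
                },
                decay_rate=float(d.get("decay_rate", 1.0)),
                cooperativity=int(d.get("cooperativity", 1)),
                multimerization_rates=(
                    tuple(map(float, d["multimerization_rates"]))
                    if d.get("multimerization_rates") is not None
                    else None
                ),
                competitive=bool(d.get("competitive", False)),
                excluded_configs=tuple(d.get("excluded_configs", ())),
            )
        )
    diffusion = tuple(
        (c["species"][0], c["species"][1], float(c["rate"]))
        for c in data.get("diffusion", ())
    )
    return GRNSpec(
        genes=tuple(genes),
        diffusion_couplings=diffusion,
        epsilon=float(data.get("epsilon", 1e-3)),
    )


def save_spec(spec: GRNSpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(spec_to_dict(spec), fh, sort_keys=False)


def load_spec(path) -> GRNSpec:
    with open(path) as fh:
        return spec_from_dict(yaml.safe_load(fh))
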