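"""Comparative reports: stochastic SPK mode counts versus deterministic
stable equilibria, and the cell-fate circuit analyses."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .fixtures import build_fixture
from .reduction import (
    DEFAULT_WEIGHT_FLOOR,
    PoissonMixture,
    find_modes,
    mixture_pmf,
)
from .validation import ode_steady_states

#: deterministic sweep variants for the self-regulating gene: the default
#: caption rates, a low-leak/weak-binding set in the bistable regime of the
#: cooperative gene, and a weak-multimerization set pinning the cooperative
#: non-leaky gene at zero.
SELF_GENE_SWEEP = (
    {},
    {"k0": 5.0, "alpha": 0.4, "beta": 10.0, "beta_minus": 50.0},
    {"alpha": 0.2, "beta": 1.0, "beta_minus": 50.0},
)


@dataclass
class Table1Report:
    """Mode/equilibrium counts for the self-activating gene across the
    leaky x cooperative grid."""

    table: pd.DataFrame
    stochastic_detail: dict = field(default_factory=dict)
    deterministic_detail: dict = field(default_factory=dict)


def _stochastic_cell(cooperative: bool, leaky: bool,
                     weight_floor: float) -> tuple[str, dict]:
    spec = build_fixture(
        "self_regulating_gene", cooperative=cooperative, leaky=leaky
    )
    mix = mixture_pmf(spec)
    report = find_modes(mix, weight_floor=weight_floor, scan_lattice=False)
    locs = [loc for loc, _ in report.component_modes]
    label = str(report.n_component_modes)
    if report.n_component_modes == 1:
        label += f" (at {locs[0][0]:g})"
    return label, {
        "modes": report.component_modes,
        "weights": mix.weights.tolist(),
    }


def _deterministic_cell(cooperative: bool, leaky: bool, n_starts: int,
                        seed: int) -> tuple[str, dict]:
    counts = []
    detail = []
    for overrides in SELF_GENE_SWEEP:
        kw = dict(overrides)
        if not cooperative:
            kw.pop("beta", None)
            kw.pop("beta_minus", None)
        spec = build_fixture(
            "self_regulating_gene", cooperative=cooperative, leaky=leaky,
            **kw,
        )
        eqs = ode_steady_states(spec, n_starts=n_starts, seed=seed)
        stable = [e for e in eqs if e.stable]
        counts.append(len(stable))
        detail.append(
            {
                "overrides": kw,
                "stable": [e.species["X"] for e in stable],
            }
        )
    lo, hi = min(counts), max(counts)
    return (str(lo) if lo == hi else f"{lo}-{hi}"), {
        "counts": counts,
        "detail": detail,
    }


def table1_report(weight_floor: float = DEFAULT_WEIGHT_FLOOR,
                  n_starts: int = 80, seed: int = 0) -> Table1Report:
    """Recompute the mode/equilibrium comparison for a self-activating
    gene: the SPK mixture component count (stochastic row) against the
    stable-equilibrium count of the mass-action ODE over the documented
    parameter sweep (deterministic row)."""
    cols = [
        ("Non-Cooperative", "Leaky"),
        ("Non-Cooperative", "Non-Leaky"),
        ("Cooperative", "Leaky"),
        ("Cooperative", "Non-Leaky"),
    ]
    stoch_row, det_row = [], []
    sdet, ddet = {}, {}
    for coop_label, leak_label in cols:
        coop = coop_label == "Cooperative"
        leaky = leak_label == "Leaky"
        s_label, s_info = _stochastic_cell(coop, leaky, weight_floor)
        d_label, d_info = _deterministic_cell(coop, leaky, n_starts, seed)
        stoch_row.append(s_label)
        det_row.append(d_label)
        sdet[(coop_label, leak_label)] = s_info
        ddet[(coop_label, leak_label)] = d_info
    table = pd.DataFrame(
        [stoch_row, det_row],
        index=["Stochastic (Slow Promoter Kinetics)", "Deterministic"],
        columns=pd.MultiIndex.from_tuples(cols),
    )
    return Table1Report(table=table, stochastic_detail=sdet,
                        deterministic_detail=ddet)


# ---------------------------------------------------------------------------
# cell-fate circuits


#: binding-rate scenarios for the PU.1/GATA.1 circuit: strong exclusive
#: self-activation leaves two dominant expression groups; weaker
#: self-binding keeps the unbound (low,low) group as a third.
PU1_GATA1_SCENARIOS = {
    "bistable": {"alpha": 20.0, "alpha_": 0.5,
                 "alpha_cross": 0.2, "alpha_cross_": 2.0},
    "tristable": {"alpha": 0.6, "alpha_": 1.0,
                  "alpha_cross": 0.2, "alpha_cross_": 2.0},
}


@dataclass
class CellFateReport:
    which: str
    mixture: PoissonMixture
    component_count: int
    quadrant_thresholds: tuple[float, float]
    group_weights: dict[tuple[str, str], float]
    dominant_groups: list[tuple[str, str]]
    scenarios: dict = field(default_factory=dict)
    deterministic_stable_count: int | None = None


def _quadrant_grouping(mix: PoissonMixture, fraction: float):
    locs = mix.locations()
    thresholds = tuple(fraction * locs[:, i].max() for i in range(2))
    groups: dict[tuple[str, str], float] = {}
    for (x, y), w in zip(locs, mix.weights):
        key = ("high" if x > thresholds[0] else "low",
               "high" if y > thresholds[1] else "low")
        groups[key] = groups.get(key, 0.0) + float(w)
    return thresholds, groups


def cellfate_report(which: str,
                    weight_floor: float = DEFAULT_WEIGHT_FLOOR,
                    quadrant_fraction: float = 0.5,
                    dominance: float = 0.1,
                    n_starts: int = 80, seed: int = 0,
                    **overrides) -> CellFateReport:
    """Mixture and quadrant-grouped view of a trans-differentiation
    circuit.

    Components are grouped into the four (low/high) x (low/high) quadrants
    with the boundary at ``quadrant_fraction`` of the largest component
    mean per axis; a group is dominant when its weight reaches
    ``dominance``.  For the PU.1/GATA.1 circuit the report additionally
    evaluates the bistable/tristable binding-rate scenarios and the
    deterministic backend (stable-equilibrium count at the default
    rates)."""
    if which not in ("independent", "pu1_gata1"):
        raise ValueError("which must be 'independent' or 'pu1_gata1'")
    name = ("cellfate_independent" if which == "independent"
            else "cellfate_pu1_gata1")
    spec = build_fixture(name, **overrides)
    mix = mixture_pmf(spec)
    thresholds, groups = _quadrant_grouping(mix, quadrant_fraction)
    dominant = [k for k, w in sorted(groups.items(), key=lambda kv: -kv[1])
                if w >= dominance]
    report = CellFateReport(
        which=which,
        mixture=mix,
        component_count=len(mix.components),
        quadrant_thresholds=thresholds,
        group_weights=groups,
        dominant_groups=dominant,
    )
    if which == "pu1_gata1":
        for label, params in PU1_GATA1_SCENARIOS.items():
            smix = mixture_pmf(build_fixture(name, **{**params,
                                                      **overrides}))
            _, sgroups = _quadrant_grouping(smix, quadrant_fraction)
            sdom = [k for k, w in sgroups.items() if w >= dominance]
            report.scenarios[label] = {
                "params": params,
                "group_weights": sgroups,
                "dominant_groups": sorted(sdom),
                "n_dominant": len(sdom),
            }
        eqs = ode_steady_states(spec, n_starts=n_starts, seed=seed)
        report.deterministic_stable_count = sum(e.stable for e in eqs)
    return report
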