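"""Structural model layer: validation, state enumeration, reaction
expansion, file round-trip."""

import hypothesis.strategies as st
import pytest
from hypothesis import given, settings

import spkmix as sx
from spkmix.grn import GeneBlock, GRNSpec


def _self_gene(gid, **kw):
    defaults = dict(
        binding_sites=(gid,),
        binding_rates=((1.0, 1.0),),
        production_rates={"0": 1.0, "1": 5.0},
        decay_rate=1.0,
    )
    defaults.update(kw)
    return GeneBlock(id=gid, **defaults)


class TestValidate:
    def test_toggle_satisfies_all_assumptions(self, toggle):
        assert sx.validate(toggle) == []

    def test_three_site_promoter_violates_a1(self):
        g = GeneBlock(
            id="X",
            binding_sites=("X", "X", "X"),
            binding_rates=((1, 1),) * 3,
            production_rates={},
            decay_rate=1.0,
        )
        problems = sx.validate(GRNSpec(genes=(g,)))
        assert any(p.startswith("A1") for p in problems)

    def test_disconnected_blocks_violate_a4(self):
        spec = GRNSpec(genes=(_self_gene("X"), _self_gene("Y")))
        problems = sx.validate(spec)
        assert any(p.startswith("A4") for p in problems)

    def test_diffusion_restores_connectivity(self):
        spec = GRNSpec(
            genes=(_self_gene("X"), _self_gene("Y")),
            diffusion_couplings=(("X", "Y", 1.0),),
        )
        assert sx.validate(spec) == []

    def test_duplicate_gene_violates_a3(self):
        spec = GRNSpec(genes=(_self_gene("X"), _self_gene("X")))
        assert any(p.startswith("A3") for p in sx.validate(spec))

    def test_cooperative_gene_needs_multimerization_rates(self):
        g = _self_gene("X", cooperativity=2)
        assert any(
            "multimerization" in p for p in sx.validate(GRNSpec(genes=(g,)))
        )

    def test_unknown_tf_reported(self):
        g = _self_gene("X", binding_sites=("Z",))
        assert any("Z" in p for p in sx.validate(GRNSpec(genes=(g,))))

    def test_missing_production_rate_reported(self):
        g = _self_gene("X", production_rates={"0": 1.0})
        assert any("no production rate" in p
                   for p in sx.validate(GRNSpec(genes=(g,))))


class TestStates:
    @pytest.mark.parametrize(
        "fixture_name, expected_count",
        [
            ("bursting_gene", 2),
            ("self_regulating_gene", 2),
            ("toggle_switch", 4),
            ("cellfate_independent", 16),
            ("cellfate_pu1_gata1", 9),
        ],
    )
    def test_state_counts(self, fixture_name, expected_count):
        spec = sx.build_fixture(fixture_name)
        assert len(sx.enumerate_states(spec)) == expected_count
        assert spec.n_states == expected_count

    def test_index_config_roundtrip(self):
        spec = sx.build_fixture("cellfate_pu1_gata1")
        for s in sx.enumerate_states(spec):
            assert sx.state_index(spec, s.config) == s.index
            assert sx.state_config(spec, s.index) == s.config

    def test_competitive_binding_set(self):
        g = GeneBlock(
            id="X",
            binding_sites=("X", "X"),
            binding_rates=((1, 1), (1, 1)),
            production_rates={"00": 1.0, "01": 0.0, "10": 0.0},
            decay_rate=1.0,
            competitive=True,
        )
        assert g.binding_set == ("00", "01", "10")

    @given(
        sizes=st.lists(st.sampled_from([2, 3, 4]), min_size=1, max_size=4)
    )
    @settings(derandomize=True, max_examples=40)
    def test_mixed_radix_bijection(self, sizes):
        """Index <-> configuration is a bijection for any mix of promoter
        binding-set sizes."""
        genes = []
        for i, size in enumerate(sizes):
            if size == 2:
                genes.append(_self_gene(f"G{i}"))
            else:
                excluded = ("11",) if size == 3 else ()
                genes.append(
                    GeneBlock(
                        id=f"G{i}",
                        binding_sites=(f"G{i}", f"G{i}"),
                        binding_rates=((1, 1), (1, 1)),
                        production_rates={
                            c: 1.0
                            for c in ("00", "01", "10", "11")
                            if c not in excluded
                        },
                        decay_rate=1.0,
                        excluded_configs=excluded,
                    )
                )
        spec = GRNSpec(genes=tuple(genes))
        states = sx.enumerate_states(spec)
        assert len(states) == spec.n_states
        seen = set()
        for s in states:
            assert sx.state_index(spec, s.config) == s.index
            seen.add(s.config)
        assert len(seen) == spec.n_states


class TestReactions:
    def test_bursting_gene_has_four_reactions(self, bursting):
        net = sx.expand_reactions(bursting)
        kinds = sorted(r.name.split(":")[0] for r in net.reactions)
        assert kinds == ["bind", "decay", "produce", "unbind"]

    def test_noncooperative_gene_has_no_multimerization(self):
        spec = sx.build_fixture("self_regulating_gene", cooperative=False)
        net = sx.expand_reactions(spec)
        assert not any("merize" in r.name for r in net.reactions)

    def test_slow_fast_classification(self, self_gene_coop):
        net = sx.expand_reactions(self_gene_coop)
        by_class = {r.name.split(":")[0]: r.klass for r in net.reactions}
        assert by_class["bind"] == "slow_gene"
        assert by_class["produce"] == "fast_protein"
        assert by_class["nmerize"] == "fast_protein"

    def test_diffusion_couplings_expand_both_directions(self, coupled):
        net = sx.expand_reactions(coupled)
        diff = [r for r in net.reactions if r.klass == "fast_diffusion"]
        # all-pairs among 3 X's and 3 Y's, reversible: 2 * 2 * C(3,2)
        assert len(diff) == 12
        names = {r.name for r in diff}
        assert "diffuse:X1->X2" in names and "diffuse:X2->X1" in names

    def test_excluded_configuration_blocks_transitions(self):
        spec = sx.build_fixture("cellfate_pu1_gata1")
        net = sx.expand_reactions(spec)
        assert not any("D_X_01" in s for r in net.reactions
                       for s, _ in r.reactants + r.products)

    def test_promoter_conservation(self, coupled):
        """Every reaction leaves each gene's total promoter copy number
        unchanged."""
        net = sx.expand_reactions(coupled)
        for r in net.reactions:
            per_gene = {}
            for s, n in r.reactants:
                if s.startswith("D_"):
                    gid = s.split("_", 2)[1]
                    per_gene[gid] = per_gene.get(gid, 0) - n
            for s, n in r.products:
                if s.startswith("D_"):
                    gid = s.split("_", 2)[1]
                    per_gene[gid] = per_gene.get(gid, 0) + n
            assert all(v == 0 for v in per_gene.values())

    def test_expansion_is_deterministic(self, toggle):
        a = sx.expand_reactions(toggle)
        b = sx.expand_reactions(toggle)
        assert a.reactions == b.reactions

    def test_slow_rates_scale_with_epsilon(self, bursting):
        net = sx.expand_reactions(bursting)
        bind = next(r for r in net.reactions if r.name.startswith("bind"))
        assert bind.effective_rate(0.01) == pytest.approx(0.01 * bind.rate)
        decay = next(r for r in net.reactions if r.name.startswith("decay"))
        assert decay.effective_rate(0.01) == decay.rate


class TestRoundTrip:
    @pytest.mark.parametrize(
        "name", ["bursting_gene", "toggle_switch", "coupled_toggles",
                 "cellfate_pu1_gata1"]
    )
    def test_yaml_roundtrip_identity(self, name, tmp_path):
        spec = sx.build_fixture(name)
        path = tmp_path / "model.yaml"
        sx.save_spec(spec, path)
        assert sx.load_spec(path) == spec

    def test_format_tag_checked(self, tmp_path):
        with pytest.raises(ValueError, match="format"):
            sx.spec_from_dict({"format": "other/9", "genes": []})
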