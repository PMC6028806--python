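"""Sub-model extraction: selection, deletion, dangling detection, overrides."""

import random

import numpy as np
import pytest

import simexpt as sx
from simexpt import fixtures as fx
from simexpt.subset import DanglingError, SubsetSpec

B = "/kinetics/binding"


def brute_force_dangling(model):
    """Independent oracle: scan every reaction/enzyme participant list."""
    out = {}
    for table in (model.reactions, model.enzymes):
        for path, entity in table.items():
            missing = [p for p in entity.participants()
                       if p not in model.pools]
            if missing:
                out[path] = sorted(missing)
    return out


def test_intact_fixture_has_no_dangling(cascade_model):
    assert not sx.find_dangling(cascade_model)


def test_removed_substrate_reported(binding_model):
    del binding_model.pools[f"{B}/L"]
    report = sx.find_dangling(binding_model)
    assert report.entries == [(f"{B}/bind", [f"{B}/L"])]


def test_dangling_matches_brute_force_on_random_deletions():
    """50 randomized deletion patterns on the cascade model."""
    rng = random.Random(20240917)
    for _ in range(50):
        m = fx.make_cascade_model(3)
        pools = sorted(m.pools)
        for p in rng.sample(pools, rng.randint(0, len(pools))):
            del m.pools[p]
        report = sx.find_dangling(m)
        assert {p: sorted(miss) for p, miss in report.entries} \
            == brute_force_dangling(m)


class TestExtractSubset:
    def test_identity_extraction(self, cascade_model):
        sub, report = sx.extract_subset(cascade_model,
                                        SubsetSpec(includePaths=["/"]))
        assert not report
        assert sub.structurally_equal(cascade_model)

    def test_translation_scenario(self, translation):
        """Select the pathway, remove the branch absent from the in-vitro
        prep; the extracted model is exactly the binding step."""
        model, doc = translation
        sub, report = sx.extract_subset(model, doc.modelMap.subset)
        assert not report
        assert set(sub.pools) == {"/kinetics/translation/40S",
                                  "/kinetics/translation/eIF4E-mRNA",
                                  "/kinetics/translation/43S"}
        assert set(sub.reactions) == {"/kinetics/translation/bind43S"}

    def test_delete_pool_strict_errors_prune_reports(self, binding_model):
        spec = SubsetSpec(includePaths=["/"], deletePaths=[f"{B}/L"])
        with pytest.raises(DanglingError) as exc:
            sx.extract_subset(binding_model, spec, policy="strict")
        assert exc.value.report.paths() == {f"{B}/bind"}
        sub, report = sx.extract_subset(binding_model, spec, policy="prune")
        assert report.paths() == {f"{B}/bind"}
        assert f"{B}/bind" not in sub.reactions

    def test_delete_whole_group(self, cascade_model):
        spec = SubsetSpec(includePaths=["/"],
                          deletePaths=["/kinetics/input_Ca"])
        sub, report = sx.extract_subset(cascade_model, spec)
        assert not report
        assert all(not p.startswith("/kinetics/input_Ca")
                   for p in sub.entity_paths())

    def test_entity_count_arithmetic(self, cascade_model):
        include = ["/kinetics/cascade", "/kinetics/input_EGF"]
        resolved = sx.resolve_paths(cascade_model, include)
        spec = SubsetSpec(includePaths=include,
                          deletePaths=["/kinetics/cascade/tier3/X3_act"])
        sub, report = sx.extract_subset(cascade_model, spec, policy="prune")
        n_pruned = len(report.entries)
        assert len(sub.entity_paths()) == len(resolved) - 1 - n_pruned
        assert n_pruned == 2   # relax3 reaction and act3 enzyme lose X3_act

    def test_idempotent(self, cascade_model):
        spec = SubsetSpec(includePaths=["/kinetics/cascade"],
                          deletePaths=["/kinetics/cascade/tier3"])
        once, _ = sx.extract_subset(cascade_model, spec)
        twice, _ = sx.extract_subset(once, spec)
        assert once.structurally_equal(twice)

    def test_entity_map_must_resolve(self, binding_model):
        spec = SubsetSpec(includePaths=[f"{B}/R"],
                          entityMap={"receptor": [f"{B}/RL"]})
        with pytest.raises(sx.PathError, match="receptor"):
            sx.extract_subset(binding_model, spec, policy="prune")


class TestApplyCondition:
    def test_buffered_pool_trajectory_constant(self, binding_model):
        m = sx.apply_condition(binding_model,
                               [(f"{B}/L", "concInit", 0.7),
                                (f"{B}/L", "buffered", True)])
        out = sx.run_time_series(m, [], {"L": [f"{B}/L"],
                                         "RL": [f"{B}/RL"]}, 20.0, 0.5)
        assert np.allclose(out.series("L"), 0.7, atol=1e-12)
        assert out.series("RL")[-1] > 0.3   # reaction still runs

    def test_zero_forward_rate_stops_flux(self, binding_model):
        m = sx.apply_condition(binding_model, [(f"{B}/bind", "Kf", 0.0)])
        out = sx.run_time_series(
            m, [(0.0, f"{B}/L", "conc", 1.0)], {"RL": [f"{B}/RL"]}, 50.0, 1.0)
        assert np.all(out.series("RL") == 0.0)

    def test_negative_concentration_rejected(self, binding_model):
        with pytest.raises(sx.ModelError, match="concInit"):
            sx.apply_condition(binding_model, [(f"{B}/R", "concInit", -1.0)])

    def test_unknown_field_rejected(self, binding_model):
        with pytest.raises(sx.ModelError, match="not overridable"):
            sx.apply_condition(binding_model, [(f"{B}/R", "Kf", 1.0)])

    def test_disjoint_overrides_commute(self, cascade_model):
        o1 = ("/kinetics/cascade/tier1/X1", "concInit", 0.3)
        o2 = ("/kinetics/cascade/tier2/relax2", "Kf", 0.5)
        ab = sx.apply_condition(sx.apply_condition(cascade_model, [o1]), [o2])
        ba = sx.apply_condition(sx.apply_condition(cascade_model, [o2]), [o1])
        assert ab.structurally_equal(ba)
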