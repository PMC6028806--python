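"""Model representation, path resolution, validation, and format round trips."""

import math

import pytest
from lxml import etree

import simexpt as sx
from simexpt import fixtures as fx
from simexpt.io_sbml import GROUPS_NS, SBML_NS

NATIVE_SMALL = """\
# hand-written three-pool model
compartment\tcyto\t1e-15
pool\t/cell/A\tcyto\t1.0\t0
pool\t/cell/B\tcyto\t0.5\t0
pool\t/cell/C\tcyto\t0.0\t1
reaction\t/cell/r1\t/cell/A:1+/cell/B:1\t/cell/C:1\t2.5\t0.125
"""


def test_native_load_counts(tmp_path):
    src = tmp_path / "small.model"
    src.write_text(NATIVE_SMALL)
    m = sx.load_model(src)
    assert len(m.pools) == 3
    assert len(m.reactions) == 1
    assert m.pools["/cell/C"].buffered
    assert m.reactions["/cell/r1"].Kf == 2.5


@pytest.mark.parametrize("maker", [
    fx.make_binding_model,
    lambda: fx.make_cascade_model(3),
    fx.make_bistable_model,
])
def test_native_round_trip_identity(maker, tmp_path):
    m = maker()
    sx.save_model(m, tmp_path / "m.model")
    m2 = sx.load_model(tmp_path / "m.model")
    assert m.structurally_equal(m2)


@pytest.mark.parametrize("maker", [
    fx.make_binding_model,
    lambda: fx.make_cascade_model(2),
    fx.make_bistable_model,
])
def test_sbml_round_trip(maker, tmp_path):
    """native -> SBML -> native preserves structure, rate constants to 12
    significant digits, and buffering flags."""
    m = maker()
    sx.export_sbml(m, tmp_path / "m.xml")
    m2 = sx.load_model(tmp_path / "m.xml")
    assert set(m2.pools) == set(m.pools)
    assert set(m2.reactions) == set(m.reactions)
    assert set(m2.enzymes) == set(m.enzymes)
    assert m2.groups == m.groups
    for p in m.pools:
        assert m2.pools[p].buffered == m.pools[p].buffered
        assert math.isclose(m2.pools[p].concInit, m.pools[p].concInit,
                            rel_tol=1e-12, abs_tol=1e-300) \
            or m.pools[p].concInit == m2.pools[p].concInit == 0
    for r in m.reactions:
        assert math.isclose(m2.reactions[r].Kf, m.reactions[r].Kf,
                            rel_tol=1e-12)
    for e in m.enzymes:
        assert math.isclose(m2.enzymes[e].Km, m.enzymes[e].Km, rel_tol=1e-12)
        assert math.isclose(m2.enzymes[e].kcat, m.enzymes[e].kcat,
                            rel_tol=1e-12)


def test_sbml_document_structure(binding_model, tmp_path):
    """Exported document is well-formed SBML L3 with the groups package,
    boundary-condition flags for buffered pools, and stimulus events."""
    binding_model.pools["/kinetics/binding/L"].buffered = True
    stim = [(10.0, "/kinetics/binding/L", "conc", 0.5),
            (20.0, "/kinetics/binding/L", "conc", 0.0)]
    sx.export_sbml(binding_model, tmp_path / "b.xml", stimuli=stim)
    root = etree.parse(str(tmp_path / "b.xml")).getroot()
    assert etree.QName(root).namespace == SBML_NS
    assert root.get("level") == "3"
    species = root.findall(f".//{{{SBML_NS}}}species")
    assert len(species) == 3
    for s in species:
        # required SBML L3 species attributes all present
        for attr in ("id", "compartment", "boundaryCondition", "constant",
                     "hasOnlySubstanceUnits"):
            assert s.get(attr) is not None
    flags = {s.get("name"): s.get("boundaryCondition") for s in species}
    assert flags["/kinetics/binding/L"] == "true"
    assert flags["/kinetics/binding/R"] == "false"
    assert len(root.findall(f".//{{{SBML_NS}}}event")) == 2
    assert root.findall(f".//{{{GROUPS_NS}}}group")


def test_sbml_unrecognized_rate_law_names_reaction(tmp_path):
    doc = f"""<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="{SBML_NS}" level="3" version="1">
 <model id="m">
  <listOfCompartments>
   <compartment id="c" size="1e-15" spatialDimensions="3" constant="true"/>
  </listOfCompartments>
  <listOfSpecies>
   <species id="A" compartment="c" initialConcentration="1"
            boundaryCondition="false" constant="false"
            hasOnlySubstanceUnits="false"/>
   <species id="B" compartment="c" initialConcentration="0"
            boundaryCondition="false" constant="false"
            hasOnlySubstanceUnits="false"/>
  </listOfSpecies>
  <listOfReactions>
   <reaction id="weird_hill" reversible="false" fast="false">
    <listOfReactants><speciesReference species="A" stoichiometry="1"
        constant="true"/></listOfReactants>
    <listOfProducts><speciesReference species="B" stoichiometry="1"
        constant="true"/></listOfProducts>
    <kineticLaw>
     <listOfLocalParameters>
      <localParameter id="Vmax" value="2"/>
      <localParameter id="n" value="4"/>
     </listOfLocalParameters>
    </kineticLaw>
   </reaction>
  </listOfReactions>
 </model>
</sbml>
"""
    (tmp_path / "weird.xml").write_text(doc)
    with pytest.raises(sx.ModelError, match="weird_hill"):
        sx.load_model(tmp_path / "weird.xml")


class TestResolvePaths:
    def test_group_selector_returns_subtree(self, cascade_model):
        hits = sx.resolve_paths(cascade_model, ["/kinetics/input_EGF"])
        assert hits == {"/kinetics/input_EGF/EGF",
                        "/kinetics/input_EGF/EGF_act"}

    def test_leaf_selector_returns_leaf(self, binding_model):
        assert sx.resolve_paths(binding_model, ["/kinetics/binding/R"]) \
            == {"/kinetics/binding/R"}

    def test_root_returns_everything(self, cascade_model):
        assert sx.resolve_paths(cascade_model, ["/"]) \
            == cascade_model.entity_paths()

    def test_empty_selector_list(self, binding_model):
        assert sx.resolve_paths(binding_model, []) == set()

    def test_unknown_selector_raises_naming_it(self, binding_model):
        with pytest.raises(sx.PathError, match="/cell/NoSuchPathway"):
            sx.resolve_paths(binding_model, ["/cell/NoSuchPathway"])

    def test_monotone_in_selectors(self, cascade_model):
        sels = ["/kinetics/cascade/tier1", "/kinetics/input_Ca",
                "/kinetics/cascade/tier2/X2"]
        acc = []
        prev = set()
        for s in sels:
            acc.append(s)
            cur = sx.resolve_paths(cascade_model, acc)
            assert prev <= cur
            prev = cur


class TestValidateModel:
    def test_valid_fixtures_clean(self, binding_model, cascade_model,
                                  bistable_model):
        for m in (binding_model, cascade_model, bistable_model):
            assert sx.validate_model(m) == []

    @pytest.mark.parametrize("fault", [
        lambda m: m.pools.pop("/kinetics/binding/L"),
        lambda m: setattr(m.pools["/kinetics/binding/R"], "concInit", -1.0),
        lambda m: setattr(m.reactions["/kinetics/binding/bind"], "Kf", -2.0),
        lambda m: setattr(m.reactions["/kinetics/binding/bind"],
                          "substrates", []),
        lambda m: setattr(m.pools["/kinetics/binding/R"], "compartment",
                          "nowhere"),
    ])
    def test_single_injected_fault_detected(self, binding_model, fault):
        fault(binding_model)
        assert len(sx.validate_model(binding_model)) >= 1

    def test_enzyme_faults_detected(self, bistable_model):
        bistable_model.enzymes["/kinetics/switch/actA"].Km = 0.0
        diags = sx.validate_model(bistable_model)
        assert any("Km" in d for d in diags)
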