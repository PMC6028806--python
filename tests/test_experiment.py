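"""Experiment document parsing, writing, unit handling, and validation."""

import math

import pytest
from hypothesis import given, settings, strategies as st

import simexpt as sx
from simexpt import fixtures as fx
from simexpt.experiment import (Combination, ExperimentDoc,
                                ExperimentFormatError, ModelMap,
                                ReadoutEntry, StimulusEntry)
from simexpt.subset import SubsetSpec
from simexpt.units import SUPPORTED_UNITS, from_canonical, to_canonical

TS_FIXTURE = """\
# two-pulse stimulus, six readout rows
Experiment metadata
exptType\tTimeSeries
transcriber\ttester
exptSource\tinHouse

Experiment context
species\trat
temperature\t30
pH\t7.2

Stimuli
stimulus\tCa\tconc\tuM
time\tvalue
10\t100
20\t0

Readouts
readout\tMAPK_act\tconc\tuM\tabsolute
time\tvalue\tstderr
5\t0.1\t0.01
15\t0.5\t0.02
25\t0.9\t
35\t0.8\t0.05
45\t0.6\t
55\t0.4\t0.04

Model mapping
refModel\tcascade.model
solver\tode_stiff
weight\t1.0
include\t/kinetics
map\tCa\t/kinetics/input_Ca/Ca
map\tMAPK_act\t/kinetics/cascade/tier3/X3_act
"""


def _write(tmp_path, text, name="e.tsv"):
    p = tmp_path / name
    p.write_text(text)
    return p


def test_parse_time_series_fixture(tmp_path):
    doc = sx.parse_experiment_tsv(_write(tmp_path, TS_FIXTURE))
    assert doc.exptType == "TimeSeries"
    assert len(doc.stimuli) == 1
    assert len(doc.stimuli[0].points) == 2
    assert sum(len(r.points) for r in doc.readouts) == 6
    # 100 uM -> 0.1 mM canonical
    assert math.isclose(doc.stimuli[0].points[0][1], 0.1)
    # blank stderr parsed as None
    assert doc.readouts[0].points[2][2] is None
    assert doc.context.temperature == 30


def test_missing_block_cites_name(tmp_path):
    text = TS_FIXTURE.replace("Readouts", "NotReadouts")
    with pytest.raises(ExperimentFormatError, match="Readouts"):
        sx.parse_experiment_tsv(_write(tmp_path, text))


def test_non_increasing_times_rejected_with_line(tmp_path):
    text = TS_FIXTURE.replace("20\t0", "10\t0")
    with pytest.raises(ExperimentFormatError, match=r":\d+.*increasing"):
        sx.parse_experiment_tsv(_write(tmp_path, text))


def test_unknown_unit_rejected(tmp_path):
    text = TS_FIXTURE.replace("stimulus\tCa\tconc\tuM",
                              "stimulus\tCa\tconc\tfurlong")
    with pytest.raises(ExperimentFormatError, match="furlong"):
        sx.parse_experiment_tsv(_write(tmp_path, text))


def test_bad_scoring_formula_rejected(tmp_path):
    text = TS_FIXTURE.replace("weight\t1.0",
                              "weight\t1.0\nscoringFormula\tmean((expt")
    with pytest.raises(ExperimentFormatError, match="formula"):
        sx.parse_experiment_tsv(_write(tmp_path, text))


@pytest.mark.parametrize("cls", ["TimeSeries", "DoseResponse",
                                 "MultiStimulus"])
def test_round_trip_fixture_classes(cls, tmp_path):
    doc = fx.make_experiment_fixture(cls)
    sx.write_experiment_tsv(doc, tmp_path / "rt.tsv")
    doc2 = sx.parse_experiment_tsv(tmp_path / "rt.tsv")
    assert doc.equivalent(doc2)
    # JSON mirror round-trips the same document
    sx.save_experiment(doc, tmp_path / "rt.json")
    doc3 = sx.load_experiment(tmp_path / "rt.json")
    assert doc.equivalent(doc3)


def test_written_file_keeps_stderr_and_blank_context(tmp_path):
    doc = fx.make_experiment_fixture("TimeSeries", noise_sd=0.01, seed=4)
    sx.write_experiment_tsv(doc, tmp_path / "n.tsv")
    text = (tmp_path / "n.tsv").read_text()
    assert "stderr" in text
    # optional context fields appear as blank rows, not omitted
    assert "temperature\t" in text and "pH\t" in text


# ---------------------------------------------------------------------------
# randomized round-trip property
# ---------------------------------------------------------------------------

_conc_units = st.sampled_from(["M", "mM", "uM", "nM", "pM"])
_values = st.floats(min_value=1e-6, max_value=1e3, allow_nan=False,
                    allow_infinity=False)
_names = st.text(alphabet="abcdefgXYZ_123", min_size=1, max_size=8)


@st.composite
def time_series_docs(draw):
    n_stim = draw(st.integers(1, 2))
    stimuli = []
    for k in range(n_stim):
        times = sorted(draw(st.lists(
            st.floats(0, 1e3, allow_nan=False), min_size=1, max_size=4,
            unique=True)))
        unit = draw(_conc_units)
        stimuli.append(StimulusEntry(f"stim{k}", "conc", unit,
                                     [(t, draw(_values)) for t in times]))
    coords = sorted(draw(st.lists(
        st.floats(0.001, 1e3, allow_nan=False), min_size=1, max_size=6,
        unique=True)))
    with_sem = draw(st.booleans())
    readouts = [ReadoutEntry(
        draw(_names), "conc", draw(_conc_units),
        draw(st.sampled_from(["absolute", "foldChange", "percentOfMax"])),
        [(c, draw(_values), draw(_values) if with_sem else None)
         for c in coords])]
    mm = ModelMap(refModel="m.model",
                  subset=SubsetSpec(includePaths=["/kinetics"],
                                    deletePaths=draw(st.lists(
                                        st.just("/kinetics/x"), max_size=1)),
                                    entityMap={"a": ["/kinetics/a"]}),
                  weight=draw(st.floats(0, 10, allow_nan=False)),
                  settleBeforeStart=draw(st.booleans()))
    return ExperimentDoc(exptType="TimeSeries", stimuli=stimuli,
                         readouts=readouts, modelMap=mm)


@settings(max_examples=120, deadline=None)
@given(doc=time_series_docs(), as_json=st.booleans())
def test_round_trip_random_documents(doc, as_json, tmp_path_factory):
    tmp = tmp_path_factory.mktemp("rt")
    dest = tmp / ("d.json" if as_json else "d.tsv")
    sx.save_experiment(doc, dest)
    assert doc.equivalent(sx.load_experiment(dest))


@settings(max_examples=100, deadline=None)
@given(value=st.floats(min_value=1e-12, max_value=1e12, allow_nan=False),
       unit=st.sampled_from(sorted(SUPPORTED_UNITS)))
def test_unit_conversion_invertible(value, unit):
    back = from_canonical(to_canonical(value, unit), unit)
    assert math.isclose(back, value, rel_tol=1e-12)


def test_100_uM_is_0p1_mM():
    assert math.isclose(to_canonical(100.0, "uM"), 0.1)
    assert to_canonical(0.1, "mM") == 0.1


# ---------------------------------------------------------------------------
# cross-validation against a model
# ---------------------------------------------------------------------------

class TestValidateExperiment:
    def test_fixture_validates_cleanly(self, binding_model):
        doc = fx.make_experiment_fixture("TimeSeries")
        assert sx.validate_experiment(doc, binding_model) == []

    def test_all_bundled_fixtures_validate(self, translation, hh_fixture):
        for model, doc in (translation, hh_fixture):
            assert sx.validate_experiment(doc, model) == []

    def test_readout_mapped_to_absent_pool(self, binding_model):
        doc = fx.make_experiment_fixture("TimeSeries")
        doc.modelMap.subset.entityMap["complex"] = ["/kinetics/binding/zzz"]
        diags = sx.validate_experiment(doc, binding_model)
        assert len(diags) == 1 and "complex" in diags[0]

    def test_duplicate_dose_flagged(self):
        doc = fx.make_experiment_fixture("DoseResponse")
        pts = doc.stimuli[0].points
        pts[1] = pts[0]
        doc.readouts[0].points[1] = (pts[0][0],) + doc.readouts[0].points[1][1:]
        diags = sx.validate_experiment(doc)
        assert any("duplicate" in d or "increasing" in d for d in diags)

    def test_missing_citation_flagged(self):
        doc = fx.make_experiment_fixture("TimeSeries")
        doc.metadata.exptSource = "paperReference"
        doc.metadata.citationId = ""
        assert any("citationId" in d for d in sx.validate_experiment(doc))
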