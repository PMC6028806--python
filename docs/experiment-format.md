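# Experiment file format (tsv dialect v1)

UTF-8, hard-tab field separator, `#` starts a comment line, blank lines are
ignored. The file is divided into five mandatory blocks; a block starts at a
line whose *first column* is one of the reserved headers:

```
Experiment metadata
Experiment context
Stimuli
Readouts
Model mapping
```

All numeric values are range-checked on parse and converted to the
canonical internal frame (concentration mM, time s, voltage mV, current
density uA/cm^2). A `.json` file with the same structure (one object per
block, arrays of points) is accepted and emitted interchangeably; the tsv
schema below is the reference.

## Experiment metadata

`key <TAB> value` rows. Keys: `exptType` (one of `TimeSeries`,
`DoseResponse`, `MultiStimulus`), `transcriber`, `organization`,
`exptSource` (`paperReference` | `inHouse` | `database`), `citationId`
(required when exptSource is `paperReference`), `authors`, `journal`.

## Experiment context

`key <TAB> value` rows: `species`, `cellType`, `preparation`,
`temperature` (degrees C, 0–60), `pH` (0–14), `notes`. Optional numeric
fields may be left blank (the row is still written).

## Stimuli

For **TimeSeries** (chemical or electrical), one or more entries:

```
stimulus <TAB> entityName <TAB> field <TAB> unit
time <TAB> value
0.0  <TAB> 0.5
300.0 <TAB> 0.0
```

`field` is `conc`, `concInit`, `buffered` (value 0/1, unit `none`) or
`current`; times are seconds, strictly increasing; concentration values
must be >= 0.

For **DoseResponse**, exactly one entry whose table is a single strictly
increasing `dose` column (the dose is the clamped value):

```
stimulus <TAB> ligand <TAB> conc <TAB> uM
dose
10
100
```

For **MultiStimulus**, named combinations of clamped settings:

```
combination <TAB> control
entity <TAB> value <TAB> unit
combination <TAB> EGF
entity <TAB> value <TAB> unit
EGF <TAB> 0.3 <TAB> mM
```

## Readouts

One or more entries:

```
readout <TAB> entityName <TAB> field <TAB> unit <TAB> normalization
settle <TAB> 300.0
time <TAB> value <TAB> stderr
5.0 <TAB> 0.21 <TAB> 0.02
```

`field` is `conc` or `Vm`; `normalization` is `absolute`, `foldChange`
(both series divided by their first point at scoring time) or
`percentOfMax` (divided by their maxima, times 100). The coordinate header
is `time` (s), `dose` (readout coordinates must equal the stimulus dose
list) or `label` (MultiStimulus; labels must name combinations). `stderr`
may be blank. The optional `settle` row (seconds) states the relaxation
time for bar/dose readouts; it is required for MultiStimulus.

## Model mapping

The only model-specific block:

```
refModel <TAB> composite.model
solver <TAB> ode_stiff          # ode_stiff | ode_nonstiff | hh
weight <TAB> 1.0                # battery weight, >= 0
scoringFormula <TAB> sqrt(mean(((expt - sim) / range) ** 2))
settleBeforeStart <TAB> 1       # equilibrate the sub-model before t=0
include <TAB> /kinetics/translation
delete <TAB> /kinetics/translation/4E-BP <TAB> /kinetics/translation/block
override <TAB> /kinetics/translation/eIF4E-mRNA <TAB> buffered <TAB> 1
map <TAB> 40S <TAB> /kinetics/translation/40S
```

`include` selectors name groups (whole subtree) or single entities;
`delete` paths remove entities or whole groups from the selection;
`override` rows are (path, field, value) with field one of `concInit`,
`buffered`, `Kf`, `Kb`, `Km`, `kcat`, `volume`; `map` rows translate one
experiment-domain name to one or more model pool paths (multi-target maps
are summed at readout time, e.g. isoforms pooled in the experiment). An
empty `scoringFormula` selects the package default. The scoring grammar
allows numbers, `+ - * / **`, comparisons, `sum`, `mean`, `sqrt`, `abs`,
`min`, `max`, and the variables `expt`, `sim`, `sem`, `range`.
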