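# bnetscore

Net ion-channel block (Bnet) scoring for torsades-de-pointes (TdP) risk
screening, plus the ranking-performance statistics used to judge such
metrics.

A drug's score is the Hill-equation percent block of the repolarizing
hERG/IKr channel minus the summed percent blocks of the depolarizing
channels (INaL, ICaL, INa), evaluated at a configurable multiple of the
unbound Cmax (default 5×). A dynamic variant replaces the static hERG term
with an Emax-scaled block (dynamic IC50 + maximal inhibition) at 1× Cmax.
Higher scores mean higher predicted TdP risk.

## Layout

| module | contents |
| --- | --- |
| `bnetscore.panel_io` | drug/channel data model, long-format CSV read/write, packaged hERG literature fixture (16 validation drugs) |
| `bnetscore.block_model` | static Hill %block and dynamic-hERG %block |
| `bnetscore.bnet_metric` | per-drug and per-panel net-block scores, static and dynamic |
| `bnetscore.evaluation` | midrank ROC AUC on both risk dichotomies, ML logistic regression with likelihood-ratio χ², Pearson r², Welch/Student t |
| `bnetscore.synthetic_panel` | seeded generator of panels with known risk structure |
| `bnetscore.cli` | `score` / `evaluate` / `simulate` subcommands |

## CLI

```sh
# generate a 28-drug synthetic panel (writes panel.csv + panel.csv.config.json)
bnetscore simulate --seed 0 --output panel.csv

# score it at 5x Cmax; "both" also emits dynamic-variant rows where
# dynamic-hERG parameters exist
bnetscore score --input panel.csv --output scored.csv --multiple 5 --variant both

# evaluate metric columns against the risk labels
bnetscore evaluate --input scored.csv --metrics bnet \
    --reference-metric external_metric --report report.json --report-csv report.csv
```

`python -m bnetscore …` works identically. Exit codes: 0 success,
2 validation/schema error, 3 I/O error, 4 degenerate-statistics error.

### Panel CSV schema

Long format, one row per drug–channel fit, header required:

```
drug, channel (IKr|INaL|ICaL|INa), ic50_uM, ic50_censored (true|false),
hill (blank = absent), cmax_free_uM, risk (low|intermediate|high),
dataset (training|validation), dyn_ic50_uM, dyn_max_inhib, dyn_hill,
external_metric
```

All concentrations are µM (no unit auto-detection). Drug-level fields must
agree across a drug's rows. A censored IC50 ("> X") is stored as
`ic50_uM = X` with `ic50_censored = true` and propagates a conservativeness
flag into the scored output. A blank Hill is treated as absent and defaults
to 1.0 at evaluation time with a `hill_defaulted` flag — never silently.

## Library example

```python
from bnetscore import DrugRecord, HillFit, Channel, bnet

drug = DrugRecord(
    name="example",
    cmax_free=0.1,
    fits={
        Channel.IKR: HillFit(ic50=0.5, hill=1.0),
        Channel.ICAL: HillFit(ic50=5.0, hill=1.1),
    },
)
result = bnet(drug, multiple=5.0)
print(result.bnet, result.channel_blocks, result.missing_channels)
```

`bnetscore.table1_fixture()` returns the packaged hERG IC50/Hill literature
values for the 16 standard validation drugs (IKr fits only; Cmax must be
supplied before they are scorable).

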