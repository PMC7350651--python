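# isotrace

A scriptable toolkit for single-tracer GC-MS stable isotope tracing data:

- **Natural isotope abundance (NIA) correction** of baseline-corrected
  isotopologue counts via a per-fragment correction matrix built from
  elemental formulas and IUPAC/CIAAW terrestrial abundances, solved by
  least squares with non-negativity clamping.
- **Labeling analytics**: mass isotopomer distributions (MIDs), mole
  percent enrichment, total / normalized / quantitative abundances, group
  means ± SD, kinetic series, and cross-metabolite comparisons.
- **Figures**: twelve bar/stacked/line graph types, carbon-circle labeling
  diagrams, and complete pathway figures overlaid on Escher metabolic-map
  JSON via BiGG identifiers, exported as deterministic SVG or PNG.

## Input formats

Measurements are long-format CSV with header
`metabolite,bigg_id,formula,n_labelable,isotopologue,<sample1>,...`, one row
per fragment-channel (`M0`, `M1`, ... contiguous from M0). `formula` is the
total ion formula (derivatization atoms included) in plain Hill notation;
`n_labelable` is the number of tracer-element atoms that can carry label.
Uncorrected files hold baseline-corrected raw counts; corrected files hold
pre-corrected values and are refused by the correction step. Maps use the
standard Escher two-element `[header, body]` JSON schema; data attach to
metabolite nodes by exact BiGG ID (`--ignore-compartment` strips the
compartment tag). Group definitions are JSON:
`{"groups": [{"name": ..., "samples": [...], "time": null, "cell_count": null}]}`.

The abundance table ships as an auditable JSON document at
`src/isotrace/data/isotope_abundances.json`; workspaces record its version.

## CLI

```bash
# generate the synthetic two-condition demo dataset
isotrace simulate --out demo --seed 42

# NIA-correct and save a workspace
isotrace correct --input demo/uncorrected.csv --tracer 13C \
    --groups demo/groups.json --out ws.json

# normalize abundances (internal standard -> cell counts -> reference group)
isotrace analyze --workspace ws.json --internal-standard nor260 \
    --cell-counts '{"Normoxia": 638333, "Hypoxia": 668750}' \
    --reference-group Normoxia --out ws.json

# one graph, or the whole pathway figure
isotrace plot --workspace ws.json --graph mid --fragment cit459 --out cit.svg
isotrace overlay --workspace ws.json --map demo/map.json --quantity mid \
    --format svg --out pathway.svg
```

Graph types: `mid`, `stacked_mid`, `single_isotopologue_label`,
`kinetic_single_label`, `abundance`, `stacked_abundance`,
`single_isotopologue_abundance`, `kinetic_single_abundance`,
`quantitative_abundance`, `kinetic_total_abundance`, `enrichment`,
`kinetic_enrichment`. Kinetic types need group time points, quantitative
needs standards, enrichment needs the labelable-atom count.

## Library

```python
from isotrace import io, correction, analytics, viz, fixtures

data = io.read_uncorrected_csv("demo/uncorrected.csv")
data.set_groups(groups)
correction.correct_dataset(data, correction.TracerSpec.parse("13C"))
mids = analytics.mid_frame(data, "cit459")          # channels x samples
analytics.normalize_abundances(data, analytics.NormalizationSpec(
    internal_standard="nor260", reference_group="Normoxia"))
fig = viz.render_graph(data, viz.GraphSpec("enrichment", "cit459"))
viz.export(fig, "svg", "enrichment.svg")
```

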