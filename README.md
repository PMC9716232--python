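# fhces

Functional characterization and combined efficacy scoring of complement
factor H (FH) variants.

## The problem

FH is the master down-regulator of the complement alternative pathway (AP):
it competes with factor B for C3b, accelerates decay of the C3 convertase
C3bBb, and is the cofactor for factor I-mediated C3b cleavage. Dozens of
missense variants in *CFH* are associated with age-related macular
degeneration (AMD), but for most of them the functional consequence is
unknown — which matters now that recombinant FH supplementation is a
candidate therapy and patient selection hinges on whether a carried variant
actually impairs AP regulation.

`fhces` implements, as a tested and reusable pipeline, the analysis used to
characterize a panel of 21 prevalent AMD-linked FH variants against a
non-risk control: per-assay readout extraction, normalization into
variant/control ratios, and aggregation into a single **Combined Efficacy
Score (CES)**. Because the raw per-variant measurements of such panels are
rarely deposited, the package includes a first-class synthetic-data module
that generates assay datasets with the statistical structure the analysis
assumes, so every stage is testable end to end without any download.

## The score

Each variant *v* is measured against the control *c* in five assays plus a
protein-yield comparison, giving six components:

```
CES = 100/6 × ( binding_vc + CA_cv + DAA_vc + AP_cv + yield_vc + hemolysis )
```

* `binding_vc` — SPR equilibrium C3b-binding response ratio RU_v/RU_c at 220 s;
* `DAA_vc` — ratio of FH-attributable C3bBb decay (beyond inherent decay) at
  175 s;
* `CA_cv`, `AP_cv` — control/variant EC50 ratios from 4PL fits of the
  factor I-cofactor assay and the sC5b-9 AP immunoassay (EC50 by
  interpolation at 50% inhibition), so that values < 1 always mean impaired
  function;
* `yield_vc` — secretion yield ratio (mg/L, variant over control);
* `hemolysis` — a ternary sheep-erythrocyte protection score: 1 (negligible
  impact), 0.5 (marginal) or 0 (severe), used instead of an EC50 because the
  hemolysis assay is too variable between days for quantitative ratios.

The control scores exactly 100. Components are summed unweighted and
uncapped. Variants with CES > 84 are classified *minimal impact*, < 75
*defective*, and in between *marginal*; ranking is by ascending CES, and a
yield-omitted CES (divisor 5) supports a sensitivity analysis of the
single-run yield component.

## Worked example

Score the default synthetic 21-variant panel under realistic noise
(`examples/04_score_and_rank.py`):

```python
from fhces import (PanelDesign, PipelineConfig, analyze_panel,
                   default_truths, simulate_variant_panel)

design = PanelDesign()
panel = simulate_variant_panel(default_truths(design), design, seed=42)
res = analyze_panel(panel, PipelineConfig())
print(res.results_table[["variant_name", "ces", "category", "rank"]].head(4))
```

prints

```
variant_name   ces   category  rank
   Arg175Pro  17.9  defective     1
    Arg53Cys  52.0  defective     2
   Arg175Gln  55.4  defective     3
   Arg567Gly  58.4  defective     4
```

Arg175Pro scores lowest: its binding, cofactor, DAA and AP ratios sit at the
panel minima (0.68, 0.07, 0.08, 0.01), its yield ratio is 0.26 and its
hemolysis protection is severely compromised (score 0). The same run reports
`yield-omission bottom-8 change: out ['Arg1210Cys'], in ['Arg303Gln']` — the
well-secreted marginal variant Arg303Gln replaces the poorly secreted but
otherwise more active Arg1210Cys in the defective eight when yield is
dropped. On a zero-noise panel the recovered CES values equal the
generator's ground truth to better than 1e-6 and reproduce a 10 / 3 / 8
minimal–marginal–defective split.

The other example scripts cover panel simulation, SPR readout extraction,
4PL fitting with the ternary hemolysis call, and confirmatory K_D
estimation by global 1:1 Langmuir fitting. A thin CLI chains the stages on
directories of TSV files:

```
fhces all --seed 42 --out scratch/run      # simulate → score → report
fhces score panel_dir --out results_dir    # analyze an existing panel
```

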