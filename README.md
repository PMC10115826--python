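# switchscreen

Quantitative analysis of **Cas-responsive translational switch panels**:
flow-cytometry-style normalization, orthogonality screening of switch ×
trigger fold-change matrices, and truth-table scoring of translational
logic circuits — all exercised end to end on synthetic per-cell data with
planted ground truth.

## The problem

CRISPR-Cas proteins can be repurposed as sequence-specific translational
regulators: a switch mRNA carries a Cas-binding guide-RNA motif in its
5′-UTR, and the cognate Cas protein (the *trigger*) represses its
translation (OFF switch) or, through a switch-inverting module, activates
it (ON switch). Building multi-input circuits from such parts raises three
quantitative questions this package answers:

1. **How strongly does each trigger act on each switch?** Per-cell reporter
   fluorescence is normalized to a co-transfected reference:

   - `NI = 1000 × median(reporter/reference)` over reference-positive cells,
   - `RI = NI(trigger+) / NI(trigger−)`,
   - `relative reporter expression = RI / RI(No-gRNA control)`,
   - `FC = RI` (ON switch) or `1/RI` (OFF switch).

2. **Which triggers are mutually orthogonal?** The crosstalk between two
   triggers *i*, *j* is the cosine distance of their 1-centered fold-change
   profiles,

   `d(i,j) = 1 − (FC_i − 1)·(FC_j − 1) / (‖FC_i − 1‖ ‖FC_j − 1‖)`,

   a combination `C` scores `min_{i,j∈C} d(i,j)` (max–min diversity), and
   combinations scoring `< 0.7` are flagged as crosstalking. The best
   combination per set size is found exactly, either by exhaustive
   enumeration or by binary search over pair distances with a max-clique
   feasibility test.

3. **Does a circuit compute its truth table?** A 2-input gate measured in
   the states `[0,0],[1,0],[0,1],[1,1]` is scored by the **net fold-change**
   (mean ON-state NI / mean OFF-state NI) and the **vector proximity
   angle** θ between the observed NI vector and the ideal 0/1 truth-table
   vector (0° best, 90° worst; θ ≤ 20° counts as functional).

Because raw cytometry from such screens is rarely deposited, the package
ships a first-class synthetic-data generator: log-normal reference and
reporter intensities, a transfection-positive subpopulation, debris and
edge events, and multiplicative trigger effects planted via a ground-truth
matrix — so every downstream stage is testable against known truth.

## Worked example

```python
import math
from switchscreen import (
    CellPopulationModel, FoldChangeMatrix, best_combination_maxmin,
)
from switchscreen.pipeline import summarize_screen
from switchscreen.simulate import (
    build_planted_screen_panel, simulate_orthogonality_screen,
)

# 16 OFF switches (on-target effect 0.1); the last three triggers each
# cross-react with two partner switches at 0.5
panel, clean, crosstalk = build_planted_screen_panel(
    n_triggers=16, n_promiscuous=3, on_target_effect=0.1, crosstalk_effect=0.5,
)
pop = CellPopulationModel(reporter_log10_noise_sd=math.log10(1.05))
dataset = simulate_orthogonality_screen(panel, pop, n_events=5000,
                                        replicates=3, seed=101)
fc = summarize_screen(dataset).fc_matrix       # trigger x switch matrix
best = best_combination_maxmin(FoldChangeMatrix.from_frame(fc), 13,
                               profile_mode="full")
print(best.distance, best.combination == clean)
```

prints

```
0.9965866210438046 True
```

i.e. the best 13-trigger combination keeps a minimum pairwise cosine
distance of ≈ 1 (ideal orthogonality) and is exactly the planted clean
set. The numbered drivers under `analysis/` run this and the other
analyses end to end and write their tables under `results/`:

```
analysis/01_screen_recovery.py      # simulate + gate + normalize; recovery vs planted truth
analysis/02_orthogonality_sweep.py  # pair distances + best combination per N = 3..13
analysis/03_and_gate_panel.py       # 60 AND circuits, 21 planted functional -> 21 pass
analysis/04_multistage_circuits.py  # repression cascade + half-subtractor (XOR / NIMPLY)
```

On the default seeds, 01 reports a maximum relative error of 0.004
against the planted effects; 03 scores 60 circuits of which exactly the
21 planted low-leak gates pass at θ ≤ 20°; 04 measures cascade NIs of
9.99, 0.99, 9.95, 0.99, 10.07 (output inverting with every added stage)
and half-subtractor angles D ≈ 1.2°, Bo ≈ 2.1°.

A `switchscreen` console command exposes the same stages
(`simulate`, `gate`, `summarize`, `orthogonality`, `gates`, `report`);
see `switchscreen --help`.

## Layout

```
src/switchscreen/   simulate, gating, metrics, orthogonality, gates, io, pipeline, cli
analysis/           numbered narrative drivers (write to results/)
tests/              pytest suite (unit, property-based, end-to-end)
docs/methods.md     model assumptions, parameter choices, limitations
```
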