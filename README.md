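# slgraph

Electrode-level functional-connectivity analysis of multichannel EEG for
within-subject two-condition designs (e.g. normal sleep vs. total sleep
deprivation), built around four pieces:

1. **Synchronization likelihood (SL)** — a generalized-synchronization
   measure between channel pairs.  Signals are time-delay embedded; for
   each reference time a critical distance is calibrated so a fraction
   p_ref of candidate states counts as recurrent, and SL is the conditional
   likelihood that one signal is recurrent given the other is.  SL = p_ref
   for independent signals, 1 for identical ones.
2. **Fixed-degree graphs and node metrics** — each SL matrix is thresholded
   to keep the floor(n·K/2) strongest connections (mean degree K); per node
   the clustering coefficient C (fraction of neighbour pairs that are
   connected) and path length L (mean shortest-path distance, ∞ when a node
   is unreachable) are computed and harmonically aggregated over epochs and
   sessions.
3. **Cluster-based permutation statistics** — node-wise paired t-tests,
   spatial clusters of significant nodes with ≥ 2 significant neighbours,
   and a Monte-Carlo null from subject-level condition swaps scored by the
   maximal summed cluster t (per sign tail, alpha 0.025 each).
4. **Band-power mediation (Sobel) analysis** — linear mixed models test
   whether band power within a significant cluster mediates the condition
   effect on the graph metric, with Z = a·b / √(b²·s_a² + a²·s_b²); this
   probes whether apparent connectivity changes could be volume-conduction
   side effects of power changes.

A synthetic-study generator produces full factorial designs (subjects ×
conditions × sessions × epochs) of band-structured multichannel signals
with spatially decaying inter-channel coupling and plantable frontal
coupling/power effects, so every stage can be validated against ground
truth.  Intended users: electrophysiologists and methods researchers who
want a tested, scriptable reference implementation of this analysis chain.

## Worked example

Simulate a reduced study with a planted frontal alpha decoupling and run
the full pipeline:

```python
from slgraph import RunConfig, run_all
from slgraph.synthdata import SynthConfig, generate_study

synth = SynthConfig(
    n_subjects=12, n_sessions=2, n_epochs=4, epoch_seconds=4.0, fs=128.0,
    n_channels=25, bands={"alpha": (8.0, 13.0)},
    coupling_delta={"alpha": -0.8}, power_delta={}, seed=1,
)
epochs, layout, truth = generate_study(synth)
cfg = RunConfig(bands={"alpha": (8.0, 13.0)}, K_values=[7],
                n_permutations=1000, seed=1)
report = run_all(epochs, layout, cfg, run_mediation=False)
for c in report["bands"]["alpha"]["K"]["7"]["C"]["clusters"]:
    print(c["nodes"], round(c["summed_t"], 1), c["p_value"], c["significant"])
print("frontal:", truth.frontal_nodes)
```

prints

```
['E02', 'E03', 'E04', 'E05', 'E06', 'E07', 'E08', 'E09', 'E10'] -154.7 0.000999000999000999 True
['E18', 'E19', 'E23'] 8.3 0.023976023976023976 True
frontal: ['E01', 'E02', 'E03', 'E04', 'E05', 'E06', 'E07', 'E08', 'E09', 'E10']
```

— the clustering coefficient dropped significantly (negative summed t,
Monte-Carlo p ≈ 0.001) in nine of the ten frontal electrodes where the
alpha coupling was planted to fall under the deprivation condition.  The
small positive posterior cluster is a real consequence of the fixed edge
budget: connections freed by the frontal decoupling redistribute to the
back of the grid and raise local clustering there.

The same pipeline is scriptable from the shell:

```bash
slgraph simulate --config synth.yaml --out study/
slgraph run-all --config run.yaml --epochs study/epochs.h5 \
        --layout study/layout.tsv --out results/
```

with stage-wise subcommands (`filter`, `connectivity`, `graphs`, `stats`,
`mediate`) that chain to the identical result.

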