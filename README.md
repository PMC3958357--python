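# gimmesub

**Data-driven subgrouping of individuals from directed resting-state
functional connectivity.**

Clinical neuroimaging samples are heterogeneous: individuals who share a
diagnostic label can carry quite different patterns of brain connectivity,
and averaging over them washes out the very effects of interest.
`gimmesub` organizes a sample into subgroups using nothing but each
individual's brain dynamics.  It is written for researchers who have
per-individual ROI time series (e.g. averaged resting-state BOLD signals)
and want, with no prior grouping information:

1. a reliable **directed connectivity map per individual**,
2. **data-driven subgroups** of individuals with similar maps,
3. evidence that those subgroups are **robust**, and
4. statements about **which connections differ** between subgroups.

## The method

**Connectivity maps — uSEM + GIMME.**  Each individual's p-variate series
follows a unified SEM (a structural VAR(1)):

    y_t = A y_t + Φ y_{t−1} + ζ_t,   ζ_t ~ N(0, Ψ),

with contemporaneous directed paths A and lagged paths Φ (autoregressive
effects on the diagonal), estimated by maximum likelihood.  Which paths
exist is decided by the GIMME search: paths whose modification indices are
significant (Bonferroni-corrected) for a majority (γ = 0.75) of individuals
form the *group map*; each individual then receives additional
individual-level paths until their model fits excellently.

**Subgrouping — modularity with a data-driven threshold.**  Each
individual's contemporaneous group-path betas are vectorized and correlated
with every other individual's, giving an N×N similarity matrix X, binarized
at threshold r (A_ij = 1 iff X_ij ≥ r).  For every r in 0, .01, …, 1, Newman
modularity maximization runs 100 times; the selected r* is the most stable
threshold — minimal std(Q) across runs, ties to the highest r — among those
before the drop in network reachability (located by maximum perpendicular
distance from the reachability curve's endpoint chord).  Final communities
are the modal partition at r*.

**Robustness — perturbation + variation of information.**  The binarized
network is rewired by degree-preserving double-edge swaps at levels 0…1;
community detection re-runs on each perturbed network and is compared with
the original partition by Meilă's VI, alongside an Erdős–Rényi baseline of
matched size.  Genuine structure yields a flat VI curve under light
perturbation; random graphs fall apart immediately.

**Comparison — ANOVA with FDR.**  Per group path, each subgroup's betas are
contrasted against the pooled others (omnibus ANOVA + subgroup-vs-rest t),
with Storey q-values controlling FDR at α = .05 across all contrasts.

A subgroup-structured Monte Carlo generator (structural VARs with shared,
subgroup-deviant, and individual-unique paths) makes the whole pipeline
testable without any data downloads.  See `docs/methods.md` for model
details, parameter defaults and limitations.

## Worked example

```python
from gimmesub import SimulationDesign, generate_panel, run_gimme, \
    detect_subgroups, matched_accuracy

design = SimulationDesign(n_individuals=24, n_subgroups=2,
                          n_timepoints=150,
                          unique_paths=[(5, 0), (6, 1)], seed=1)
panel, truth = generate_panel(design)
maps = run_gimme(panel)                      # group + individual search
part, scan, net = detect_subgroups(maps, rng=7)
print(scan.selected_r, part.n_communities,
      matched_accuracy(truth.labels, part.labels))
```

Running `python examples/simulate_and_fit.py` prints:

```
group-level contemporaneous paths (source -> target):
  ROI0 -> ROI1
  ...
  ROI8 -> ROI9
autoregressive paths freed for all ROIs: 10/10
individual-level paths per person: mean 0.25 (these absorb the subgroup-unique connections)
connection recovery (presence + direction): 98.93%
```

i.e. the search recovers every simulated group path with its direction, the
AR baseline, and (here) 98.9% of all true directed connections across
individuals.  `python examples/full_pipeline.py` continues through
subgrouping:

```
selected threshold r* = 0.66
2 subgroups (sizes [12, 12]), Q = 0.492
subgroup accuracy vs ground truth: 100.0%
8 subgroup-vs-rest contrasts significant at q <= 0.05
```

— the data-driven threshold lands where 100 modularity runs agree exactly,
the two simulated subgroups are recovered member-for-member, and the
comparison step flags the paths whose weights were simulated to deviate.
Each script in `examples/` is a short narrative of one capability
(simulation+fitting, subgroup detection, robustness, comparison, motion
scrubbing, the full pipeline).

## Command line

The same stages are available as a thin CLI for shell use:

```bash
gimmesub simulate --out sim --seed 1
gimmesub fit --input sim/timeseries --out fitted
gimmesub subgroup --betas fitted/group_betas.tsv --out sg --seed 2
gimmesub robustness --adjacency sg/adjacency.tsv --partition sg/partition.tsv --out rob.tsv
gimmesub compare --betas fitted/group_betas.tsv --partition sg/partition.tsv --out cmp
gimmesub all --out results --seed 1        # everything, config-driven
```

Inputs are plain delimited text (one T×p file per individual, NaN/NA rows
as scrubbed-frame placeholders); outputs are TSV tables (edge lists,
similarity matrix, threshold scan, partition, robustness curve, comparison
tables).  Motion scrubbing from 6-parameter realignment files is available
via `gimmesub.compute_fd` / `scrub_frames` (FD > 0.2 mm → placeholder row).

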