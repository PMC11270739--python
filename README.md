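# tunneltransit

Enzymes with buried active sites exchange substrates with the solvent
through networks of transport tunnels.  Deciding *which* tunnel a ligand
used for each entry or exit — and how fast binding and unbinding happen —
is a trajectory-analysis problem: given per-frame positions of the ligand
and a few landmark residue groups (the catalytic machinery and the
bottleneck residues of each tunnel), classify every bulk↔active-site
crossing and estimate kinetics.  `tunneltransit` implements that analysis
as a reusable desk-scale pipeline for computational enzymologists working
with molecular-dynamics data, validated end to end on synthetic
trajectories with planted ground truth.

## What it computes

**Distances and regions.**  For each frame the package measures
d_cat (ligand COM ↔ catalytic-machinery COM), d_bt[T] (ligand COM ↔
bottleneck COM of tunnel T), and the instantaneous tunnel length
L[T] (catalytic COM ↔ bottleneck COM).  Frames are classified by d_cat
into active-site cavity (≤ 5 Å), tunnel (5–19 Å) and bulk (> 19 Å).

**Transit tracking.**  With T\* the tunnel whose bottleneck is closest,
each frame is one of: bulk (`out_`, d_cat > L + bt_cutoff_along),
interior (`in_`, d_cat < L − bt_cutoff_along), bottleneck band (`bt_`,
|d_cat − L| ≤ bt_cutoff_along and d_bt[T\*] ≤ bt_cutoff_across), or
`bt_unknown` (in the band but far from every bottleneck).  A state
machine then extracts every completed bulk↔interior crossing: direct
crossings are assigned a tunnel when both endpoint frames agree (a
dist_tolerance of 1 Å can reconcile near-ties; otherwise *mixed*), and
band-mediated crossings inherit the tunnel of the last band frame
(*unknown* if that frame was `bt_unknown`).  Counts are aggregated per
trajectory, replicate and scheme (mean ± sd over replicates).

**MSM kinetics.**  Distance features → TICA (lag 2 ns) → k-means
microstates → transition matrix P(τ) at lag 20 ns → implied timescales
t_i = −τ/ln λ_i, Chapman–Kolmogorov validation, spectral lumping into
metastable states, and mean first-passage times between a bulk source
and a bound sink: k_on = 1/MFPT_on, k_off = 1/MFPT_off,
K_d = k_off/k_on (reported as the dimensionless MFPT ratio).

**Unified ligand states.**  Metastable states from different replicates
are matched by a 20-component fingerprint (mean, p25, p50, p75 of the
five characteristic distances), reduced to three principal components
and clustered with HDBSCAN (min_cluster_size = 2); noise points become
singleton states, and a presence matrix reports each unified state's
mean stationary probability per replicate.

A `seeding` module also provides the bulk-solvent grid placement used to
start such simulations (5×5×5 grid, 5 Å padding, clash filtering), and a
`synthgen` module generates all the synthetic inputs used for validation.

## Worked example

```python
import numpy as np
import tunneltransit as tt

# a toy enzyme with three tunnels of different lengths
spec = tt.ToyNetworkSpec(tunnels={
    "p1a": ((0, 0, 1), 14.0),
    "p1b": ((0, 1, 0), 16.0),
    "p2":  ((1, 0, 0), 12.0),
}, noise_sd=0.3)
net, _ = tt.make_toy_network(spec)

# script a trajectory: enter through p2, leave through p1a, re-enter via p2
plan = tt.PlantedEventPlan([
    tt.PlannedTransit("p2", "out_in"),
    tt.PlannedTransit("p1a", "in_out"),
    tt.PlannedTransit("p2", "out_in"),
])
traj, truth = tt.simulate_ligand_walk(spec, plan, seed=7)
ds = tt.build_distance_series(traj, net)

print("region fractions:", tt.region_fractions(tt.classify_region(ds)))
for ev in tt.track_transits(ds):
    print(f"{ev.direction:7s} via {ev.category:4s} frames {ev.start_frame}-{ev.end_frame}")
```

prints

```
region fractions: {'cavity': 0.0, 'tunnel': 0.7971014492753623, 'bulk': 0.2028985507246377}
out_in  via p2   frames 4-9
in_out  via p1a  frames 26-31
out_in  via p2   frames 57-62
```

— every scripted crossing is recovered with its direction and tunnel
(the toy walk never dips below 5 Å from the catalytic COM, so the cavity
fraction is zero).  Kinetics from a known three-state chain
(bound / tunnel / bulk):

```python
P = np.array([[0.95, 0.04, 0.01],
              [0.05, 0.90, 0.05],
              [0.02, 0.08, 0.90]])
centers = np.array([[0., 0], [5, 0], [10, 3]])
sample = tt.simulate_markov_chain(P, centers, 100000, noise_sd=0.4, seed=7)
labels, cc = tt.cluster_microstates(sample.features, 3, seed=0)
relabel = np.array([np.argmin(np.linalg.norm(centers - c, axis=1)) for c in cc])
Pest, pi, _ = tt.transition_matrix(tt.count_matrix([relabel[labels]], lag=1),
                                   reversible=False)
kin = tt.rates_and_kd(tt.mfpt(Pest, [2], [0], pi=pi),
                      tt.mfpt(Pest, [0], [2], pi=pi))
print(f"MFPT on {kin.mfpt_on:.1f}  off {kin.mfpt_off:.1f} frames, k_d = {kin.k_d:.3f}")
```

prints

```
MFPT on 30.1  off 46.6 frames, k_d = 0.646
```

against analytic values of 30.0 / 46.7 frames and K_d = 0.643 for the
generating chain.

A command-line interface mirrors the library
(`tunneltransit distances|regions|transit|msm|uls|seeds|simulate|run`);
`tunneltransit run --manifest runs.yaml --config config.yaml --out out/`
executes the whole pipeline and writes a JSON report plus TSV tables.

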