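# cadclust

A coarse-grained 2D Brownian-dynamics simulator of cadherin clustering at
cell–cell junctions, with trans/cis binding cooperativity and a cortical
actin meshwork that corrals and tethers cadherins. It is written for
quantitative cell biologists and biophysical modellers who want to explore
how binding affinities, actin architecture and filament turnover shape
adhesion-cluster size, stability and spatial patterning.

## Model

Two apposed membranes coexist as planes in one periodic 2D domain
(default 1 µm × 1 µm). Each cadherin extracellular region is a disc of
radius *r* = 2.5 nm carrying one **trans** site on its axis and a **cis**
donor/acceptor site pair on opposite flanks; the donor–acceptor axis defines
the orientation θ. Per time step Δt (default 10⁻⁵ s) a free monomer moves a
fixed step √(4DΔt) in a uniform random direction and rotates by ±√(2D_rot Δt)
about the membrane normal.

Binding is split into a diffusion part and an intrinsic part. Two
monomers become eligible when the relevant site distance *d* falls below a
cutoff (*d*_c = 1.5 nm trans, 3 nm cis, 3.5 nm cadherin–actin) and their
orientations deviate from the bond's ideal packing by less than
*a*_c = 30°. An eligible pair then binds with the per-step probability

    p_ass = 1 − exp(−k_ass Δt)

and every existing bond breaks with p_dis = 1 − exp(−k_dis Δt). After a
trans bond the pair is made coaxial with a 90° packing offset and diffuses
as one unit; after a cis bond the pair is packed into a linear chain
(centres one diameter apart, orientations synchronised) and immobilised.

F-actin is projected onto each membrane as rigid line segments of length
L_F = h_actin·tan φ. The whole segment obstructs diffusion (moves crossing
it are rejected — corralling); a contiguous fraction of it can bind
cadherins through implicit linker proteins (tethering), immobilising them
while leaving rotation free. The filament count per plane holds the actin
concentration fixed, and filaments turn over stochastically with an
exponential lifetime, releasing tethered cadherins.

The measurement suite computes cluster partitions (connected components of
the bond graph), maximum/mean cluster size, trans/cis bound fractions, the
2D cis dissociation constant K_D = ⟨ρ_freeDonor·ρ_freeAcceptor/ρ_bond⟩,
time+ensemble-averaged MSD with log-log slopes (anomalous exponents),
cluster lifetime tracking across snapshots, nearest-neighbour cluster
distances and cluster-size CV.

## Worked example

```python
import numpy as np
from cadclust import (KineticParams, PeriodicDomain, RunSchedule, run,
                      find_clusters, max_cluster_size, fraction_trans,
                      summarize_run)

params = KineticParams(cad_density=1200,   # per um^2 per membrane
                       actin_conc=60.0,    # uM
                       L_F=200.0,          # nm
                       kass_cis=1e5, kdis_cis=1e3)
schedule = RunSchedule(duration=2.0, snapshot_interval=0.5,
                       trajectory_interval=0.01, seed=1)
result = run(PeriodicDomain(500.0, 500.0), params, schedule)
stats = summarize_run(result)
print({k: round(v, 3) for k, v in stats.items() if not np.isnan(v)})
```

prints (seed 1):

```
{'max_cluster_size': 26, 'mean_cluster_size': 9.614, 'fraction_trans': 0.76,
 'fraction_cis': 0.747, 'nnd': 27.798, 'size_cv': 0.495, 'kd_cis': 920.992,
 'msd_alpha_short': 0.856, 'msd_alpha_long': 0.917, 'mean_lifetime': 0.783}
```

After two simulated seconds at 1200 cadherins/µm² under 60 µM obstructing
and binding actin, the largest cluster holds 26 monomers, 76% of cadherins
are trans-dimerised and 75% carry a cis bond; the sub-unity MSD exponents
(0.86 and 0.92) reflect obstructed diffusion and progressive
immobilisation, and qualifying clusters (≥5 monomers) sit ~28 nm from
their nearest neighbour. The K_D here is still relaxing — it is measured
from the late snapshots of this short run, and keeps falling as clusters
absorb free cadherins.

The same engine is scriptable from the shell:

```bash
cadclust run --config my_run.yaml --seed 1 --out out/
cadclust sweep --config my_sweep.yaml --out sweep.csv
cadclust analyze --snapshot out/snapshot_t00001.000000 --out stats.csv
```

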