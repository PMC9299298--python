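# Methods

## Model summary

`cadclust` simulates the extracellular domains of cadherins on two apposed
membranes as discs of radius 2.5 nm diffusing in a shared periodic 2D
domain, together with each membrane's cortical actin projected onto it as
rigid line segments. Monomers carry one trans site (on the disc axis) and a
cis donor/acceptor pair (on opposite flanks, defining the orientation θ).
The dynamics are fixed-time-step Brownian dynamics: per step Δt a mobile
unit takes a displacement of fixed magnitude √(4DΔt) in a uniform random
direction, and eligible partners react with per-step probabilities
1 − exp(−kΔt) derived from intrinsic association/dissociation rates. The
model deliberately separates the diffusion-limited part of binding (the
geometric eligibility criteria) from the reaction-limited part (the
intrinsic rates), so effective on-rates are emergent, not inputs.

A per-step update executes, in order: actin turnover; diffusion of mobile
units with move rejection against obstructing filaments; rotation;
dissociation trials; association over eligible bond proposals in uniformly
shuffled order with at most one attempt per free site per step, followed by
structural packing of new bonds. Associations therefore see post-move
positions; the ordering's effect vanishes as Δt → 0.

## Eligibility and packing conventions

* Trans: opposite membranes, both trans slots free, axis distance
  < 1.5 nm, and the orientation difference within 30° of the ±90° trans
  packing. The packing sign is not fixed, which keeps the criterion
  symmetric in the two monomers; on binding, the pair is made coaxial and
  the offset snaps to whichever of ±90° is nearer.
* Cis: same membrane, donor slot of one and acceptor slot of the other
  free, donor→acceptor site distance < 3 nm, orientations within 30° of
  parallel. On binding, centres are set one diameter (5 nm) apart along the
  donor axis and orientations synchronised — consecutive cis bonds thereby
  build the linear, 180°-packed chain arrangement.
* Cadherin–actin: same membrane, monomer centre within 3.5 nm of the
  filament's *binding* sub-segment (the obstruction region does not bind);
  no angular condition, since the linker attachment sits inside the
  membrane. Tethered cadherins stop translating but still rotate.

The angle cutoff could equally be read as a bare |Δθ| < 30° condition for
both bond kinds; that reading makes the trans criterion contradict the 90°
post-binding adjustment, so the deviation-from-packing form is the default
and the bare form remains available as `angle_convention="raw"`.

A deliberately conservative deviation from the packing rules: a monomer
already carrying *any* cis bond (not only members of chains longer than
two), an actin bond, or a trans partner with either, is never relocated by
a later bond's packing step; the new bond then forms without relocation.
Moving a member of even a two-monomer chain would break that chain's exact
5 nm separation, which the structural audit enforces after every step.
For the same reason the engine applies the trans midpoint adjustment
mobility-aware: two free monomers meet at the midpoint, a free monomer
snaps to an anchored partner, and two anchored monomers bond in place
(their residual axis offset is below the 1.5 nm eligibility cutoff).
Relocating or re-orienting a monomer always carries its trans partner
rigidly, so coaxiality survives every step.

## Actin meshwork

A filament tilted by φ from the membrane normal across an effective cortex
slab of thickness h_actin projects to length L_F = h_actin·tan φ. When an
explicit L_F is given it wins and φ is back-computed for the record, since
sweeps are naturally parameterised by projected length. The filament count
per plane is set from the actin concentration: the subunit budget in the
slab volume (area × h_actin) is converted to filament length at 370
subunits/µm (2.7 nm helical rise) and divided by L_F. Filaments are rigid
and static between turnover events; each is removed per step with
probability 1 − exp(−Δt/τ) and instantly replaced by a freshly sampled one
(count, length and binding fraction conserved), releasing its tethered
cadherins. Each membrane's cadherins are corralled only by their own
cortex; a trans dimer spans both membranes and is blocked by either.

## Parameters, units and defaults

One unit system everywhere: nm, s, µM, µm⁻², degrees.

| parameter | default | meaning |
|---|---|---|
| Δt | 10⁻⁵ s | time step; must keep √(4DΔt) < d_c(cis) |
| D | 10⁵ nm²/s | lateral diffusivity (0.1 µm²/s), step = 2 nm |
| D_rot | (10°)²/(2Δt) | rotational scale: a 10° step per Δt |
| r_cad | 2.5 nm | monomer radius |
| d_c trans / cis / actin | 1.5 / 3 / 3.5 nm | eligibility cutoffs |
| a_c | 30° | angular cutoff (deviation from ideal packing) |
| θ_trans / θ_cis | 90° / 180° | packing angles |
| k_ass/k_dis cis | 10⁵ / 10³ s⁻¹ | weak-cis working point (ratio 100) |
| k_ass/k_dis trans | 10⁵ / 1 s⁻¹ | stable trans dimer (package choice) |
| k_ass/k_dis cad-actin | 10⁵ / 0.1 s⁻¹ | strong, long-lived tether |
| [cad] | 1200 µm⁻² | surface density, per membrane |
| h_actin | 100 nm | effective cortex thickness |
| L_F | 200 nm | projected filament length |
| binding fraction | 0.2 | fraction of filament length that binds |
| τ (actin lifetime) | ∞ | turnover disabled unless set |

Δt, D, D_rot and the trans rates are package choices (set once, before any
result-level comparisons): the step length must stay below the cis cutoff
for adequate sampling of the eligibility shell, the angular step is chosen
to decorrelate orientation on the same footing as position, and the trans
rates make trans dimers long-lived relative to cis bonds, as expected for
the adhesive bond proper.

## Measurements

Clusters are connected components over current trans+cis bonds (a trans
dimer is a size-2 cluster; clusters span both membranes). Mean cluster
size, nearest-neighbour distance between cluster centroids and the
cluster-size CV consider clusters of ≥ 5 monomers; centroids use the
circular mean per coordinate. K_D(cis) is the mass-action surface-density
form ⟨ρ_freeDonor · ρ_freeAcceptor / ρ_cisBond⟩ averaged over late
snapshots and both planes. MSD uses unwrapped trajectories (every position
change, including packing relocations, accumulates) and averages over both
time origins and particles; exponents are least-squares slopes of log MSD
vs log lag over a stated window. Cluster lifetimes track components of ≥ 2
monomers across uniformly spaced snapshots by maximal member overlap
(≥ 50% of the smaller set; ties break to the lowest minimum member id);
tracks alive at the end are right-censored and excluded from mean
lifetimes. Filament lifetime statistics use the renewal estimator
(observed filament-time / removals), which avoids the length-biased
exclusion of intervals straddling the observation window.

## Numerical implementation

The hot loop is a numba kernel over flat arrays. Filaments are cut into
short collinear chunks binned into padded cell grids (obstruction and
binding separately), so one cell lookup bounds every chunk a move path or
binding test could touch; monomers are re-binned each step into a cell list
whose cell size exceeds the largest eligibility distance (association runs
after the move phase, so no step margin is needed and no eligible pair can
be missed). Move directions come from a 4096-entry unit-vector table
(0.09° resolution — far below the 10° rotational step); per-monomer
cos θ/sin θ are cached, updated by exact rotation identities and refreshed
every 4096 steps against drift. Randomness is an in-kernel xorshift128+
stream; a run derives independent sub-seeds for initialisation and for each
simulation chunk from its single seed, making runs bit-reproducible.
Minimal-image arithmetic uses the half-open convention [−L/2, L/2), so the
tie at exactly L/2 resolves deterministically; a move path touching a
filament at a single point counts as blocked.

## Synthetic data and what the tests show

There is no external data: initial states are uniform random placements at
the configured surface density, and the actin network is sampled from its
spec. Hand-built fixture states (a closed obstructing triangle, a square
box with a gap, a minimal three-monomer bonded arrangement) exercise the
geometry and bookkeeping deterministically; they are synthetic
constructions, not simulation output. Passing tests therefore demonstrate
internal consistency of the model's rules and estimators (free-diffusion
law, reaction-probability mapping, oracle-equivalent cluster detection,
confinement, turnover statistics, trend directions under corralling and
tethering), not agreement with any particular experimental junction: real
membranes add excluded volume, membrane undulation, filament flexibility
and force-dependent bond kinetics, all outside this model.

## Problem sizes used by the bundled studies

Trend-level studies run at desk scale as the package's standard test
conditions: a 0.5 × 0.5 µm domain (600 monomers at 1200 µm⁻²), 3
replicates per condition, 5 simulated seconds at Δt = 2×10⁻⁵ s (step
2.83 nm, still below the cis cutoff). `scripts/acceptance.py` uses the same
domain with Δt = 10⁻⁵ s: 3 s runs with 1 ms trajectory sampling for the
short-lag MSD slope (filament lengths 200, 600, 1000 nm at 60 µM,
obstruction only), and 10 s runs (one per density in 800–2000 µm⁻²,
K_D from the late 5 s of snapshots) for the cis dissociation constant.

## Known limitations

No excluded volume between non-bonded monomers (lattice packing emerges
from bond geometry alone); filaments are rigid, unbranched and immobile
between turnover events; linker proteins are implicit, with no
catch/slip-bond force dependence; dimers diffuse with the monomer step
(no size-dependent mobility); the two membranes are flat and parallel.
Equilibrium constants measured from the simulation are emergent, kinetic
quantities — the immobilisation and packing rules break detailed balance,
so K_D depends on density and history as in the underlying model, not on
the rate ratio alone. Because instant rebinding makes packed bonds very
long-lived, the default stable-trans kinetics drive dense actin-free
systems to near-complete trans/cis conversion within seconds (the
trend-level tests measure this); with a saturated bulk, strong
cadherin–actin tethering redistributes monomers out of clusters and lowers
the cis-bound fraction rather than raising it, so tether-enhanced cis
binding only emerges when the bulk is kept below saturation (weaker trans
kinetics, lower density, or stronger corralling).
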