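# Methods

## Model overview

`cellcolony` is a center-based (off-lattice) model of epithelial cell
colonies in two dimensions. Cells are elastic spheres characterised by a
position in the monolayer plane, a radius, a cell-cycle state and an
intracellular adhesion-pathway state. All internal units are µm, min, pN
and percent: concentrations are expressed as % of the maximal number of
E-cadherin–β-catenin complexes a cell can form (100 = every β-catenin
bound), which makes them intensive quantities that survive division
unchanged. 1 Pa equals 1 pN/µm², so moduli in Pa carry over numerically.

### Adhesion pathway

Each cell carries cytosolic pools `E` (free E-cadherin, initial value =
the cell's expression level E_t), `B` (free β-catenin, initial 100) and
`EB` (non-junctional complexes, initial 0), plus one compartment `EBc_i`
per cell–cell contact site. The deterministic kinetics are

    dE/dt  = −ν_p·E·B + ν_n·EB
    dB/dt  = −ν_p·E·B + ν_n·EB
    dEB/dt =  ν_p·E·B − ν_n·EB − Σᵢ cᵢ + Σᵢ dᵢ
    dEBcᵢ/dt = cᵢ − dᵢ (+ r_inᵢ − r_outᵢ in the dynamic-adhesion variants)

with exocytosis flux `cᵢ = (ρ_c·EB·a_cᵢ + ρ_u·EB·Aᵢ/(4πR²))·sat`,
disassembly endocytosis `dᵢ = ρ_d·a_dᵢ·EBcᵢ`, and redistribution
`r_inᵢ = γ·Σⱼ max(0, EBcⱼ − EBcᵢ)` (and symmetrically for `r_out`), where
`Aᵢ` is the contact area with neighbour *i*. Two conservation laws hold
exactly at all times: `E + EB + Σ EBcᵢ = E_t` and `B + EB + Σ EBcᵢ = 100`.

The saturation factor `sat` distinguishes the variants: Model 1 (static
adhesion) caps each site at τ_E = E_t/6, so a cell can always serve six
neighbours; Models 2/3 (dynamic adhesion) cap the junction-bound *total*
at 0.8·E_t, so a lone contact can recruit nearly the whole complement and
redistribution equalises sites when new neighbours appear. The 0.8 factor
is fixed by the calibration anchor (80% of complexes ↔ 210 nN) together
with the requirement that two simultaneous neighbours split the two-cell
force in half (40 + 40).

**Area-change factors.** `a_c` and `a_d` are the relative contact-area
change rates, `min(max(±d(lnA)/dt, 0), 1)` — dimensionless, in [0, 1] —
so all rate constants keep units of min⁻¹. Transport driven by junction
remodelling engages in proportion to how fast the junction grows or
shrinks, saturating at unit relative rate (vesicle traffic cannot follow
millisecond-scale area changes). A fully detached site has `a_d = 1`
and drains as `dEBcᵢ/dt = −ρ_d·EBcᵢ` until its compartment falls below
10⁻⁶ %, at which point it is deleted and the residue returned to `EB`.
Discretely, the factor consumed per bookkeeping step is
`min(ΔA/A, dt·1 min⁻¹)`. An earlier per-step formulation without the rate
clamp made the influx from noise-driven contact flicker scale with the
number of steps — a dt-dependent artifact — and was replaced.

Default rates (min⁻¹): ρ_u = 8.2, ν_n = 0.6, ν_p = 0.02 (per % per min),
ρ_c = 0.6, γ = 0.16; ρ_d is scenario-dependent (0.6 in the headline
colony scenario). These are the values the package's own calibration
pipeline recovers from two- and three-cell assay data (see below).

### Mechanics

Overlapping spheres repel with the Hertz force; the contact area is the
disc bounded by the sphere–sphere intersection circle (for equal spheres
a² = R² − (d/2)²). This geometric choice reproduces the anchor
correspondences exactly: at the "natural state" spacing d* = 8.52 µm
(contact diameter = circumference/6 for R = 5 µm) six neighbours exert
6 × 2179 ≈ 13 070 pN — within 1% of the 13 000 pN contact-inhibition
threshold.

Adhesion maps the *limiting* side of a bond, m = min(EBc self, EBc
partner), linearly onto force: F = m/80 · 210 nN (Models 2/3) or
m/15 · 210 nN (Model 1), extrapolating linearly beyond the anchor. In
Model 3 the bond only resists separation: the force is zero for pairs at
or inside their natural state, ramping linearly to its full value over a
thin 0.1 µm band beyond d*. The ramp regularises a discontinuous force
law; without it a bound pair has no stable rest point and chatters across
the jump at the integrator's finest resolution. The band is far below the
contact-geometry scale and inside the positional noise amplitude. Within
the band the pair's axial dynamics are still stiff (the force swings by
the full bond strength over 0.1 µm) but possess a stable equilibrium
whose relaxation time (~10⁻⁵ min) is far below any integration step;
the engine therefore projects bonded in-band pairs directly onto that
equilibrium each sub-step, which removes the stiffness without changing
where cells rest.

"Pressure" is the scalar sum of the repulsive force magnitudes on a cell
(a symmetric hexagon has zero *net* force but full pressure); it is the
quantity compared with the 13 000 pN arrest threshold.

Motion is overdamped, `dx/dt = (ΣF + f)/(6πηR)` with η = 10 Pa·s
(drag 15.7 pN·min/µm for R = 5 µm). The noise term `f` is uncorrelated
with zero mean; its strength is parameterised as an effective diffusivity
D (µm²/min) so that displacement variance per axis is 2·D·Δt regardless
of the integration step. Colony scenarios default to D = 0.05 µm²/min
(3 µm²/h — weak epithelial jiggling, sub-µm displacements per minute);
pipette and hexagon scenarios run noise-free. The two halves of an
M-phase dumb-bell receive a common noise realisation: the dumb-bell is
one body and must not diffuse apart internally.

### Cell cycle

G1 (7 h) grows the radius linearly from R/2^{1/3} to R; the lumped
G0/S/G2 rest phase is drawn uniformly from 8–18 h each cycle; M lasts 2 h.
Total cycle length is 17–27 h (mean 22 h). Division happens at M *entry*:
the mother is replaced by two daughters of radius R/2^{1/3} (volume is
conserved exactly) at ±R/2 along the axis of highest pressure — the
dominant eigenvector of Σⱼ |F_rep,j|·(ûⱼ⊗ûⱼ) over repelling neighbours,
with a uniformly random axis for isolated or isotropic cells. During M the
siblings are the dumb-bell: they do not interact with each other (no
contact site, no forces), are exempt from collapse detection, and move as
one rigid body — the inter-centre distance stays fixed at R and both
halves receive a common noise realisation. Without the rigidity,
neighbours could silently squeeze the force-free pair together during the
2 h M phase. Division
disassembles junctions: the mother's bound complexes — and her partners'
complexes facing her — return to the respective cytosolic pools, keeping
conservation exact on every cell. Concentrations are intensive and carry
over to both daughters unchanged.

With contact inhibition enabled, a cell whose pressure exceeds
13 000 pN at the end of its rest phase is arrested; the check repeats
every step, so arrested cells resume when neighbours give way. The
founder cell of a colony run starts at a uniformly random point of its
cycle.

## Numerical scheme

Operator splitting per step of length `dt_pathway`: (1) contact
bookkeeping — sites are created for overlapping non-sibling pairs (a new
site's previous area equals its current area, so contact formation is not
itself "area growth"), persist with area 0 while draining after
separation, and are deleted when drained; (2) one forward-Euler pathway
update per cell, with outflows proportionally clipped to their donor pools
(clipped mass stays put), gains clipped to the remaining saturation
headroom, and the linear inter-site redistribution subsystem advanced by
its exact exponential update (unconditionally stable for any γ),
which keeps every concentration non-negative and
both conservation laws exact to round-off; (3) overdamped mechanics
sub-stepped so that no cell moves more than 0.05 µm per sub-step
(explicit-Euler stability; contact relaxation times are seconds while the
kinetics evolve over minutes); (4) cycle advancement and divisions;
(5) collapse detection — the run halts with status `collapsed` when any
non-sibling pair's centre distance falls below 0.2·(R_i+R_j), the regime
in which cells can no longer be identified individually.

`dt_pathway` defaults to 0.01 min; the colony scenario uses 0.05 min
(kinetic rates are at most 8.2 min⁻¹, so the pathway update stays well
resolved, and the mechanics sub-steps are displacement-capped
independently of `dt_pathway`). Halving the step changes 100-min pipette
trajectories by well under 1%.

The per-cell reference integrator (`adhesion_pathway.step_pathway`)
additionally sub-steps adaptively so no pool loses more than half its
content per sub-step; the engine's vectorised kernel and the dedicated
collinear pipette integrator implement the same scheme and agree with each
other within 1% on the two-cell assay (tested).

In the pipette integrator, a pair whose adhesion exceeds its repulsion at
a centre distance below 0.2 µm is pinned at coincidence: past that point
the model has no mechanical equilibrium (see limitations) and the
overdamped dynamics would only jitter around the crushed state at the
finest sub-step resolution. Coincident centres exert no force (the
direction is undefined); pipette scenarios run with collapse detection
off, because the assay's pipettes hold the cells.

Determinism: every stochastic draw (cycle durations, initial cycle
position, division-axis ties, positional noise) derives from the single
run seed; identical (config, seed) gives bit-identical trajectories.

## Calibration pipeline

`fit_kinetics` recovers (ρ_u, ν_n, ν_p, ρ_c) from a two-cell force time
course (5/10/30/60 min at full expression) plus a 30-min force series over
expression levels (100, 58, 41, 38, 14, 2%), by Nelder–Mead simplex in
log₁₀-rate space, multi-started from log-uniform draws in [10⁻⁶, 10⁶]
(default 50 restarts). `fit_redistribution_rate` then fixes γ on
three-cell criteria: simultaneous neighbours must split the two-cell force
in half, and a neighbour arriving 20 min late must reach force parity with
the established bond roughly 30 min after contact. With idealised
criteria alone the objective is flat for all sufficiently large γ (any
fast-enough redistribution equalises by the deadline) — it bounds γ from
below; fitting against recorded reference trajectories is well posed and
is what the recovery test uses.

No public dataset ships with printed per-time-point separation forces, so
the repository's fixture dataset is *synthetic*: generated from the model
itself at the default rates (`make_synthetic_pipette_dataset`). It
reproduces the study design — the 210 nN maturation anchor, near-steady
force from 30 min, monotone force-vs-expression — but carries no
measurement noise and no biological replicate scatter; parameter-recovery
results on it demonstrate identifiability of the fitting pipeline, not
accuracy against laboratory data. User-supplied CSVs (columns
`time_min, force_nN` and `expression_pct, force_nN_at_30min`) drop in via
`PipetteDataset.from_csv` or `cellcolony fit`.

## Test problem sizes

The always-on suite runs reduced but behaviourally decisive problem
sizes, chosen once: the endocytosis-regime sweep uses two simulated days
per run (the first division falls within 27 h and the fate of the
resulting pair decides survival or collapse within hours); the headline
Model-3 colony test uses a four-day reduced-power variant of the 7-day
scenario at the colony step of 0.05 min (the full seven days run through
the same scenario, e.g. via the CLI, in roughly a quarter of an hour).
Pipette assays run at full fidelity (0.01 min, 60–100 min horizons).
A small (4-day, ~16-cell) colony is rim-dominated, so its
neighbour-number histogram cannot yet peak at six — see the last
limitation below.

## Known limitations

* **Dynamic adhesion has no pair equilibrium.** The calibrated separation
  force (210 nN at 80% bound complexes) exceeds the largest possible Hertz
  repulsion between two R = 5 µm, 1 kPa spheres (ƒ ≈ 37 nN at complete
  overlap) roughly six-fold. Under Models 1/2, where bonds pull
  continuously, an isolated adherent pair therefore has no mechanical
  equilibrium once its bond level passes ≈14% — and because disassembly
  endocytosis is gated on contact-area *loss*, a monotone approach never
  drains the bond, for any ρ_d. Every isolated Model-1/2 pair collapses to
  coincident centres shortly after its bond matures; in colonies this
  surfaces as the collapse of the first daughter pair. This is an
  intrinsic property of the constantly-pulling variants and is precisely
  what motivates the separation-force variant (Model 3) combined with
  pressure-gated arrest, which is stable across the entire ρ_d range and
  is the package's default colony model. Colony survival of Model 2 at
  very high endocytosis rates can only be produced by coarse-stepping
  artifacts (integration overshoot masquerading as junction remodelling)
  and is deliberately not reproduced.
* Cells are rigid spheres: no shape change, no 3-D colony geometry, no
  explicit membranes; the monolayer plane is unbounded and substrate
  friction beyond Stokes drag is absent.
* E-cadherin production and degradation are not modelled (total pools are
  stationary), so long-term expression regulation is out of scope.
* The noise amplitude is a model choice (no measured value); all
  pipette-level results are noise-free and unaffected by it.
* Neighbour-number histograms count every cell, including the colony rim,
  whereas experimental histograms typically sample interior cells only;
  small colonies therefore under-represent six-neighbour cells.
* The arrest threshold (13 000 pN) equals, by construction, the pressure
  of exactly six contacts at the natural-state spacing — the packing that
  Model-3 colonies settle into. Interior cells therefore sit right at the
  threshold and are predominantly arrested, making colony growth
  rim-dominated (slower than a free exponential with ~22 h doubling) once
  the colony is more than a few cells deep. Positional noise lets
  borderline cells slip below the threshold and divide occasionally, but
  dense colonies grow more like a perimeter process than an exponential
  one at late times.
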