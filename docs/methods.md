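# Methods

`hbflex` analyses protein thermal adaptation from three directions:
thermodynamic stability (CD melting curves), average sub-nanosecond
flexibility (elastic incoherent neutron scattering), and residue-resolved
mechanics (coarse-grained Brownian dynamics of an elastic network).  This
note records the models, conventions, defaults and known limitations.

## Elastic-scan analysis (`neutron_elastic`)

**Model.** In the Gaussian approximation the elastic incoherent intensity
decays as

    I(q) = I0 · exp(−⟨u²⟩ q² / 6),

where ⟨u²⟩ is the full 3-D mean square displacement of the (hydrogen-
dominated) atomic motion inside the instrument's space–time window.
⟨u²⟩ is obtained from a weighted straight-line fit of ln I versus q²
inside a fixed window where the decay is linear — 1.6 ≤ q² ≤ 3.5 Å⁻² for a
thermal backscattering setup (≈0.1 ns window, "IN13-like") and
0.36 ≤ q² ≤ 3.10 Å⁻² for a cold one (≈1 ns, "SPHERES-like").  The mean
resilience (effective force constant) follows from the slope of ⟨u²⟩
versus T:

    ⟨k′⟩ = 0.00276 / (d⟨u²⟩/dT)   [N m⁻¹ with ⟨u²⟩ in Å², T in K].

The divisor-6 exponent and the 0.00276 constant form one linked
convention; the package also ships the divisor-3 / 0.00138 pairing, and
the two cannot be mixed (they are selected by a single option).  The
divisor-6 pairing is the default because it closes consistently: a
resilience of 0.15 N m⁻¹ fitted over 280–315 K with ⟨u²⟩(T_b) anchored at
1.49 Å² returns an RMSD of 1.22 Å at 36.6 °C.

**Gaussian validity.** Each fit carries a flag raised when the exponent at
the window edge, ⟨u²⟩·q²_max/6, exceeds a configurable bound (default 2):
beyond it the low-q expansion is unreliable and the fitted ⟨u²⟩ is an
underestimate.  Fits are weighted by 1/σ² when intensity errors are given;
parameter covariances propagate first-order into k′ and into
RMSD(T_b) = √(intercept + slope·T_b).

**Three-window powder fits.** Hydrated-powder scans show three
quasi-linear ⟨u²⟩(T) regimes — the harmonic solid below ~100 K, a
methyl-rotation regime to ~200 K, and the post-dynamical-transition regime
— fitted independently over 10–100, 100–200 and 252–292 K (window edges
configurable).

## Two-state thermodynamics (`cd_thermo`)

The ellipticity at 222 nm is taken proportional to the folded fraction
after linear pre-/post-transition baselines y_F(T), y_U(T) are fitted in
user-chosen windows:

    f_F(T) = (y_U − y) / (y_U − y_F),      ΔG(T) = −R T ln(f_U / f_F),

with f_U = 1 − f_F.  A line fit ΔG = ΔH − TΔS over the mid-transition
points (0.1 ≤ f_F ≤ 0.9 by default) yields ΔH and ΔS at the melting
temperature, with Tm = ΔH/ΔS the root of the line (equivalently
f_F = 1/2; the raw crossing is logged too and a >0.5 K discrepancy is
flagged).  ΔCp is taken as zero (ΔG linear in T) and heating is assumed
quasi-equilibrium.  f_F is clipped to [ε, 1−ε] (ε = 10⁻⁴) before the log.

**Bias structure.** The two-step procedure is exact only when the
baseline windows are pure: points inside a window that still carry a few
tenths of a percent of the other state tilt the fitted baseline and bias
ΔH at the ~1% level.  Window choice must therefore be adapted to the
transition width (the hot side needs more kelvin than the cold side —
the transition is symmetric in 1/T, not T).  The van't Hoff step itself is
exact: on noise-free folded fractions it recovers (ΔH, Tm) to <0.1%.

## Coarse-grained mechanics (`cg_model`, `brownian_dynamics`, `rigidity`)

**Reduced model.** Each residue contributes a pseudoatom at Cα plus one
side-chain bead for small residues or two (stem/tip split) for Arg, Lys,
Glu, Gln, Met, Trp, Tyr, Phe, His; Gly has none.  Side-chain beads sit at
the geometric centre of mapped heavy atoms (table in
`data/sidechain_beads.tsv`).  The exact placement rules of the original
reduced-model implementation are not published; this table is a documented
reconstruction, so absolute spring counts on real structures may deviate
at the ~1% level.  Hetero groups — including the haem — are excluded: the
prosthetic group has little influence on computed force constants.

**Elastic network.** All bead pairs strictly closer than 9 Å are joined by
identical springs (0.6 kcal mol⁻¹ Å⁻² = 0.42 N m⁻¹) relaxed at the input
geometry.  "Strictly closer" is a deliberate boundary convention; pairs at
exactly the cutoff are excluded.  Intra-residue pairs are joined like any
other ("all pseudoatoms").  Alternate locations resolve to the
highest-occupancy conformer.

**Dynamics.** The network is propagated with the first-order
Ermak–McCammon scheme, dr = (D/k_BT)F dt + N(0, 2D dt), 200 000 steps of
10 fs at 300 K by default (2 ns).  Free-draining dynamics (diagonal,
identical D per bead) is the default: hydrodynamic coupling (available via
the Rotne–Prager–Yamakawa tensor with uniform bead radius) changes
relaxation times but not the equilibrium averages the rigidity analysis
consumes.  Per-bead friction comes from Stokes' law at the chosen bead
radius (3 Å default) in water; like the hydrodynamics switch it affects
only time scales.  Trajectories are bit-reproducible under a fixed seed.

**Analytic oracle.** For any connected network the Boltzmann ensemble of
the harmonic model is Gaussian with covariance k_BT H⁺ (H the ENM Hessian,
pseudoinverse over the non-rigid modes; >6 near-zero modes ⇒ "floppy
network" error).  `sample_equilibrium` draws i.i.d. frames from this
ensemble.  These frames are statistically equivalent to an infinitely long
equilibrated BD trajectory and converge much faster per frame, so
tetramer-scale rigidity work defaults to ensemble sampling while BD–oracle
agreement (≤10% per residue on ≤50-bead toys) is verified in the test
suite.  The equivalence holds in the harmonic regime; soft collective
modes with large curvilinear amplitudes (e.g. loosely coupled rigid
bodies) genuinely depart from the Gaussian ensemble, which the stiffness
of the test networks is chosen to avoid.

**Rigidity profile.** For each pseudoatom i, d_i is its mean distance to
all beads j excluding (a) beads of i's own residue and (b), when i is a
Cα, the Cα of residues m±1 (whether the adjacent-Cα rule also covers
side-chain beads is ambiguous in the source description; it is a config
switch, default Cα–Cα only).  The effective force constant is

    k_i = 3 k_B T / ⟨(d_i − ⟨d_i⟩)²⟩,

averaged over post-equilibration frames (first 10% of BD frames
discarded — a documented deviation from averaging "over the whole
simulation"; i.i.d. ensemble frames are used in full).  The 3k_BT
prefactor follows the rigidity-profiling literature and is configurable;
it cancels in peak locations and in the sign structure of Δk.  A
residue's k is the mean over its beads, and the ordered per-residue
sequence is the rigidity profile.  Monomer ("domain-separated") profiles
restrict the partner set of d_i to the bead's own chain, removing
inter-subunit rigid-body contributions; Δk compares two profiles residue
by residue (default mapping: same chain label and residue number, or an
explicit alignment-derived mapping).  Globin helix-position labels (G3,
E11, …) are attached from a static table of canonical helix boundaries —
they are names, not a secondary-structure computation.

## Synthetic data (`synthetic_data`)

The generators stand in for instruments whose raw output is not
redistributable; each stores its ground truth in a sidecar so recovery
tests never re-derive truth from the generated data.

* **Elastic scans** — I(q²) = exp(−u²q²/6 + c₄·max(q²−q²_on, 0)²)·(1+η),
  u²(T) = intercept + slope·T, with multiplicative Gaussian noise η
  (counting statistics at high rates; CV 0.02 for solution-like scans).
  The optional curvature term beyond q²_on (default 3.5 Å⁻²) emulates the
  breakdown of linearity outside the initial-slope window.  Temperature
  grids mirror the instruments: stepwise 280–315 K points
  (solution), and a 10–300 K ramp binned at 5 K (powder).  Powder noise
  defaults to CV 0.005, the level whose propagated slope uncertainty in
  the 10–100 K window reproduces the published ±1.2 N m⁻¹ error on k₁.
* **Melting curves** — two-state closed form
  K = exp(−(ΔH/R)(1/T − 1/Tm)), signal = f_F·y_F + (1−f_F)·y_U + noise,
  with sloping baselines and additive noise scaled to the baseline
  separation at Tm (CV 0.01 default; baselines must stay >5× noise apart).
* **Toy structures** — deterministic Cα geometries (chain, puckered ring,
  ideal-helix bundles, two compact clusters plus sparse linker) plus a
  four-chain helix-bundle *tetramer stand-in* with exact 4-fold symmetry
  and a "softened" variant (one chain pulled 1.5 Å off the bundle axis).
  The stand-in is explicitly synthetic — it exercises tetramer-scale
  machinery (monomer separation, Δk) and makes no claim about real
  haemoglobin.

**What the generators do not emulate:** instrument resolution functions,
detector geometry, multiple scattering, D₂O background, aggregation or
irreversibility of melts, and real protein anharmonicity.  Passing
recovery tests therefore demonstrates correctness of the estimators under
the stated noise models, not robustness to every artefact of real data.

## Reference parameters and problem sizes

`workflows.py` carries the published per-species parameters (body and
melting temperatures, ΔH, ΔS, solution and powder force constants, RMSD at
T_b) used to parameterise the generators.  Recovery studies use 50
replicate seeds; the tetramer stand-in uses 4×30 residues and 2000
ensemble frames; BD–oracle checks use a 20-bead compact network with
200 000 steps of 5 fs — sizes chosen so each study's statistical error
sits comfortably inside the tolerance it is compared against.

## Known limitations

* Absolute rigidity values scale with the 3k_BT convention and the
  uniform spring constant; only relative features (peaks, Δk) are
  physically meaningful.
* The side-chain mapping is a reconstruction (above); spring counts on
  crystal structures carry a documented ±1% uncertainty.
* The two deoxy haemoglobin crystal structures themselves are not
  shipped; crystal-structure comparisons run only when the user supplies
  `data/structures/2DN2.pdb` and `1HBR.pdb`.
* Baseline-window choice remains the analyst's responsibility; the
  package flags degenerate baselines but cannot recover information a
  scan that ends mid-transition never contained.
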