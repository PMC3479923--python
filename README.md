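# hbflex

Haemoglobin adapts its internal dynamics to the body temperature of the
animal it comes from: stiffer molecules (higher resilience) pair with
higher melting temperatures, and the amplitude of thermal motion at body
temperature converges to an RMSD near 1.2 Å across species.  `hbflex` is a
toolkit for the three analyses behind that picture, aimed at people
working with backscattering spectrometers, CD spectropolarimeters, or
coarse-grained protein mechanics:

1. **Elastic neutron scans → resilience.**  Mean square displacements from
   the Gaussian approximation, I(q) = I₀ exp(−⟨u²⟩q²/6), fitted in fixed
   q² windows; the effective force constant ⟨k′⟩ = 0.00276/(d⟨u²⟩/dT)
   N m⁻¹; three-window fits for hydrated-powder scans; RMSD at body
   temperature.
2. **CD melting curves → two-state thermodynamics.**  Baseline correction
   to a folded fraction f_F, ΔG = −RT ln(f_U/f_F), and the line fit
   ΔG = ΔH − TΔS giving ΔH, ΔS and Tm = ΔH/ΔS.
3. **Structures → rigidity profiles.**  A reduced protein model (Cα plus
   one or two side-chain beads per residue), an elastic network joining
   all bead pairs closer than 9 Å with 0.6 kcal mol⁻¹ Å⁻² springs,
   Brownian dynamics (or direct Boltzmann-ensemble sampling), and
   per-residue force constants k_i = 3k_BT/var(d_i) from distance
   fluctuations — including domain-separated monomer profiles and
   Δk comparisons between homologous structures.

Because raw spectrometer and spectropolarimeter data are not
redistributable, `hbflex.synthetic_data` generates every input format with
known ground truth (seeded, with truth sidecars), and the test suite is
built on recovery studies against those truths.

See `docs/methods.md` for models, conventions and limitations.

## Worked example

Recover the human solution-state resilience and the melting
thermodynamics from synthetic data parameterised by the published values
(50 replicate datasets each):

```bash
hbflex reproduce neutron-demo --seed 1 --n-seeds 50 --out out/neutron
hbflex reproduce cd-demo --seed 1 --n-seeds 50 --out out/cd
```

prints (abridged):

```json
{
 "k_truth_N_m": 0.15,
 "k_recovered_N_m": 0.152513073259166,
 "k_recovered_sd": 0.018685979570724747,
 "rmsd_Tb_recovered_A": 1.2209061380720658
}
{
 "Tm_truth_C": 63.8,
 "Tm_recovered_C": 63.802057136176586,
 "dH_truth_kJ_mol": 320.0,
 "dH_recovered_kJ_mol": 320.1059877882764,
 "dS_recovered_kJ_mol_K": 0.9500045511189981
}
```

The generator→fit round trip recovers the resilience (0.153 ± 0.019 vs
0.15 N m⁻¹), the 1.22 Å RMSD at 36.6 °C body temperature, and the
calorimetric parameters (Tm 63.8 °C, ΔH 320 kJ mol⁻¹, hence
ΔS = ΔH/Tm = 0.950 kJ mol⁻¹ K⁻¹) within their replicate spread.

The pipeline pieces are also available individually:

```bash
hbflex cg-build --pdb my_structure.pdb --cutoff 9.0 --k 0.6 --out out/net
hbflex bd-run --network out/net --steps 200000 --dt 10 --temp 300 --seed 1 --out out/run
hbflex rigidity --traj out/run --network out/net --per-monomer --out out/prof
hbflex neutron-fit --scans scans.tsv --q2-min 1.6 --q2-max 3.5 --tb 309.75 --out out/nfit
hbflex cd-fit --curve melt.tsv --pre 20:45 --post 83:95 --out out/cdfit
hbflex simulate elastic|melt|structure --seed 1 --out out/sim
```

Every command writes a JSON manifest (inputs, seeds, conventions)
sufficient to re-run bit-identically; table outputs are TSV with a header
comment recording units and conventions.

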