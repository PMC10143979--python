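# dispermd

Desk-scale molecular-dynamics toolkit for screening drug–polymer
miscibility in amorphous solid dispersions.

The package bundles everything needed to run the screening workflow end
to end on a laptop:

- **a minimal MD engine** — OPLS-style Lennard-Jones + Coulomb potential
  with geometric combining rules, 1-2/1-3 exclusions and scaled 1-4
  pairs; harmonic bonds/angles and cosine dihedrals; steepest-descent
  minimization; Maxwell–Boltzmann velocity initialization; leap-frog
  integration with a stochastic velocity-rescale thermostat (NVT), an
  NVE validation mode, and an isotropic weak-coupling barostat (NPT);
- **analysis statistics** — time-averaged group–group interaction
  energies (E_coul / E_LJ / E_total), the energy ratio
  E(API–polymer)/E(API–API), geometric hydrogen-bond counting
  (donor–acceptor distance ≤ 3.5 Å and hydrogen–donor–acceptor angle
  ≤ 30°, boundaries inclusive), radial distribution functions,
  mean-squared displacement of molecular centres of mass with an
  Einstein-relation diffusion fit, and crystal density/lattice
  validation metrics;
- **a synthetic-system generator** — toy API archetypes
  (neutral-aromatic, ion-pair with counter-ion, small-neutral ester,
  hydroxyl-donor-rich) and excipient monomer archetypes, 10-monomer
  polymer chains, randomly packed mixture boxes at a prescribed API
  wt%, and replicated crystal supercells;
- **pipelines** — the API × excipient screening matrix, the loading
  comparison (e.g. 5 vs 50 wt%) and the temperature sweep
  (300/373/433 K), all fully seeded and regenerable from a plan file.

Internal units are nm / ps / kJ·mol⁻¹ / K / e / amu throughout; file
readers convert Å-based formats (PDB, XYZ) at the boundary.  The toy
molecule templates are chemically plausible stand-ins, **not**
parameterizations of real drugs; real systems can be supplied through
the documented text topology format.

## Command line

```sh
dispermd templates                      # list packaged molecule templates
dispermd build --api api_small_neutral --excipient exc_ester \
    --n-api 3 --wt 5 --density 0.65 --out mix      # mix.gro + mix.top
dispermd run --config run.toml          # minimize + MD (nve/nvt/npt)
dispermd energy --traj traj.bin --top mix.top \
    --group-a "resname SMN" --group-b "resname EPE" --window 2:10
dispermd rdf    --traj traj.bin --top mix.top --group "resname EPE"
dispermd hbonds --traj traj.bin --top mix.top \
    --group-a "resname SMN" --group-b "resname EPE"
dispermd msd    --traj traj.bin --top mix.top --group "resname SMN" \
    --origins multi
dispermd crystal                        # toy-crystal NPT validation
dispermd screen    --plan plan.toml --out results/
dispermd loading   --plan plan.toml --out results/
dispermd tempsweep --plan plan.toml --out results/
```

A minimal study plan (`plan.toml`):

```toml
[plan]
apis = ["api_small_neutral", "api_ion_pair"]
excipients = ["exc_ester", "exc_acid", "exc_aromatic"]
wt_levels = [5.0]
temperatures = [300.0]
seeds = [1, 2, 3]
equil_ps = 3.0
production_ps = 7.0
density = 0.65
cutoff_nm = 0.9
```

Selection expressions use a small grammar: `resname`, `element`,
`molid` (values OR-ed), combined with `and` / `or` / `not` and
parentheses.  Analysis windows accept `2:10` (ps) or `2ns:10ns`.

## File formats

- structures: PDB (ATOM/HETATM + CRYST1), GRO (3- or 9-field box line),
  XYZ;
- trajectories: multi-frame XYZ, multi-model PDB, and a documented
  little-endian binary format (`DMDT` magic; header layout in
  `dispermd/core/traj_io.py`);
- topologies: a section-based text format (`[meta]`, `[defaults]`,
  `[atoms]`, `[bonds]`, `[angles]`, `[dihedrals]`, `[pairs14]`,
  `[molecules]`, `[coords]`) documented in `dispermd/topology.py`;
- configs and plans: TOML (preferred) or YAML; keys ending in
  `_angstrom` are converted to nm on load.

## Notes on fidelity

Electrostatics use a real-space cutoff with an energy shift at r_c by
default (a plain non-mesh Ewald sum is available as a diagnostic for
small orthorhombic systems); group interaction energies use unshifted
real-space pairwise terms within the cutoff, the standard practical
convention for "interaction energy between groups".  The default LJ
cutoff is 1.4 nm with no long-range dispersion correction; pairs at
exactly r = r_c are included.  Cell-list and brute-force neighbor paths
produce bit-identical results by construction of their accumulation
order.
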