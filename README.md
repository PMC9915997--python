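# stromasim

Agent-based simulation of contractile stromal cells embedded in a
cross-linked fiber matrix beneath a deformable triangulated membrane,
together with the quantification pipeline used to characterise the
resulting wrinkles and fiber remodeling: membrane deformation / density /
alignment / order maps, two-cell migration metrics, wrinkle ridge
extraction and wrinkle index, FFT + stump-ensemble wavelength importance,
orientation alignment percentage, focal-adhesion polarity, and
ratiometric FRET images. Synthetic-data generators stand in for
microscope data, so everything runs offline.

## Model summary

All mobile points (fiber endpoints, cross-linker hinges, membrane
vertices, cell centres) obey overdamped Langevin dynamics integrated with
explicit Euler: `r(t+Δt) = r(t) + (F + F_T)/ζ · Δt`, with thermal forces
drawn per the fluctuation–dissipation relation (variance `2 k_B T ζ/Δt`
per component). Deterministic forces are harmonic extension, harmonic
angle bending (three-node hinges and membrane dihedrals), and short-range
harmonic volume exclusion between fiber segments and between fiber
segments and membrane triangles, distributed to element nodes so net
force and torque of the closest-approach point force are preserved.
Phantom cells bind fiber endpoints inside a spherical shell at a constant
rate, pull them with a constant force toward the cell centre (receiving
the opposite reaction, which drives migration), and unbind via a
catch-bond law `k_off = k_off0 · exp(−|F| x/k_B T)`. The rectangular
domain has repulsive walls; membrane perimeter vertices and near-wall
fiber endpoints are permanently anchored to faces, which move elastically
under the transmitted stress.

The protocol runs two phases: matrix self-assembly + relaxation (cells
inert), then membrane–matrix coupling, wall anchoring, and the
cell-interaction phase.

Internal units are pN–µm–s; configs use SI-flavoured units (N/m, N·m,
Pa, Pa·s) converted once at the boundary.

## CLI

```bash
# two-cell run from a named preset (desk-scale, minutes on one CPU)
stromasim simulate --preset reduced --d-c 12 --seed 1 --out out/run

# the initial-distance sweep preset
stromasim simulate --preset two-cell-sweep --seed 1 --out out/sweep

# full-scale configuration template (faithful printed parameters; the
# stability-bounded timestep makes this far too slow to actually run on a
# desktop — use it as a template or for short tests)
stromasim simulate --preset full --out out/full

# from a YAML config
stromasim simulate --config run.yaml --seed 2 --out out/custom

# maps + separation series from a finished run
stromasim analyze --traj out/run --maps deformation,density,alignment,order --grid 1.0

# image-side calculations
stromasim synth wrinkle --out w.tif --wavelength 50 --amplitude 10 --seed 0
stromasim morph index w.tif
stromasim morph align 350 10
stromasim synth fret --out-prefix f --seed 0
stromasim morph fret f.da.tif f.dd.tif --out ratio.csv
```

Run outputs: a legacy-ASCII VTK polydata series (fibers as lines,
membrane as polygons, cells as vertices), `scalars.csv` (per-stride cell
positions, separation, link counts, face offsets), `trajectory.npz`
(compact form read by `analyze`), and a lossless final-state snapshot.

### Notes on parameters

Printed model parameters (stiffnesses, rest lengths, repulsion constants,
cell radius/shell/force, on-rate, domain size, membrane height, d_c
values, phase durations) are the config defaults. Quantities the source
leaves to an unavailable parameter table are configurable with documented
defaults: medium viscosity (0.86 Pa·s), thermal energy (4.11e-3 pN·µm),
catch-bond `k_off0`/`x_bell` (required fields in YAML configs), boundary
modulus/thickness/rate, and matrix densities. The `reduced` preset
additionally softens extensional stiffnesses by documented factors so the
explicit-Euler stability bound allows a millisecond timestep; see its
docstring.

## Layout

- `src/stromasim/model_core.py` — element types, force kernels,
  closest-point geometry, drag/thermal forces
- `src/stromasim/assembly.py` — membrane triangulation, matrix seeding,
  cross-linking, membrane–matrix coupling, cell placement
- `src/stromasim/cell_dynamics.py` — binding/unbinding kinetics,
  contractile loading, cell motion
- `src/stromasim/boundary.py` — walls, anchoring, elastic face motion
- `src/stromasim/engine.py` — state container, stepper, two-phase protocol
- `src/stromasim/config.py` — versioned YAML schema and presets
- `src/stromasim/io.py` — snapshots, VTK/CSV/npz trajectory export
- `src/stromasim/sim_analysis.py` — gridded maps, separation series
- `src/stromasim/morphometrics.py` — image-side calculations
- `src/stromasim/synthetic_data.py` — synthetic fixtures
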