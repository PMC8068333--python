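# amideshell

Analysis toolkit connecting a peptide carbonyl group's hydration shell to
its vibrational frequency, built for MD-style trajectories:

- **trajectory_io** — multi-frame XYZ read/write, YAML topologies, named atom
  groups, orthorhombic minimum-image convention.
- **synthetic** — generators with known ground truth: a two-atom C=O
  oscillator with a piecewise-constant frequency schedule, hydration
  trajectories hitting scheduled hydrogen-bond counts with water-identity
  exchange, correlated scalar series, interaction-energy records in planted
  zones, Markov-switching backbone-torsion series.
- **hbond** — geometric hydrogen-bond detection (H···acceptor ≤ 2.5 Å,
  ≤ 45° deviation from linearity, both inclusive), per-group count series,
  combined distance–angle distributions with running integrals, per-frame
  water ranking (W1–W4), and water-bridge search over the hydrogen-bond
  graph (orders up to 7).
- **spectra** — power and IR spectra via autocorrelation + Fourier
  transform on a calibrated cm⁻¹ axis; resolution is
  `1/(c · pad_factor · depth · dt)`; parabolic peak refinement.
- **wavelet** — Morlet–Gabor continuous wavelet transform (σ = 8,
  ω₀ = 2π), time–frequency spectrograms, instantaneous-frequency ridge
  extraction, and sub-1500 cm⁻¹ jump filtering with rolling-median
  smoothing.
- **fragment_energy** — H-capped CONH fragment extraction, supermolecular
  interaction energies `E(AB) − E(A) − E(B)` through a pluggable backend
  (deterministic point-charge + Lennard-Jones toy model built in), k-means
  interaction zones (strong/moderate/weak), zone occupancy, and
  energy–frequency Pearson correlation.
- **conformation** — torsion angles, histogram free-energy surfaces
  `F = −k_B T ln(H/H_max)`, backbone-state assignment (α/β/L/other) and
  joint state probabilities.
- **pipeline / cli** — end-to-end orchestration producing a per-window
  report table (Fourier peak, wavelet mean, H-bond statistics, per-rank
  water energies, zone occupancy).

Units: Å, fs, cm⁻¹, kcal/mol, degrees; atom indices are 0-based.

## Tests

```sh
python -m pytest -q tests/
```

The suite includes brute-force oracles (direct O(n²) wavelet transform,
exhaustive hydrogen-bond/bridge enumeration, two-pass Pearson) checked
against the production implementations, property tests, and
`tests/test_acceptance.py` with the end-to-end three-window recovery
scenario.

## CLI

The `amideshell` entry point exposes thin wrappers over the library:

```sh
amideshell synth oscillator --segments "0:8000:1600,8000:16000:1594" --dt 0.5 --out osc.xyz
amideshell synth hydration  --segments "0:8000:1.0:0.002" --dt 0.5 --out hyd.xyz
amideshell hbond    --traj hyd.xyz --topology top.yaml --dt 0.5 --group "C2=O2" --out hb.tsv
amideshell spectrum --traj osc.xyz --dt 0.5 --kind power --range 1500:1700 --out spec.tsv
amideshell wavelet  --traj osc.xyz --dt 0.5 --band 1000:2200 --out instfreq.tsv
amideshell fragment --traj hyd.xyz --topology top.yaml --dt 0.5 --bond 1,3 --out frag.xyz
amideshell zones    --records records.tsv --k 3 --out zones.tsv
amideshell rama     --angles angles.tsv --out fes.tsv
amideshell run      --config config.yaml --out report.tsv
```

Exit codes: 0 success, 2 validation/config error, 1 stage failure.
All tabular output is TSV with a one-line header.

Example pipeline config (`config.yaml`):

```yaml
seed: 2148
dt: 0.5
windows: [[0, 8000], [8000, 16000], [16000, 24000]]
frequency_segments: [[0, 8000, 1600], [8000, 16000, 1594], [16000, 24000, 1584]]
hydration_segments: [[0, 8000, 1.0, 0.002], [8000, 16000, 1.5, 0.002], [16000, 24000, 2.0, 0.002]]
oscillator: {noise_sd: 0.003}
```

Instead of synthetic schedules, `input: {trajectory: traj.xyz, topology:
top.yaml}` analyzes an existing trajectory.

## Notes

- The energy backend is a contract (`evaluate(geometry) -> kcal/mol`); the
  shipped toy model reproduces qualitative hydrogen-bond physics (single
  minimum near 1.8 Å, repulsive wall, ~r⁻³ long-range falloff), not
  quantum-chemical magnitudes. External engines can be adapted behind the
  same interface.
- Instantaneous frequencies use the plane-wave ridge conversion
  ν = ω₀/(2πs) (exactly 1/s at ω₀ = 2π); the wavelength-based
  effective-frequency factor (1.01/s) is available separately as
  `wavelet.scale_to_frequency`.
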