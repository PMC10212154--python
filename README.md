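# mocapkit

A toolkit for marker-based motion-capture analysis and synthesis:

- **skeleton_io** — read/write hierarchical skeleton + motion files
  (standard BVH; the CMU ASF/AMC dialect for reading).
- **kinematics** — forward kinematics, instantaneous angular velocities,
  root-relative coordinates, the five-part body partition and the
  96-dimensional three-channel point-cloud feature per frame.
- **reconstruction** — 11-parameter DLT camera model with polynomial lens
  distortion, linear calibration, multi-camera triangulation by
  uncertainty minimization, two-step iterative distortion refinement, and
  per-point / per-marker / whole-set uncertainty statistics.
- **convrbm** — convolutional restricted Boltzmann machine (Gaussian or
  Bernoulli visibles) trained by contrastive divergence; low-dimensional
  per-frame embeddings; threshold-filtered similar-frame detection.
- **motion_graph** — motion-graph construction over candidate transition
  pairs, bottleneck-similarity transition selection, and blended
  synthesis with a linear window (quaternion slerp for rotations).
- **waveform_stats** — mean-shift alignment and the coefficient of
  multiple correlation (CMC) for comparing joint-angle waveforms from two
  measurement systems.
- **synthetic** — deterministic generators for every stage: humanoid
  skeletons, styled cyclic motions (walking / running / jumping),
  multi-camera rigs with known distortion, noisy marker observations, and
  paired two-system waveforms with closed-form expected CMC.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (exact DLT
recovery, the uncertainty identity, noise scaling, distortion recovery,
enumeration-exact RBM likelihoods, CD learning signal, brute-force
similar-frame equivalence, transition contracts, CMC recovery, and
end-to-end determinism), one test per criterion.

## CLI

All functionality is exposed through the `mocap` command; every
subcommand is a thin wrapper over a library function and honors `--seed`
wherever randomness exists.

```sh
# synthetic fixtures
mocap simulate motion --style walking --n-frames 240 --seed 42 --out walk.bvh
mocap simulate rig --n-cameras 8 --seed 42 --out rig.json
mocap simulate waveforms --seed 42 --out waveforms.csv

# file conversion and features
mocap convert --in subject.asf --amc trial.amc --out trial.bvh
mocap features --in walk.bvh --interval 1 --reference root --out walk.h5

# reconstruction
mocap triangulate --cameras rig.json --obs obs.csv --out points.csv --report uncertainty.json

# embedding + matching + synthesis
mocap train --features walk.h5 --features run.h5 --epochs 15 --seed 42 --out model.h5
mocap match --model model.h5 --a walk.h5 --b run.h5 --threshold auto --out pairs.csv

# waveform agreement
mocap cmc --a optical.csv --b inertial.csv --align --out cmc_report.csv

# full pipeline: simulate -> features -> train -> match -> graph -> transition
mocap run --seed 42 --from walking --to running --out run_dir/
mocap transition --run-dir run_dir/ --from walking --to running --window 30 --out blend.bvh
```

`mocap run` accepts `--config cfg.json` with any subset of the config
keys (unknown keys are rejected); reruns with the same config and seed
are bit-identical.

## Conventions

- Angles are stored in degrees everywhere (BVH convention); radians only
  appear inside kinematics.
- World frame is right-handed, Z-up; Euler rotations compose
  intrinsically in each joint's declared channel order.
- The DLT denominator convention is `L9*x + L10*y + L11*z + 1`.
- Distortion coefficients (k1, k2, p1, p2) act on coordinates normalized
  about the principal point by half the image width.
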