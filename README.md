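# endosfm

Self-supervised estimation of dense depth, SE(3) ego-motion and pinhole
camera intrinsics from monocular video, with a plane-sweep cost-volume
branch as auxiliary supervision for the intrinsic predictor. Aimed at
endoscopic footage, where no calibration is available and the light
source moves with the camera; everything runs on CPU with NumPy, on the
package's own reverse-mode automatic-differentiation engine.

## The problem

A monocular video determines its own geometry only up to scale — and if
the camera is uncalibrated, the intrinsics must be estimated too. The
training signal is photometric: predict depth for a centre frame, the
rigid motion to each neighbour, and the intrinsics; inversely warp the
neighbour through that geometry; and minimise the reconstruction error.
Two complications drive the design:

- **Brightness is not constant.** In endoscopy the illumination moves
  with the camera, so an appearance-flow network predicts a per-pixel
  brightness calibration field that is added to the target before
  comparison, with a smoothness penalty so it cannot absorb geometry.
- **Intrinsics are weakly observable.** Focal length and rotation rate
  trade off almost exactly in the photometric loss. A plane-sweep cost
  volume — built by warping source features through fronto-parallel depth
  hypotheses using the *predicted* intrinsics — yields a second depth
  estimate; a consistency loss between it and the network depth gives the
  intrinsic heads a direct geometric gradient.

See `docs/methods.md` for the models, losses and the observability
analysis behind the self-calibration study.

## Worked example

Ground-truth geometry reconstructs the target almost exactly, and a wrong
focal length measurably degrades it (`examples/01_geometry_and_losses.py`):

```
$ python examples/01_geometry_and_losses.py
valid pixels: 94.5%
mean |warped - target| on valid pixels: 0.00022
data-fidelity loss, true intrinsics:      0.01066
data-fidelity loss, focal x 0.8:         0.01124
data-fidelity loss, focal x 1.2:         0.01111
```

Training end to end on a synthetic sequence
(`examples/02_train_and_evaluate.py`, a smoke-scale run, ~2 min CPU):

```
$ python examples/02_train_and_evaluate.py
steps: 30   first loss 0.0166   last loss 0.0063
abs_rel (mean over snippets): 0.1170
delta_1 (mean over snippets): 85.4546
```

(delta_1 is reported in percent.)

Recovering the camera from image data alone
(`examples/03_self_calibration.py`, ~4 min CPU per arm; rendering camera
fx=0.82, fy=1.02, cx=cy=0.5):

```
$ python examples/03_self_calibration.py 0
[cost-volume ON ] seed 0
  fx 0.9391 (gt 0.82)   fy 0.9417 (gt 1.02)   cx 0.4944   cy 0.5031
  focal rel. error 11.1%   cx abs 0.0056   cy abs 0.0031
  final loss 0.0001
[cost-volume OFF] seed 0
  fx 0.9828 (gt 0.82)   fy 0.9894 (gt 1.02)   cx 0.4990   cy 0.5009
  focal rel. error 11.4%   cx abs 0.0010   cy abs 0.0009
  final loss 0.0001
```

Over the five pre-declared study seeds, the recovered medians are
fx error 10.2%, fy error 12.8%, cx error 0.0056 and cy error 0.0057
(computed by `tests/test_acceptance.py`).

## Command line

```
endosfm synth OUT_DIR [--surface plane|tilted_plane|sphere ...]
endosfm train DATA_DIR [--config cfg.yaml --checkpoint-dir D --log L]
endosfm evaluate CHECKPOINT DATA_DIR [--cap C]
endosfm predict CHECKPOINT DATA_DIR --out OUT_DIR
endosfm calibrate [--seed S --steps N --cost-volume/--no-cost-volume]
```

## Reproduction

- `python -m pytest tests/` runs the full suite: unit and property tests
  for every module plus `tests/test_acceptance.py`, whose tests verify
  the warp against a per-pixel oracle, the loss identities and scalar
  oracles, plane-sweep depth recovery, median-scaling invariance and
  metric closed forms, the learning-rate schedule, training-loss descent
  over 5 seeds, the 5-seed intrinsic-recovery study (cost-volume on vs
  off on the same pre-declared seeds), and deterministic checkpoint
  resume. The recovery study dominates the runtime (the full suite takes
  about 13 minutes on one CPU core). One acceptance test is
  a known honest failure: the cost-volume on-vs-off focal comparison is
  within seed noise at this study size — it held on five held-out
  validation seeds (10.1% vs 13.5% median focal error) but not on the
  five pre-declared acceptance seeds (11.5% vs 9.9%). The test is kept
  as stated rather than weakened; see the limitations in
  `docs/methods.md`.
- `python scripts/acceptance.py --seed 0 --out results.json` runs the
  same computations end to end for one seed and writes the quantities
  (oracle differences, recovery fractions, losses, recovered intrinsics
  with and without the cost-volume consistency) as JSON.

All data is synthetic and rendered programmatically; the same seed gives
bit-identical sequences, so every number above is reproducible exactly.
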