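# softinverse

Non-destructive recovery of hidden physical parameters in soft bodies from
surface deformation.  Given the trajectories D of a few tracked surface
keypoints under a known load program, `softinverse` builds a finite-element
*virtual twin* of the object and finds the material moduli M together with
the position P and shape S of a stiff internal abnormality that make the
simulated trajectories D̂ match the observation:

    M*, P*, S* = argmin ‖D − D̂(M, P, S)‖²

The minimization is gradient-free parallel Bayesian optimization: a
random-forest surrogate of the loss, the moment-generating-function (MGF)
acquisition

    M(x, t) = Φ((L_min − L̂′)/s) · exp((L_min − L̂ − 1)t + s²t²/2),  L̂′ = L̂ − s²t

with temperatures t ~ Lognormal(0, 1) balancing exploration against
exploitation, and a batch of q candidates per iteration, each maximizing
its own tempered criterion with an evolution strategy.  The forward solver
supports nearly-incompressible Neo-Hookean hexahedra (with mean-dilatation
volumetric treatment), incompressible Neo-Hookean membranes with follower
pressure, quasi-static and implicit-dynamic (Newmark) stepping, and a
Saint Venant-Kirchhoff variant for cross-model tests.

Intended users: researchers in soft-tissue biomechanics and soft robotics
who want to prototype deformation-based parameter identification — e.g.
locating and grading a stiff (calcified) region in a valve-like membrane
from a few tracked points — without coupling to a large external FE stack.

Three benchmark families ship with printed ground truths: a bending
**beam** with a brick inclusion, an inflated **balloon** with an
irregularly shaped stiff patch (revolved-curve generator
R(θ) = R₀(1 + C₁cos4θ + C₂cos8θ)), and a simplified parametric **valve**
whose material is summarized by the arterial stiffness AS = E·T.
Observations are generated by the package's own solver ("inverse-crime"
mode), optionally with additive Gaussian noise.

## Worked example

Recover the base modulus of the homogeneous beam from its own synthetic
observation:

```bash
softinverse forward beam_case1 -o tracks.csv --preset desk
softinverse invert beam_case1 --observed tracks.csv -o result.json \
    --budget 100 -q 4 --seed 5
softinverse report result.json
```

which prints (the inverse run takes about a minute on one CPU):

```
case: beam_case1 (preset desk)
final loss: 4.625483e-10 after 92 evaluations
estimates:
  E_a  = 1e+06
  C    = 40
  W    = 10
  E_b  = 999.999   (rel. error 0.000%)
```

`E_b` is the recovered Young's modulus in Pa (truth 1e3 Pa); the fixed
parameters of the case are echoed alongside.  The final loss is the squared
keypoint-trajectory mismatch in mm²; the run stopped early because it fell
below the convergence tolerance.  The same workflow applies to
`beam_case4` (all of E_b, E_a, C, W unknown), the balloon cases (add
`softinverse evaluate result.json` to score the recovered abnormality
shape against the truth by spherical-map SSIM), and the valve cases
(reported as arterial stiffness).

Python API: `softinverse.cases.get_case`, `generate_observation`,
`softinverse.pipeline.run_inverse`, `softinverse.bayesopt.optimize`.

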