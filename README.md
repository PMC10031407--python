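# wingsense

Insect wings are sensors as well as aerofoils: strain-sensitive organs
(campaniform sensilla) scattered over the wing report its deformation, and
flies and moths use that feedback to detect body rotations mid-wingbeat.
How well this works depends not only on the sensors but on the *structure*
they sit in — the wing's stiffness gradient and damping shape the strain
field that the sensors read.

`wingsense` is a self-contained computational pipeline for studying this
question.  It needs no external data: a structural model generates the
strain, a neural encoder turns it into spikes, and a sparse-optimisation
stage finds the best sensor locations.

1. **Wing model** — a hawkmoth-scale rectangular plate (50 mm span, 25 mm
   chord, 127 µm thick, ρ = 1180 kg m⁻³, ν = 0.35) modelled with
   C¹-conforming Kirchhoff plate finite elements, clamped at the base.
   Young's modulus is uniform or declines log-linearly from the
   leading-edge base to the trailing-edge tip,
   E(x, y) = E_c·10^(−m_x x − m_y y) / mean(·), spanning two orders of
   magnitude at the measured decline rate m_x = m_y = 26.67 m⁻¹.  The wing
   flaps as φ(t) = A₁ sin(2πf₁t) + A₂ sin(2πf₂t) (A₁ = π/12, f₁ = 25 Hz,
   A₂ = π/60, f₂ = 50 Hz) while the body optionally rotates at 1 rad s⁻¹
   about roll, pitch or yaw; rigid-body inertial loads (Euler, centrifugal
   and Coriolis terms) drive the plate in its co-rotating frame.  Viscous
   damping follows c = 2ζmω_n with ζ ∈ {0.2, 1, 2} and ω_n recomputed per
   stiffness configuration.  Time integration is backward Euler (BDF-1) at
   Δt = 0.2 ms.
2. **Neural encoding** — at every node of the 26 × 51 grid (1 mm spacing),
   spanwise strain is convolved with a damped-cosine feature
   f(t) = cos(2πω(t+τ))·exp(−(t+τ)²/δ²) (ω = 1/2π ms⁻¹, τ = 5 ms,
   δ = 4 ms), passed through the sigmoid N(g) = 1/(1+exp(−α(g−β)))
   (α = 5·10⁵, β = 10⁻⁴), and spikes are drawn per 0.1 ms bin against
   uniform variates under a 15 ms refractory period.  The readout is the
   first-spike latency per wingbeat (0 = no spike), 100 trials per
   condition.
3. **Sensor placement (SSPOC)** — standardise the pooled training
   latencies, take an m = 3 PCA basis Ψ, find the LDA direction w in that
   subspace, then solve
   s = argmin λ‖s′‖₁ + (1−λ)‖s′‖₂² s.t. Ψᵀs′ = w (λ = 0.9) and keep the
   10 largest-|s| nodes.
4. **Evaluation** — midpoint-boundary LDA on the raw latencies of the
   selected sensors, trained on 90% of trials, scored on the held-out 10%;
   repeated over 20 iterations.  Placement sensitivity is
   acc_optimised / acc_random − 1.
5. **Modal analysis** — POD/SVD of the strain wingbeat into spatial and
   temporal modes, and detection accuracy as a function of the number of
   modes retained.

## Worked example

```bash
python examples/04_evaluate_accuracy.py
```

prints (gradient-stiffness wing, mean stiffness 3 GPa, overdamped, yaw
rotation at 1 rad s⁻¹):

```
optimised sensors: accuracy 0.960 +/- 0.010 (mean +/- SEM over 20 iterations, 20 held-out trials each)
random sensors:    accuracy 0.588 (mean over 20 random 10-sensor draws per iteration)
placement sensitivity: 0.63 (0 = placement-agnostic, 1 = fully placement-dependent)
mean spanwise sensor location: 0.46 (fraction of span from base to tip)
```

Ten well-placed spiking sensors detect a 1 rad s⁻¹ yaw rotation — whose
strain signature is hundreds of times smaller than the flapping strain —
almost perfectly, while random placements hover near chance: sensing
performance is a property of the wing's structure, not just of the
sensors.  The other examples walk through each stage: `01` the strain
simulation, `02` the spiking encoder, `03` the sparse placement, `05` the
modal analysis.  A thin CLI (`wingsense simulate / encode / place /
evaluate / modes / sweep / report / fixture`) exposes the same pipeline
for scripted experiments with YAML configs.

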