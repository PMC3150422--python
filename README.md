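# rirrsim

Agent-based simulation of mitochondria-driven ROS propagation
(ROS-induced ROS release, RIRR) in a 2D cell.

Mitochondria leak superoxide (O₂⁻) during respiration. ROS in turn damage
mitochondria and raise their leak rate, so a local oxidative insult can
propagate through the mitochondrial network as a positive-feedback wave —
RIRR. Whether that wave is carried by short-lived, poorly
membrane-permeant O₂⁻ or by long-lived, permeant H₂O₂ depends on the
network's geometry: its density, regularity, motion and clustering.
`rirrsim` lets you build those networks, run the stochastic model, and
quantify dose-response curves, RIRR thresholds, and messenger kinetics.
It is aimed at systems-biology modelers studying inter-organelle
signaling and oxidative-stress sensitivity.

## Model in brief

A cell is a pixel grid with mitochondria as 54 × 54 px squares. O₂⁻,
H₂O₂, Mn-SOD, CuZn-SOD and Gpx are point agents; each step every agent
moves per axis by `max_speed · U(−0.5, 0.5)` and ROS cross mitochondrial
membranes with predefined probabilities. Reactions fire on pixel
co-location: SOD converts O₂⁻ → H₂O₂, Gpx removes H₂O₂. Each
mitochondrion draws `Poisson(0.01·area)` respiration events per step and
leaks one O₂⁻ per event with probability

    p(z) = a₀ + a₁ · (σ(z − c) − σ(−c)) / (1 − σ(−c)),
    z = 0.01·n(H₂O₂) + 0.09·n(O₂⁻),

a shifted, normalized logistic rising from the 1 % normal-respiration
leak (a₀) to the 20 % damaged-mitochondrion ceiling (a₀ + a₁), with the
counts taken inside that mitochondrion. A mitochondrion with more than 50
O₂⁻ agents is *reactive*; the headline observable is the percent of
reactive mitochondria, reported as mean ± sd over five seeded replicates
of 3000 steps. Dose-response curves (reactive fraction vs initial H₂O₂
bolus or an antioxidant multiplier) are fit with second- or third-order
polynomials `y = A + Bx + Cx² (+ Dx³)`, and the **RIRR threshold** is the
dose at which the fit reaches 20 % reactive mitochondria. Messenger reach
uses the 2D random-walk law ⟨x²_N⟩ = 2NL².

See `docs/methods.md` for the full model, parameter table conventions,
calibration decisions and known limitations.

## Worked example

Leakage rule and messenger kinetics from the command line:

```text
$ rirr leak --ns 0 --nh 0
0.010000 (1.0000%)          # quiet mitochondrion: 1% electron leak
$ rirr leak --ns 1000000 --nh 0
0.200000 (20.0000%)         # saturated (damaged): 20%
$ rirr lifetime --species O2minus --spontaneous-only
{
 "species": "O2minus",
 "p_total": 0.00769,
 "lifetime": 130.03901170351105,
 "step_scale": 11.66,
 "reach": 188.04005881491247
}
$ rirr lifetime --species H2O2 --spontaneous-only
{
 "species": "H2O2",
 "p_total": 1e-05,
 "lifetime": 99999.99999999999,
 "step_scale": 11.31,
 "reach": 5057.985765104524
}
```

By spontaneous decay alone, O₂⁻ survives ~130 steps and diffuses ~188 px
(≈ 3 inter-mitochondrial gaps), while H₂O₂ survives 10⁵ steps and out-ranges
the whole cell — the kinetic asymmetry behind the messenger switch. With the
standard enzyme complements the contrast persists: O₂⁻ reaches ~79 px, H₂O₂
~822 px.

A small simulation end to end (the bundled mini fixture: 3 × 3 lattice,
200 steps, 2 replicates, 300-agent H₂O₂ bolus):

```text
$ rirr fixture -o mini && rirr simulate -c mini/config.yaml -o mini/out
wrote mini/out/metrics.csv (seeds [0, 1])
```

`metrics.csv` holds one row per (replicate, step) with the reactive
fraction, species counts, and source/sink event counters;
`reactive_fraction_mean.csv` the per-step mean ± sd. A full-size run uses
a config with `layout: {name: regular}` and default parameters
(`python -c "from rirrsim.config import RunConfig; RunConfig().dump('cell.yaml')"`),
and `rirr sweep … --variable initial_H2O2` + `rirr threshold` produce
dose-response curves and RIRR-threshold estimates. `rirr render` writes
snapshots (mitochondria red, H₂O₂ white, O₂⁻ green on black).

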