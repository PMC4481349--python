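# lipidgate

Geometric post-processing of molecular-dynamics trajectories of lipid
substrates in multi-pocket enzyme binding sites, built around the fatty
acid amide hydrolase (FAAH) analysis problem: where does a fatty-acid
amide's acyl chain sit among the membrane-access (MA) channel, the
acyl-chain-binding (AB) channel and the MA/AB transition (T) region; what
shape does the chain adopt; how do the gating residues of the *dynamic
paddle* (Phe432/Trp531) rotate; and how often is the enzyme–substrate
geometry favourable for hydrolysis.  The package also fits the matching
bench kinetics (Michaelis–Menten saturation and competition-assay decays)
and ships a seeded synthetic-trajectory generator so every stage can be
exercised, tested and benchmarked without multi-microsecond MD data.

It is aimed at computational structural biologists who already have
unwrapped trajectories (multi-model PDB natively; XTC/DCD/TRR with a PDB
topology) and want reproducible occupancy/conformation statistics, and at
enzymologists fitting saturation and competition assays.

## The core quantities

**Pocket occupancy.**  Per frame, the minimum distances between the centre
of mass of the acyl chain's last three heavy atoms and the residue-group
centres of mass lining each pocket are computed:

- *d*-MA — MA channel group (Asp403, Ile407, Arg486, Ile530),
- *d*-AB — AB channel group (Tyr335, Glu373, Arg428, Phe527),
- *d*-T  — transition-region group (Phe381, Phe432, Trp531).

The frame is labelled **MA** if *d*-MA < 6 Å and *d*-AB > 6 Å, **AB** if
*d*-MA > 6 Å and *d*-AB < 6 Å, otherwise **T** if *d*-T < 5 Å; frames with
all three distances beyond a configurable not-bound threshold (12 Å) are
**NB**, and anything left is UNASSIGNED.  The 6/6/5 Å defaults reflect the
~16/17 Å separation of the MA and AB group centres.

**Chain shape.**  Torsions ω over every four-atom window of the declared
chain path are mapped onto an Applegate–Glomset-style taxonomy: elongated
(Ex, Uex), hooked (J, J′) and curved (U, Hx, Hx-A/B).  Saturated chains,
which lack a discriminating torsion signature, fall back to an
end-to-end/contour length-ratio rule.

**Dynamic paddle and pre-reactive states.**  The side-chain torsions about
the Cα–Cβ axes of Phe432 (φF) and Trp531 (φW) are reported in [0°, 360°);
φF ≈ 65° marks the closed MA gate and φF ≈ 150–180° the open gate.  A
frame is *pre-reactive* when a configurable set of near-attack criteria
holds (by default: nucleophile-attack distance Ser241:Oγ–carbonyl C
≤ 4.0 Å, attack angle Oγ···C=O within 75–115°, two oxyanion-hole H-bonds
≤ 3.5 Å — package defaults, meant to be overridden per system).
Occupancies, pre-reactive cross-tabs, MA↔AB transfer counts and gate-flip
counts are aggregated after a configurable equilibration cutoff and pooled
over the two monomers of the homodimer.

**Kinetics.**  v = V·S/(Km+S) by nonlinear least squares (Hanes–Woolf
start), simple exponential decays y = A·e^(−kt) (+ optional plateau) for
competition time courses, and substrate-selectivity ratios k₁/k₂ with
propagated standard errors.

## Worked example

Generate a 5,000-frame synthetic trajectory (Markov pocket hopping with
stationary distribution 24/68/7/1 % over MA/T/AB/NB, per-state shape and
gating-angle emissions, per-state pre-reactive injection 0.10/0.40/0.05/0)
and analyse it:

```sh
lipidgate simulate --output demo --seed 1 --n-frames 5000
lipidgate make-config --output demo/pipeline.yaml --fixture demo
lipidgate occupancy --config demo/pipeline.yaml
```

prints, among other fields,

```
"percent": {
  "AB": 6.34,
  "MA": 25.16,
  "NB": 0.78,
  "T": 67.72,
  "UNASSIGNED": 0.0
}
```

— the recovered pocket occupancy, within sampling error of the
generator's stationary distribution.  `lipidgate prereactive --config
demo/pipeline.yaml` reports the pre-reactive statistics:

```
"overall_pct": 31.12,
"conditional_pct": {"MA": 8.35, "T": 90.36, "AB": 1.29}
```

i.e. 31 % of frames are pre-reactive (closed form for these generator
settings: 30.0 %), and among them 90 % sit in the transition region —
the T-heavy pattern the per-state injection probabilities encode.
`lipidgate report --config demo/pipeline.yaml --output demo/out` writes
the full machine-readable bundle (report.json, per-frame and polar CSVs).

For bench data, `lipidgate kinetics-fit --input mm.csv --kind mm` fits a
saturation curve from a `concentration_uM,velocity` table and prints Km
and Vmax with standard errors.

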