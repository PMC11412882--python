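# nnsim — natural-number simulation of biochemical reaction networks

`nnsim` simulates stoichiometric reaction networks while keeping every
molecule count an exact natural number — from a single gene copy to 2×10²⁴
water molecules in the same framework.  It is aimed at systems-biology
modelers who want discrete, stochastic time courses (gene circuits, enzyme
kinetics, ionization equilibria) from nothing more than stoichiometry, rate
constants and initial counts, without writing differential equations or a
full chemical-master-equation propensity model.

## The method

Each step, every reaction `q1·X1 + q2·X2 + … -> r1·Y1 + …` draws

```
B ~ Binomial(n, p),   n = floor(min_i X_i/q_i),
p = Π_{i≠lim} (k·X_i/(q_i·N)) / (1 + k·X_i/(q_i·N)),
```

and counts change by `ΔX_i = −q_i·B`, `ΔY_j = +r_j·B`.  The limiting
reactant sets the trial count, so counts can never go negative; the
normalization parameter `N` divides counts inside `p`, making rate
constants transferable across system sizes.  Single-reactant reactions use
`p = k/(1+k)`; linear in/outflow families make one trial per step.  Draws
beyond the 64-bit sampler range switch to a moment-matched normal
approximation.  Because each draw is binomial, every event also has a
well-defined self-information `−log2 pmf(B; n, p)` and entropy, which the
analytics module accumulates per reaction.

Details, defaults and design choices: [`docs/methods.md`](docs/methods.md);
the model-file dialect: [`docs/format.md`](docs/format.md).

## Worked example

Water ionization `H2O <-> H+ + OH-` with rate constants derived from flux
balance so that pure water is neutral:

```python
from nnsim import examples, run
from nnsim.analytics import pseudo_ph

model = examples.build_water(N=2e19)       # 2e19 water molecules, ions at 0
trajectory = run(model, seed=1)
final = trajectory.final_counts()
print(final["H+"], final["OH-"])
print(pseudo_ph(final))
```

```
1999998792450 1999998792450
7.000000218786806
```

Starting from zero ions, dissociation and recombination balance at about
2×10¹² ions — a proton-to-water ratio of 10⁻⁷, i.e. pseudo-pH ≈ 7 (the
single-step value above fluctuates in the seventh decimal; the tail-averaged
value is 7.0000000).  The same rate constants equilibrate a 2×10²⁴-molecule
system to the same pH.

The same models run from the shell:

```sh
nns example michaelis_menten            # write michaelis_menten.txt
nns run michaelis_menten.txt --seed 42 --out-dir out --info
```

which writes `trajectory.csv`, per-reaction `info_*.csv` / `entropy_*.csv`
and the requested plots.  Six ready-made systems ship under `examples/`:
irreversible binding, water ionization, Michaelis–Menten kinetics,
cooperative O₂–hemoglobin binding, a one-gene negative-feedback loop and a
two-stimulus feed-forward loop.

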