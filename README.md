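# fermsurro

Surrogate-model optimization of microbial fermentation conditions:
uniform experimental design, a quadratic stepwise-regression baseline, and
a genetic-algorithm-optimized back-propagation neural network.

## The problem

Strains that secrete hard-to-quantify bioactive compounds — here an
algicidal actinomycete whose broth kills the bloom-forming alga
*Phaeocystis globosa* — are awkward to optimize: the active compound has
no direct assay, so a bioassay proxy (the **algicidal ratio**,
(F₀ − F_t)/F₀ from chlorophyll fluorescence of treated vs control
cultures) stands in for its concentration, alongside **dry mycelial
weight** (g/100 mL broth) for biomass. Both responses over five factors —
starch (8–22 g/L), NaNO₃ (0.3–1.7 g/L), inoculum size (3.5–10.5 % v/v),
initial pH (3.5–10.5) and fermentation time (60–228 h) — are screened with
only 15 runs by a uniform design U₁₅(15⁵), in which every factor visits
each of its 15 equally spaced levels exactly once and the runs are spread
to minimise the centered L₂-discrepancy.

Two models are then fitted to the 15 runs and each is maximised over the
factor box:

1. a **quadratic response surface**
   y = b₀ + Σᵢ bᵢXᵢ + Σᵢ bᵢᵢXᵢ² + Σ_{i<j} bᵢⱼXᵢXⱼ,
   with terms chosen by partial-*F* stepwise selection or fixed in advance;
2. a **5–h–1 feed-forward network** whose weights and thresholds are first
   sought by a real-coded genetic algorithm (fitness = sum of absolute
   training errors) and then refined by back-propagation; a second GA run
   searches the condition box for the input maximising the trained
   surrogate's prediction.

The package ships the 15-run dataset, the two published regression
equations and the verification-table constants as fixtures, plus a
synthetic response-surface generator for testing the whole protocol
against known ground truth.

## Worked example

Refit and maximise the published dry-weight response surface:

```sh
$ python -c "import fermsurro as fs; fs.load_table1().to_csv('table1.csv')"
$ fermsurro regress table1.csv --response Y2 --mode published --optimize
Y2 model (13 terms):
  intercept = -0.543313758
  X1       +0.02295247367
  ...
  optimum: [16.3066, 1.35, 10.5, 5.4097, 228.0] -> 0.2598 g/100 mL
  note: factor(s) X2 appear in no term; the optimum is unconstrained in them
```

The surface peaks at 0.2598 g/100 mL with 16.31 g/L starch, pH 5.41, and
inoculum size and fermentation time pinned at their upper bounds (10.5 %,
228 h) — boundary extremes being a known weakness of quadratic surfaces on
small designs. NaNO₃ (X2) survives in no term of this model, so the
optimum does not constrain it.

Train the GA-initialised network surrogate and search its optimum:

```python
import fermsurro as fs

data = fs.Dataset.from_frame(fs.load_table1())
factors = fs.load_factors()
bounds = [(f.minimum, f.maximum) for f in factors]

net = fs.BPNetRegressor(n_hidden=9, random_state=1).fit(data.X, data.y2)
print(f"final training MSE (scaled): {net.loss_trace_[-1]:.2e}")
conditions, value = net.maximize(bounds, seed=2)
print(f"predicted dry mycelial weight: {value:.4f} g/100 mL")
```

prints

```
final training MSE (scaled): 9.98e-07
predicted dry mycelial weight: 0.2483 g/100 mL
```

The network interpolates all 15 runs (training MSE reaches the 1e-6 goal)
and its box optimum lands near the best observed run (0.2283 g/100 mL)
rather than extrapolating beyond it — the saturating output unit bounds
predictions to the neighbourhood of the observed response range.
`fermsurro run` executes the full protocol (regression baseline, optional
hidden-neuron scan, GA-BP training, GA condition search) for both
responses from one command.

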