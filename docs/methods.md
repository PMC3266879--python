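# Methods

## The model

A single postsynaptic cell receives feed-forward input from `N_E`
excitatory and `N_I` inhibitory presynaptic neurons, each firing as a
stationary Poisson process at a common rate `r` (default 10 spikes/s).
Synaptic efficacies `w ∈ [0, 1]` evolve under a temporally asymmetric
Hebbian STDP rule applied additively over all pre/post spike pairs:

    Δw = +λ (1−w)^μ K(Δt)        Δt = t_post − t_pre > 0   (potentiation)
    Δw = −λ α w^μ   K(|Δt|)      Δt < 0                    (depression)

with the exponential temporal filter `K(s) = exp(−s/τ)`, `τ = 20 ms`.
`α` is the area ratio of the depressing to the potentiating branch and
`μ ∈ [0, 1]` interpolates between additive (`μ = 0`) and multiplicative
(`μ = 1`) weight dependence.  For an *inhibitory* synapse this rule is a
negative feedback: a strong synapse suppresses postsynaptic spikes that
would otherwise follow its own presynaptic spikes, moves spike pairs onto
the acausal branch, and is depressed.  For an excitatory synapse the same
rule is the classical positive feedback.  Inhibitory weights therefore
admit a single stable fixed point (no weight dependence is needed; `μ_I =
0` throughout), and the inhibitory fixed point tracks — balances — the
net excitatory drive.

Two postsynaptic models are implemented:

* a conductance-based leaky integrate-and-fire neuron
  (`C_m dV/dt = −(V−V_rest)/R_m − g_E(V−E_ex) − g_I(V−E_in)`), integrated
  by forward Euler on the input bin grid, threshold crossing detected at
  end of bin, reset to rest;
* the delayed linear Poisson neuron used by the theory: per-bin firing
  probability `clip(e·dt + Σ w_E x_E(t−d) − Σ w_I x_I(t−d), 0, 1)` with a
  one-bin causal delay `d`.

## Mean-field theory

In the slow-learning limit the stochastic update is replaced by its
expectation over the spike statistics at fixed weights.  For the linear
neuron with instantaneous input correlations `C` this gives, per second,

    dw_i/dt = λ r [ (1−w_i)^μ (ν τ ∓ K(d) (C w)_i) − α w_i^μ ν τ ],

(− for inhibitory, + for excitatory synapses), with postsynaptic rate
`ν = e + r Σw_E − r Σw_I`.  Under isotropy the uniform vector is an
eigenvector of `C` (eigenvalue `C1`) and the homogeneous fixed point
solves a scalar (or 2-d) equation; the package finds it by a bracket scan
plus Brent's method restricted to the admissible region `ν > 0` (the
second root with net-inhibitory input is unphysical: a neuron with net
inhibitory input does not fire, so there is no learning there).  At
`μ = 1` the scalar equation is a quadratic whose closed form serves as an
algebraic cross-check of the solver.

The stability matrix at the homogeneous point block-diagonalises in the
eigenbasis of `C`: each non-uniform eigenvector contributes one
eigenvalue (`het-I` directions are always negative — the uniform
inhibitory solution is always stable; `het-E` directions can cross zero
when `μ_E` is small and the excitatory correlation eigenvalue large), and
the uniform directions couple through the shared rate `ν` in a 1×1 or 2×2
block.  Every spectrum is verified in the tests against a dense
finite-difference Jacobian of the drift field.

For a *single* inhibitory synapse onto the (nonlinear) integrate-and-fire
cell the correlation term is replaced by the measured linear response:
the dip `w·Γ(s)` in the conditional postsynaptic rate a time `s` after an
inhibitory input spike.  `Γ` is fitted from spike-triggered averages as
an exponential-recovery dip `A e^{−(s−l)/τ_Γ}` with the latency `l` fixed
at the zero crossing of the dip and `(A, τ_Γ)` least-squares optimised;
the drift then uses the overlap `∫ K(s) Γ(s) ds` (closed form
`A e^{−l/τ} τ τ_Γ/(τ+τ_Γ)` for exponential kernels, adaptive quadrature
at relative tolerance 1e-8 otherwise).

### Finite-bin corrections

Simulations are exact Bernoulli processes on bins of width `dt`, so the
package can optionally evaluate the theory with the matching discrete
corrections (`bin_width_ms`): the filter integral becomes the geometric
sum `τ_eff = dt/(e^{dt/τ}−1)`, the delay snaps to the bin grid, and the
count-covariance term carries the Bernoulli `(1−q)` factor.  These
corrections are what make the Monte-Carlo/ODE comparison a sharp test
(sub-percent agreement in the floor-free regime) rather than a loose one.

The linear closure fails by construction once the rate floor engages —
whenever a single inhibitory spike can push the per-bin probability to
zero, i.e. when weights are comparable to `e·dt`.  The package flags this
region (`RateFloorError`), and the Monte-Carlo validation is run at
operating points whose fixed point sits well below the floor threshold.

## Input generation

Correlated Poisson inputs are Bernoulli processes on the simulation grid
with block-structured instantaneous (same-bin) pairwise correlations.
Construction: every group owns a latent Bernoulli(q) train, every
correlated group pair another; in each bin a neuron copies its group
latent with probability `a_g`, the pair latent with probability
`√c_gh`, or draws fresh.  Because the branches are mutually exclusive per
bin, marginals are exactly Bernoulli(q) and the pairwise correlation is
exactly the summed product of shared copy probabilities; solving
`a_g = √(w_g − Σ_h c_gh)` realises the requested within/between
coefficients at any q.  Admissibility for this construction is
`Σ_h c_gh ≤ w_g` per group (reported with the offending pair on
violation).  Random streams are keyed `(seed, kind, population, neuron,
chunk)` with a fixed internal chunk length, so runs are bit-reproducible,
chunking cannot affect results, extending the duration extends the trains
without altering their prefix, and adding neurons never perturbs existing
trains.

## Simulation parameters and operating point

Membrane and synaptic constants follow the canonical conductance-LIF
values of the feed-forward STDP literature: `τ_m = 20 ms`
(`C_m = 200 pF`, `R_m = 100 MΩ`), `V_rest = −70 mV`, `V_th = −54 mV`,
reset to rest, `E_ex = 0 mV`, `E_in = −70 mV`, `τ_syn = 5 ms`, kernel cut
off at `10 τ_syn`, Euler step `dt = 0.1 ms`.  Peak conductances are
scaled by `A(N) = 1000/N` so the mean synaptic current is independent of
the population size at fixed mean weight (factor 5 at `N_I = 200`, 1 at
`N_E = 1000`).

The remaining free constants were calibrated once, by forward reasoning
about the operating point, before the quantitative experiments were run:

* base conductances `ḡ_E = 0.2 nS`, `ḡ_I = 1.0 nS` and a fixed background
  (1000 excitatory synapses at w = 0.5, inhibitory background at
  w = 0.175) put the cell in the fluctuation-driven regime at ~10
  spikes/s — presynaptic and postsynaptic rates of the same order, the
  regime in which the spike-triggered dip is linear in the probe weight;
* single-synapse experiments keep `N_I = 200` (weak-coupling regime of
  the linear-response closure); population-learning experiments use a
  small plastic population (`N_I = 40`, two or four blocks) where
  per-synapse effects are resolvable;
* the balance experiments use `ḡ_I = 0.4 nS` (0.8 nS for joint E/I
  learning), which places the asymptotic inhibitory weights inside the
  working range [0.5, 0.85] used for the balance regressions;
* inhibitory rules use `α_I` in 0.7–0.9 with `μ_I = 0`; the excitatory
  rule of the joint-learning experiments is `α_E = 1.2`, `μ_E = 0.5`
  (net depression, interior homogeneous fixed point), and the
  segregation experiments use the competitive `α_E = 1.5`, `μ_E = 0.05`.

## Learning-rate schedule and problem sizes

When only asymptotic weights matter, learning is accelerated with
`λ(ρ) = λ_base (1 + 15 e^{−ρ/0.06})` over run progress `ρ`: it starts at
`16 λ_base`, and the trailing 70% of the run sits within ~10% of
`λ_base = 1e-3`.  Weight fluctuations anneal with `√λ`, so the
dispersion of final weights reflects the base rate.

The figure protocols run, by default, at a reduced reference scale chosen
so each effect is resolved with comfortable statistical margin: 600 s of
simulated activity per spike-triggered-average weight, 128 repeats × 1800
s for the weight-density evolution, 1800 s per sweep point (×4 seeds) for
the asymptotic-weight sweeps, 1800 s for the population-convergence runs
and 900–1200 s per balance point.  A `scale` argument multiplies
durations and repeat counts toward the full-scale protocols (e.g. 1999
repeats, 2400 simulated minutes).

## What the synthetic inputs do and do not capture

The generator reproduces stationary rates and instantaneous pairwise
correlations exactly — the two statistics the theory depends on.  It does
not emulate temporally structured (lagged) correlations, rate
nonstationarity, bursting, or correlations between the excitatory and
inhibitory populations; conclusions drawn from passing tests therefore
concern the model class, not those features of biological spike trains.
In particular, E/I input correlations (present in thalamocortical
circuits) would add a coupling term to the inhibitory drift that can
remove the homogeneous inhibitory solution when excitation segregates;
this regime is outside the package's scope.

## Numerical choices, ties and degenerate inputs

* Same-bin pre/post pairs contribute no weight change (the rule's two
  branches disagree at Δt = 0 and the event has vanishing measure in
  continuous time); within a bin, presynaptic events are processed before
  the postsynaptic spike decision, identically in the fast kernels, the
  pure-Python online update, and the all-pairs oracle.
* Weights are hard-clipped to [0, 1] after every update.  At `μ = 0` the
  soft bounds vanish, so clipping is load-bearing there; at `μ > 0` it
  only guards λ-sized overshoots.
* The all-pairs oracle applies pairs sequentially (weight updated between
  pairs), which differs from the trace-based scheme — identical to the
  drift expansion — by O(λ²) at `μ > 0` and is exact at `μ = 0`; this
  independence is what makes the equivalence test informative.
* Fixed-point solving: bracket scan on a 1000-point grid + `brentq`
  (tolerance 1e-12); stability classified by the sign of the leading
  eigenvalue.  Boundary fixed points (drift one-signed on the admissible
  interval) are returned flagged rather than silently.
* Correlation matrices are validated symmetric PSD; the isotropy
  assumption (uniform vector an eigenvector) is checked via equal row
  sums before `C1` is used.
* Mode counting for the weight density smooths the 100-bin histogram
  with a Gaussian of 0.02 weight units and counts strict local maxima
  (boundary bins included, since clipped weights can pile up there).
* Convergence of a population to the uniform solution is timed as one
  e-folding of the initial across-synapse spread.
* Constant (all-zero) spike trains yield a sentinel, not NaN, in the
  empirical correlation matrix.

## Known limitations

* The linear-response kernel `Γ` is measured at a mid-range weight and
  treated as linear in `w`; at strong coupling (large `A(N)·ḡ_I`) the
  measured dip saturates and the single-synapse theory overestimates the
  feedback.  The 15% theory/simulation agreement band is honest about the
  residual mismatch of this closure.
* The discrete linear neuron floors at zero probability per *bin*; the
  continuous theory's linear superposition of delta rates therefore only
  corresponds to the simulation while weights are small against `e·dt`.
  Outside that regime the simulation is still well-defined, but it is not
  the printed drift equation — comparisons are restricted accordingly.
* Excitatory learning at small `μ_E` is bistable/competitive; asymptotic
  excitatory weights then depend on noise history, and only ensemble
  statements (segregation indices over seeds) are meaningful.
* No Fokker–Planck treatment of finite-λ weight fluctuations: dispersion
  around the mean-field fixed point is reported empirically, not
  predicted.
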