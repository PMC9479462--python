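# Methods

`ecbnet` simulates retrograde endocannabinoid (eCB) signalling at
cortico-striatal synapses embedded in a small spiking network, and the three
experiments built on it: homeostasis of excess neurotransmitter,
glutamate-flux perturbation studies, and a sweep of the global
excitation/inhibition (E/I) balance. This note records the model, the
numerical choices, and the places where the design was genuinely open,
so that results can be read with the right caveats.

## Model

### Dynamical forms

Every component is one of four scalar forms (`ecbnet.forms`):

* **alpha form** — a rise/decay cascade
  `τ_r a′̇ = −a′ + I`, `τ_d ȧ = −a + a′`, with unit DC gain. Used for
  receptor activation traces (AMPAR 4/30 ms, mGluR5 250/250 ms, NMDAR
  20/100 ms, GABAR 0.8/13 ms), calcium transients (10/8 ms in spine and
  dendrite), presynaptic CB1R activation (4/22.5 s) and process X (4/22.5 s).
* **recovery form** — relaxation to a ceiling, `τ v̇ = v_max − v`:
  available transmitter (τ = 4.28 s toward 2 a.u.) and the GABA Goodwin k1
  (τ = 4.28 s toward 10).
* **adaptation form** — a drift `v̇ = Z·φ` summed into the recovery rate
  where both apply. φ is expressed in a.u. per second; the defaults are
  −0.5 s⁻¹ for available transmitter (Z = min(cleft-domain eCB, #CB1R)) and
  −1.0 s⁻¹ for the GABA k1 (Z = X). These magnitudes are set so that full
  CB1R occupancy can overcome the recovery term (maximum recovery rate
  2/4.28 ≈ 0.47 a.u. s⁻¹): weaker adaptation cannot move the transmitter
  pool appreciably within a run and the homeostat would be inert.
* **leaky accumulator** — `τ v̇ = −v + I`: cleft glutamate (τ = 45 ms),
  cleft GABA (5 ms) and the NMDAR open probability (100 ms, clamped to
  [0, 1]).

All updates are the exact exponential solution for a drive held constant
over the step, so the default `dt` = 1 ms is accurate even for the 0.8 ms
GABAR rise constant; bounds are enforced by projection after each step.
The Goodwin loop is advanced by explicit Euler (its fastest rate is
k5/τ_G = 0.75 s⁻¹, three orders of magnitude slower than `dt`), with all
three derivatives evaluated from the pre-step state.

### Spike-gated inputs

Spike-gated inputs (AMPAR, mGluR5, GABAR from presynaptic release; NMDAR
and dendritic calcium from the back-propagating action potential) enter
their form ODEs as the input `I` held for the spike's timestep. The cleft
is the deliberate exception: the full released amount is *added*, so the
cumulative transmitter entering each cleft equals the sum of per-spike
available-pool values exactly (release bookkeeping used by the flux
analyses). The NMDAR open probability is driven continuously by the
residual cleft glutamate, excluding the quantum released in the same step —
it tracks ambient transmitter left over from previous releases, which is
what the back-propagating spike reads out.

### eCB production, CB1R occupancy and the gene loop

Spine eCB production requires both calcium and mGluR5 activity
(`S′(Ca·S′(mGluR5))`, normalised sigmoid with gain 10 and midpoint 0.5);
dendritic production requires calcium alone. Production is memoryless,
clamped to [0, 1], and mixed into glutamate- and GABA-facing cleft domains
with 25 % crosstalk when a synaptic space carries both bouton types.

Release suppression uses the instantaneous occupancy
Z = min(domain eCB, #CB1R). The Goodwin loop's input, the *unbound*
fraction, is `#CB1R − max(domain eCB, CB1R activation trace)`, clamped to
[0, 1]. The slow activation trace (4/22.5 s alpha form of the same min)
acts as a floor on the bound fraction: receptor activation outlasts ligand
presence, so brief eCB dips between input spikes do not expose the whole
pool to the transcriptional inhibitor. Without this floor the inhibitor GZ
— whose degradation rate k6/τ_G = 5·10⁻⁵ s⁻¹ makes it an effectively
one-way integrator on simulation timescales — ratchets up during every
inter-spike gap and eliminates CB1R network-wide within ~100 s.

Even with the floor, the GZ ratchet produces a slow receptor decline beyond
roughly 60 s of simulated time: transient over-expression early in a run is
eventually paid back, and GZ never relaxes. All experiments therefore use
the 50 s horizon at which the excess-neurotransmitter distributions have
stabilised; steady-state statistics are final-5 s window means. Longer
horizons probe the ratchet, not the homeostat.

The dendritic VSCC weight is 3.0 per back-propagating spike step. Under
leaky 10/8 ms calcium kinetics a per-spike drive is discounted by the
firing duty cycle (f·dt), so this value places the dendritic calcium of a
baseline (~10² Hz) spike train near the production sigmoid's midpoint;
materially smaller values leave the dendritic eCB pathway — the
GABA-side activity sensor — numerically inert.

### Network

100 leaky integrate-and-fire neurons (τ_m = 20 ms, threshold 0.4 a.u.,
reset 0, refractory 2 ms — all configurable; the membrane relaxes exactly
toward the summed synaptic drive) own 80 spines each, 20 of which belong to
paired synaptic spaces that also carry a GABAergic bouton and dendritic
compartment: 8,000 glutamatergic and 2,000 GABAergic boutons, 6,000
glutamate-only spaces. Each pathway listens to one of 100 excitatory or
100 inhibitory Poisson channels whose rates are drawn uniformly from
1–20 Hz. The neuron drive is
`w_E·Σ(AMPAR+NMDAR) − w_I·Σ(GABAR)`: GABAR traces are kept non-negative and
the inhibitory sign of their weight (−1.6) is applied here. Back-propagating
spikes reach all of the neuron's spines and dendritic compartments and take
effect in the following 1 ms step.

The threshold of 0.4 was chosen so that the summed AMPAR drive of 80 spines
(~0.5 a.u.) puts baseline firing in a graded regime (~10² Hz) that responds
continuously to the global weights; a substantially higher threshold
silences the network (no back-propagation, no NMDAR or dendritic calcium,
inert E/I weights), a substantially lower one pins it at the refractory
limit.

### Initial conditions

Alpha- and leaky-form components start at 0. Available transmitter, the
GABA k1, #CB1R, #AMPAR and #GABAR are drawn uniformly within their bounds
([0,2], [0,10], [0,1], [0,1], [0,1]). The Goodwin loop starts internally
consistent with the sampled receptor count: GY = #CB1R/0.0067,
GX = GY·k4/k3, GZ = 0 — receptor counts can then both grow (toward the
clamp at 1) and be trimmed by the inhibitor, which is what lets initially
receptor-poor synapses acquire control.

All randomness flows from one master seed through named substreams
(connectivity, rates, initial conditions, excitatory/inhibitory trains,
perturbation streams); identical seeds give bit-identical runs.

## Experiments and their measures

* **Excess neurotransmitter** is `available − #receptors` per bouton,
  sampled every 10 ms. **Time to steady state** is the first sample inside
  the ±1 SD band of the trace's final-5 s statistics. First entry is used
  because the model's traces approach steady state monotonically up to
  Poisson jitter; a "never leaves the band again" rule is degenerate under
  that jitter (a stationary noisy trace has ~32 % of samples outside a
  ±1 SD band, so its last excursion is always near the end of the trace).
* **Synapse groups**: median splits on time-to-steady and |steady excess|
  (ties on the low side) give the four timely/untimely × strong/weak
  classes.
* **Glutamate flux** after a perturbation is the accumulated per-spike
  *excess* release `max(released − #AMPAR, 0)` from the perturbation to the
  synapse's new steady state — the clearance burden that the excitotoxicity
  argument concerns. Accumulated total release over the same window is
  reported as a cross-check; it cannot reproduce the expected
  LTP-below-baseline ordering because steady release tracks #AMPAR + ε, so
  adding receptors always raises total turnover. Defaults: perturb a
  quarter of the glutamatergic synapses at 25 s (LTD ×0.5, LTP ×2,
  rate ×2), leaving the rest of the network as an unperturbed context.
* **E/I sweep**: for each global weight pair, the final-window mean #CB1R
  per bouton class, normalised to the class maximum across the grid (×100).
  The default grid holds w_I = 1 and lowers w_E over [1.0, 0.95, 0.9, 0.85],
  the band in which network firing responds gradedly; below ~0.7 the network
  falls silent and grid points tie.

## Scale of the shipped experiments

The tests and the acceptance script run the model reduced to 10 neurons
(800 + 200 boutons) for the stabilisation and homeostasis measurements and
5 neurons for the flux and sweep experiments, keeping all per-synapse
parameters, the 100 + 100 input channels and the 50 s horizon of the
full-size model. The channel count is deliberately not scaled down: it sets
the per-pathway rate distribution, and coarsening it changes the sweep's
statistics. Full-size (100-neuron) runs use the same code path and differ
only in cost (~10× the reduced runtime).

## What the simulations do and do not show

The network is a caricature: homogeneous Poisson inputs, no axonal delays,
a one-compartment threshold neuron, uniform initial distributions, and
transporter kinetics folded into a single cleft decay constant. Passing
behavioural tests show that the eCB feedback architecture produces
homeostatic compression of excess glutamate, weaker and broader control of
GABA, flux orderings, and asymmetric CB1R loss *within this model* — not
that striatal tissue is quantitatively described. The Goodwin inhibitor
ratchet (k6 ≈ 0) and the saturating production sigmoid are the two
structural features most likely to dominate any extrapolation; both are
kept configurable.
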