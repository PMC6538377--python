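# Model and methods

`ltpie` simulates how a transient rise in intrinsic excitability (LTP-IE)
of recently active hippocampal pyramidal cells can store a just-travelled
trajectory as a *set* of tagged neurons, and how the recurrent network then
spontaneously replays that trajectory — forward or backward — during
quiescence. The package has two engines: a conductance-based spiking
network and a discrete-time reduced model, plus the analysis stack that
quantifies replay.

## Spiking network

### Membrane and synapse dynamics

Each cell is a leaky integrate-and-fire unit with conductance synapses
(voltages mV, times ms, conductances relative to leak):

    tau_m dV/dt = -(V - E_leak) - g_E (V - E_E) - g_I (V - E_I) + I_ext

Pyramidal cells (PCs): tau_m = 50, E_leak = -68, v_th = -36, tau_r = 8 ms.
Inhibitory cells (INH): 5 / -60 / -50 / 2 ms. Reversals E_E = 0,
E_I = -80 mV; synaptic time constants tau_E = tau_I = 2 ms. Conductances
are exponentially filtered spike trains: on each presynaptic spike the
postsynaptic conductance jumps by the synaptic weight (unit-peak kernel)
and decays with its time constant. `I_ext` is expressed directly in mV of
expected deflection.

Numerics: forward Euler at dt = 0.5 ms; exact exponential decay factors
for conductances; threshold tested after the voltage update; reset to
E_leak held for tau_r while conductances keep integrating (incoming spikes
during refractoriness are not lost); spikes reach postsynaptic
conductances on the next step (one fixed 0.5 ms delay). Results are
therefore weakly dt-dependent; dt is a config knob, 0.5 ms everywhere in
the shipped experiments. The unit-peak (rather than unit-area) synaptic
kernel is the reading consistent with the single-cell behaviour the model
is built around: at the default gate weight (0.8216) a fully potentiated
cell sits near -48 mV with ~6 mV fluctuations — depolarised but
subthreshold, spiking rarely on its own — while at roughly double that
weight spontaneous spiking becomes common.

### Architecture

3000 PCs tile a 2 m x 2 m environment on a near-square lattice of
place-field centres (12000 PCs on 4 m x 4 m for the stimulus-response
mapping regime). Recurrent excitation is Gaussian in place-field
separation, w_ij = 2.6 exp(-d^2 / (2 * 0.053^2)), zeroed below 0.1 —
i.e. only pairs within ~0.135 m connect (~40 partners per cell). The
matrix is symmetric with no self-connections (the distance rule is defined
for cell pairs; a 2.6-strength autapse would be anomalous). 300 INH cells
(N_PC/10) are untuned: every PC->INH and INH->PC pair connects
independently with probability 0.5 (two independent random graphs), at
weights 0.03 and 0.02. There are no INH–INH connections and INH cells
receive no gating input.

Every PC receives an independent Poisson "gate" train at r_G = 125 Hz
through weight sigma_i * 0.8216. Gate spikes are drawn per step
(Bernoulli, p = r_G dt) from a seeded generator, so runs are reproducible
without storing trains.

### LTP-IE profile

The encoding run is never simulated. A cell's expected peak rate during
the trajectory is the Gaussian place-field tuning (r_max = 20 Hz,
lambda = 0.15 m) evaluated at the exact distance from its field centre to
the nearest point of the trajectory polyline (per-segment projection, no
sampling resolution). The gate-weight scaling follows the shifted
logistic sigma(r) = 1 + (sigma_max - 1) / (1 + exp(-(r - 10))), so cells
the trajectory passed through carry sigma ~ 2 and distant cells sigma ~ 1.
For branched layouts the profile is the pointwise maximum over branches.

### Replay epoch and triggers

`run_network` simulates only the quiescent epoch: gate noise everywhere,
optional 10 ms current pulses into a region to trigger propagation.
Trigger parameters are deliberately uncritical; the default amplitude is
the calibrated single-cell value below. With the default parameters
spontaneous events arise at ~5 per second; triggered trials therefore
identify "their" event as the first detected event starting within 100 ms
of the pulse.

### Single-cell protocols

15 s runs characterise the voltage distribution as a function of sigma;
a 125 s run with 10 ms pulses every 250 ms measures the pulse-evoked
minus spontaneous spike probability (spontaneous windows are matched
no-pulse windows offset half a period). The pulse amplitude is nowhere a
published constant; it is the one deliberately calibrated quantity in the
package. The documented default, 65 mV of expected deflection, is the
"moderate drive" of the model: it converts ~50% of pulses into spikes in
a fully potentiated cell while leaving an unpotentiated cell essentially
silent (contrast < 0.01). Smaller amplitudes shrink the contrast toward
zero; larger ones saturate it.

## Event analysis

* **Detection.** The cell-averaged PC rate (per 0.5 ms bin) is smoothed
  with a unit-sum Gaussian kernel (2 ms std, truncated at ±4 std,
  edge-renormalised so constant traces are unchanged). Stretches strictly
  above 0.5 Hz lasting over 30 ms become events; gaps under 10 ms are
  merged, iterated to a fixed point.
* **Blowup classification.** An event is a blowup when more than 25% of
  its spikes come from cells below the sigma midpoint
  1 + (sigma_max-1)/2. The two knobs are package conventions (the
  qualitative criterion is "confined primarily to tagged cells"); both
  sit in the config.
* **Virtual speed.** Ordinary least squares of spikers' linearised
  trajectory positions against spike times over the middle 80% of the
  event window (every spike counted once per emission). Events qualify
  only when 50–400 ms long and when the fitted |slope| exceeds 10 m/s:
  slow slopes come from bidirectional or stalled events whose regression
  cancels toward zero, not from unidirectional propagation. Genuine
  replay here runs at ~15–25 m/s (the 4 m trajectory replayed in
  100–200 ms), and the slope sign distinguishes forward from reverse.
* **Decoding.** Median x and median y of the place-field peaks of cells
  spiking in 5 ms windows with at least five spikes.
* **Spectra.** Mean-subtracted periodogram of the population rate during
  each event (no window function, event-length resolution, power summing
  to the segment variance), averaged over events after interpolation onto
  the longest event's frequency grid. Segments under 64 samples are
  skipped. Replay events ring at tens of Hz; the peak moves up with
  stronger inhibitory feedback — the shipped comparison uses
  w_PC,INH = 0.01 vs 0.03, which peak near ~23 vs ~62 Hz.

### Parameter sweeps

Event-frequency sweeps run n_trials seeded simulations per grid cell and
report accepted (non-blowup) events per second; cells whose events are
mostly blowups are flagged. Speed sweeps trigger at the trajectory start
(up to 20 trials of 600 ms, stopping at 10 successes, reporting only
cells with ≥5); a success is the first event after the trigger with a
measurable speed. The shipped 3x3 grid spans w_PC,PC in {2.2, 2.4, 2.6}
and lambda_PC,PC in {0.051, 0.054, 0.057} m — chosen inside the regime
where triggered propagation succeeds and speeds are measurable; larger
values drift into merged/continuous activity, smaller ones fail to
propagate. Within the grid, mean speed rises with both parameters.

## Reduced model

Discrete time; v_i(t) = sum_j w_ij s_j(t-1) + i_ext + i_g sigma_i; units
above v_th spike, capped at the n_max highest voltages per step (ties:
lowest index), with a tau_r-step refractory. The cap stands in for
inhibition.

**Head-direction lattice** (intersecting trajectories): 64 x 64 positions
on 2 m x 2 m, each unit also preferring one of 8 headings, every window of
8 units along a row containing all 8 (fixed cyclic order by default; a
seed draws an independent permutation per window). Weights are separable
Gaussians in position (lambda_xy = 0.25 m) and circular heading distance
(lambda_theta = pi/7). The gamma-shaped trajectory starts eastbound at
(-1, 0.25), loops through the lower-right quadrant on a smooth 0.55 m
radius arc, crosses itself at (-0.25, 0.25) (eastbound vs northbound) and
ends at (-0.25, 1). Only the three printed points are contractual; the
interior uses the arc because propagation can only follow heading changes
gentler than the theta-coupling scale. The LTP-IE profile maximises a
Gaussian proximity score z over the trajectory sampled at 0.02 m (heading
= local tangent; scales 0.2 m / 0.2 m / pi/16) and maps it through
sigma = 1 + 1/(1 + exp(-20 (z - z0))). The published table omits z0; the
package centres the logistic at z0 = 0.5, the midpoint of z's range
(config knob). Triggers are squared-exponential current bumps (amplitude
15, length scale 0.15 m) at either trajectory end. Spatial parameters:
v_th = 11, i_g = 5, n_max = 10, tau_r = 6 steps, T = 50.

**Switchboard** (non-spatial mappings): ensembles S1, S2, M1, M2 (100
cells each) and a 2000-cell pool B. Per stimulus, 200 uniformly drawn B
cells each receive 10 random inputs from that stimulus (weight 0.88); per
motor ensemble, 200 drawn B cells each project to 25 random motor cells
(weight 2.33); motor ensembles are internally all-to-all recurrent at
0.35 (no self-connections); no recurrence within S or B. Draws are
independent, so subsets can overlap. A mapping is encoded by setting
sigma = 2 exactly on B cells that both receive from a stimulus and
project to its mapped motor ensemble. Step parameters: v_th = 10,
i_g = 3, n_max = 50, tau_r = 5, T = 5; the trigger is one current pulse
into all cells of one stimulus ensemble at the second timestep (under the
cap, 50 of the 100 fire).

The weights make recall threshold-critical by design: a tagged B cell
fires when ≥5 of its 10 stimulus inputs are active, an untagged one only
at ≥8; a motor cell needs 4 coincident switchboard inputs
(3 x 2.33 + 3 = 9.99 just misses threshold). Consequences, measured over
hundreds of wiring seeds: the mapped motor ensemble activates strongly in
~95% of runs, the unmapped ensemble is silent in ~90% and receives at
most a few percent of its cells otherwise (from B cells that happen to be
cross-wired to both associations, plus the hypergeometric tail of
untagged receivers). Routing is therefore assessed at the ensemble
readout level — which ensemble activates — not as the absence of any
single stray spike; the tests require the mapped ensemble to dominate the
unmapped one by an order of magnitude in aggregate and to activate in at
least 80% of runs. Perfect single-spike exclusivity is not a property of
these wiring statistics.

## Synthetic data and what the tests show

All inputs are generated: trajectory polylines (the 4.0 m Z, a U-shaped
alternative, a three-branch star, the gamma loop, the mapping paths),
lattices, random graphs, Poisson gate noise. The generator emulates the
study conditions — sizes, rates, weights as tabulated — not real
recordings: there is no measurement noise, no cell-to-cell parameter
heterogeneity, no theta or behavioural state structure, and place fields
tile space uniformly. Passing tests therefore show the mechanism is
implemented and behaves as described under those idealised conditions;
they do not show the mechanism explains recorded hippocampal replay.

Problem sizes in the shipped tests and the acceptance script: three 10 s
replay epochs of the full 3000-PC network for spontaneous-event
statistics, 600 ms trials for triggered protocols, one 125 s single-cell
protocol, 20 wiring seeds for each reduced-model property. These sizes
give standard errors comfortably inside every tolerance used.

## Known limitations

* One fixed integration scheme (forward Euler, 0.5 ms); no convergence
  study. Strong conductances (>~200 relative to leak) would leave the
  Euler stability region — untouched by all shipped parameter sets.
* LTP-IE is static within a run: no decay, no interaction with synaptic
  plasticity, no neuromodulation.
* The Poisson generator is per-bin Bernoulli, exact only in the
  small-p limit (p = 0.0625 at defaults).
* Replay speed, event rate and spectra inherit the discretisation and
  the one-step synaptic delay; their absolute values are
  implementation-flavoured, which is why the tests pin trends,
  boundaries and invariants rather than absolute speeds or frequencies
  (the >1 Hz event-rate floor and the single-cell ~0.5 contrast are the
  exceptions, and both clear their bands by wide margins).
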