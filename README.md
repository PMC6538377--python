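# ltpie — excitability-gated sequence replay in spiking networks

`ltpie` is a simulator and analysis toolkit for a hippocampal sequence-
induction model in which *intrinsic excitability*, not synaptic change,
stores a recent trajectory. Cells that fired fast during a run (place
cells along the path) undergo LTP-IE: their responses to a stochastic
upstream gating input G are multiplicatively scaled by

    sigma(r) = 1 + (sigma_max - 1) / (1 + exp(-beta_sigma (r - r_sigma)))

with r the cell's peak trajectory-evoked rate, r_sigma = 10 Hz,
beta_sigma = 1, sigma_max = 2. Tagged cells sit closer to threshold under
gate noise, so in a recurrent network whose weights fall off with
place-field distance (w_ij = w^PC,PC exp(-d_ij^2 / 2 lambda^2)),
activity propagates preferentially along the tagged band: the network
spontaneously replays the trajectory, forward or backward, in
sharp-wave-ripple-like bursts. Because LTP-IE stores only the *set* of
active cells, direction and speed of replay are properties of the
network, not of the experience.

The package contains:

* `ltpie.lif` — conductance-based LIF dynamics (forward Euler,
  dt = 0.5 ms) and the single-cell gating protocols;
* `ltpie.profile` — analytic trajectory-evoked rates and LTP-IE profiles;
* `ltpie.network` — place-field lattice, Gaussian recurrent weights with
  cutoff, random PC↔INH wiring;
* `ltpie.simulator` — the replay-epoch engine (3000 PCs + 300 INH at
  defaults), triggers, region readouts;
* `ltpie.analysis` — event detection (2 ms smoothing, 0.5 Hz threshold,
  30 ms minimum, 10 ms merging), blowup classification, virtual replay
  speed, median decoding, event spectra, parameter sweeps;
* `ltpie.reduced` — a discrete-time winner-take-all model: a
  head-direction lattice that replays self-intersecting trajectories
  without branching, and a random "switchboard" network that stores
  temporary stimulus→response mappings;
* `ltpie.fixtures` — deterministic trajectories (the 4 m Z, a U-shaped
  alternative, a branched star, the self-intersecting gamma loop) and
  the mapping layout;
* `ltpie.config` / `ltpie.io` / `ltpie.cli` — YAML configs holding every
  published parameter as a named key, CSV/JSON/HDF5 output, and the
  `ltpie` command-line tool.

## Worked example

```python
import numpy as np
import ltpie

z = ltpie.z_trajectory()                      # 4.0 m Z-shaped path
net = ltpie.assemble_network(seed=1)          # 3000 PCs + 300 INH
sigma = ltpie.profile_from_trajectory(net.peaks, z)

result = ltpie.run_network(net, sigma, duration=3_000.0, seed=2)
events = ltpie.analyze_run(result, sigma, trajectory=z, peaks=net.peaks)

print(f"{len(events)} replay events in 3 s")
for ev in events[:3]:
    speed = "unmeasured" if ev.speed is None else f"{ev.speed:+.1f} m/s"
    print(f"  {ev.t_start:6.0f}-{ev.t_end:6.0f} ms  "
          f"{ev.n_spikes:5d} spikes  {speed}")
```

Output:

    17 replay events in 3 s
        98-   210 ms    589 spikes  +15.7 m/s
       242-   418 ms    940 spikes  unmeasured
       451-   686 ms   1214 spikes  unmeasured

Seventeen spontaneous events in three seconds: replay is frequent at the
default operating point (well above 1 per second). Each event is a
100–250 ms population burst. The first event swept forward along the Z
at 15.7 m/s (a 4 m trajectory compressed into ~100 ms; negative speeds
mark reverse replay); "unmeasured" events were partial, bidirectional or
outside the 50–400 ms acceptance band — see `docs/methods.md` for the
speed-acceptance rules.

The same from the shell:

    ltpie simulate --seed 3 --out out/        # raster.csv, rate.csv,
                                              # events.json, config echo
    ltpie reduced gamma --seed 0 --out g.csv  # intersecting-trajectory
                                              # replay in the reduced model
    ltpie sweep --kind speed --out speeds.csv

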