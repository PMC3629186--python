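# mothnav

Moths track pheromone plumes with a stereotyped behavioural alternation:
**surge** upwind while the odour is perceived, **cast** crosswind or in
spirals when it is lost.  `mothnav` is a desk-scale simulator of a neuronal
mechanism for that switch: antennal-lobe projection neurons respond to a
pheromone pulse with a *multiphasic* pattern — an On burst that tracks the
stimulus, a few-hundred-millisecond inhibitory silence (I), and a tonic Off
discharge that outlasts the stimulus by seconds — and those three phases can
drive action selection directly (On → surge; Off → recent loss → crosswind
cast; baseline → prolonged absence → spiral).

The package provides, as importable library modules with a thin CLI on top:

* **`mothnav.neuron`** — a single-compartment Hodgkin–Huxley command neuron
  with Na⁺, K⁺, leak, Ca²⁺ and SK (small-conductance Ca²⁺-activated K⁺)
  currents.  Ca²⁺ entering during the On burst activates SK, which carves
  the inhibitory phase; scaling the SK conductance to zero turns the
  response monophasic.
* **`mothnav.orn`** — the olfactory-receptor-neuron population drive: a
  triphasic (rise / adaptation / biphasic decay) rate model with a
  saturating dose law, non-homogeneous Poisson spiking (42 ORNs), and an
  exponential synaptic kernel.
* **`mothnav.metrics`** — On/I/Off phase segmentation, spike-timing
  precision σ and reliability ρ with ISI-preserving shuffle nulls, PSTH,
  autocorrelation, and multi-neuron coincidence ROC analysis.
* **`mothnav.controller`** — the online surge trigger (three interspike
  intervals < 70 ms followed by ≥ 350 ms of silence) and the one-step
  (surge/spiral) and two-step (surge/zigzag/spiral) casting policies.
* **`mothnav.arena`** — a closed-loop 2-D arena with wind, an intermittent
  meandering plume and the full sensing-to-action pipeline.
* **`mothnav.theory`** — worst-case (competitive-ratio) analysis of the
  casting strategies: logarithmic-spiral casting plus surge achieves
  r = 22.513 at the optimal growth rate, doubling crosswind zigzag plus
  surge achieves r = √82 ≈ 9.0554 when the target is not downwind.
* **`mothnav.fixtures` / `mothnav.experiments`** — synthetic spike-train
  generators and the figure-level experiment drivers (dose series, duration
  series, pulsed-gap series, SK-block sweep, navigation batches).

## Worked example

Simulate one 200 ms, 1 ng stimulus response and segment it:

```
$ mothnav simulate-neuron --duration 200 --dose 1 --seed 1
{
  "n_spikes": 37,
  "on_latency_ms": 230.08,
  "on_duration_ms": 185.09,
  "i_duration_ms": 384.33,
  "off_duration_ms": 3351.61
}
```

The On burst starts ≈ 230 ms after stimulus onset (the printed latency law
at 1 ng) and lasts about as long as the stimulus; the ≈ 400–500 ms silence
that follows is the SK-mediated inhibitory phase; the Off discharge then
persists for seconds.  With the SK conductance blocked the same stimulus
gives a monophasic response (`--sk-factor 0` reports `i_duration_ms: null`).

The two search-theory bounds:

```
$ mothnav theory-ratios
{
  "spiral_surge": {"r": 22.5131, "growth_rate": 0.1137, ...},
  "zigzag_surge": {"r": 9.0554, "factor": 2.0, "casting_multiplier": 9.0, ...}
}
```

i.e. with detection only at the plume centerline, an optimal logarithmic
spiral guarantees a total path at most 22.513× the initial distance, and
doubling crosswind zigzag (knowing the target is not downwind) at most
9.055× — the theoretical reason two-step casting is the stronger strategy.

Closed-loop navigation batches:

```
$ mothnav navigate --strategy one_step --n-trials 10 --seed 7
$ mothnav navigate --strategy one_step --sk-factor 0 --n-trials 10 --seed 7
```

report success rate, search distance and track-angle statistics per
condition; with SK intact the track-angle histogram has a significant mode
at 0° (upwind) and most trials reach the source, while the SK-blocked
neuron leaves the agent casting until timeout.

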