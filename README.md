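# mtfold

Analysis pipeline for single-molecule magnetic-tweezers measurements of a
two-state (folded/unfolded) protein under force, together with a
ground-truth trajectory simulator.  The package covers the full chain
from bead-height time series to a reconstructed zero-force free-energy
landscape:

* **polymer** — worm-like-chain (Marko–Siggia) elasticity of the unfolded
  peptide, single-segment freely-jointed-chain model of the folded
  domain, the force-dependent unfolding step size Δx(f), and the
  stretching work ∫Δx df.
* **kinetics** — Bell force-dependent rate laws, the Evans–Ritchie
  rupture-force distribution under constant loading rate (density, CDF,
  closed-form mode, exact inverse-CDF sampling), weighted log-linear
  Bell fits of rate-vs-force data, maximum-likelihood and binned
  least-squares rupture-distribution fits with bootstrap errors,
  critical (coexistence) force, and barrier heights from an attempt
  rate.
* **constructs** — per-variant physical models (two-regime unfolding
  laws, folding law, elasticity, attempt rate) with defaults for the
  tagged protein variants LE-CSP-GS / KL-CSP-GS / KL-CSP-LE and the
  untagged protein.
* **simulate** — exact Gillespie two-state hopping at constant force,
  thinning-based simulation along force ramps (±1 pN/s sweeps with
  hysteresis), and force-jump protocols; bead height is the
  state-dependent polymer extension plus drift and Gaussian (optionally
  Ornstein–Uhlenbeck) noise, recorded at a configurable sampling rate
  (default 200 Hz) with ground-truth state labels and transition events.
* **trajectory** — moving-average smoothing, two-Gaussian occupancy fits
  (unfolding probability P_u), two-state Gaussian-HMM segmentation
  (Baum–Welch + Viterbi), run-length dwell extraction with boundary
  censoring, exponential survival fits (closed-form MLE and cumulative
  least squares), and two-window change-point step detection.
* **ramp** — rupture collection across many ramp traces, unit-area
  rupture histograms, and the end-to-end ramp-distribution fit reporting
  the most probable unfolding force.
* **landscape** — transition-state positions along the N–C distance
  coordinate, barrier and well energies (U as the zero reference, the
  native state at −ΔG0), ΔG0 both from a one-parameter fit of P_u(f) and
  from the stretching work at the coexistence force, and the native N–C
  distance from a PDB/mmCIF structure.
* **io / pipeline / cli** — TSV trajectory files with JSON metadata
  sidecars (gzip accepted), validated JSON/YAML run configs (seed
  mandatory), and a deterministic multi-stage pipeline.

## Command line

```bash
# simulate one constant-force trace
mtfold simulate --protocol constant --force 5.4 --duration 300 \
    --seed 1 --out trace.tsv

# HMM segmentation + dwell rates for equilibrium traces
mtfold analyze-equilibrium trace.tsv --out rates.json

# fit a rupture-force distribution (from traces or a force list)
mtfold analyze-ramp --forces-file forces.txt --loading-rate 1.0

# unfolding steps and waiting times from force-jump traces
mtfold analyze-jump jump1.tsv jump2.tsv

# reconstruct the zero-force landscape for a construct
mtfold landscape --construct KL-CSP-GS --out landscape.json

# small end-to-end demonstration (simulate -> segment -> fit -> landscape)
mtfold demo --outdir demo_out
```

Every stochastic stage requires a seed; re-running a config reproduces
all numbers exactly.

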