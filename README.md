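# mcmflow

Single-cell flow-cytometry analysis of **replication licensing** (chromatin-bound
MCM2–7) and **restriction-point state** (anchored RB1), measured simultaneously
in G1 cells.

## The assay and the question

Two events prepare a G1 cell for S phase: loading of the MCM2–7 helicases onto
chromatin (origin licensing) and passage through the RB1-dependent restriction
point, marked by CDK2–cyclin E hyper-phosphorylation of RB1. Whether licensing
must wait for the restriction point is not obvious: hypo-phosphorylated RB1 is
anchored in the nucleus, while hyper-phosphorylated RB1 is released — so after
a pre-fixation salt/detergent extraction, the surviving RB1 immunofluorescence
reports "before the restriction point" and the surviving MCM signal reports
"licensed". Plotting MCM against RB1 for gated G1 cells splits them into four
quadrants:

| quadrant | MCM | RB1 | interpretation |
|---|---|---|---|
| Q1 | + | − | licensed, past the restriction point |
| Q2 | + | + | licensed **before** the restriction point |
| Q3 | − | + | before the restriction point, not yet licensed |
| Q4 | − | − | ambiguous: past the restriction point and unlicensed, *or* very early G1 with RB1 not yet phosphorylated |

Q2 is the money quadrant: a conservative lower bound on the fraction of cells
that license before the restriction point.

`mcmflow` implements the full desk side of this assay:

* **`mcmflow.simulate`** — a ground-truthed generator of list-mode events for
  four scenarios: asynchronous exponential growth, release from quiescence
  (restriction point from ~9 h, licensing from ~11 h, S entry from ~14.5 h),
  the same release with an irradiation-induced G1 arrest, and release from a
  mitotic (nocodazole) block with two waves of licensing. Includes the
  measurement model (log-normal channel noise, backgrounds), doublet
  injection, and 4-level fluorescent cell barcoding.
* **`mcmflow.gating`** — automated gating: pulse width singlet gate, G1/G2 DNA
  peak detection (Gaussian-on-background fits), the left-side-of-G1-peak gate,
  MCM threshold from the S/G2-border negative reference, RB1 threshold between
  the S-phase (washed-out) and anchored G1 populations, quadrant
  classification with Wilson intervals.
* **`mcmflow.barcoding`** — Gaussian-mixture demultiplexing of barcoded pools.
* **`mcmflow.kinetics`** — time-course assembly, logistic onset estimation
  with bootstrap CIs, and loading-order verdicts.
* **`mcmflow.io` / `mcmflow.cli`** — FCS 3.0/3.1 and CSV reading/writing,
  YAML configuration, and the `mcmflow` command-line tool
  (`simulate`, `gate`, `quadrants`, `demux`, `timecourse`, `run`).

## Worked example

Score an asynchronous fibroblast-like population in which 14% of cells license
before the restriction point:

```python
import mcmflow as mf

sc = mf.get_scenario("bj_exponential", n_cells=50_000, seed=1)
cells = mf.simulate_cells(sc, 0.0)                      # ground-truth cells
events = mf.apply_measurement_model(cells, mf.OpticsConfig(), seed=1)
singlets, gates = mf.auto_gate(events)                  # full gating chain
qr = mf.classify_quadrants(singlets, gates, label="exponential BJ")
print(f"G1 peak {gates.g1_peak:.1f}, G2 peak {gates.g2_peak:.1f}")
print(f"MCM threshold {gates.mcm_threshold:.1f}, RB1 threshold {gates.rb1_threshold:.1f}")
print(f"G1 events {qr.n_total}")
print(f"Q1 (MCM+/RB1-) {qr.frac_q1:.1%}   Q2 (MCM+/RB1+) {qr.frac_q2:.1%}")
print(f"Q3 (MCM-/RB1+) {qr.frac_q3:.1%}   Q4 (MCM-/RB1-) {qr.frac_q4:.1%}")
order = mf.summarize_order(qr, misclass_floor=0.02)
print(f"verdict: {order.verdict}; Q2 = {order.q2_frac:.3f} "
      f"CI ({order.q2_ci[0]:.3f}, {order.q2_ci[1]:.3f})")
```

prints

```
G1 peak 199.9, G2 peak 397.7
MCM threshold 17.4, RB1 threshold 98.9
G1 events 13885
Q1 (MCM+/RB1-) 6.1%   Q2 (MCM+/RB1+) 14.2%
Q3 (MCM-/RB1+) 53.0%   Q4 (MCM-/RB1-) 26.7%
verdict: loading_before_rp_detected; Q2 = 0.142 CI (0.136, 0.148)
```

The DNA peaks land at 2N/4N (gain 100 per genome equivalent), the derived MCM
threshold sits just above the S/G2-border background, and the measured Q2
fraction (14.2%) recovers the simulated pre-restriction-point licensing
propensity (14%) — the verdict says a real Q2 population is present, i.e.
licensing before the restriction point was detected. The same chain driven
from a configuration file:

```sh
mcmflow run --config examples/bj_g0_release.yaml --out results/
```

runs a quiescence-release time course and reports the three onsets
(restriction point, licensing, S entry) with bootstrap CIs.

## Documentation

`docs/methods.md` describes the biological model behind the generator, every
gating rule and its rationale, the numerical choices (threshold estimators,
onset definition, tie-breaking), and the known limitations of the synthetic
populations.
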