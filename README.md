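# sernet

SER (susceptible–excited–refractory) excitable dynamics simulated on signed
functional-connectivity networks, with the full surrounding protocol:

- **connectivity** — signed Pearson correlation matrices from region×time
  panels, group averaging, and two proportional-threshold schemes
  (`absolute`: top |r| pairs; `signed`: independent positive/negative cost
  levels) producing ternary {−1, 0, +1} networks at exact link counts.
- **dynamics** — the three-state agent engine. Each region cycles
  S → E → R → S; susceptible nodes excite spontaneously with probability
  `sop`, deterministically when the positive-neighbor field passes its
  threshold `pi_p` (and the negative field does not), never when only the
  negative field passes `pi_n`; refractory nodes recover with probability
  `nep`. Updates are fully synchronous and seeded.
- **fit** — raster → simulated connectivity → upper-triangle Pearson
  goodness-of-fit against a target matrix, replicated over seeded runs, and
  a resumable sweep harness with the three standard grids
  (`series1_grid`, `series2_grid`, `series3_grid` — the last is the
  15 × 7 signed-cost factorial).
- **stats** — Friedman rank test (mid-ranks, tie correction) and
  Tukey–Kramer post hoc on treatment rank means, for crossed cost designs
  or subject-blocked tables.
- **synthetic** — seeded generators for block-modular population
  correlation matrices with anticorrelated systems (defaults: 105 regions,
  ≈70 % positive / 30 % negative pairs at full density) and per-subject
  Gaussian time-series panels.

## CLI

Each stage is a subcommand of `sernet`; every run writes a JSON manifest
with config, seeds, and SHA-256 digests of all inputs/outputs.

```sh
# synthetic subject panels + population matrix
sernet synth --seed 1 --out-dir data/

# per-subject correlation + group average
sernet connectivity --panels data/ --out group.csv

# threshold into a signed network
sernet threshold --matrix group.csv --scheme absolute --cost 0.15 --out net.csv
sernet threshold --matrix group.csv --scheme signed \
    --positive-cost 0.25 --negative-cost 0.10 --out net_signed.csv

# one simulation run (200 steps by default)
sernet simulate --network net.csv --sop 0.025 --nep 0.225 \
    --pi-p 0.1 --pi-n 0.1 --steps 200 --seed 1 --out raster.csv

# goodness-of-fit sweep (series 3 = signed 15x7 cost factorial);
# resumable via the checkpoint CSV in --out-dir
sernet sweep --series 3 --matrix group.csv --reps 100 --steps 200 \
    --seed 1 --out-dir sweep3/

# Friedman + Tukey-Kramer on the sweep table
sernet stats --sweep sweep3/sweep.csv --treatment positive_cost \
    --blocks negative_cost --out stats.json
```

Custom grids can be given as YAML (`sernet sweep --grid grid.yaml ...`), with
keys matching `sernet.fit.SweepGrid`.

## Conventions worth knowing

- Link count at cost *c* is round-half-up of `c × P` over `P = R(R−1)/2`
  pairs; ties at the cutoff break lexicographically by (i, j), so networks
  are deterministic and nested across the cost grid.
- The absolute cost grid is 5 %–100 % (20 levels); the signed grids include
  0 % (15 positive × 7 negative levels).
- Neighbor averages are compared with `≥` by default (`SERParams.comparison`
  switches to strict `>`); nodes without neighbors of a sign get a zero
  field regardless of the threshold.
- Goodness-of-fit targets default to the positive part of the matrix
  (negative entries zeroed); pass `target_mode="signed"` for the full
  signed target.
- Replicate *k* of a batch uses seed `base_seed + k`; sweep combinations
  get disjoint seed blocks, so parallel (`--jobs`) and serial runs are
  bit-identical.
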