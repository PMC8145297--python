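# rtquic

Analysis pipeline for **RT-QuIC** (real-time quaking-induced conversion) and
related seed amplification assays: per-plate fluorescence thresholding,
replicate-based positivity calling, kinetic curve metrics, endpoint-dilution
titration, and cohort summaries — plus a synthetic plate-kinetics generator
with known ground truth so the whole pipeline is verifiable end to end.

RT-QuIC detects minute amounts of misfolded protein aggregates (prions,
pathological alpha-synuclein, ...) by letting them seed the conversion of a
recombinant substrate in a shaken 96-well plate; amyloid formation is read
out as thioflavin T (ThT) fluorescence, in relative fluorescence units (RFU),
one read per well per hour over a ≥ 40-h run. The package is aimed at labs
running such assays who want transparent, reproducible calling of their
plate-reader exports, and at methodologists who need a simulated test bed.

## The rules implemented

For a plate with wells $w = 1..W$ and hourly reads $F_w(t_k)$:

- **Threshold.** Pool the first $n=5$ reads of every well into one set and
  take $\theta = \bar{F} + 10\,s$, where $\bar F$ and $s$ are the pooled mean
  and sample standard deviation. One threshold per plate, never shared.
- **Well metrics.** $\mathrm{RFU}_{initial} = F_w(t_0)$;
  $\mathrm{RFU}_{max} = \max_{t_k \le 40\,h} F_w(t_k)$; the ratio
  $\mathrm{RFU}_{max}/\mathrm{RFU}_{initial}$; lag = first read time with
  $F_w \ge \theta$ (no interpolation between hourly reads).
- **Positivity.** Each sample × dilution is run in quadruplicate and called
  positive when ≥ 2 of 4 replicate wells cross $\theta$. A group where
  exactly one well crossed is negative but flagged as a *spontaneous
  positive*.
- **Titration.** Samples are seeded as serial tenfold dilutions of tissue
  (exponent $e \le -3$; $10^{-2}$ = 1 % homogenate). The endpoint is the most
  dilute positive call; a sample negative everywhere is **ND**. Endpoint
  comparisons use powers of ten of the exponent gap (a $10^{-8}$ brain vs a
  $10^{-5}$ colon endpoint is a $10^3$-fold difference); ND is ordered below
  every positive endpoint and never treated as a number. Series negative at
  $10^{-3}$ but positive deeper are kept and flagged (assay inhibitors at low
  dilution), not truncated.

The simulator (`rtquic.simulate`) draws each well from a single-hit Poisson
conversion model ($P(\text{convert}) = 1 - e^{-d}$ for effective dose $d$
seeding units) followed by logistic ThT growth with log-dose-dependent lag —
enough to reproduce dose-dependent lag, partial-well positivity near the
endpoint, flat negatives, spontaneous late positives, and saturation at
260,000 RFU. See `docs/methods.md` for the model and its calibration.

## Worked example

```sh
rtquic demo --out-dir demo --seed 2
```

simulates a study-shaped cohort (ages 1, 3, 6 and 12 months; three
transgenic subjects plus a non-carrier control per age; brain and colon
plates), calls every plate, titrates and summarizes. It logs:

```
plate study-12m-brain: threshold 20320 RFU (76 wells pooled), 12/19 groups positive
plate study-12m-colon: threshold 19416 RFU (40 wells pooled), 9/10 groups positive
plate study-1m-colon: threshold 19916 RFU (28 wells pooled), 0/7 groups positive
plate study-3m-brain: threshold 19465 RFU (40 wells pooled), 0/10 groups positive
plate study-3m-colon: threshold 19267 RFU (32 wells pooled), 5/8 groups positive
plate study-6m-brain: threshold 19575 RFU (40 wells pooled), 1/10 groups positive
plate study-6m-colon: threshold 20929 RFU (40 wells pooled), 7/10 groups positive
earliest positive age [brain]: 6 months
earliest positive age [colon]: 3 months
```

Each line reports the plate's own pooled-baseline threshold (all inside the
15,000–25,000 RFU band typical of this assay) and how many sample × dilution
groups were positive; the closing lines are the cohort-level readout — colon
seeding activity appears months before brain seeding activity. The output
directory holds `curves.csv`, `calls.csv` (per-well metrics + per-group
calls), `titration.csv` (endpoints, with `ND` spelled literally),
`cohort.csv`, a threshold-provenance sidecar and run manifests. Because
near-endpoint wells convert stochastically, individual endpoints can land
one dilution off the generative truth on any given seed, and occasional
spontaneous single-well (or, rarely, two-well) conversions appear — exactly
the behaviours the spontaneous and non-monotone flags exist to audit.

The same stages are available as subcommands on real data
(`rtquic call --curves curves.csv --samplesheet sheet.csv --out calls.csv`,
then `rtquic titrate`, `rtquic summarize`), and as library functions
(`read_plate`, `call_plate`, `titrate_calls`, `summarize_cohort`).
`rtquic summarize-study` summarizes the packaged cohort endpoint fixture:

```
 age_months tissue  n_positive  n_total
          1  colon           0        3
          3  brain           0        3
          3  colon           3        3
          6  brain           1        3
          6  colon           3        3
         12  brain           3        3
         12  colon           3        3
```

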