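# rfsafe

Tier-based safety assessment for custom-built MRI RF transmit coils.

The package quantifies the **modeling uncertainty** of an electromagnetic coil
model from simulated-vs-measured field maps, estimates **intersubject
variation** from peak-SAR populations, propagates the three uncertainty
sources (modeling, intersubject, power monitoring) into a **safety factor**
by root-sum-of-squares, and derives per-channel **average-power limits** for
three validation tiers:

- **Tier 1** — no simulation: all RF power is assumed dissipated in one 10-g
  averaging mass (very conservative closed-form limit).
- **Tier 2** — simulation validated by B1+ maps only; the safety factor is
  multiplied by an additional buffer (default 2).
- **Tier 3** — simulation validated by both B1+ maps and spatial temperature
  (SAR) maps; no buffer.

## Modules

| module | role |
| --- | --- |
| `rfsafe.core_maps` | `FieldMap` / `TemperatureSeries` data model, NIfTI/TSV I/O, block-average resampling, mask erosion, mask-aware Gaussian smoothing |
| `rfsafe.thermometry` | voxel-wise SAR = Cp·dT/dt by OLS over a fit window, plus an R² linearity check |
| `rfsafe.validation` | normalized voxel-wise difference maps, the 99.9 %-of-voxels (nearest-rank) modeling uncertainty, worst-case aggregation over shims/modalities, per-channel global phase alignment |
| `rfsafe.population` | gamma MLE fit of pSAR samples, pSAR99 quantile, gamma- and max/min-based intersubject variation |
| `rfsafe.safety_tiers` | RSS uncertainty propagation, safety factor, tier-2 buffer, corrected pSAR, total and per-channel power limits; `paper` (1-decimal chain) and `full_precision` rounding modes |
| `rfsafe.synthetic` | seedable generators: multichannel phantom fields, shim combination, perturbed “measurements”, heating curves, gamma pSAR populations |
| `rfsafe.reporting` | tier-table reports (CSV/JSON), difference histograms with the quantile marker, audit trails |

## CLI

```sh
# tier assessments from a YAML config -> CSV + JSON report
rfsafe assess config.yaml --out report.json

# modeling uncertainty from a measured/simulated map pair
rfsafe compare-maps --meas meas.tsv --sim sim.tsv --modality SAR --out cmp.json

# gamma fit + intersubject variation from a pSAR sample column
rfsafe fit-psar psar.txt --out fit.json

# SAR map from temperature frames (SAR = Cp dT/dt)
rfsafe thermo f0.tsv f1.tsv f2.tsv --times 0,30,60 --out sar.tsv

# synthetic phantom data (deterministic per --seed)
rfsafe synth shim-maps --shim left --seed 1 --out maps/
rfsafe synth psar -n 1000 --seed 1 --out psar.txt
rfsafe synth heating --seed 1 --out frames/
```

An `assess` config lists one entry per assessment:

```yaml
assessments:
  - {tier: 1, n_channels: 8, label: tier 1}
  - tier: 2
    n_channels: 8
    psar_sim_mean: 2.3      # W/kg at reference_power
    reference_power: 8.0    # W total
    buffer: 2.0
    label: tier 2
    budget: {modeling: 0.64, intersubject: 0.39, power_monitoring: 0.12}
```

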