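# csfdyn

Analysis toolkit for preclinical CSF-dynamics experiments: intracranial
pressure (ICP) waveform analysis, CSF outflow resistance, CSF secretion
rate, dye-dispersion flow, ⁸⁶Rb⁺ tracer flux kinetics, brain water content,
and the accompanying cohort statistics — plus seeded synthetic generators
that emulate every experimental input with known ground truth, so the whole
pipeline is testable without animal data.

## Modules

| module | what it does |
|---|---|
| `csfdyn.icp_waveform` | despiking, zero-phase anti-alias downsampling to 100 Hz, spectral 1.6–5.5 Hz bandpass with Tukey-tapered edges, per-cardiac-cycle peak-to-peak → mean wave amplitude (MWA); baseline ICP |
| `csfdyn.csf_dynamics` | outflow resistance `R_out = (ICP_f − ICP_i)/I` from constant-rate infusion steps; secretion rate `Vp = r_i(C_i − C_o)/C_o` from ventriculo-cisternal dye dilution; dye-dispersion flow slope; brain water percentage |
| `csfdyn.tracer_flux` | ³H-mannitol-corrected ⁸⁶Rb⁺ influx with ouabain-sensitive fractions; count-conserving reconstruction of remaining activity A_t/A₀ from timed bath aliquots; log-linear efflux rate constants and bumetanide-sensitive fractions |
| `csfdyn.cohort_stats` | Shapiro–Wilk gate, Student's unpaired t, one-way ANOVA with Sidak-adjusted comparisons, simple regression, single-pass Grubbs outlier test, percent-change summaries |
| `csfdyn.synthetic_data` | seeded generators (ICP traces, infusion studies, perfusion runs, dye series, efflux pairs, cohorts) returning ground truth; defaults parameterized from a bundled reference group table |
| `csfdyn.io_cli` | semicolon-separated trace files (decimal-comma tolerant), CSV sample/cohort tables, JSON/CSV result writers, and the `csfdyn` CLI |

## CLI

All stages are subcommands of `csfdyn`; `simulate` closes the loop by
writing synthetic inputs in the same formats the analysis stages read:

```sh
csfdyn --out-dir sim --seed 4 simulate trace
csfdyn --out-dir out mwa --input sim/trace.txt --band 1.6:5.5 --fs-out 100

csfdyn --out-dir sim simulate infusion
csfdyn --out-dir out rout --input sim/infusion.csv --icp-i 3.4

csfdyn --out-dir sim simulate vcp
csfdyn --out-dir out vcp --input sim/perfusion.csv --ri 9 --steady-window 30

csfdyn --out-dir sim simulate efflux
csfdyn --out-dir out efflux --input sim/efflux.csv --bath-volume-ul 1000 --aliquot-ul 200

csfdyn --out-dir sim simulate cohort
csfdyn --out-dir out cohort --input sim/cohort.csv --measure icp \
    --groups control,HFD --tests shapiro,ttest
```

Other subcommands: `dyeflow`, `influx`, `brainwater`. A YAML file passed to
`--config` supplies per-subcommand option defaults; every JSON summary
embeds the parameter set used so runs are reproducible from their output.

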