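# backmap

Analysis toolkit for **TMS motor-cortex mapping of paraspinal (back) muscles**:
from raw stimulus-locked EMG sweeps to topographic map metrics and
between-group statistics, plus a synthetic-cohort simulator with known ground
truth so every stage of the chain can be validated without access to raw
recordings.

It is written for motor-neurophysiology labs that map the primary motor cortex
(M1) representation of trunk muscles with transcranial magnetic stimulation
(TMS): stimuli are delivered over a 5 × 8 scalp grid (1 cm spacing, midline to
4 cm lateral, 2 cm posterior to 5 cm anterior of the vertex) while the
participant holds a gentle tonic contraction (~10% MVC), and motor evoked
potentials (MEPs) are recorded from four back muscles (deep and superficial
multifidus DM/SM, lumbar erector spinae LES, thoracic erector spinae TES).

## The analysis

Per sweep, the MEP amplitude is the RMS EMG between MEP onset and offset minus
the background RMS over −500…−5 ms pre-stimulus (clamped at zero); amplitudes
are averaged over the 5 stimuli per site. Onset/offset come from a
threshold-crossing detector (rectified, 2 ms-smoothed signal above background
mean + 3 SD for ≥ 5 ms inside a 10–40 ms latency band), with manual window
annotations taking precedence when supplied.

The site-amplitude map is normalised to the hot spot and sites below 25% of
the peak are removed. On the thresholded map `z_i` at sites `(x_i, y_i)`:

- **centre of gravity**  CoG_x = Σ z_i·x_i / Σ z_i (likewise CoG_y), in cm;
- **CoG vector**  ‖(CoG_x, CoG_y)‖;
- **map volume**  Σ z_i (total excitability);
- **map area**  number of active sites;
- **overlap** between two muscles' maps: |A∩B| / |A∪B| of the active masks
  (Jaccard index);
- **CoG variation**  per-subject distance of the CoG from the group-mean CoG
  (per axis and as a vector) — the between-subject heterogeneity index.

Metrics are compared across groups with classic one-way ANOVA (Duncan's
multiple range test post hoc) or, when a median-centred Levene test finds
unequal variances, Welch's ANOVA (Games–Howell post hoc). Effect sizes are
η² = SSB/(SSB+SSW); Spearman's rank correlates metrics with pain (0–10 NRS);
no multiplicity adjustment is applied. Both ANOVAs are also available **from
printed group summaries** (mean, SD, n) — the F statistics depend only on the
sufficient statistics — so published tables can be recomputed without raw data.

The simulator draws, per participant and muscle, a latent Gaussian amplitude
surface (`peak·exp(−d²/2σ²)`) whose centre scatters between subjects with a
group-specific dispersion, then renders raw sweeps (tonic Gaussian background
EMG + a damped-sinusoid MEP burst with lognormal amplitude noise) so the full
pipeline can be exercised against known ground truth.

## Worked examples

Recompute a published between-group comparison from its printed summaries:

```python
from backmap.stats import SummaryStats, anova_from_summary

summ = SummaryStats(labels=("NcP-FP", "MP", "NpP"),
                    means=(4.30, 10.62, 5.96), sds=(3.01, 2.84, 3.46), ns=(10, 5, 3))
r = anova_from_summary(summ)
print(f"F({r.df1:.0f}, {r.df2:.0f}) = {r.F:.2f}, p = {r.p:.3f}, eta^2 = {r.eta_squared:.3f}")
```

prints `F(2, 15) = 7.28, p = 0.006, eta^2 = 0.492`: the group factor explains
49% of the variance in LES map volume, with the mixed-pain group's mean
(10.62) well above the others.

Simulate a cohort with a 3× CoG-dispersion contrast and analyse it end to end:

```python
from backmap import (GroupProfile, SimulationConfig, simulate_cohort,
                     PipelineConfig, analyze_cohort)
from backmap.stats import run_group_report

profiles = [
    GroupProfile(label="NcP-like", true_cog_mean=(2.0, 1.5), cog_dispersion=(0.3, 0.3), n_subjects=12),
    GroupProfile(label="NpP-like", true_cog_mean=(2.0, 1.5), cog_dispersion=(0.9, 0.9), n_subjects=12),
]
cfg = SimulationConfig(seed=7)
cohort = simulate_cohort(profiles, cfg, muscles=("DM",))
result = analyze_cohort(cohort, PipelineConfig(grid=cfg.grid), muscles=("DM",))
report = run_group_report(result.metrics)
row = report.omnibus.set_index("variable").loc["cog_variation_vector DM"]
print(f"CoG variation (vector, DM): {row['method']} F({row['df1']:.0f}, {row['df2']:.1f}) "
      f"= {row['F']:.2f}, p = {row['p']:.4f}, eta^2 = {row['eta_squared']:.3f}")
```

prints `CoG variation (vector, DM): welch F(1, 13.6) = 11.41, p = 0.0047,
eta^2 = 0.341` — the variance gate picked Welch's test, and the mean recovered
per-subject CoG deviation was 0.34 cm (NcP-like) vs 0.78 cm (NpP-like),
reflecting the generating contrast.

The same chain is available from the shell:

```bash
backmap simulate cohort --seed 7 --out cohort.h5 --muscles DM
backmap process sweeps --cohort cohort.h5 --out amps.csv
backmap map compute --amplitudes amps.csv --out metrics.csv
backmap stats report --metrics metrics.csv --out report/
```

## Documentation

See `docs/methods.md` for the model, its assumptions, parameter defaults and
known limitations.
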