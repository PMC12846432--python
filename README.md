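# ehtkit

Analysis toolkit for WHO-style **experimental hut trials (EHTs)** of
insecticide-treated nets (ITNs/LLINs), written for vector-control
entomologists and biostatisticians evaluating candidate nets against
active comparators.

In an EHT, wild free-flying mosquitoes enter baited huts fitted with
candidate nets; every hut-night yields counts of mosquitoes by location
(room / veranda trap / window trap), blood-feeding status and survival.
Treatment arms rotate between huts weekly in a Latin square and baits
rotate daily, removing hut and host confounding. `ehtkit` covers the
whole analysis pipeline:

- **trial data** — validated hut-night records with the fully
  cross-classified 12-cell count matrix, CSV/JSON I/O, Latin-square
  balance checks;
- **endpoints** — exophily, blood feeding and mortality with 95% CIs,
  plus the relative indices (with u = untreated, t = treated;
  T = caught, B = blood-fed, K = dead):
  blood-feeding inhibition `100·(1 − (Bt/Tt)/(Bu/Tu))`,
  personal protection `100·(Bu − Bt)/Bu`,
  insecticidal effect `100·(Kt − Ku)/Tu`,
  deterrence `100·(Tu − Tt)/Tu`;
- **glm** — binomial (logit) and Poisson (log) regression by IRLS with
  hut and bait as fixed effects and a cluster-robust sandwich variance
  over hut-nights, yielding adjusted odds ratios (AORs);
- **noninferiority** — conversion of the WHO 7-percentage-point margin
  to the odds-ratio scale at the comparator proportion π₀,
  `NIM = odds(π₀ ∓ δ)/odds(π₀)`, and the
  non-inferior / superior decision rules;
- **bioassay** — WHO tube-test susceptibility classification (98%/90%
  thresholds, Abbott's correction) and cone-bioassay scoring against
  the ≥80% mortality / ≥95% knockdown cut-offs;
- **chemistry** — wash durability: retention `100·Cn/C0` and the
  per-wash wash-resistance index `100·(Cn/C0)^(1/n)`;
- **simulate** — a synthetic trial generator (Latin-square rotation,
  negative-binomial hut entries, per-mosquito Bernoulli outcomes) and
  simulation-based power for non-inferiority comparisons.

## Worked example

Published per-arm totals from a seven-arm Tanzanian hut evaluation of
an alpha-cypermethrin + PBO net ship with the package:

```python
import ehtkit as ek
from ehtkit.refdata import ARM_TOTALS, DELTA

u = ARM_TOTALS["untreated"]        # caught 374, fed 171, dead 17
t = ARM_TOTALS["yahe_unwashed"]    # caught 343, fed 110, dead 159

print(ek.proportion_endpoint(t.dead, t.caught))       # 46.4 (41.1-51.6)
print(round(ek.blood_feeding_inhibition(t, u), 1))    # 29.9
print(round(ek.insecticidal_effect(t, u), 1))         # 38.0

ref = ARM_TOTALS["duranet_unwashed"]
nim = ek.nim_odds_ratio(ref.dead / ref.caught, DELTA, "mortality")
print(round(nim, 2))                                  # 0.76
print(round(ek.wash_resistance_index(5.25, 2.09, 20), 1))  # 95.5
```

The treated arm killed 46.4% of entering mosquitoes (the untreated
control killed 4.5%), reduced the blood-feeding rate by 29.9% relative
to control, and killed an excess of 38% of a control hut's worth of
entries per night. A mortality odds ratio against the active comparator
must keep its lower 95% bound above 0.76 for the candidate to be
declared non-inferior at the 7-point margin. The standard comparator's
coated alpha-cypermethrin retained only `(2.09/5.25) = 39.8%` of its
content over 20 washes — a per-wash wash-resistance index of 95.5%.

The same pipeline runs end to end on simulated data from the shell:

```sh
ehtkit simulate --out trial.csv --seed 7
ehtkit analyze  --input trial.csv --output summary.csv
ehtkit ni-test  --input trial.csv --output decision.csv \
        --candidate yahe_unwashed --reference duranet_unwashed \
        --endpoint mortality
ehtkit power    --candidate yahe_unwashed --reference duranet_unwashed \
        --replicates 200 --seed 7
```

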