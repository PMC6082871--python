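# clampchem

Single-molecule force-clamp analysis of thiol–disulfide mechanochemistry:
stochastic trajectory simulation, step detection, summed-trace reduction
kinetics, Bell/Arrhenius landscape reconstruction, and a thermodynamic model
of disulfide-bond reformation after force quench.

## The scientific problem

In force-clamp AFM, a polyprotein of eight identical I27 titin domains —
each carrying a buried engineered disulfide bond — is held at constant
force while its end-to-end extension is recorded. A 150 pN / 0.5 s pulse
unfolds the domains (~15 nm steps) up to the mechanically rigid disulfide,
exposing it to solvent. A second, higher pulse (300–500 pN) lets a small
thiolate nucleophile cleave each disulfide by bimolecular SN2 substitution
(~10 nm steps). The cleavage rate follows the Bell/Arrhenius law

    r(F) = A · [S⁻] · exp(−ΔG‡/kBT) · exp(F·Δx/kBT)

with pre-exponential A = 10⁷ M⁻¹s⁻¹, active thiolate concentration
[S⁻] = C_total / (1 + 10^(pKa − pH)) (Henderson–Hasselbalch), activation
barrier ΔG‡, and distance to the transition state Δx (~0.35 Å). Because the
applied force lowers the barrier by F·Δx, even *thermodynamically
disfavored* cleavage (ΔG° > 0, e.g. by cysteine methyl ester) proceeds
under load. When the force is quenched to zero for t_q = 8 s, the reduced
protein thiolate can re-attack the mixed disulfide; in the two-state
thermodynamic limit the reformation probability is the Boltzmann partition

    p_reform = 1 / (1 + exp(−ΔG°_red / kBT)),

exactly 50% when ΔG° = 0 (the cysteine/cystine equilibrium), near 1 for
poor nucleophiles (good leaving groups), and near 0 for strong reducing
agents such as mesna — force makes an otherwise impossible reaction both
happen and reverse.

The package is aimed at single-molecule biophysicists who want a tested,
reproducible reimplementation of this analysis chain, plus a seeded
synthetic-data generator that stands in for the (unavailable) raw AFM
recordings when validating the estimators.

## What is in the box

| module                   | contents |
|--------------------------|----------|
| `clampchem.core`         | constants, compound parameter table, protocols, Bell rate, barriers, titration curve, 3-level landscape |
| `clampchem.simulate`     | seeded generator of two-pulse kinetics and five-pulse reformation trajectories, titration curves, cohorts |
| `clampchem.detect`       | change-point step detection (binary segmentation), event classification, trace-acceptance filters |
| `clampchem.kinetics`     | summed/normalized reduction traces, single-exponential fits, bootstrap errors |
| `clampchem.landscape`    | Bell/Arrhenius regression (Δx, r₀, ΔG‡), Henderson–Hasselbalch pKa fits, generic correlations |
| `clampchem.reversibility`| quench-partition models, reformation-fraction scoring, reformation-vs-pKa correlation |
| `clampchem.io` / `.cli`  | TSV+JSON trajectory round trip, run manifests, `clampchem` command-line interface |

## Worked example

```python
import clampchem as cc
from clampchem.pipeline import kinetics_cohort_rate, force_series_fit, reformation_cohort

table = cc.load_compound_table()

# reduction kinetics of cysteine methyl ester at 350 pN, [S-] = 2 mM
est, n_acc = kinetics_cohort_rate(table["cysteine-methyl-ester"], 350.0,
                                  n_traces=100, seed=11, n_bootstrap=200)
print(f"Cys-ME  350 pN: r = {est.rate_s:.3f} +/- {est.rate_sd_s:.3f} s^-1  "
      f"(r/[S-] = {est.concentration_normalized_rate_M_s:.1f} M^-1 s^-1, "
      f"{n_acc}/100 traces accepted)")

# force series and Bell fit for N-acetyl-cysteine
rates, fit = force_series_fit(table["nac"], n_per_force=50, seed=11, n_bootstrap=200)
print(f"NAC Bell fit: dx = {fit.dx_A:.3f} +/- {fit.dx_sd_A:.3f} A, "
      f"r0/[S-] = {fit.r0_norm_M_s:.0f} M^-1 s^-1, "
      f"dG = {fit.dG_barrier_kT:.2f} +/- {fit.dG_barrier_sd_kT:.2f} kT")

# reformation after an 8 s zero-force quench, mesna
res, n = reformation_cohort(table["mesna"], 50, seed=11, model="equilibrium2")
print(f"mesna reformation after 8 s quench: {100*res.fraction_reformed:.1f}% "
      f"+/- {100*res.fraction_sd:.1f}% ({n}/50 accepted)")
```

prints

```
Cys-ME  350 pN: r = 0.403 +/- 0.018 s^-1  (r/[S-] = 201.3 M^-1 s^-1, 80/100 traces accepted)
NAC Bell fit: dx = 0.331 +/- 0.015 A, r0/[S-] = 297 M^-1 s^-1, dG = 10.42 +/- 0.15 kT
mesna reformation after 8 s quench: 0.0% +/- 0.0% (42/50 accepted)
```

i.e. the full pipeline (simulate → detect → filter → sum/normalize →
exponential fit) recovers the generative 0.40 s⁻¹ cleavage rate with a
bootstrap error of ~4%, the Bell regression recovers the 0.35 Å / 10.6 kT
landscape of N-acetyl-cysteine from 250 noisy trajectories, and the
strongly exergonic reducer mesna shows essentially no disulfide reformation
— its low-energy mixed disulfide is a poor leaving group.

The same stages are available from the shell:

```bash
clampchem simulate --compound l-cysteine --n-traces 20 --seed 1 --out run/
clampchem detect --traces run/ --out run/events.tsv
clampchem fit-kinetics --traces run/ --seed 1 --out run/rate.json
clampchem full-pipeline --compound nac --seed 1 --out run/
clampchem reformation --compound mesna --seed 1 --out run/reform.json
clampchem titration --pka 8.3 --seed 1 --out run/pka.json
```

Each run writes a manifest (config hash, seed, version, outputs) so results
are reconstructible.

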