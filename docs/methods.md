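# Methods

## System being modelled

A double-seeded primary gill cell culture on a 0.9 cm² permeable membrane
separates an apical compartment (1.5 mL; culture medium at pH 7.4, or
artificial freshwater at pH 7.7, adjustable to 6.0–9.5) from a basal
compartment (2.0 mL of L-15 medium at pH 7.4). Symmetric conditions have
medium on both sides; asymmetric conditions have freshwater apically, which
mimics the in-vivo gill and drives the transepithelial potential
basolateral-negative. Drug moves between the compartments; 100 µL aliquots
are withdrawn from each compartment at 0, 6, 24, 30 and 48 h (0 and 24 h
for the mannitol calibration) and beta-counted.

## Kinetic model

State: total amounts `N_A`, `N_B` (pmol). Between sampling times the
volumes are constant and

```
dN_A/dt = −J_net,   dN_B/dt = +J_net
J_net = J_passive + J_paracellular + J_uptake + J_efflux     (pmol/s, A→B > 0)

J_passive      = P_trans · A · b · (f_n(pH_A)·C_A − f_n(pH_B)·C_B)
J_paracellular = P_para(TER) · A · (C_A − C_B)
J_uptake       =  Jmax_u · A · C_A / (Km_u + C_A)
J_efflux       = −Jmax_e · A · C_B / (Km_e + C_B)
```

* `f_n(pH)` is the Henderson–Hasselbalch neutral fraction; multiprotic
  compounds use the product of per-site neutral fractions (independent-site
  approximation — no microspeciation).
* `b = asym_bias ≥ 1` applies only when the apical medium is freshwater and
  the compound is a pure base. It is a lumped stand-in for the
  basolateral-negative transepithelial potential favouring cation entry;
  no Goldman-type electrodiffusion is modelled. Default 2.
* `P_para(TER)` is anchored to the measured mannitol tiers — 3.6e-6 cm/s on
  cell-free inserts (TER 0), 1.1e-6 over 0.2–1.0 kΩ·cm², 0.1e-6 at and above
  2 kΩ·cm² — with log-linear interpolation between anchors.
* Inhibitors scale the targeted carrier's `Jmax` by a per-inhibitor
  `fraction_remaining`, identically for apical and basal application (both
  sides were found inhibitory in the assays this emulates).

Integration uses LSODA with rtol 1e-9 and atol 1e-12 (pmol scale). At each
sampling time the aliquot amount `C · 0.1 mL` leaves each compartment (the
sample is counted, not returned) and the compartment volume drops by
0.1 mL. Mass balance — dose = in-system + withdrawn — holds to better than
1e-6 relative at every output time, and the passive-only fixed-volume limit
matches the analytic two-compartment exponential to 1e-8.

## Measurement model

Counted dpm per aliquot = `amount_to_dpm(C · V_aliquot)` using the
compound's specific activity (1 Ci = 2.22e12 dpm), multiplied by a mean-one
lognormal pipetting factor (CV 5% by default) and then Poisson-sampled
(counting error). With noise off the records are exact; all randomness is
driven by explicit seeds, and dataset generation derives one child stream
per insert from the master seed keyed by the scenario name (CRC32), so
output is byte-reproducible.

## Estimators and decision rules

* **TER gate.** Only inserts with TER ≥ 5 kΩ·cm² enter the analysis; the
  mannitol calibration sweep is exempt because it exists to span the whole
  TER range. Ties are retained.
* **Papp.** Two-point slope of the receiver amount over 0→6 h:
  `Papp = ΔQ/Δt / (A · C0) / 3600`. Receiver amounts are corrected for
  previously withdrawn aliquots by default (an uncorrected mode exists for
  sensitivity analysis); `C0` comes from the t = 0 donor sample. The stated
  `dQ/dt` unit of pmol·L⁻¹·h⁻¹ (a concentration rate) is implemented as an
  amount rate — receiver concentration rate times receiver volume — since a
  flux requires an amount. No multi-point regression of Q(t) is attempted.
* **Mannitol formula.** `P = ΔM_BL · V_donor / (M_AP · t · 3600 · A)`; the
  "volume" is read as the donor volume, which makes the formula identical
  to the Papp estimator with `C0 = M_AP / V_donor` (tests verify agreement
  to 1e-9 on a common trajectory). Note the estimator is a 24-h two-point
  slope: on leaky inserts with ~19% donor depletion it reads ~15% below the
  instantaneous permeability. The analytic two-point value is the oracle in
  tests.
* **Transport ratios.** `TR_uptake = Papp(A:B)/Papp(B:A)` on group-mean
  Papp values, reciprocal for efflux; `TR ≥ 1.5` (ties inclusive) flags
  active transport. Pairs are matched by scenario label (uptake/efflux tag
  stripped) plus drug, condition and apical pH, which keeps
  concentration-series and control inserts out of the ratios.
* **Statistics.** Pooled-variance two-sided t-test; one-way ANOVA on
  natural-log values (all observations must be positive); alpha 0.05; no
  multiple-testing correction (matching the practice the pipeline mirrors).
  Degenerate zero-variance cases: equal means give p = 1 by convention,
  unequal constant groups are rejected.
* **Dose-response.** The 17-level series (0.014–10,000 µg/L) is fit through
  the origin; the low range (≤ 0.14 µg/L) is additionally fit with a
  degree-2 polynomial with intercept alongside the nested linear fit.
  Degree 2 (not 3) is the default because it is the description attached to
  the reported low-range fit quality; the degree is selectable.
* **Plasma read-across.** `[plasma] = 0.87 [water]` (the propranolol
  blood:water partition coefficient; µg/L and ng/mL coincide numerically).
  In-vitro basal concentrations are regressed with intercept on predicted
  (7 rows) and on measured in-vivo plasma (5 rows after dropping missing
  entries pairwise). These fits use condition means, not the underlying
  21 individual inserts, so the "actual" slope carries ~1% indeterminacy.

## The synthetic study catalog

`paper_catalog()` builds: 7 drugs × {symmetric, asymmetric} × {BTA uptake,
BTA efflux, CETA} at 1 µg/L; the propranolol pH series (6.0, 8.0, 9.5, both
directions); 54 concentration-series inserts over 17 log-spaced levels —
8 levels × 3 inserts covering 0.014–0.14 µg/L (24 inserts) and 9 more
levels carrying the remaining 30 up to 10,000 µg/L; six inhibitors
(amantadine, cimetidine, cyclosporine A, MK571, quinidine, verapamil;
400 nM) × {apical, basal} plus an inhibitor-free control group; and a
mannitol sweep over TER 0–18.1 kΩ·cm². Default group sizes are 3 inserts
(6 controls), the low end of the replication the protocol uses; they keep
the full catalog under a few seconds to simulate and are adjustable.

## Calibration fixtures

Per-drug `TransportParams` are fixtures, not fits (no raw data is
published). Propranolol's four parameters are solved so the noise-free
simulated Papp values reproduce 1.7e-6 cm/s (symmetric A:B), 2.7e-6
(asymmetric A:B) and 0.8e-6 (asymmetric B:A); with `b ≥ 1` these three plus
the symmetric B:A value (1.1e-6) are jointly infeasible under a single
net-passive bias — the model cannot lower asymmetric efflux below symmetric
efflux — so symmetric B:A comes out near 0.5e-6 and the symmetric uptake TR
high (~3.3 instead of ~1.5). The same structural limit applies to the
imipramine/metoprolol/atenolol symmetric rows; fixtures for those drugs
target the asymmetric flag pattern first. The propranolol uptake carrier's
Km is set to 0.2 nM so that Michaelis saturation falls inside the
0.014–0.14 µg/L (0.054–0.54 nM) window, producing the low-range curvature
(quadratic beating linear) while leaving the full series effectively
linear. Inhibitor `fraction_remaining` values reproduce the reported
percent-of-control endpoints where reachable; a full carrier block floors
at ~53% of control at 1 µg/L because the passive share remains, so the
strongest inhibitions saturate there.

## What the synthetic data does and does not show

The generator reproduces the kinetic structure the estimators assume:
two well-mixed compartments, mass-removing sampling, saturable carriers,
pH-partition behaviour and counting noise. It does not model unstirred
boundary layers or mucus microclimate pH, intracellular accumulation or
metabolism (a lumped cell pool exists but is off by default), adsorption to
plasticware, TEP electrophysiology beyond the scalar bias, or
between-culture biological variability. Passing tests therefore demonstrate
estimator correctness and internal consistency on data obeying the model —
not that the model captures every feature of real insert data.

## Numerical and design choices

* Radioactivity constant fixed at 1 Ci = 2.22e12 dpm. The stated mannitol
  dose "0.013 µCi (2.2e5 dpm)" is internally inconsistent (0.013 µCi =
  2.886e4 dpm); the simulator uses the dpm figure.
* Speciation discrepancy: with pKa 9.42 the ionized fraction at pH 8 is
  96.3%, not the stated 98%; recorded, not resolved. Percent-ionized
  reporting rounds half-up to integer percent.
* Externally reported pH-adjusted log Kow values are stored verbatim
  (`log_kow_ph_adjusted`) and kept separate from the computed log Dow,
  which they do not follow.
* The paracellular leak can be disabled (`paracellular_scale = 0`) to
  realise exact zero-transport and passive-only limits in tests.
* Concentration series x-values in fits are the measured exposure
  (recovered from the t = 0 donor count), not the nominal dose.
* The `cli_pipeline` surface is a thin typer CLI (`simulate`, `analyze`,
  `report`, `reproduce`) over `pipeline.py`; all tabular I/O is CSV with
  the record schema defined in `simulator.py`, and scenario catalogs load
  from TOML.

## Known limitations

Carriers are medium-independent, so condition-dependent efflux changes
(symmetric vs asymmetric) cannot be reproduced — see calibration notes.
The two-point Papp under-reads at high permeability or long windows
(quantified above); sink conditions are not enforced. The lumped inhibition
model cannot exceed the carrier share of transport. Replicate structure is
i.i.d. per insert; no mixed-effects modelling of biological replicates.
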