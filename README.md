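# nlcopt

Design-of-experiments optimization and characterization toolkit for lipid
nanoparticle formulations.

Developing a nanostructured lipid carrier (NLC) — a solid-lipid nanoparticle
whose matrix is disordered by a liquid oil so it can hold lipophilic drugs —
typically proceeds through a fixed analysis chain: a designed experiment over
the formulation factors, polynomial response-surface models for the measured
quality attributes, a multi-response desirability optimization to pick the
formulation, and then characterization of that formulation (drug entrapment
and loading, matrix crystallinity, in vitro release, pharmacokinetics).
`nlcopt` implements that chain as a tested, scriptable library for
formulation scientists, with a synthetic-data module so every stage can be
exercised and validated without laboratory data.

It ships with a complete worked study: a 13-run central composite design in
two factors (solid lipid and surfactant amounts, mg) with three responses
(particle size in nm, polydispersity index, zeta potential in mV), plus the
corresponding non-compartmental pharmacokinetic summary table.

## What it computes

**Central composite designs (CCD).** For k factors: the 2^k factorial
points, 2k axial points at coded distance ±α, and replicated center runs.
With α = (2^k)^(1/4) the design is rotatable (prediction variance depends
only on distance from the center). Factor levels convert between coded and
actual units via `actual = center + coded·step`.

**Response-surface models.** Ordinary least squares on the per-run response
means, in four nested classes: first-order (FO), FO + interactions (TWI),
FO + squares ("pure quadratic", PQ) and full second-order (SO). Each fit
carries coefficients in both unit systems, R²/adjusted R², and an ANOVA
that splits the residual into lack-of-fit and pure error estimated from the
replicated center points. A selection rule (significant overall F, lack of
fit not rejected, then highest adjusted R² with parsimony tie-breaks)
chooses a class per response; explicit overrides and factor-subset models
are supported.

**Desirability optimization.** Derringer–Suich transforms map each predicted
response to d ∈ [0,1] (smaller-is-better, larger-is-better, or target); the
overall desirability is the weighted geometric mean
D = (∏ dᵢ^{wᵢ})^{1/Σwᵢ}, maximized over the coded design region by a
deterministic dense grid plus a local Nelder–Mead polish.

**Characterization arithmetic.**
entrapment efficiency %EE = (W₀ − C_fd·V_f)/W₀ × 100; drug loading
%DL = (W₀ − C_fd·V_f)/m_lipid × 100 with the oil phase converted to mass by
its density; DSC endotherm integration (linear baseline, trapezoid over
time, mW/mg·s → J/g); crystallinity index
CI% = ΔH_dispersion/(ΔH_reference · c_lipid) × 100.

**Release and PK.** Fixed-volume replacement sampling correction
C′ₙ = Cₙ + (V_s/V_t)·Σ_{i<n} Cᵢ, converted to cumulative percent of dose;
non-compartmental analysis (Cmax, Tmax, linear-trapezoid AUC with an
optional C(0)=0 point for extravascular dosing) and between-formulation
ratio/percent-increase summaries.

**Synthetic data.** Seeded generators for CCD responses (polynomial truth +
Gaussian replicate noise), biphasic burst-plus-first-order or immediate
release curves (emitted as the raw sampled concentrations the correction
must undo), and one-compartment oral-absorption PK profiles
C(t) = (F·D·k_a/(V(k_a−k_e)))(e^{−k_e t} − e^{−k_a t}) with lognormal
between-animal variability under destructive sampling.

## Worked example

```python
from nlcopt.pipeline import study_config, run_full_pipeline, format_report

report = run_full_pipeline(study_config())
print(format_report(report))
```

```
Design: 13 runs (4 factorial, 4 axial, 5 center), alpha=1.4140
  particle_size: PQ model, R2=0.7603, adjR2=0.6405, p(model)=0.0133 [override]
  pdi: SO model, R2=0.7480, adjR2=0.5679, p(model)=0.045 [override]
  zeta_potential: FO model, R2=0.6778, adjR2=0.6485, p(model)=0.000545 [override]
Optimum (D=0.741): lipid=251.0, surfactant=365.5
  predicted particle_size = 209.7 (d=0.892)
  predicted pdi = 0.273 (d=0.806)
  predicted zeta_potential = -12.49 (d=0.566)
  measured particle_size = 175.3 (relative error 19.6%)
  measured pdi = 0.232 (relative error 17.7%)
  measured zeta_potential = -8.35 (relative error 49.6%)
```

Reading the output: the packaged 13-run design is fitted with a pure
quadratic model for particle size, a full second-order model for the
polydispersity index and a straight line in the surfactant amount for zeta
potential (the classes used in the original study, applied here as explicit
overrides). Joint minimization of the three responses under observed-range
anchors and equal weights puts the most desirable formulation at about
251 mg lipid and 366 mg surfactant with overall desirability 0.741; the
validation lines compare each prediction at that point against the values
measured on the optimized formulation. See `docs/methods.md` for why the
desirability figure depends strongly on the (usually unpublished) anchor
convention.

The same chain is available from the shell:

```sh
nlcopt design --out design.csv          # build the 13-run rotatable CCD
nlcopt fit --out models.json            # fit/select surface models
nlcopt run --out report.json            # full pipeline incl. optimization
nlcopt simulate pk --seed 1 --out pk.csv
nlcopt nca --input pk.csv               # Cmax / Tmax / AUC
```

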