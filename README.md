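# nmrmap

Solution-NMR interaction mapping for protein–peptide binding studies, built
around the workflow used to characterize the J-domain co-chaperone Sis1 and
the docking of the Hsp70 (Ssa1) C-terminal EEVD tail onto its two
client-binding domains.

Given peak lists from ¹H–¹⁵N correlation spectra recorded under different
conditions, the package maps where and how a ligand binds:

- **Chemical-shift perturbation (CSP) mapping** — combined amide shift
  changes `CSP = sqrt((Δδ15N/10)² + Δδ1H²)`, significance by the
  mean + k·SD rule, per-domain summaries, and global (shared-K_D)
  fast-exchange titration fitting with the exact two-state quadratic binding
  isotherm — required at millimolar affinity where ligand depletion is not
  negligible.
- **Paramagnetic relaxation enhancement (PRE)** — intensity-ratio
  normalization against an unaffected reference set, a linear
  ratio-to-distance calibration (12–30 Å), region-specific attenuation
  cutoffs, and export of CNS/XPLOR-style ambiguous distance restraints for
  data-driven docking.
- **¹⁵N relaxation dynamics** — monoexponential R₁/R₂ fitting from
  three-point decays with Monte-Carlo uncertainties, R₂/R₁-based rotational
  correlation times per domain (`τc = sqrt(6·R2/R1 − 7)/(4π·νN)`), 1-SD
  ratio trimming, conformational-exchange flagging, and free-vs-bound
  comparisons (Welch's t-test).
- **Competition analysis** — three-condition experiments (free, +client,
  +client+competitor) classified per residue as `none`, `client_only`,
  `competitive`, or `broadened`.
- **Structure comparison** — Kabsch (SVD) Cα superposition, ensemble RMSD,
  and grid scans over model/residue-range choices.
- **Synthetic data generators** — every analysis has a ground-truth-emitting
  generator (`nmrmap simulate …`) so the full pipeline can be validated by
  recovery, not by eyeballing.

The Sis1 domain architecture ships as a constant
(`nmrmap.SIS1_DOMAINS`: J-domain 1–72, GF 73–121, GM 122–178, CTDI 179–257,
CTDII 258–335, DD 336–352); any other protein is a YAML file away.

## Worked example

Simulate a millimolar fast-exchange titration and fit the shared K_D:

```console
$ nmrmap simulate titration --seed 7 --out sim
wrote titration dataset to sim
$ nmrmap titrate --series sim/series.yaml --out fit.json
K_D = 2.007 +- 0.008 mM (19 residues)
```

(The generator's ground truth, written to `sim/truth.yaml`, is 2 mM.)

Fit ¹⁵N relaxation decays and estimate per-domain tumbling times:

```console
$ nmrmap simulate relax --seed 7 --out simr
wrote relax dataset to simr
$ nmrmap relax --series simr/decays.csv --out rates.csv --domain-out dyn.csv
J-domain: R2/R1 = 22.1 +- 1.3 (n=48/72), tau_c = 9.8 +- 0.3 ns
GF: R2/R1 = 28.0 +- 1.6 (n=34/49), tau_c = 11.1 +- 0.3 ns
GM: R2/R1 = 27.7 +- 1.8 (n=41/57), tau_c = 11.0 +- 0.4 ns
CTDI: R2/R1 = 73.2 +- 5.0 (n=53/79), tau_c = 18.1 +- 0.6 ns
CTDII: R2/R1 = 73.0 +- 5.0 (n=57/78), tau_c = 18.1 +- 0.6 ns
DD: R2/R1 = 75.8 +- 3.9 (n=14/17), tau_c = 18.5 +- 0.5 ns
```

The J-domain arm tumbles at ~9.8 ns while the dimeric C-terminal core
tumbles at ~18 ns — independent segmental motion, exactly the signature the
analysis is designed to expose.

Turn PRE attenuation profiles into docking restraints (spin label on
residue 202):

```console
$ nmrmap simulate pre --seed 7 --out simp
wrote pre dataset to simp
$ nmrmap pre --para simp/para.csv --dia simp/dia.csv --csv pre.csv \
      --tbl r.tbl --label-residue 202 --label-atom SG
alpha = 0.8000; 19 residues below cutoff
19 restraints -> r.tbl
$ head -2 r.tbl
assign (resid 202 and name SG) (resid 30 and name H) 1.8 0.0 10.2
assign (resid 202 and name SG) (resid 31 and name H) 1.8 0.0 10.2
```

Classify competitive binding across three conditions:

```console
$ nmrmap simulate compete --seed 7 --out simc
wrote compete dataset to simc
$ nmrmap compete --free simc/free.csv --client simc/client.csv \
      --both simc/both.csv --out comp.csv
threshold 0.07864 ppm; 23 competitive residues
  CTDI: [183, 184, 185, 186, 187, 188, 189, 190, 191, 192, 193, 194, 195,
         196, 197, 198, 199, 200, 201, 202, 203, 204, 205]
```

`nmrmap run --config pipeline.yaml` chains all stages over real peak lists
and writes per-stage CSV tables plus a `run.log` recording every threshold
and normalization constant.

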