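# raftgen

Comparative population-genetic connectivity analysis for codominant
microsatellite data, built around the question of whether intertidal
invertebrates associated with buoyant kelp (and hence able to disperse
by rafting on drifting holdfasts) maintain higher gene flow across
habitat discontinuities than their rock-dwelling relatives.

The package is aimed at population geneticists working with
multiallelic codominant markers in species with weak structure
(global F_ST on the order of 0.01), where null alleles are abundant
and the interesting signal lives in *geographic patterns* of
connectivity rather than in overall differentiation.

## What it computes

Given genotype tables (Genepop or CSV), site coordinates (or a
user-supplied marine-route distance matrix) and a habitat-gap
partition:

- **Species assignment** — a no-admixture Bayesian clustering
  (Gibbs sampler, K clusters, Dirichlet(λ) prior on allele
  frequencies, HWE within clusters), per-individual membership
  proportions *Q*, and threshold-based species calls (*Q* > 0.8,
  boundary discarded).
- **Null alleles** — Monte-Carlo homozygote-excess tests; EM estimates
  of the per-cell null frequency *r* under the observation model
  visible/visible → heterozygote, visible/null → apparent homozygote,
  null/null → blank; a simplified diagnostic separating null-allele-like
  from large-allele-dropout-like heterozygote deficits.
- **Differentiation** — H_S and H_T with Nei–Chesser small-sample
  corrections; Jost's
  *D*<sub>est</sub> = [(H_T − H_S)/(1 − H_S)]·k/(k − 1) with an
  HWE-conditional bootstrap CI; Weir's θ (raw and ENA null-corrected);
  Hedrick's standardized
  *G″*<sub>ST</sub> = k(H_T − H_S)/[(kH_T − H_S)(1 − H_S)]; and the
  equilibrium island-model migrant number
  *N*<sub>m</sub> = (1 − *G″*<sub>ST</sub>)/(4 *F*<sub>ST</sub>),
  globally (k = 4) and for all population pairs (k = 2).
- **Distances and spatial tests** — Cavalli-Sforza & Edwards chord
  distance *D*<sub>C</sub> = (2/π)√(2(1 − Σ<sub>a</sub>√(p_a q_a)))
  per locus, averaged over loci, with the null class included as one
  shared allelic state (INA); Mantel and partial Mantel permutation
  tests of genetic distance against geographic distance and a binary
  habitat-gap indicator; and the spatial analysis of shared alleles
  (SAShA), comparing the observed mean distance between same-allele
  copies (OM) with the panmictic expectation (EM).
- **Synthetic data** — a Balding–Nichols island-model generator with a
  null-allele observation layer, so every stage is testable end to end
  with known truth.

## Worked example

The numbered scripts under `analysis/` run the whole study on a
synthetic dataset with the study's structure (two cryptic species,
four sites spanning 372 km with a 180-km habitat gap, seven loci with
5–40 alleles, null alleles at frequencies 0–0.30):

```bash
python analysis/01_simulate_dataset.py --seed 7
python analysis/02_assign_species.py   --seed 7 --burnin 1000 --iters 4000 --chains 3
python analysis/03_null_alleles.py     --seed 7
python analysis/04_differentiation.py  --seed 7 --boot 500
python analysis/05_spatial_structure.py --seed 7 --mantel-perms 10000 --sasha-perms 5000
```

prints, among other things:

```
wrote 231 individuals x 7 loci at 4 sites (11.5% missing genotypes)
  cluster 0: 122 assigned
  cluster 1: 106 assigned
chains converged: True (min pairwise Q correlation 1.0000)
species 0: 14/28 cells with significant homozygote excess; null r range 0.00-0.46
species 1 (n=106): H_S=0.710 H_T=0.708 D_est=-0.006 (-0.031, 0.022) FST=0.013 FST(ENA)=0.005 G''ST=-0.010 N_m=51.9
species 0: Gen~Geo r=-0.20 (p=0.71); Gen~Gap|Geo r=-0.81 (p=1.00); SAShA OM=145.4 km EM=144.2 km (p=0.23)
```

Reading: the clustering cleanly separates the two simulated species
(the habitat × species cross-tab shows the expected imperfect habitat
segregation); null alleles are recovered where they were simulated;
both species show the near-zero differentiation the generator was
configured for (F_ST ≈ 0.01), so N_m is large or indefinite; and
neither species shows significant isolation by distance, matching a
panmictic SAShA outcome (OM ≈ EM).

The same workflow is available as a single command over a YAML config
(`raftgen run --config study.yaml`) and as per-stage CLI subcommands
(`raftgen simulate|convert|filter|assign|nullalleles|diffstats|distances|mantel|sasha`).

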