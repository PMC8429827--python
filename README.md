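# scnet

Structural covariance network analysis of brain subregion volumes, with
weighted graph-theory measures and permutation-based group inference.

## The problem

In temporal lobe epilepsy with hippocampal sclerosis, the amygdala,
hippocampus and thalamus are candidate hubs of the epileptogenic
network, and differences in their *intrinsic* networks — group-level
covariance structure among subregion volumes — have been proposed as
markers of surgical outcome. `scnet` implements that analysis chain for
cohorts of subjects with FreeSurfer-style subregional volumetry
(9 amygdala nuclei, 21 hippocampal subfields, 25 thalamic nuclei per
hemisphere):

1. **Volume normalization** — each raw volume (mm³) is expressed as a
   percentage of the subject's estimated total intracranial volume,
   `v = 100 · raw / eTIV`, and hemispheres are relabeled *ipsilateral* /
   *contralateral* relative to each subject's side of hippocampal
   sclerosis.
2. **Network construction** — for each structure × hemisphere × outcome
   group, a weighted graph whose nodes are the subregions and whose
   edge weights are partial correlations of normalized volumes across
   subjects, controlling for age and sex:
   `r_ij·(age,sex) = corr(ε_i, ε_j)` where `ε` are OLS residuals.
   Negative partial correlations are clipped to zero by default
   (absolute value available as a policy).
3. **Graph measures** — twelve weighted scalars per network: average
   strength, radius, diameter, eccentricity, characteristic path length
   `L`, global efficiency, local efficiency, mean clustering
   coefficient `C` (Onnela form), transitivity, modularity (seeded
   Louvain), assortativity coefficient, and the small-worldness index
   `σ = (C/C_rand)/(L/L_rand)` against degree-preserving rewired
   references. Edge length is `1/w`.
4. **Inference** — group differences in each measure are tested by
   label-permutation (the whole pipeline, residualization included, is
   re-run per permutation; p uses the add-one convention, so the
   smallest p at 1,000 permutations is 1/1001). Per-region volumes are
   compared by Student's t or Mann-Whitney depending on Shapiro-Wilk
   normality, Bonferroni-corrected within per-structure families
   (18 / 42 / 50 volume tests, 12 network measures).

Because no subject-level data of this kind are publicly deposited, the
package ships a first-class synthetic cohort generator
(`scnet.synthetic`) that draws two-group cohorts with realistic volume
scales, block-structured inter-region correlation, age/sex confounding
and ICV scaling, so the entire chain is testable end to end.

## Worked example

Two synthetic groups (29 vs 40 subjects) over the thalamic atlas, where
the poor-outcome group has inflated within-structure covariance
(ρ = 0.6 vs 0.3) — a network-level effect with no mean volume shift:

```python
from scnet import (SyntheticSpec, generate_cohort, normalize_volumes,
                   lateralize, build_group_network, measure_set,
                   NullModelSpec, network_group_difference)

spec = SyntheticSpec(structures=("thalamus",), n_modules=1,
                     rho_within=0.3, corr_inflation_poor=0.3)
cohort = generate_cohort(spec, seed=7)
nvm = lateralize(normalize_volumes(cohort))
for group in ("poor", "good"):
    conn = build_group_network(nvm, "thalamus", "ipsi", group)
    ms = measure_set(conn, NullModelSpec(n_random=50), seed=7)
    print(f"{group}: strength={ms.average_strength:.3f} "
          f"L={ms.characteristic_path_length:.3f} "
          f"eccentricity={ms.eccentricity:.3f} "
          f"sigma={ms.small_worldness_index:.3f}")
out = network_group_difference(cohort, "thalamus", "ipsi",
                               "average_strength", n_perm=1000, seed=7)
print(f"poor-good strength difference = {out.observed:.3f}, "
      f"p = {out.p_value:.3f}")
```

prints

```
poor: strength=15.020 L=1.634 eccentricity=2.170 sigma=1.001
good: strength=6.980 L=3.472 eccentricity=5.286 sigma=0.983
poor-good strength difference = 8.040, p = 0.002
```

The denser covariance of the poor group shows up as higher average
strength and shorter characteristic path length; shuffling outcome
labels 1,000 times and rebuilding both networks each time shows the
observed strength difference is essentially never matched under the
null (p = 2/1001).

The same analysis is available from the shell:

```sh
scnet run-all --seed 7 --n-perm 1000 --out results/demo
```

which writes per-group connectivity matrices (TSV + JSON provenance),
`measures.tsv` (12 measures × structure × hemisphere × group),
`permutations.json` (permutation outcomes per measure), `volumes.tsv`
and `clinical.tsv` comparison tables, and a `manifest.json` echoing the
effective configuration and master seed. Subcommands `simulate`,
`build-network`, `measures` and `compare` run partial stages; a YAML
config (`--config`) can set anything the flags can.

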