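# scentsel

Geographic variation and phenotypic selection analysis for hyperdiverse,
zero-inflated floral-scent matrices.

Chemical ecologists quantifying inflorescence volatiles by GC/MS end up
with wide trait matrices — hundreds of compounds, most of them absent
(non-detects) from most samples — plus per-individual fruit counts as a
female-fitness proxy.  `scentsel` packages the full analysis chain for
such data:

1. **Data transforms** — compound filtering against leaf/air controls,
   relative (percent) amounts, per-sample totals and richness, percentage
   and population-relative fruit set, z-standardisation.
2. **Geographic statistics** — Bray–Curtis / Euclidean distances, nested
   PERMANOVA (region + population-within-region, sequential sums of
   squares, seeded permutations), Mantel tests (Spearman), constrained
   ordination of principal coordinates (CAP/db-RDA) with compound-vector
   fitting and FDR correction, random-forest out-of-bag distinctness,
   Mann–Whitney and nested ANOVA.
3. **Non-detect gate** — a simulation quantifying how detection rate
   biases penalised-regression coefficients, used to decide which
   compounds are reliable enough for selection analyses.
4. **Pre-selection** — elastic net (linear signals) and a Boruta-style
   shadow-feature random-forest screen (non-linear signals), as
   scikit-learn estimators.
5. **Selection gradients** — Lande–Arnold multivariate regression of
   relative fitness w on z-scored traits: directional gradients β from
   `w = 1 + Σ β_c z_c`, quadratic gradients γ reported as twice the
   fitted squared-term coefficient of `w = 1 + Σ β_c z_c + ½ Σ γ_c z_c²`,
   with VIF-driven interaction substitution and Cook's-distance outlier
   handling.
6. **Synthetic studies** — a generator with known ground truth
   (hurdle-model emissions, regional multiplier, planted β/γ surface,
   binomial fruit readout) so every stage can be validated against
   planted signals and nulls.

See `docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

```python
from scentsel import (SyntheticTruth, generate_study, filter_compounds,
                      bray_curtis, permanova_nested, relative_fitness,
                      z_transform, ElasticNetSelector, fit_linear_gradients)

truth = SyntheticTruth(
    populations={"north": [("JOS", 70)], "south": [("DAO", 70)]},
    n_compounds=60,
    detection_probs=[0.95] * 2 + [0.5] * 58,
    sigma_range=(0.4, 0.7),
    beta={0: 0.4},            # directional selection on compound C000
    region_multiplier=3.0,    # 3-fold southern emission excess
    seed=5,
)
study, _ = generate_study(truth)
scent = filter_compounds(study.inflorescence(), None)

perm = permanova_nested(bray_curtis(scent), study.samples["region"],
                        n_perm=999, seed=1)
print(perm.table.loc["region", ["pseudo_F", "p"]].round(3))

# selection analysis within the southern focal population
dao = scent.subset_samples([s for s in scent.sample_ids
                            if s.startswith("DAO")])
dao = dao.subset_compounds([c for c in dao.compound_ids
                            if dao.values[c].nunique() > 1])
w = relative_fitness(study.fitness,
                     study.samples["population"]).loc[dao.sample_ids,
                                                      "rel_fruit_set"]
Z = z_transform(dao.values)
sel = ElasticNetSelector(random_state=1).fit(Z, w)
model = fit_linear_gradients(Z[sel.selected_], w)
print(model.gradients_.head(3).round(3))
```

Output:

```
pseudo_F    22.126
p            0.001
Name: region, dtype: float64
        type  estimate     se      t      p  significant
term
C000  linear     0.306  0.052  5.874  0.000         True
C012  linear     0.125  0.050  2.489  0.016         True
C029  linear    -0.093  0.053 -1.738  0.087        False
```

The regional term is overwhelmingly significant (the generator plants a
3-fold southern emission excess), and the planted directional gradient on
`C000` (beta = 0.4) is recovered as the strongest significant positive
selection gradient, 0.31 +- 0.05 — attenuated slightly by the binomial
fruit-count readout.  The weaker terms around it are the sampling noise a
one-SE elastic net admits at n = 70 among 60 candidate compounds.

A `scentsel` command-line interface wraps the same pipeline
(`scentsel simulate|summarize|geostats|eligibility|preselect|gradients|full
--config cfg.yaml --out results/`), writing tidy CSVs, a run manifest and
a log; identical configuration and seed reproduce byte-identical outputs.

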