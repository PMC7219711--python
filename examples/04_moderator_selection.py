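"""Forward-select macro-environmental moderators of the income elasticity.

Candidates are screened for pairwise collinearity, then added one at a time
to an OLS regression of per-country elasticities, first covering all five
dimensions (globalization, demographic, economic, labor, health policy),
then freely while BIC improves.  In the default synthetic truth moderators
m01–m05 (one per dimension) carry real effects; the rest are noise.
"""

import warnings

import obesity_elasticity as oe

ds = oe.generate_dataset(oe.GeneratorConfig(strata=("overall",)), seed=1)

pairs = oe.correlation_screen(ds.moderators, threshold=0.7)
print(f"correlation screen: {int(pairs.excluded.sum())} of {len(pairs)} pairs excluded")

elasticities = oe.ols_elasticities(ds.panel, "overall")["beta"]
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    state = oe.forward_select(elasticities, ds.moderators)

print(f"selected ({state.n_selected}): {state.selected}")
print("dimensions covered:",
      sorted({ds.moderators.dimensions[v] for v in state.selected}))
print("\nselection trace (chosen rows):")
chosen = state.trace[state.trace.chosen]
print(chosen[["phase", "round", "candidate", "dimension", "aic", "bic", "tstat"]]
      .round(2).to_string(index=False))
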