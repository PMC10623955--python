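"""Analyse the faecal bile-acid panel: composition, OPLS-DA/VIP, ROC.

Summarises the primary/secondary split, tests each of the 24 BAs,
fits OPLS-DA to rank variables by VIP, and evaluates the top marker with
a ROC curve and Youden cutpoint.
"""

import numpy as np

from bileaxis import (
    SimulationConfig,
    differential_bas,
    fit_oplsda,
    roc_analysis,
    simulate_ba_panel,
    summarize_composition,
    vip_select,
)

panel, truth = simulate_ba_panel(SimulationConfig.ba_panel_default(seed=1))

comp = summarize_composition(panel.values, panel.groups)
print(f"secondary-BA proportion: AF median {comp.median_prop_af:.3f} vs "
      f"control {comp.median_prop_control:.3f} (Wilcoxon p = {comp.p_value:.2e})")

diff = differential_bas(panel.values, panel.groups)
sig = diff[diff.p_value < 0.05]
print(f"differential BAs at p<0.05: {(sig.direction == 'up').sum()} up, "
      f"{(sig.direction == 'down').sum()} down in AF "
      f"(planted: 12 up, 4 down)")

model = fit_oplsda(panel.values, panel.groups)
print(f"\nOPLS-DA: R2Y = {model.r2y:.3f}, Q2 = {model.q2:.3f}, "
      f"mean VIP^2 = {(model.vip ** 2).mean():.6f}")
selected = vip_select(model, p_table=diff)
print(f"VIP > 1 selects {len(selected)} BAs, top five:")
for row in selected.head(5).itertuples(index=False):
    print(f"  {row.variable:<12} VIP={row.vip:.2f}  p={row.p_value:.1e}")

labels = (panel.groups == "AF").to_numpy()
curve = roc_analysis(panel.values["UDCA"].to_numpy(), labels)
print(f"\nUDCA as an AF marker: AUC = {curve.auc:.3f} "
      f"(95% CI {curve.ci95[0]:.3f}-{curve.ci95[1]:.3f})")
print(f"Youden cutpoint {curve.optimal_cutpoint:.1f} nmol/g: "
      f"sensitivity {curve.sens_at_cut:.2f}, specificity {curve.spec_at_cut:.2f}")
print("A strongly enriched UDCA yields an AUC well above 0.5; the cutpoint "
      "is the faecal concentration that best separates the groups.")
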