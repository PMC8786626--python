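"""Virtual pharmacology: SIRT1 inhibition and the diabetes check.

Reduces SIRT1 bioavailability to 10% at three nutrient levels (indirect
AMPK inhibition), then halves insulin-receptor abundance (a diabetes-like
condition) and reports normalized mTORC1 activation.
"""
from ampkmtor import baseline_parameters
from ampkmtor.experiments import run_diabetes_validation, run_sirt1_inhibition

params = baseline_parameters()

sirt1 = run_sirt1_inhibition((0.1, 0.005, 0.002687), params)
for v in (0.1, 0.005, 0.002687):
    key = f"vir_{v:g}"
    print(f"V_IR={v:<9g} control regime: {sirt1.derived[key + '_class_control']}")
    for out in ("pAMPK", "pmTORC1", "pmTORC2"):
        print(f"   {out:8s} change: {sirt1.derived[f'{key}_{out}_percent']:+7.1f} %")

diab = run_diabetes_validation(params)
print(f"\ndiabetes (IR x0.5): pmTORC1 normalized = "
      f"{diab.derived['pmTORC1_normalized']:.2f} (below 1 = reduced mTORC1)")
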