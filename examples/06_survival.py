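"""Stratify a simulated cohort by gene expression and compare survival.

Generates an expression/survival cohort in which high expression of the
target gene raises the event hazard, splits patients into top and bottom
expression quartiles, and compares the arms with Kaplan-Meier curves and a
log-rank test.
"""

from revscreen import generate_cohort, km_curve, logrank, stratify

cohort = generate_cohort(n=400, r_target=0.9, hr=3.0, censor_frac=0.2, seed=5)
cohort = cohort.set_index("sample_id")

strat = stratify(cohort["TARGET1"], top_frac=0.25, bottom_frac=0.25, gene="TARGET1")
arms = strat.groups[strat.groups != "middle"]
sub = cohort.loc[arms.index]
curves = km_curve(sub["time_months"], sub["event"], arms)

for grp, curve in curves.items():
    at_36 = curve.loc[curve["time"] <= 36, "survival"].iloc[-1]
    print(f"{grp}: S(36 months) = {at_36:.3f}")

chi2, p = logrank(sub["time_months"], sub["event"], arms)
print(f"log-rank chi-square = {chi2:.1f}, p = {p:.2e}")
# High expressors of the hazard-raising gene die faster; with 100 patients
# per arm and a true hazard ratio of 3 the log-rank test is decisive.
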