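"""Run the complete workflow and print the geometric-accuracy report.

Simulates a phantom with two embedded lesions (one in a strongly distorted
region, one where distortion is negligible), corrects with b0- and b50-based
reference pairs, and evaluates mutual information against the structural
reference plus Dice / centroid-distance / average-Hausdorff of the lesion
segmentations — demonstrating that the benefit of correction is location
dependent.
"""

from rpgdwi.io import run_full

res = run_full(
    {
        "seed": 3,
        "outdir": "scratch/example05",
        "protocol": {"n_stations": 2},
        "unwarp": {"fwhm_step_mm": 2.0},  # quick demo schedule
    }
)

df = res["report"].to_dataframe()
for metric in ("MI", "DSC", "ED", "AVD"):
    table = df[df.metric == metric].pivot_table(
        index="where", columns="condition", values="value"
    )
    print(f"\n{metric} ({df[df.metric == metric]['units'].iloc[0] or 'unitless'})")
    print(table.round(4).to_string())

print("\nMI rises with correction for every station; the lesion in the")
print("high-distortion region improves sharply while the low-distortion")
print("lesion is unchanged -- the location dependence of the correction.")
for t in res["report"].test_results:
    print(f"{t['comparison']}: W={t['statistic']}, p={t['p_value']:.3g} (n={t['n']})")
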