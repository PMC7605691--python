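"""Fit final size against applied volume and check seedling quality (H/D).

Across the four deficit treatments, final height and diameter respond
roughly linearly to the total volume applied; the slope (cm/L or mm/L) is
the marginal growth return per litre. H/D (height in cm over collar
diameter in mm) below 8 indicates a sturdy, plantable seedling.
"""

from seedwater import build_inpaper_fixture, fit_response, hd_ratio

ds = build_inpaper_fixture()
final = ds.final_sizes("tube")

print("species        response   slope      r^2")
for sp, g in final.groupby("species"):
    for response, col, unit in (("height", "height_cm", "cm/L"),
                                ("diameter", "diameter_mm", "mm/L")):
        fit = fit_response(list(zip(g["total_volume_l"], g[col])), response=response)
        print(f"{sp:14s} {response:9s} {fit.slope:7.3f} {unit}  {fit.r_squared:.3f}")

print("\nfull-replacement H/D quality check:")
for _, row in final[final["treatment"] == "V4"].iterrows():
    r = hd_ratio(row["height_cm"], row["diameter_mm"])
    verdict = "outside" if r.exceeds_limit else "within"
    print(f"  {row['species']:14s} H/D = {r.value:.2f}  ({verdict} the <8.0 range)")
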