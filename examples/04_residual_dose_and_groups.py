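"""Residual-dose conversion and group summary tables.

After a needle-free jet injection part of the 100 µL dose stays on the
skin surface; wiping it off and weighing the gauze gives a mass that the
suspension density (0.9527 g/mL, i.e. 1 g ↔ 1.0496 mL) converts to a
residual volume.  Group statistics then summarize measurements per
condition the way study tables do: mean ± sample SD per group and a
pooled mean across groups.
"""

from cryodist import group_stats, residual_dose

for mass in (0.0953, 0.0286, 0.0762):
    rd = residual_dose(mass)  # defaults: density 0.9527 g/mL, 100 µL injected
    print(f"gauze gain {mass*1000:5.1f} mg -> residual "
          f"{rd.residual_volume_ul:5.1f} µL = {rd.residual_fraction_pct:5.1f}% "
          f"of the injected dose (factor {rd.conversion_factor} mL/g)")

# pooling printed jet-injection group means (equal group sizes)
keloid = group_stats({"4 bar": [329.0], "5 bar": [384.0], "6 bar": [489.0]})
normal = group_stats({"4 bar": [210.0], "6 bar": [287.0]})
print(f"\nkeloid jet-injection pooled mean : {keloid.pooled_mean_rounded} µL")
print(f"normal-skin jet-injection pooled : {normal.pooled_mean_rounded} µL")

# a triplicate group, mean ± sample SD
gs = group_stats({"6 bar": [512.0, 466.0, 489.0]})
row = gs.table.iloc[0]
print(f"\ntriplicate example               : {row['mean']:.0f} µL ± "
      f"{row['sd']:.0f} (n = {row['n']})")
# The pooled means reproduce the arithmetic that turns per-pressure group
# means into the overall per-tissue summary figures.
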