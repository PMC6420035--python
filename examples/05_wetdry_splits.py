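"""How the diel wet-dry split moves the optimal attachment threshold.

Scans the wet-period length H and, per H, the attachment threshold
Q_PA (reduced scale), reporting the per-H optimum.
"""

from surfcol import SimulationParams, wetdry_scan

table = wetdry_scan(SimulationParams(), H_values=[8, 12, 16],
                    qpa_grid=[4, 8, 12, 16], n_reps=2)
for H, grp in table.groupby("H"):
    best = grp[grp.is_best].iloc[0]
    print(f"H = {H:4.0f} h wet: best Q_PA = {best.Q_PA:.0f} "
          f"(mean yield {best.mean_yield:.0f})")
print(table.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
# Longer wet periods let aggregates grow clonally before stress hits,
# so the threshold for joining an aggregate can afford to be higher.
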