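"""Phospho-FAK LRET plate reduction: scaled acceptor/donor ratio minus background.

Each well yields R = 1e4 x I665/I620; the antibody-only background R0 is
subtracted.  The synthetic plate is generated at the active device's
response of 1.23e4.
"""

from nanowinch import gen_plate, lret_ratio

plate = gen_plate(true_response=1.23e4, cv=0.10, wells_per_condition=3, seed=2024)
print(plate.to_string(index=False))

out = lret_ratio(plate)
row = out.iloc[0]
print(f"\n{row['condition']}: R(A/D) - R0 = {row['response']:.3g} +/- {row['sd']:.2g} "
      f"(n = {row['n_wells']} wells)")
print("\nA response near 1.2e4 over background indicates FAK phosphorylation -")
print("the mechanotransduction readout the device is designed to trigger.")
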