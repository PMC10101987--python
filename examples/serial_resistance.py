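"""Track drug sensitivity across serial samples with acquired resistance.

Simulates two time-points of the same synthetic patient screen where one
entry (drug_000) loses a factor of 10 in potency at T1 — the signature of
acquired resistance. Each time-point is scored independently and the DSS
tables are aligned; the drifted entry's delta is strongly negative while
undrifted entries stay near zero.
"""

from cllscreen import (
    SimScreenConfig,
    SimSerialConfig,
    analyze_screen,
    compare_screens,
    simulate_serial,
)

serial = simulate_serial(
    SimSerialConfig(time_points=("T0", "T1"),
                    potency_drift={"drug_000": {"T1": 1.0}}),
    SimScreenConfig(seed=7, n_singles=8, n_combos=4),
)
tables = {
    tp: analyze_screen(s.plate_maps, s.plates, s.library)[0]
    for tp, s in serial.screens.items()
}
cmp_res = compare_screens(tables, baseline="T0")

print("mDSS3 per time-point and delta vs T0:")
out = cmp_res.matrix.copy()
out["delta_T1"] = cmp_res.delta["T1"]
print(out.round(2).to_string())
print("\ndrug_000 carries a +1 log10 EC50 shift at T1 (10x potency loss);")
print(f"its delta of {cmp_res.delta.loc['drug_000', 'T1']:.1f} mDSS3 points "
      "flags the acquired resistance.")
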