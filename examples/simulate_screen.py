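"""Simulate a screen scenario and write its tables to disk.

Generates the 'heterogeneous' scenario (70% drug-sensitive clone, 30%
resistant subclone), writes the measurement/layout/ground-truth tables,
and cross-checks the dataset consistency report.
"""

from pathlib import Path

from orgscreen import (
    default_scenarios,
    simulate_plate,
    validate_dataset,
    write_layout,
    write_measurements,
)

out = Path("scratch/example_screen")
out.mkdir(parents=True, exist_ok=True)

cfg = default_scenarios(seed=1)["heterogeneous"]
measurements, layout, truth = simulate_plate(cfg)

write_measurements(measurements, out / "measurements.csv")
write_layout(layout, out / "layout.yaml")
truth.wells.to_csv(out / "truth_wells.csv", index=False)

report = validate_dataset(measurements, layout)

print(f"wells simulated:        {len(layout.wells)}")
print(f"measurement rows:       {len(measurements)}")
print(f"organoids per well:     ~{cfg.organoids_per_well:.0f} (Poisson)")
print(f"consistency findings:   {len(report.findings)}")
print(f"tables written to {out}/")
# Each row is one organoid at one timepoint: masked brightfield area, its
# dead-signal overlap, the invasive annulus, brightness and texture. The
# ground-truth table records each well's noise-free expected NDR and class.
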