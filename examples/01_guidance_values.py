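"""Derive human-biomonitoring guidance values (HBM-GV Gen Pop).

For each pyrethroid and metabolite, the guidance value is the urinary
concentration expected at steady dietary exposure equal to the ADI.  The
permethrin values (64 adult / 97 child ug DCCA/L) reflect its revised ADI
of 0.01 mg/kg bw/day.
"""

from pyrethrisk import derive_hbm_gv, load_default_registry

registry = load_default_registry()

print(f"{'substance':<20} {'metabolite':<10} {'ADI':>7}  {'adult':>8} {'child':>8}  (ug/L urine)")
for name in registry.substance_names:
    substance = registry.substance(name)
    for met in substance.metabolite_ids:
        adult = derive_hbm_gv(substance, met, registry.group("adult"), "current")
        child = derive_hbm_gv(substance, met, registry.group("child"), "current")
        print(f"{name:<20} {met:<10} {substance.adi_current:>7} "
              f"{round(adult):>8} {round(child):>8}")

print("\nA measured level equal to the guidance value corresponds to chronic")
print("exposure at the ADI; hazard quotients divide measured levels by these.")
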