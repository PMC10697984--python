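#!/usr/bin/env python
"""Tabulate electron stopping powers in liquid water.

Builds the default table of unrestricted S(E) and Δ = 1 keV restricted
L_Δ(E) collision stopping powers (200 log-spaced points, 1 keV – 6.5 MeV)
and writes it as TSV, printing a few anchor values.
"""

from pathlib import Path

from letfield import materials as m

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

table = m.build_table(m.default_energy_grid(), delta_kev=1.0)
table.write_tsv(OUT / "water_stopping_powers.tsv")

print(f"wrote {OUT / 'water_stopping_powers.tsv'} ({len(table.energy_grid_mev)} rows)")
for e in (0.001, 0.01, 0.1, 1.0):
    s = m.collision_stopping_power(e)
    l = m.restricted_let(e, 1.0)
    print(f"  E = {e * 1e3:7.1f} keV   S = {s:8.3f} keV/um   L_1keV = {l:8.3f} keV/um")
print("restricted equals unrestricted below 2 keV (no delta ray can carry > E/2)")
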