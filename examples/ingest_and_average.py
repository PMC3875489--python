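"""Harmonizing a raw instrument table into the canonical layout.

Builds a small LI-6400-style CSV (plus one bad row), reads it with the
built-in dialect, and averages replicates per leaf-hour.
"""

import tempfile
from pathlib import Path

import pandas as pd

from hydrostoma import average_by_leaf_hour, convert_units, read_gas_exchange_table

rows = [
    # Date, HHMMSS, Leaf, Cond, Photo, Ci, VpdL, Press, Tleaf
    ["2005-07-01", "10:05:00", "A", 0.20, 8.1, 281, 1.4, 95.0, 27.9],
    ["2005-07-01", "10:40:00", "A", 0.24, 8.5, 285, 1.5, 95.0, 28.3],
    ["2005-07-01", "10:20:00", "B", 0.31, 9.0, 278, 1.4, 95.0, 28.0],
    ["2005-07-01", "10:30:00", "C", 0.28, 8.8, 280, -0.2, 95.0, 28.1],  # bad VPD
]
cols = ["Date", "HHMMSS", "Leaf", "Cond", "Photo", "Ci", "VpdL", "Press", "Tleaf"]

with tempfile.TemporaryDirectory() as td:
    f = Path(td) / "syringa_site3.csv"
    pd.DataFrame(rows, columns=cols).to_csv(f, index=False)
    table = read_gas_exchange_table(f, species="Syringa pekinensis", pft="DCDS")
    print(f"read {len(table)} valid records (1 row dropped: negative VPD)")
    hourly = average_by_leaf_hour(table)
    print(f"after leaf-hour averaging: {len(hourly)} records")
    print(hourly.data[["date", "hour", "leaf", "gs_mol", "vpd_kpa"]].to_string(index=False))

# unit conversions used while harmonizing older instruments:
print("\nresistance 2.5 m2 s mol-1      ->", convert_units(2.5, "m2 s mol-1", "mol m-2 s-1"),
      "mol m-2 s-1")
print("velocity 0.01 m s-1 at 25C/sea ->",
      round(convert_units(0.01, "m s-1", "mol m-2 s-1", T=25, P=101.325), 4), "mol m-2 s-1")
print("\nLeaf A's two replicates in hour 10 became one averaged record; "
      "leaves stay separate to avoid pseudo-replication in the fit.")
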