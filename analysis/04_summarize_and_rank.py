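"""Summarize the screen: regression, ranking, and ortho steric maps.

Reads the run produced by 03_screen.py, reports the standardized
regression coefficients and the most/least stable candidates, and
tabulates the molecule-only buried volume for every ortho-substituent
combination -- the steric-map view of how ortho bulk shields the
phenoxyl oxygen.
"""

import json
from itertools import combinations_with_replacement
from pathlib import Path

import pandas as pd

from phenoxscreen.descriptors import steric_map
from phenoxscreen.geometry import build_radical_geometry
from phenoxscreen.library import SUBSTITUENT_CODES, SubstitutionPattern
from phenoxscreen.pipeline import summarize

ROOT = Path(__file__).resolve().parents[1]
RUN = ROOT / "results" / "screen"
OUT = ROOT / "results"

model = json.loads((RUN / "model.json").read_text())
print("standardized regression k_hat = b0 + b1*x_D + b2*x_HB + b3*x_BV")
print(f"  b0 = {model['beta0']:.2f}, b1 = {model['beta1']:.2f}, "
      f"b2 = {model['beta2']:.2f}, b3 = {model['beta3']:.2f}  "
      f"(R^2 = {model['r_squared']:.2f}, n = {model['n']})")

preds = pd.read_csv(RUN / "predictions.csv")
cands = pd.read_csv(RUN / "candidates.csv")
ranked = preds.merge(cands, left_on="candidate_id", right_on="id")
slot_cols = [f"slot_{p}" for p in range(2, 7)]
print("\nmost stable (lowest predicted k):")
for _, r in ranked.head(3).iterrows():
    print(f"  k_hat {r.k_hat_ns_inv:6.2f} /ns  " + "-".join(r[c] for c in slot_cols))
print("least stable (highest predicted k):")
for _, r in ranked.tail(3).iterrows():
    print(f"  k_hat {r.k_hat_ns_inv:6.2f} /ns  " + "-".join(r[c] for c in slot_cols))

tables = summarize(RUN)
print("\nmean H-bond probability by position class and substituent:")
print(tables["hbond_groups"].to_string(index=False))

rows = []
for a, b in combinations_with_replacement(SUBSTITUENT_CODES, 2):
    pattern = SubstitutionPattern((a, "H", "H", "H", b))
    pct = steric_map(build_radical_geometry(pattern), grid_step=0.15).buried_pct
    rows.append((f"{a}/{b}", pct))
ortho = pd.DataFrame(rows, columns=["ortho_pair", "buried_pct"]).sort_values(
    "buried_pct"
)
ortho.to_csv(OUT / "ortho_buried_volume.csv", index=False)
print("\nmolecule-only buried volume by ortho pair (%):")
print(ortho.to_string(index=False))
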