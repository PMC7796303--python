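"""Curate a raw endpoint table: standardize structures, convert units,
deduplicate.

Builds a small in-memory table mixing an organic salt, a metal complex,
an inhalation unit risk and a plain oral slope factor, then runs the
curation rules and prints what survived and why the rest was rejected.
"""

from sfqsar import curate

rows = [
    # sodium acetate with an oral slope factor: salt is reduced to the
    # neutral parent acid
    {"id": "acetate_salt", "smiles": "CC(=O)[O-].[Na+]", "route": "oral",
     "value": "1.5", "units": "per_mg_kg_day"},
    # cisplatin-like platinum complex: rejected (metal)
    {"id": "pt_complex", "smiles": "[Pt](Cl)(Cl)(N)N", "route": "oral",
     "value": "2.0", "units": "per_mg_kg_day"},
    # vinyl chloride with an inhalation unit risk per (ug/m3): converted
    # to an inhalation slope factor per (mg/kg-day) via ISF = IUR*BW*CF/IR
    {"id": "vinyl_chloride", "smiles": "C=CCl", "route": "inhalation",
     "value": "8.8e-6", "units": "per_ug_m3"},
    # benzene twice with conflicting values: both rejected
    {"id": "benzene_a", "smiles": "c1ccccc1", "route": "oral",
     "value": "0.055", "units": "per_mg_kg_day"},
    {"id": "benzene_b", "smiles": "C1=CC=CC=C1", "route": "oral",
     "value": "0.1", "units": "per_mg_kg_day"},
    # no value: a candidate non-carcinogen for the classifier
    {"id": "ethanol", "smiles": "CCO", "route": "oral", "value": "",
     "units": ""},
]

dataset = curate(rows)

print("curated records:")
for r in dataset.records:
    print(f"  {r.identifier:15s} {r.smiles:12s} route={r.route.value:10s} "
          f"value={r.raw_value}")
print("rejected:")
for ident, reason in dataset.rejected:
    print(f"  {ident:15s} {reason.value}")

# The vinyl chloride IUR of 8.8e-6 (ug/m3)^-1 becomes
# 8.8e-6 * 70 * 1000 / 20 = 0.0308 (mg/kg-day)^-1 — the same dose scale
# as the oral slope factors, so one regression pipeline serves both routes.
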