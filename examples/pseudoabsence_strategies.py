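"""Build the five response datasets and compare pseudoabsence draws.

Three presence-only strategies draw 284 pseudoabsences from the 801
unsurveyed lakes: anywhere (random), outside the convex hull around
invaded lakes (distant), or inside it (proximal). Distant pseudoabsences
are environmentally most different from presences, which inflates
apparent discrimination ability.
"""

import numpy as np

from milfoilsdm import SimulationConfig, build_dataset, generate_landscape, presence_hull

table = generate_landscape(SimulationConfig(seed=1))
part = presence_hull(table)
print(f"presence hull: {len(part.inside_ids)} unsurveyed lakes inside, "
      f"{len(part.outside_ids)} outside")

rng = np.random.default_rng(1)
for kind in ("PA", "PO_random", "PO_distant", "PO_proximal", "ABUNDANCE"):
    ds = build_dataset(table, kind, rng=rng)
    roles = ds.df["role"].value_counts().to_dict()
    print(f"{kind:12s} rows={len(ds.df):4d} roles={roles}")

# Mean degree days of each zero-labelled group: distant pseudoabsences
# come from far colder lakes than true absences do, so a model trained
# against them faces an easier (and less informative) contrast.
pa = build_dataset(table, "PA")
dist = build_dataset(table, "PO_distant", rng=np.random.default_rng(2))
gdd_abs = pa.df.loc[pa.df["role"] == "absence", "gdd_wtr_10c"].mean()
gdd_pseudo = dist.df.loc[dist.df["role"] == "pseudoabsence", "gdd_wtr_10c"].mean()
print(f"mean degree days - true absences: {gdd_abs:.0f}, "
      f"distant pseudoabsences: {gdd_pseudo:.0f}")
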