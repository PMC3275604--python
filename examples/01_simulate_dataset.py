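"""Generate one synthetic study: population, group sightings, attributes.

Builds a 58-male population with six social communities, simulates group
sightings until every male reaches his target count, applies the
social-transmission overlay, and prints the summary statistics the design
is calibrated to (sighting counts, raider fraction, converted males).
"""

import raidnet as rn

cfg = rn.PopulationConfig(seed=1)
ds = rn.generate_dataset(cfg)

counts = ds.sightings.groupby("male_id")["sighting_id"].nunique()
print(f"{len(ds.attributes)} males, {ds.sightings['sighting_id'].nunique()} group sightings")
print(
    f"sightings per male: mean {counts.mean():.1f}, median {counts.median():.0f}, "
    f"min {counts.min()}, max {counts.max()}"
)
print(
    f"raiders: {ds.attributes['raider'].sum()} of {len(ds.attributes)} "
    f"({ds.attributes['raider'].mean():.1%}); {len(ds.converted)} acquired the "
    "behavior from an older raider among their top-2 associates"
)
paths = ds.write("scratch/example_data")
print("wrote:", ", ".join(paths.values()))

# The counts are calibrated to a long-tailed field design: a median male is
# seen ~18 times while the most-seen male approaches ~107 sightings, and the
# raider fraction is centred on 21/58 before transmission.
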