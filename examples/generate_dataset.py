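"""Generate a small synthetic drawing dataset on disk.

Writes PNG renders, vector stroke JSONs, ground-truth JSONs and a
manifest CSV for a scaled-down five-individual corpus, then prints the
per-individual and per-period composition.
"""


from apedraw import RunConfig, generate_dataset

config = RunConfig(
    seed=7,
    counts={"Gypsy": 4, "Julie": 4, "Yuki": 4, "Kiki": 4, "Molly": 38},
    px_per_mm=1.0,
)
manifest = generate_dataset(config, "example_dataset")
print(f"wrote {len(manifest)} drawings to example_dataset/")
print("\nper individual:")
print(manifest["individual"].value_counts().to_string())
molly = manifest[manifest["individual"] == "Molly"]
print("\nMolly drawings per 3-month period (balanced subsampling):")
print(molly["period"].value_counts().sort_index().to_string())
# The longitudinal individual is spread as evenly as possible over the
# 19 periods; everyone else draws on dates scattered over the window.
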