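"""Generate a synthetic multi-site OTU + environment time series with ground truth.

The generator emulates the processed data layer of a monthly river survey:
3 sites x 2 depths x 15 months, OTU relative abundances plus an
environmental panel, with planted summer blooms, lagged pairwise couplings
and module structure.
"""

from mran import GeneratorConfig, generate_dataset, write_fixture

cfg = GeneratorConfig(n_otus=60, n_modules=4, n_cyano_otus=4, seed=42)
table, truth = generate_dataset(cfg)

print(f"samples: {len(table.data)}  (3 sites x 2 depths x 15 months, minus gaps)")
print(f"features: {len(table.otu_features)} OTUs "
      f"({len(table.cyano_features)} cyanobacterial) + {len(table.env_features)} environmental")
print(f"planted couplings: {len(truth.planted_edges)} "
      f"(recurrent) + {len(truth.spurious_edges)} (single series set only)")
print(f"true bloom samples: {len(truth.bloom_months)}")

paths = write_fixture((table, truth), "scratch/example_fixture")
print("fixture files:", ", ".join(p.name for p in paths))
# The bloom samples are the (site, depth, month) combinations where the
# bloom-forming OTU exceeds 10% of the community while chl-a exceeds 15 ug/L.
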