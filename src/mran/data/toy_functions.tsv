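# Synthetic toy function mapping for tests and examples.
# Two-column layout: function <tab> taxon selector (exact rank label or OTU id).
# Not derived from any external database.
nitrate_reduction	Herbaspirillum
nitrate_reduction	Rhodobacter
aerobic_ammonia_oxidation	Nitrosomonas
fermentation	Flavobacterium
fermentation	Sediminibacterium
hydrocarbon_degradation	Phenylobacterium
hydrocarbon_degradation	Paucimonas
ureolysis	Sporichthya
human_pathogens	Roseomonas
nitrogen_fixation	Herbaspirillum
photoautotrophy	Cyanobacteria
methylotrophy	Methylophilus
intracellular_parasites	Polynucleobacter
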