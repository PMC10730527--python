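"""Generate a seeded synthetic two-species world and look at its structure.

The world emulates what the real analysis consumes: an anatomy ontology, two
species' annotation tables and weighted PPI networks with one planted module
each, and an ortholog map with teleost-style duplicates. Everything is
reproducible from the seed.
"""

from anatomod import SyntheticConfig, generate_world, write_world

cfg = SyntheticConfig(seed=1)
world = generate_world(cfg)

print(f"ontology terms:        {len(world.ontology.terms)}")
print(f"proteins per species:  {cfg.n_proteins}")
print(f"network edges (A/B):   {world.net_a.n_edges()} / {world.net_b.n_edges()}")
print(f"planted module size:   {len(world.module_a)} per species")
print(f"conserved members:     {len(world.conserved_a)} "
      f"(= round({cfg.conserved_fraction} * {cfg.module_size}))")
print(f"original / hidden:     {len(world.original_a)} / {len(world.hidden_a)} "
      "(hidden members are the prediction targets)")
print(f"ortholog pairs:        {len(world.orthologs)}")

dups = sum(1 for c in world.orthologs.b_to_a().values() if len(c) > 1)
print(f"duplicated B genes:    {dups} "
      f"(~{cfg.duplication_rate:.0%} of B genes have two A copies)")

paths = write_world(world, "scratch/example_world")
print(f"\nfiles written: {', '.join(sorted(p.name for p in paths.values()))}")
print("These are the OBO / TSV dialects the pipeline reads back in.")
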