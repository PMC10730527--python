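"""Cross-species module comparison: conserved proteins as hubs.

Two homologous modules are partitioned into conserved and module-specific
proteins through the ortholog map; weighted degrees are normalised by module
size and compared with Wilcoxon rank-sum tests. The generator plants the
conserved-hub effect (hub_bias > 0), so the comparison should recover it.
"""

import numpy as np

from anatomod import (
    SyntheticConfig,
    assemble_module,
    compare_modules,
    generate_world,
)

world = generate_world(SyntheticConfig(seed=1))
module_a = assemble_module(world.net_a, world.entity_a.target, world.module_a)
module_b = assemble_module(world.net_b, world.entity_b.target, world.module_b)

result = compare_modules(module_a, module_b, world.orthologs)
print(f"module A: {len(module_a.nodes)} proteins "
      f"({len(result.conserved_a)} conserved, {len(result.specific_a)} specific)")
print(f"module B: {len(module_b.nodes)} proteins "
      f"({len(result.conserved_b)} conserved, {len(result.specific_b)} specific)")

for sp, conserved, specific, nwd in (
    ("A", result.conserved_a, result.specific_a, result.nwd_a),
    ("B", result.conserved_b, result.specific_b, result.nwd_b),
):
    med_c = np.median([nwd[p] for p in conserved])
    med_s = np.median([nwd[p] for p in specific])
    stat, p = result.tests[sp.lower()]
    print(f"species {sp}: median normalised weighted degree "
          f"conserved {med_c:.4f} vs specific {med_s:.4f} "
          f"(Wilcoxon p = {p:.2e})")

print("\ntop matched ortholog pairs by in-module rank:")
print(result.rank_table.sort_values("rank_a").head(5).to_string(index=False))
print("\nConserved proteins carry more module weight than specific ones — "
      "the planted hub bias is recovered as a significant rank-sum shift.")
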