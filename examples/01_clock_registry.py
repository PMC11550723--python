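"""Load the bundled clock site lists and partition the array universe.

The seven bundled coefficient files are synthetic stand-ins whose per-clock
site counts and overlap structure mirror the published clocks (Horvath 353,
Hannum 71, Weidner 102, Zhang elastic-net 514; PhenoAge 513, DNAmTL 140,
DunedinPACE 173).  Grouping them by generation and deduplicating shared
sites yields the two clock-site sets every enrichment compares against the
rest of the array.
"""

from clocktraj import build_site_groups, load_bundled_clocks, site_coefficient_direction

clocks = load_bundled_clocks()  # DNAmTL coefficients arrive already reversed
for c in clocks:
    print(f"{c.name:12s} {c.generation.value:13s} {len(c):4d} sites")

universe = {s for c in clocks for s in c.site_ids} | {f"cg9{i:07d}" for i in range(2000)}
groups = build_site_groups(clocks, universe)
print(f"\nfirst-generation union:        {len(groups.first_gen_sites)} unique sites")
print(f"second/third-generation union: {len(groups.second_third_gen_sites)} unique sites")
print(f"background for first-gen comparison: {len(groups.background('first'))} sites")

directions = site_coefficient_direction(clocks)
counts = {d: sum(v == d for v in directions.values()) for d in ("positive", "negative", "mixed")}
print(f"coefficient directions across clocks: {counts}")
# The union sizes are what the enrichment analyses condition on: each clock
# group is compared against every other measured site on the array.
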