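"""Annotate genes in a raw synthetic genome by peptide-pattern matching.

Plants four reverse-translated proteins in a random genome and runs
both annotation modes: fungal (2000-base fragments, six-frame scoring,
5800-base merging) and bacterial (independent stop-to-stop ORFs longer
than 50 residues).
"""

import pepsig as ps
from pepsig import synthetic as syn

spec = syn.SyntheticSpec(n_families=2, subfamilies_per_family=2,
                         proteins_per_subfamily=10, seed=2)
proteins, truth = syn.generate_family_pool(spec)
groups = []
for family in truth.families:
    members = [p for p in proteins if truth.protein_truth[p.id][0] == family]
    built, _ = ps.build_subfamilies(members, ps.PPRConfig(), family=family)
    groups.extend(built)

picks = [p for p in proteins if p.id.endswith("_p001")]
genome, planted = syn.generate_genome(picks, truth, spacing=(8000, 12000), seed=3)
print(f"genome of {len(genome.seq)} bases with {len(planted.genes)} planted genes\n")

for mode in ("fungal", "bacterial"):
    calls = ps.annotate_genome(genome, groups, ps.HotpepConfig(mode=mode))
    print(f"{mode} mode: {len(calls)} gene calls")
    for c in calls:
        print(f"  {c.family} {c.group_id}  {c.start + 1}-{c.end}  "
              f"score {c.score:.2f}  ({c.n_fragments} fragment(s))")
    print()
# Fungal-mode intervals are merged fragment spans around each gene;
# bacterial-mode intervals are the exact stop-to-stop coding regions.
# The score is the sum of the matched peptides' subfamily frequencies.
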