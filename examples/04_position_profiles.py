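"""Profile where a subfamily's conserved peptides sit along its proteins.

Each peptide is placed at the median of its first-occurrence start over
the member proteins and binned into 20-residue intervals; summing the
per-subfamily profiles gives the family-level accumulated profile.
"""

import pepsig as ps
from pepsig import synthetic as syn
from pepsig.distribution import accumulated_profile, position_profile

spec = syn.SyntheticSpec(n_families=1, subfamilies_per_family=3,
                         proteins_per_subfamily=10, seed=5)
proteins, truth = syn.generate_family_pool(spec)
by_id = {p.id: p for p in proteins}
groups, _ = ps.build_subfamilies(proteins, ps.PPRConfig(), family="FAM1")

profiles = []
for g in groups:
    profile = position_profile(g, [by_id[m] for m in sorted(g.members)])
    profiles.append(profile)
    bins = ", ".join(f"[{s}-{s + 19}]: {c}" for s, c in sorted(profile.counts.items()))
    print(f"{g.id}: {bins}")

acc = accumulated_profile(profiles)
print("\naccumulated over subfamilies:")
for start, count in sorted(acc.counts.items()):
    print(f"  residues {start}-{start + 19}: {count} peptides")
# Each subfamily's 70 peptides pile up in the few bins spanning its
# planted conserved region, the synthetic analogue of a conserved
# catalytic-site region in a real enzyme family.
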