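"""Distance-based phylogeny of planted P450 families.

Turns the all-vs-all identity matrix into distances (d = 1 - identity/100),
infers a neighbor-joining tree and serializes it as Newick.  Members of the
same planted family should group together.
"""

import numpy as np

from arcp450.identity import identity_matrix
from arcp450.io_formats import write_newick
from arcp450.phylo import identity_to_distance, nj_tree
from arcp450.synthetic_data import P450FamilySpec, generate_p450_family

rng = np.random.default_rng(6)
records, seeds = [], []
for name in ("A", "B", "C"):
    fam_records, truth = generate_p450_family(
        P450FamilySpec(name, n_members=3), rng, previous_seeds=seeds
    )
    seeds.append(truth.seed_sequence)
    records.extend(fam_records)

matrix = identity_matrix(records)
tree = nj_tree(identity_to_distance(matrix))
print(write_newick(tree))
print("\nLeaf labels are protein ids; branch lengths are identity distances "
      "(0 = identical, 1 = no identity).  Each planted family forms a clade.")
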