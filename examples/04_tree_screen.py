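"""Detect a planted accelerated lineage in a simulated gene family.

Simulates an alignment on an 8-taxon tree with the focal tip's terminal
branch stretched 5x, rebuilds the tree by neighbor-joining on Jukes-Cantor
distances, compares its topology to the truth with Robinson-Foulds, and
runs the terminal-branch acceleration screen.
"""

import numpy as np

from sbgturnover import (
    jc_distance_matrix,
    nj_tree,
    read_newick,
    rf_distance,
    simulate_alignment,
    terminal_branch_screen,
)

TREE = (
    "(((A:0.05,B:0.05):0.05,(C:0.05,D:0.05):0.05):0.02,"
    "((E:0.05,F:0.05):0.05,(G:0.05,H:0.05):0.05):0.02);"
)
rng = np.random.default_rng(7)
truth = read_newick(TREE)
aln = simulate_alignment(truth, 5000, rng,
                         acceleration_factor=5.0, focal_species="A")
est = nj_tree(jc_distance_matrix(aln))

congruence = rf_distance(est, truth)
print(f"RF distance to the true topology: {congruence.rf} "
      f"(normalized {congruence.normalized_rf:.2f})")

report = terminal_branch_screen(est)  # ratio >= 3 AND robust z >= 2
print(f"{'leaf':<6}{'terminal':>10}{'ratio':>8}{'robust z':>10}  flagged")
for row in report.rows:
    print(f"{row.leaf:<6}{row.terminal_length:>10.4f}{row.ratio:>8.2f}"
          f"{row.robust_z:>10.2f}  {'<-- accelerated' if row.flagged else ''}")
print()
print("the ratio compares each terminal branch with the median of the")
print("others; the planted 5x branch stands out while unaccelerated tips")
print("stay near ratio 1.")
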