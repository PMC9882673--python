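"""Order array conformations by structural similarity.

Computes all-pairs superposition RMSD (proper rotations only) over the bp
traces of 8 mononucleosome models and sorts them by single-linkage
hierarchical clustering; similar conformations end up on adjacent leaves of
the dendrogram, mimicking the most-populated-to-rarest ordering used to
morph between states.
"""

from nucarray import rmsd_matrix, single_linkage_order
from nucarray.synthetic import generate_population, load_preset

models = generate_population(load_preset("mono_5mM"), 8, seed=3)
mat = rmsd_matrix(models)
order = single_linkage_order(mat)

print("pairwise RMSD (A), upper triangle:")
for i in range(len(models)):
    row = " ".join(f"{mat.values[i, j]:6.1f}" for j in range(i + 1, len(models)))
    print(f"  model {i}: {row}")
print("single-linkage leaf order:", list(order.leaf_order))
print("dendrogram (newick):", order.to_newick())
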