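"""Faith's PD, MNTD, redundancy and the invasion-strategy statistic.

Works through the standard three-species fixture ((A:1,B:1):1,C:2); by hand:
A and B are sisters two branch-length units apart, C is four units from
either.  The strategy statistic compares community packing before and after
the non-native species arrive.
"""

from invadiv import faiths_pd, invasion_strategy, mntd, patristic_distances
from invadiv.diversity import redundancy_transform
from invadiv.trees import TreeIndex

tree = TreeIndex.from_newick("((A:1,B:1):1,C:2);")

pd_native = faiths_pd(tree, ["A", "B"])          # natives: A, B
pd_entire = faiths_pd(tree, ["A", "B", "C"])     # C is the newcomer
d = patristic_distances(tree, ["A", "B", "C"])
mntd_native = mntd(d, [0, 1])
mntd_entire = mntd(d)

print(f"native PD  = {pd_native:.4f}   (branch length spanning A,B + root path)")
print(f"entire PD  = {pd_entire:.4f}   (adding C reaches the whole tree)")
print(f"native MNTD = {mntd_native:.4f}  (A and B are each other's nearest taxon)")
print(f"entire MNTD = {mntd_entire:.4f}  (C sits 4 units from its nearest neighbour)")

# redundancy reflects MNTD against the dataset maximum: larger = more packed
print(f"redundancy at reference max 4 = {redundancy_transform(mntd_entire, 4.0):.4f}")

s = invasion_strategy(mntd_native, mntd_entire)
print(f"invasion strategy = {s:+.4f}")
print("positive: the newcomer made the community more phylogenetically"
      " dispersed (invasion via dissimilarity); negative would mean it"
      " nested inside the native clade (via similarity).")
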