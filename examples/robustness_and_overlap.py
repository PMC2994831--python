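"""The set-wise similarity metric behind robustness and overlap rate.

Robustness of mapping averages the Jaccard similarity |A n B| / |A u B|
over all pairs of voxel sets selected in different cross-validation
folds; the same metric applied to the maps of two different contrasts is
the overlap rate.
"""

from micmap import overlap_rate, robustness

fold_sets = [
    {1, 2, 3, 4, 5},
    {1, 2, 3, 4, 6},
    {1, 2, 3, 7, 8},
    {1, 2, 3, 4, 5},
]
print(f"identical sets        -> robustness {robustness([fold_sets[0]] * 4):.3f}")
print(f"disjoint sets         -> robustness "
      f"{robustness([{1, 2}, {3, 4}, {5, 6}, {7, 8}]):.3f}")
print(f"four CV-fold maps     -> robustness {robustness(fold_sets):.3f}")
print(f"two contrasts, half shared -> overlap rate "
      f"{overlap_rate(set(range(100)), set(range(50, 150))):.3f}")
print("\n1 means the same voxels are selected every fold; 0 means the map"
      "\nmoves entirely between folds.")
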