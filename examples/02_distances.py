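"""Compare barcodes with the barcode distance and the bottleneck distance.

The barcode distance integrates |difference of the two density profiles|
(components alive at each radius) and is the workhorse for grouping; the
bottleneck distance is the classical stable diagram metric.
"""

from topomorph import (PersistenceBarcode, bottleneck_distance, dist_bar,
                       density_profile)

b1 = PersistenceBarcode([[10.0, 0.0], [6.0, 4.0]])   # a Y-shaped neurite
b2 = PersistenceBarcode([[10.0, 0.0]])               # a single branch

prof = density_profile(b1)
print("components alive at radius 5 in b1:", prof(5.0))   # both bars cover 5

print("dist_bar(b1, b2) =", dist_bar(b1, b2))
# 2.0: the profiles differ by one component exactly on [4, 6].

print("bottleneck(b1, b2) =", bottleneck_distance(b1, b2))
# 1.0: the cheapest matching sends the short bar (6,4) to the diagonal at
# cost |6-4|/2 and matches the long bars exactly.
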