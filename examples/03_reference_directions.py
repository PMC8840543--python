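"""Das-Dennis reference directions used by NSGA-III's niching.

With M = 3 objectives (gender, age, action) and p = 8 partitions the
simplex lattice has C(3+8-1, 8) = 45 directions — below the population
size of 50, as required for well-behaved niching.
"""

from privhar import das_dennis_directions

for M, p in [(3, 8), (3, 3), (2, 4)]:
    ref = das_dennis_directions(M, p)
    print(f"M={M}, p={p}: {len(ref)} directions; first three:")
    for d in ref.directions[:3]:
        print("   ", d)
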