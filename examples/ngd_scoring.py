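"""Normalized Google Distance from co-occurrence counts, and the composite score.

NGD measures dissimilarity of two terms from how often each occurs and
co-occurs in a corpus of size N:

    NGD(x, y) = (max(log f(x), log f(y)) - log f(x,y))
                / (log N - min(log f(x), log f(y)))

A term is at distance 0 from itself; terms that never co-occur are
infinitely distant. The result score turns NGD into a bounded similarity
and blends it with record support and path length.
"""

import math

from fedkg import CooccurrenceTable, ngd
from fedkg.scoring import length_factor, support_factor

table = CooccurrenceTable.from_dict(
    {
        "N": 1000,
        "terms": {"diabetes": 100, "CDK2": 50, "metformin": 25, "zebrafish": 40},
        "pairs": [
            ["diabetes", "CDK2", 25],
            ["CDK2", "metformin", 10],
        ],
    }
)

for x, y in [("diabetes", "CDK2"), ("CDK2", "metformin"), ("diabetes", "zebrafish"),
             ("diabetes", "diabetes")]:
    d = ngd(x, y, table)
    shown = "inf" if math.isinf(d) else f"{d:.5f}"
    print(f"NGD({x}, {y}) = {shown}")

print()
for n in (1, 2, 3, 5, 10):
    print(f"support factor for {n:>2} records: {support_factor(n):.3f}")
for L in (1.0, 1.5, 2.0):
    print(f"length factor for mean distance {L}: {length_factor(L):.3f}")
# NGD(diabetes, CDK2) ~ 0.463: frequently co-occurring, hence similar;
# never co-occurring terms (diabetes/zebrafish) are infinitely distant and
# contribute zero similarity. The support factor grows with diminishing
# returns; the length factor rewards results whose open nodes sit close to
# the pinned node.
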