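"""Intervals on [0,1] and the three admissible linear orders.

Overlapping intervals are often incomparable under the componentwise
partial order; classification decisions therefore use a linear order.
"""

from intervalens import Interval, compare, join, meet, partial_leq

x, y = Interval(0.2, 0.4), Interval(0.1, 0.5)
print(f"x = {x}, y = {y}")
print(f"componentwise x vs y : {partial_leq(x, y).value}")
print(f"join(x, y) = {join(x, y)},  meet(x, y) = {meet(x, y)}")

# Equal bound sums (0.6 each) force the Xu-Yager tie-break on widths
# (0.2 vs 0.4): the narrower interval precedes.
for order in ("xy", "lex1", "lex2"):
    c = compare(x, y, order)
    rel = {-1: "x before y", 0: "equal", 1: "y before x"}[c]
    print(f"under {order.upper():4}: {rel}")

# -1/+1 say which interval the order ranks lower; the ensemble always
# picks the class whose aggregated interval ranks highest.
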