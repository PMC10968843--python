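"""The ten interval-valued aggregation functions A1-A10.

Each maps n class intervals (one per classifier group) to a single
interval; families differ in how optimistic the combined bounds are.
"""

from intervalens import Interval, aggregate, available_aggregations

xs = [Interval(0.2, 0.4), Interval(0.1, 0.5), Interval(0.3, 0.9)]
print("inputs:", ", ".join(map(str, xs)))
for name in available_aggregations():
    out = aggregate(name, xs)
    print(f"{name:>3}: [{out.lower:.4f}, {out.upper:.4f}]  width={out.width:.4f}")

# All results stay inside the hull [0.1, 0.9] of the inputs (averaging
# character); A1 is the plain arithmetic mean of both bounds, the Lehmer
# and power-mean families shift weight toward larger member scores.
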