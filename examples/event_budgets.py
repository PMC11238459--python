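"""The event-budget arithmetic that drives every evolutionary stage.

The number of transcripts undergoing an AS event of type x at one
evolutionary stage is ceil(k_tc * c_s_r * n * tc_x) on a branch of
length c_s_r with n source transcripts, and ceil(n * tc_x) at the
root.  The ceiling guarantees at least one event whenever the product
is positive, so even short branches reshape transcript sets.
"""
from splicesim import event_budget, root_event_budget

print("root stage, 2 sources, tc_es=0.3:",
      root_event_budget(2, 0.3), "es event(s) -> 3 sources at next stage")
print("branch stage, 7 sources, tc_ir=0.1, k_tc*c_s_r=1:",
      event_budget(7, 0.1, 1.0, 1.0), "ir event(s)")
print("branch stage, 3 sources, tc_es=0.2, k_tc*c_s_r=1:",
      event_budget(3, 0.2, 1.0, 1.0), "es event(s)")

print("\nbudget growth with branch length (n=10, tc_es=0.25, k_tc=5):")
for c in (0.0, 0.05, 0.2, 0.5, 1.0):
    print(f"  c_s_r={c:4.2f}: {event_budget(10, 0.25, 5.0, c)} events")
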