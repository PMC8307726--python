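"""Build the L9(3^4) screening plan for the four camera factors.

Nine runs cover four 3-level factors so that any two factors see all
nine level combinations exactly once; per-level means of a response
computed over these runs therefore isolate each factor's effect.
"""

from lfa_taguchi import default_factors, l9_array, make_plan

design = l9_array()
design.audit()  # raises if balance or orthogonality were broken
print("L9 level indices (A B C D):")
for row in design.rows:
    print("  ", *row)

plan = make_plan(default_factors(), design)
print("\nrun  lux  contrast  saturation  tone")
for rp in plan:
    s = rp.settings
    print(
        f"{rp.run_id:>3}  {s['illuminance']:3.0f}  {s['contrast']:8.2f}"
        f"  {s['saturation']:10.2f}  {s['tone']:4.2f}"
    )

# Run 1 holds every factor at level 1 (200 lux, contrast 0.13, saturation
# 0.35, tone 0.35); each subsequent run changes levels per the array.
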