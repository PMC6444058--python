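"""Re-classify the two packaged worked examples with the ACMG engine.

GLI3 p.Ile808Met: population frequency far above the maximum credible
frequency for a rare dominant syndrome -> strong benign evidence (BS1),
plus healthy carriers (BS2, down-weighted for incomplete penetrance);
the in vitro assay is disregarded. ATP7B p.Met645Arg: extremely low
frequency with no homozygotes (PM2), in-trans observations with a
pathogenic variant (PM3), but wild-type-like transport activity (BS3) —
irreconcilable polarities.
"""

from varconcord import classify_profile, render_report
from varconcord.study import load_worked_examples

for profile in load_worked_examples():
    result = classify_profile(profile)
    print("=" * 70)
    print(profile.variant)
    print("-" * 70)
    print(render_report(result))
# The GLI3 report ends in "Likely benign" (one strong plus one
# supporting benign criterion); the ATP7B report ends in "Uncertain
# significance" with the conflicting-evidence note, because moderate
# pathogenic and strong benign criteria fire no combining rule together.
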