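"""Concordance of the 4286 shared variant interpretations.

Materializes per-variant pairs from the packaged cross-resource
comparison counts, tallies them into the 3x3 contingency table, and
computes per-bucket and overall percent agreement plus the projected
agreement after full re-curation.
"""

from varconcord import (
    build_contingency,
    overall_concordance,
    project_concordance,
)
from varconcord.concordance import round_half_away
from varconcord.study import (
    load_global_comparison,
    pairs_from_contingency,
    recuration_rates,
)

pairs = pairs_from_contingency(load_global_comparison())
table = build_contingency(pairs)
report = overall_concordance(table)

print("3x3 cross-classification (rows: curated bucket, cols: repository bucket):")
print(table.to_dataframe().to_string())
print()
print(f"agreeing interpretations: {report.n_agree} / {report.n_total}")
for bucket, pct in report.per_category.items():
    print(f"  {bucket.value:<13} concordance: {round_half_away(pct)}%")
print(f"  overall concordance: {round_half_away(report.overall)}%")

retained, resolved = recuration_rates()
projection = project_concordance(table, retained, resolved)
print()
print(
    f"projected agreement after re-curating everything "
    f"(retention {retained:.0%}, resolution {resolved:.0%}): "
    f"{round_half_away(projection)}%"
)
# The diagonal holds interpretations both resources agree on; the
# per-bucket percentages divide it by the union of either resource's
# interpretations of that bucket, so disagreement on *either* side
# lowers the number. Uncertain-significance variants agree rarely.
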