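"""Cross-study consensus vote-counting over published candidate lists.

Harmonizes the candidate lists of five genome-wide circulating-miRNA studies
(and, separately, ten earlier qPCR studies) as simple directional fold
changes and measures how often independent studies agree.
"""

from mirscreen.cross_study import classify_overlaps, qpcr_composite
from mirscreen.datasets import (
    load_genomewide_overlaps,
    load_genomewide_totals,
    load_qpcr_candidates,
)

totals, studies = load_genomewide_totals()
report = classify_overlaps(load_genomewide_overlaps(), totals)
print("Genome-wide studies:", ", ".join(studies["study"]))
print(f"pooled candidate miRNAs:      {report.total_candidates}")
print(f"overlapping (>=2 studies):    {report.n_overlapping}")
print(f"direction-consistent:         {len(report.consistent)} "
      f"({', '.join(sorted(report.consistent))})")
print(f"direction-contradictory:      {len(report.inconsistent)}")
print(f"concordance:                  {report.concordance_pct:.1f}%")
print()

composite = qpcr_composite(load_qpcr_candidates())
print(f"qPCR composite: {composite.n_unique} unique miRNAs "
      f"({composite.n_up} up, {composite.n_down} down)")
print(f"corroborated by independent groups: {', '.join(sorted(composite.corroborated))}")
print()
print("A concordance of a few percent means nearly every reported candidate")
print("is unreplicated or contradicted across studies.")
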