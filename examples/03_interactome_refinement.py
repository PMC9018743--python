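"""Refine the interactome for one condition and augment it by link prediction.

Hubs (degree > 900 and > 10 SD above the mean) lose their edges, edges with
an endpoint expressed below 2.0 are dropped, then Adamic/Adar link prediction
proposes missing interactions, filtered by shared subcellular localization
and appended with confidences scaled into [0, 0.5].
"""

from drugnetstrat import CohortConfig, generate_cohort
from drugnetstrat.interactome import (
    adamic_adar_scores,
    augment_interactome,
    expression_filter,
    localization_filter,
    remove_hubs,
)

bundle = generate_cohort(CohortConfig(seed=0))
panel = bundle.panels[("CL00", "drug00")]
expr = dict(zip(panel.genes, panel.treated.mean(axis=1)))

g0 = bundle.interactome
g1, hubs = remove_hubs(g0)
g2 = expression_filter(g1, expr, thresh=2.0)
preds = adamic_adar_scores(g2)
kept = localization_filter(preds, bundle.localization)
g3 = augment_interactome(g2, kept)

print(f"reference interactome : {g0.number_of_edges()} edges")
print(f"after hub removal     : {g1.number_of_edges()} edges ({len(hubs)} hubs)")
print(f"after expression filter: {g2.number_of_edges()} edges")
print(f"link prediction        : {len(preds)} candidates, {len(kept)} pass localization")
print(f"augmented interactome  : {g3.number_of_edges()} edges")
print(f"top prediction: {kept[0].pair} (Adamic/Adar score {kept[0].aa_score:.2f})")
# Predicted edges carry weight <= 0.5, i.e. solver cost >= 0.5, so they are
# used only when no plausible curated path exists.
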