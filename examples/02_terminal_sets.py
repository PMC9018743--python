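"""Turn one condition's omics into a prized terminal set.

Differentially expressed genes nominate transcription factors (>=3
significant regulated genes), significant phosphosites nominate proteins
directly, and the drug's known targets are appended with a uniform prize.
"""

from drugnetstrat import CohortConfig, generate_cohort
from drugnetstrat.pipeline import build_condition_terminals
from drugnetstrat.terminals import differential_expression

bundle = generate_cohort(CohortConfig(seed=0))
cl, drug = "CL00", "drug00"

diff = differential_expression(bundle.panels[(cl, drug)], alpha=0.05)
print(f"{len(diff.significant_genes)} of {len(diff.table)} genes significant (ANOVA p<0.05)")

terminals = build_condition_terminals(bundle, cl, drug)
by_source = {}
for prot, (prize, source) in terminals.entries.items():
    by_source.setdefault(source, []).append((prize, prot))
for source, entries in sorted(by_source.items()):
    top = max(entries)
    print(f"{source:12s}: {len(entries):3d} terminals, top prize {top[0]:.2f} ({top[1]})")
# Prizes are what the PCSF solver forfeits for leaving a protein out: higher
# prize means the evidence pulls harder to include that protein.
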