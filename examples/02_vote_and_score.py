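"""Pool one group's responses under the three voting protocols.

Takes a single case, samples a 9-member group, and shows how frequency
(plurality), experience-weighted and confidence-weighted voting rank the
distinct candidate responses, and whether each ranking is strictly/loosely
correct against the gold standard.
"""

import numpy as np

import crowdecg as cc

dataset = cc.generate(cc.preset("growth", n_readers=60, seed=3))
case_id = sorted(dataset.cases)[0]
gold = dataset.cases[case_id].gold_findings
annotations = dataset.annotations_for_case(case_id)

rng = np.random.default_rng(11)
members = rng.choice(len(annotations), size=9, replace=False)
group = [annotations[i] for i in members]

print(f"case {case_id}, gold = {set(gold)}, group of {len(group)}\n")
for protocol in cc.PROTOCOLS:
    ranking = cc.aggregate(group, protocol, np.random.default_rng(5),
                           dataset=dataset)
    sa = cc.group_sa(ranking, gold)
    la = cc.group_la(ranking, gold, k=5)
    print(f"{protocol} protocol  (SA={sa}, LA@5={la}):")
    for entry in ranking.entries:
        marker = " <- gold" if entry.findings == gold else ""
        print(f"   {sorted(entry.findings)!s:<14} weight {entry.weight:g}{marker}")
    print()

# SA=1 means the top-ranked response equals the gold set exactly; LA@5=1
# means the gold set appears somewhere in the top five candidates — the
# 'second opinion menu' a clinician would be shown.
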