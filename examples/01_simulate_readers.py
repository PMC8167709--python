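"""Generate a synthetic reader population and inspect its composition.

Builds the ten-case study configuration (two questionnaire blocks of five
cases spanning easy/medium/difficult regimes), draws 160 readers, and prints
the experience mix and per-case individual accuracy.  Individual strict
accuracy (SA) is the fraction of readers whose coded answer equals the gold
finding set exactly; loose accuracy (LA) only requires the gold findings to
be present among the reader's findings.
"""

import collections

import crowdecg as cc

config = cc.default_study_config(n_readers=160, seed=7)
dataset = cc.generate(config)

print(f"{len(dataset.readers)} readers, {len(dataset.cases)} cases, "
      f"{len(dataset.annotations)} annotations")

mix = collections.Counter(
    p.experience_category for p in dataset.readers.values()
)
print("\nexperience mix (target ~26/51/20/3%):")
for cat, n in mix.most_common():
    print(f"  {cat:<22} {n:>4}  ({n / len(dataset.readers):.1%})")

print("\nper-case individual accuracy (mean over that case's readers):")
print(f"  {'case':<8}{'difficulty':<12}{'SA':>6}{'LA':>6}")
for case_id in sorted(dataset.cases):
    sa = cc.mean_individual_accuracy(dataset, case_id, "SA")
    la = cc.mean_individual_accuracy(dataset, case_id, "LA")
    print(f"  {case_id:<8}{dataset.cases[case_id].difficulty:<12}{sa:>6.2f}{la:>6.2f}")

# A low SA with a higher LA (e.g. the two-finding cases) means readers often
# spot part of the diagnosis but rarely report the complete finding set.
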