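"""Combine ACMG/AMP evidence criteria into a posterior and a seven-class call.

The Bayesian points framework turns criterion counts into a posterior
probability of pathogenicity (prior 0.10, very-strong odds 350): one
very-strong criterion alone reaches ~0.975 (likely pathogenic); adding a
moderate criterion crosses the 0.99 pathogenic bound; a stand-alone benign
criterion forces class B regardless of anything else.
"""

from melpanel import EvidenceProfile, combine_evidence, is_reportable

profiles = [
    ("no evidence", EvidenceProfile()),
    ("PVS1", EvidenceProfile(n_pvs=1)),
    ("PVS1 + PM2", EvidenceProfile(n_pvs=1, n_pm=1)),
    ("PS1 + PM1 + PP3", EvidenceProfile(n_ps=1, n_pm=1, n_pp=1)),
    ("PM1 + PP3", EvidenceProfile(n_pm=1, n_pp=1)),
    ("BS1 + BP4", EvidenceProfile(n_bs=1, n_bp=1)),
    ("BA1 overrides PVS1", EvidenceProfile(n_pvs=1, n_ba=1)),
]

print(f"{'profile':22s} {'posterior':>9s}  {'class':20s} reportable")
for label, e in profiles:
    res = combine_evidence(e)
    print(
        f"{label:22s} {res.posterior:9.4f}  {res.label:20s} "
        f"{is_reportable(res.label)}"
    )

print(
    "\nReportable means the variant counts as a positive test result\n"
    "(classes P, LP, VUS-3B and VUS); the three benign-side classes never do."
)
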