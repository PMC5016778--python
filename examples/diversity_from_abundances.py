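"""Per-site diversity and NIS summaries from a raw abundance table.

Builds a ~100-individual intertidal mollusc sample for one site, then
reports species richness (Margalef's d), Simpson's index and the proportion
of non-indigenous species at both the species and the individual level —
the two NIS proportions answer different questions (how much of the species
inventory is foreign vs how much of the standing biomass).
"""

from coastnis import AbundanceEntry, AbundanceTable, nis_proportions

site = AbundanceTable(
    "demo-bay",
    [
        AbundanceEntry("Littorina scutulata", 41, is_nis=False),
        AbundanceEntry("Nucella ostrina", 22, is_nis=False),
        AbundanceEntry("Mytilus trossulus", 18, is_nis=False),
        AbundanceEntry("Lottia digitalis", 11, is_nis=False),
        AbundanceEntry("Mytilus galloprovincialis", 6, is_nis=True),
        AbundanceEntry("Batillaria attramentaria", 2, is_nis=True),
    ],
)

s = nis_proportions(site)
print(f"site {s.site_id}: {s.s_total} species, {site.total_individuals} individuals")
print(f"  NIS species proportion:    {s.nis_species_proportion:.3f}  ({s.s_nis} of {s.s_total} species)")
print(f"  NIS individual proportion: {s.nis_individual_proportion:.3f}  (8 of 100 individuals)")
print(f"  Margalef richness d:       {s.richness_index:.3f}  # (S-1)/ln N")
print(f"  Simpson index (unbiased):  {s.simpson:.3f}  # 0 = monoculture, ->1 = even")
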