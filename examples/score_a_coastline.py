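"""Score a coastal window for protection and a site for aquaculture pressure.

A 10-km stretch of coast with 1 km fully protected (level 5), 3 km in an
ecological reserve (3), 2 km in a regional park (2) and 4 km unprotected (1)
gets the length-weighted score (0.1*5 + 0.3*3 + 0.2*2 + 0.4*1) = 2.2 —
i.e. on average this coast sits a little above "lightly regulated".
Multiplying each segment by its protection age (in decades) turns the score
into standardized protection-years per km.
"""

from coastnis import (
    FarmRecord,
    ProtectionSegment,
    aquaculture_vector,
    likert_rescale,
    local_protection_status,
    weighted_protection,
)

segments = [
    ProtectionSegment(level=local_protection_status("MPA"), length_km=1, duration=1.0),
    ProtectionSegment(level=local_protection_status("ecological reserve"), length_km=3, duration=3.0),
    ProtectionSegment(level=local_protection_status("regional park"), length_km=2, duration=2.5),
    ProtectionSegment(level=local_protection_status("none"), length_km=4, duration=0.0),
]

plain = weighted_protection(segments, window_km=10)
aged = weighted_protection(segments, window_km=10, include_duration=True)
print(f"10-km protection score (level only):      {plain:.2f}   # 1 = none ... 5 = full MPA")
print(f"10-km protection score (level x decades): {aged:.2f}   # protection-years per km")

# aquaculture vector: one native oyster farm, two exotic clam farms, one
# farm of a listed invasive mussel, all within 10 km of the site
farms = [
    FarmRecord("Pinctada margaritifera", status_weight=1, n_farms=1, distance_to_site_km=4),
    FarmRecord("Ruditapes philippinarum", status_weight=2, n_farms=2, distance_to_site_km=7),
    FarmRecord("Mytilus galloprovincialis", status_weight=3, n_farms=1, distance_to_site_km=9),
]
raw = aquaculture_vector(farms, radius_km=10)
print(f"raw aquaculture vector value:             {raw:.0f}      # sum of weight x farms")

# across a survey, raw scores are normalized onto 0-5 with zero kept at zero
survey_raw = [0, 0, raw, 3, 63]
scaled = likert_rescale(survey_raw, 0, 5, anchor_zero=True)
print(f"Likert-scaled across survey (max 63):     {scaled.round(4)}")
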