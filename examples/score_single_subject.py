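"""Score one subject on CAPS and CAPS-MT from raw chart data.

Builds a minimal clinical record — two dated MMSE scores (one entered as a
MoCA and converted), an NPI-Q profile, and MRI visual ratings — and prints
the component points and the predicted amyloid class.
"""

from datetime import date

from capscore import (
    CognitiveScore,
    ImagingRatings,
    NPIQProfile,
    Subject,
    annualized_decline,
    compute_caps,
    compute_caps_mt,
)

subject = Subject(
    id="case-01",
    age=72.0,
    sex="female",
    npiq=NPIQProfile.from_partial({"depression": 2, "irritability": 1}),
    cognitive_scores=(
        CognitiveScore("MoCA", 21, date(2022, 3, 1)),   # converts to MMSE 26
        CognitiveScore("MMSE", 22, date(2023, 3, 1)),
    ),
    imaging=ImagingRatings(fazekas=1, scheltens_mtla=3),
    amyloid_status_reference="unknown",
)

decline = annualized_decline(subject.mmse_scores)
print(f"annualized decline: {decline.rate:.2f} MMSE points/year (rapid: {decline.rapid})")

caps = compute_caps(subject)
print(
    f"CAPS components: NPI-Q {caps.npiq_points}, decline {caps.decline_points}, "
    f"Fazekas {caps.fazekas_points} -> total {caps.caps_total}/4"
)
print(f"predicted amyloid status (threshold >= 3): {caps.predicted_status}")

mt = compute_caps_mt(subject)
print(f"CAPS-MT (adds 1 point for Scheltens > 2): {mt.caps_mt_total}/5 -> {mt.predicted_status}")
# A total of 3 or more flags the subject as likely amyloid-positive and
# worth prioritizing for CSF or PET biomarker confirmation.
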