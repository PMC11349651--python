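"""Clinical instruments: NPI-Q aggregation, MoCA->MMSE crosswalk, Hachinski,
CSF amyloid rules, ADL staging, and subject validation."""

import random
from datetime import date

import pytest
from hypothesis import given
from hypothesis import strategies as st

from capscore import (
    AmyloidStatus,
    CognitiveScore,
    CSFPanel,
    ImagingRatings,
    IndeterminateStatusError,
    NPIQ_DOMAINS,
    NPIQProfile,
    Subject,
    ValidationError,
    adl_stage,
    csf_amyloid_status,
    hachinski_class,
    moca_to_mmse,
    npiq_summary,
    reference_from_measurements,
)

severity_maps = st.fixed_dictionaries({d: st.integers(0, 3) for d in NPIQ_DOMAINS})


class TestNPIQ:
    @pytest.mark.parametrize(
        "severities, expected",
        [
            ({}, (0, 0)),  # no reported symptoms
            ({"depression": 1, "irritability": 1}, (2, 2)),
            ({d: 3 for d in NPIQ_DOMAINS}, (36, 12)),  # severity ceiling
        ],
    )
    def test_summary(self, severities, expected):
        assert npiq_summary(NPIQProfile.from_partial(severities)) == expected

    def test_out_of_range_severity_names_domain(self):
        full = {d: 0 for d in NPIQ_DOMAINS} | {"apathy": 4}
        with pytest.raises(ValidationError, match="apathy"):
            NPIQProfile(full)

    def test_unknown_and_missing_domains_rejected(self):
        with pytest.raises(ValidationError):
            NPIQProfile({d: 0 for d in NPIQ_DOMAINS[:-1]})
        with pytest.raises(ValidationError):
            NPIQProfile.from_partial({"melancholy": 2})

    @given(severity_maps)
    def test_total_invariant_under_permutation_and_bounds(self, severities):
        total, count = npiq_summary(NPIQProfile(severities))
        shuffled_vals = list(severities.values())
        random.Random(0).shuffle(shuffled_vals)
        permuted = dict(zip(severities.keys(), shuffled_vals))
        assert NPIQProfile(permuted).total_score == total
        assert count <= total <= 3 * count


class TestMocaToMMSE:
    # the full published crosswalk table, duplicates included
    TABLE = [
        (15, 21), (28, 29), (11, 18), (25, 28), (12, 19), (30, 30), (26, 29),
        (21, 26), (26, 29), (24, 28), (13, 20), (21, 26), (14, 20), (18, 24),
    ]

    @pytest.mark.parametrize("moca, mmse", TABLE)
    def test_reproduces_published_pairs(self, moca, mmse):
        assert moca_to_mmse(moca) == mmse

    def test_interpolation_between_anchors(self):
        # linear between (15, 21) and (18, 24)
        assert moca_to_mmse(16) == 22
        assert moca_to_mmse(17) == 23

    def test_monotone_and_bounded_over_full_range(self):
        values = [moca_to_mmse(m) for m in range(31)]
        assert all(a <= b for a, b in zip(values, values[1:]))
        assert all(m <= v <= 30 for m, v in zip(range(31), values))

    @pytest.mark.parametrize("bad", [-1, 31, 2.5, "15"])
    def test_rejects_out_of_range(self, bad):
        with pytest.raises(ValidationError):
            moca_to_mmse(bad)


class TestHachinski:
    @pytest.mark.parametrize(
        "score, expected",
        [(2, "non_vascular"), (4, "non_vascular"), (5, "vascular"), (0, "non_vascular")],
    )
    def test_classification(self, score, expected):
        assert hachinski_class(score) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            hachinski_class(-1)


class TestCSFStatus:
    def test_high_ptau_ratio_positive(self):
        status = csf_amyloid_status(CSFPanel(ptau_abeta42_ratio=0.030))
        assert status == AmyloidStatus("positive", "csf_ratio")

    def test_all_normal_negative(self):
        panel = CSFPanel(abeta42=1200.0, ptau_abeta42_ratio=0.010, ttau_abeta42_ratio=0.10)
        assert csf_amyloid_status(panel) == AmyloidStatus("negative", "csf_ratio")

    def test_low_abeta42_absolute_fallback(self):
        assert csf_amyloid_status(CSFPanel(abeta42=900.0)) == AmyloidStatus(
            "positive", "csf_absolute"
        )

    def test_ratio_derived_from_analytes(self):
        # 40/1200 = 0.033 >= 0.024 even though abeta42 alone is normal-range
        panel = CSFPanel(abeta42=1200.0, ptau=40.0)
        assert csf_amyloid_status(panel) == AmyloidStatus("positive", "csf_ratio")

    def test_borderline_equality_is_positive(self):
        assert csf_amyloid_status(CSFPanel(ptau_abeta42_ratio=0.024)).status == "positive"
        assert csf_amyloid_status(CSFPanel(abeta42=1030.0)).status == "positive"

    def test_deterministic(self):
        panel = CSFPanel(abeta42=800.0, ptau=35.0, ttau=400.0)
        results = {csf_amyloid_status(panel) for _ in range(5)}
        assert len(results) == 1

    def test_no_usable_analyte_raises(self):
        with pytest.raises(IndeterminateStatusError):
            csf_amyloid_status(CSFPanel())

    def test_inconsistent_stored_ratio_rejected(self):
        with pytest.raises(ValidationError):
            CSFPanel(abeta42=1000.0, ptau=30.0, ptau_abeta42_ratio=0.050)

    def test_pet_takes_precedence_over_csf(self):
        abnormal_csf = CSFPanel(ptau_abeta42_ratio=0.030)
        status = reference_from_measurements(csf=abnormal_csf, pet_status="negative")
        assert status == AmyloidStatus("negative", "pet")
        assert reference_from_measurements(csf=abnormal_csf).basis == "csf_ratio"


class TestADLStage:
    @pytest.mark.parametrize(
        "total, expected", [(23, "prodromal"), (22, "dementia"), (0, "dementia")]
    )
    def test_staging(self, total, expected):
        assert adl_stage(total) == expected

    @pytest.mark.parametrize("bad", [-1, 24])
    def test_out_of_range(self, bad):
        with pytest.raises(ValidationError):
            adl_stage(bad)


class TestSubject:
    def test_cognitive_scores_sorted_by_date(self):
        s = Subject(
            id="x", age=70, sex="male",
            cognitive_scores=(
                CognitiveScore("MMSE", 20, date(2023, 6, 1)),
                CognitiveScore("MMSE", 24, date(2022, 6, 1)),
            ),
        )
        assert [c.raw for c in s.cognitive_scores] == [24, 20]

    def test_moca_visits_convert_in_mmse_view(self):
        s = Subject(
            id="x", age=70, sex="male",
            cognitive_scores=(CognitiveScore("MoCA", 15, date(2022, 6, 1)),),
        )
        assert s.mmse_scores[0].raw == 21
        assert s.baseline_mmse == 21

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"age": 0},
            {"sex": "other"},
            {"amyloid_status_reference": "maybe"},
            {"hachinski": 19},
            {"lawton_brody": 24},
        ],
    )
    def test_invalid_fields_rejected(self, kwargs):
        base = dict(id="x", age=70, sex="male")
        with pytest.raises(ValidationError):
            Subject(**(base | kwargs))

    def test_imaging_rating_bounds(self):
        with pytest.raises(ValidationError):
            ImagingRatings(fazekas=4)
        with pytest.raises(ValidationError):
            ImagingRatings(fazekas=0, scheltens_mtla=5)
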