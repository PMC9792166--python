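"""Tracking-score computation and panel selection (incl. brute-force oracle)."""

from itertools import combinations

import pytest
from hypothesis import given
from hypothesis import strategies as st

from mrdtrack.tracking_panel import (
    PANEL_SIZE_MAX,
    PANEL_SIZE_MIN,
    build_panel,
    plasma_detectability_flag,
    score_variant,
    select_panel,
    selection_key,
)
from mrdtrack.variant_io import Consequence, GeneRole

from conftest import make_variant


def brute_force_panel(scored, n):
    """Enumerate all subsets of the eligible variants and pick the
    lexicographically best by sorted per-variant selection keys."""
    eligible = [s for s in scored if not s.variant.in_low_complexity]
    k = min(max(PANEL_SIZE_MIN, min(PANEL_SIZE_MAX, n)), len(eligible))
    best = min(
        combinations(eligible, k),
        key=lambda subset: tuple(sorted(selection_key(s) for s in subset)),
    )
    return sorted(best, key=selection_key)


@st.composite
def variant_profiles(draw, max_size=12):
    n = draw(st.integers(1, max_size))
    variants = []
    for i in range(n):
        variants.append(
            make_variant(
                gene=draw(st.sampled_from(["APC", "TP53", "KRAS", "BRAF"])),
                chrom=draw(st.sampled_from(["1", "2", "X"])),
                pos=draw(st.integers(1, 5)),
                consequence=draw(
                    st.sampled_from(
                        [
                            Consequence.MISSENSE,
                            Consequence.NONSENSE,
                            Consequence.FRAMESHIFT,
                        ]
                    )
                ),
                # coarse grid to force plenty of exact ties
                ffpe_vaf=draw(st.sampled_from([0.1, 0.2, 0.3])),
                cosmic_count=draw(st.sampled_from([0, 4, 100])),
                clinvar_pathogenic=draw(st.booleans()),
                predicted_deleterious=draw(st.booleans()),
                gene_role=draw(st.sampled_from(list(GeneRole))),
                in_house_validated=draw(st.booleans()),
                in_low_complexity=draw(
                    st.booleans() if i > 0 else st.just(False)
                ),
            )
        )
    return variants


class TestScoreVariant:
    def test_stopgain_tsg_pathogenic(self):
        v = make_variant(
            gene="APC",
            consequence=Consequence.NONSENSE,
            ffpe_vaf=0.40,
            clinvar_pathogenic=True,
            gene_role=GeneRole.TUMOR_SUPPRESSOR,
        )
        s = score_variant(v)
        assert s.criterion_flags == (True, True, False, False)
        assert s.score == pytest.approx(2.40)

    def test_recurrent_oncogene(self):
        v = make_variant(
            gene="KRAS",
            consequence=Consequence.MISSENSE,
            ffpe_vaf=0.30,
            cosmic_count=10000,
            predicted_deleterious=True,
            gene_role=GeneRole.ONCOGENE,
        )
        s = score_variant(v)
        assert s.criterion_flags == (True, False, True, False)
        assert s.score == pytest.approx(2.30)

    def test_cosmic_recurrence_strictly_greater_than_three(self):
        base = dict(gene="KRAS", gene_role=GeneRole.ONCOGENE)
        at_three = score_variant(make_variant(cosmic_count=3, **base))
        at_four = score_variant(make_variant(cosmic_count=4, **base))
        assert not at_three.recurrent_oncogene
        assert at_four.recurrent_oncogene

    def test_synonymous_rejected(self):
        with pytest.raises(ValueError, match="not trackable"):
            score_variant(make_variant(consequence=Consequence.SYNONYMOUS))

    def test_pathogenic_or_deleterious_is_an_or(self):
        clinvar_only = score_variant(make_variant(clinvar_pathogenic=True))
        sift_only = score_variant(make_variant(predicted_deleterious=True))
        assert clinvar_only.pathogenic_deleterious
        assert sift_only.pathogenic_deleterious


class TestSelectPanel:
    def test_top_five_of_twelve(self):
        variants = [
            make_variant(pos=i + 1, ffpe_vaf=0.05 + 0.05 * i) for i in range(12)
        ]
        panel = select_panel([score_variant(v) for v in variants], n=5)
        assert len(panel.members) == 5
        top_vafs = sorted((v.ffpe_vaf for v in variants), reverse=True)[:5]
        assert [m.variant.ffpe_vaf for m in panel.members] == top_vafs

    def test_availability_bound(self):
        variants = [make_variant(pos=i + 1) for i in range(3)]
        panel = select_panel([score_variant(v) for v in variants], n=5)
        assert len(panel.members) == 3
        assert not panel.below_minimum

    def test_vaf_breaks_flag_ties(self):
        a = make_variant(pos=1, ffpe_vaf=0.30, clinvar_pathogenic=True)
        b = make_variant(pos=2, ffpe_vaf=0.20, clinvar_pathogenic=True)
        panel = select_panel([score_variant(b), score_variant(a)], n=2)
        assert panel.members[0].variant.ffpe_vaf == pytest.approx(0.30)

    def test_n_clamped_to_bounds(self):
        variants = [make_variant(pos=i + 1) for i in range(12)]
        scored = [score_variant(v) for v in variants]
        assert len(select_panel(scored, n=50).members) == PANEL_SIZE_MAX
        assert len(select_panel(scored, n=0).members) == PANEL_SIZE_MIN

    def test_single_variant_flagged_below_minimum(self):
        panel = select_panel([score_variant(make_variant())])
        assert len(panel.members) == 1
        assert panel.below_minimum

    def test_low_complexity_excluded_and_empty_errors(self):
        masked = make_variant(in_low_complexity=True)
        with pytest.raises(ValueError, match="no trackable"):
            select_panel([score_variant(masked)])

    def test_ranks_are_one_based_permutation(self):
        variants = [make_variant(pos=i + 1, ffpe_vaf=0.1 * (i + 1)) for i in range(6)]
        panel = select_panel([score_variant(v) for v in variants], n=4)
        assert [m.rank for m in panel.members] == [1, 2, 3, 4]

    @given(profile=variant_profiles())
    def test_matches_brute_force_subset_oracle(self, profile):
        scored = [score_variant(v) for v in profile]
        if all(s.variant.in_low_complexity for s in scored):
            return
        panel = select_panel(scored, n=5)
        oracle = brute_force_panel(scored, 5)
        assert [m.variant for m in panel.members] == [s.variant for s in oracle]

    @given(profile=variant_profiles(), seed=st.integers(0, 1000))
    def test_permutation_invariant(self, profile, seed):
        """Selection is deterministic: input order never changes the panel."""
        import random

        scored = [score_variant(v) for v in profile]
        if all(s.variant.in_low_complexity for s in scored):
            return
        shuffled = scored[:]
        random.Random(seed).shuffle(shuffled)
        a = select_panel(scored, n=5)
        b = select_panel(shuffled, n=5)
        assert [m.variant for m in a.members] == [m.variant for m in b.members]

    @given(profile=variant_profiles())
    def test_scores_non_increasing_and_drop_invariance(self, profile):
        scored = [score_variant(v) for v in profile]
        if all(s.variant.in_low_complexity for s in scored):
            return
        panel = select_panel(scored, n=5)
        scores = [m.score for m in panel.members]
        assert scores == sorted(scores, reverse=True)
        # removing a non-selected variant never changes the panel
        chosen = {m.variant for m in panel.members}
        rest = [s for s in scored if s.variant in chosen or s is not scored[-1]]
        if scored[-1].variant not in chosen:
            again = select_panel(
                [s for s in scored if s.variant is not scored[-1].variant], n=5
            )
            assert [m.variant for m in again.members] == [
                m.variant for m in panel.members
            ]


class TestDetectabilityFlag:
    @pytest.mark.parametrize(
        "vaf, expected", [(0.10, True), (0.099, False), (1.0, True)]
    )
    def test_boundary(self, vaf, expected):
        assert plasma_detectability_flag(make_variant(ffpe_vaf=vaf)) is expected


def test_build_panel_skips_synonymous():
    variants = [
        make_variant(pos=1, consequence=Consequence.SYNONYMOUS),
        make_variant(pos=2),
    ]
    panel = build_panel(variants)
    assert len(panel.members) == 1
    assert panel.members[0].variant.pos == 2
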