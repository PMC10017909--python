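import itertools
import json

import pytest
from hypothesis import given, settings, strategies as st

from dhpmd.constants import AA1
from dhpmd.mutscreen import (
    MutationCandidate,
    attach_scores,
    consensus_filter,
    enumerate_saturation,
    heatmap_matrix,
    score_candidates,
    surrogate_scorer,
)
from dhpmd.synthetic_data import toy_hydrolase_sequence

SCREEN_REGIONS = [(67, 76), (176, 181), (320, 333)]

#: the experimentally pursued consensus set
THIRTEEN = {
    "A321I", "S325F", "S325Y", "S325N", "Q332E", "Q332G",
    "H68A", "H68L", "H68M", "H68K", "H68Y", "K70R", "A178L",
}


class TestEnumeration:
    def test_single_position_gives_19(self):
        assert len(enumerate_saturation("ACD", [(2, 2)])) == 19

    def test_ten_residue_loop_gives_190(self):
        sequence = toy_hydrolase_sequence()
        assert len(enumerate_saturation(sequence, [(67, 76)])) == 190

    def test_three_selected_regions_give_570(self):
        sequence = toy_hydrolase_sequence()
        candidates = enumerate_saturation(sequence, SCREEN_REGIONS)
        # 10 + 6 + 14 = 30 positions × 19 substitutions
        assert len(candidates) == 570
        assert len({(c.position, c.mut_aa) for c in candidates}) == 570

    def test_deterministic_order(self):
        candidates = enumerate_saturation("AC", [(1, 2)])
        assert [c.position for c in candidates[:19]] == [1] * 19
        assert [c.mut_aa for c in candidates[:3]] == ["C", "D", "E"]

    def test_no_identity_substitution(self):
        for c in enumerate_saturation("ACD", [(1, 3)]):
            assert c.mut_aa != c.wt_aa

    def test_nonstandard_residue_rejected(self):
        with pytest.raises(ValueError, match="non-standard"):
            enumerate_saturation("AXD", [(1, 3)])

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(start=st.integers(1, 40), length=st.integers(1, 20))
    def test_count_is_19_per_position(self, start, length):
        sequence = "ACDEFGHIKLMNPQRSTVWY" * 3
        end = min(start + length - 1, len(sequence))
        candidates = enumerate_saturation(sequence, [(start, end)])
        assert len(candidates) == 19 * (end - start + 1)


def synthetic_consensus_scores(sequence):
    """Score table in which exactly the thirteen pursued mutants pass the
    dual filter (ΔΔG_A < 0 and ΔΔG_B > 0)."""
    scores = {}
    for c in enumerate_saturation(sequence, SCREEN_REGIONS):
        if c.label in THIRTEEN:
            scores[(c.position, c.mut_aa)] = (-1.2, +0.8)
        else:
            scores[(c.position, c.mut_aa)] = (+0.4, -0.3)
    return scores


class TestConsensusFilter:
    def test_thirteen_mutant_membership(self):
        sequence = toy_hydrolase_sequence()
        candidates = attach_scores(
            enumerate_saturation(sequence, SCREEN_REGIONS),
            synthetic_consensus_scores(sequence),
        )
        _, stabilizing = consensus_filter(candidates)
        assert {c.label for c in stabilizing} == THIRTEEN

    def test_strict_inequalities_at_zero(self):
        scored, stabilizing = consensus_filter(
            [MutationCandidate(1, "A", "C", ddg_a=0.0, ddg_b=1.0)]
        )
        assert scored[0].verdict == "not-stabilizing"
        assert stabilizing == []

    @pytest.mark.parametrize(
        "ddg_a,ddg_b", list(itertools.product([-1.0, 0.0, 1.0], repeat=2))
    )
    def test_sign_grid_truth_table(self, ddg_a, ddg_b):
        scored, stabilizing = consensus_filter(
            [MutationCandidate(1, "A", "C", ddg_a=ddg_a, ddg_b=ddg_b)]
        )
        expected = ddg_a < 0 and ddg_b > 0
        assert (scored[0].verdict == "stabilizing") is expected

    def test_missing_score_is_incomplete_and_excluded(self):
        scored, stabilizing = consensus_filter([
            MutationCandidate(1, "A", "C", ddg_a=-1.0, ddg_b=None),
            MutationCandidate(1, "A", "D", ddg_a=None, ddg_b=1.0),
        ])
        assert {c.verdict for c in scored} == {"incomplete"}
        assert stabilizing == []

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        ddg_a=st.floats(-3, 3, allow_nan=False),
        ddg_b=st.floats(-3, 3, allow_nan=False),
        better_a=st.floats(0, 2),
        better_b=st.floats(0, 2),
    )
    def test_filter_monotone_in_both_scores(self, ddg_a, ddg_b, better_a, better_b):
        base = consensus_filter(
            [MutationCandidate(1, "A", "C", ddg_a=ddg_a, ddg_b=ddg_b)]
        )[0][0].verdict
        improved = consensus_filter(
            [MutationCandidate(1, "A", "C", ddg_a=ddg_a - better_a,
                               ddg_b=ddg_b + better_b)]
        )[0][0].verdict
        if base == "stabilizing":
            assert improved == "stabilizing"


class TestSurrogateScorer:
    def test_deterministic(self):
        sequence = toy_hydrolase_sequence()
        c = MutationCandidate(68, "H", "A")
        assert surrogate_scorer(sequence, c, seed=7) == surrogate_scorer(
            sequence, c, seed=7
        )
        assert surrogate_scorer(sequence, c, seed=7) != surrogate_scorer(
            sequence, c, seed=8
        )

    def test_sequence_mismatch_rejected(self):
        with pytest.raises(ValueError, match="disagrees"):
            surrogate_scorer("AAA", MutationCandidate(2, "H", "A"))

    def test_all_570_candidates_scored_reproducibly(self):
        sequence = toy_hydrolase_sequence()
        candidates = enumerate_saturation(sequence, SCREEN_REGIONS)
        first = score_candidates(sequence, candidates, seed=1)
        second = score_candidates(sequence, candidates, seed=1)
        assert all(
            a.ddg_a == b.ddg_a and a.ddg_b == b.ddg_b
            for a, b in zip(first, second)
        )
        import math
        assert all(math.isfinite(c.ddg_a) and math.isfinite(c.ddg_b) for c in first)


class TestHeatmap:
    def test_single_position_row(self):
        candidates, _ = consensus_filter(
            score_candidates("ACD", enumerate_saturation("ACD", [(2, 2)]), seed=0)
        )
        matrix = heatmap_matrix(candidates)
        assert len(matrix["rows"]) == 1
        row = matrix["rows"][0]
        assert row["wt"] == "C"
        assert row["cells"]["C"] is None
        filled = [aa for aa, cell in row["cells"].items() if cell is not None]
        assert len(filled) == 19

    def test_json_round_trip(self):
        candidates, _ = consensus_filter(
            score_candidates("ACD", enumerate_saturation("ACD", [(1, 3)]), seed=0)
        )
        matrix = heatmap_matrix(candidates)
        assert json.loads(json.dumps(matrix)) == matrix

    def test_cells_flagged_consistently_with_filter(self):
        sequence = toy_hydrolase_sequence()
        scored, stabilizing = consensus_filter(
            attach_scores(
                enumerate_saturation(sequence, SCREEN_REGIONS),
                synthetic_consensus_scores(sequence),
            )
        )
        matrix = heatmap_matrix(scored)
        flagged = {
            f"{row['wt']}{row['position']}{aa}"
            for row in matrix["rows"]
            for aa, cell in row["cells"].items()
            if cell is not None and cell["verdict"] == "stabilizing"
        }
        assert flagged == {c.label for c in stabilizing}
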