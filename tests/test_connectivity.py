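import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tspath.connectivity import (
    DrugInstanceProfile,
    KSInput,
    drug_drug_score,
    intersect_and_rerank,
    ks_score,
    score_instance,
    therapeutic_score,
)
from tspath.signatures import PathwaySignature


def ks_oracle(positions, n, tol=1e-12):
    """Independent oracle: the signed KS statistic from the empirical-CDF
    definition, sweeping every integer threshold of the drug list rather
    than evaluating the closed-form max over query indices."""
    m = len(positions)
    if m == 0:
        return 0.0

    def F(t):  # empirical CDF of query positions
        return sum(1 for v in positions if v <= t) / m

    a = max(F(t) - t / n for t in range(1, n + 1))
    b = max(t / n - F(t - 1) for t in range(1, n + 1))
    if abs(a - b) <= tol:
        return 0.0
    return a if a > b else -b


@st.composite
def ks_inputs(draw, max_n=60):
    n = draw(st.integers(1, max_n))
    m = draw(st.integers(0, n))
    positions = tuple(sorted(draw(st.permutations(range(1, n + 1)))[:m]))
    return KSInput(m=m, positions=positions, n=n)


class TestKSScore:
    @pytest.mark.parametrize("m, n, positions, expected", [
        (1, 10, (1,), 0.9),     # query gene at the very top
        (1, 10, (10,), -1.0),   # query gene at the very bottom
        (2, 10, (1, 10), -0.5),  # split: a = 0.4, b = 0.5
        (1, 2, (1,), 0.0),      # a = b = 0.5 tie -> null connectivity
    ])
    def test_hand_derived_cases(self, m, n, positions, expected):
        assert ks_score(KSInput(m=m, positions=positions, n=n)) == \
            pytest.approx(expected)

    def test_empty_query_scores_zero(self):
        assert ks_score(KSInput(m=0, positions=(), n=5)) == 0.0

    def test_position_bounds_enforced(self):
        with pytest.raises(ValueError):
            KSInput(m=1, positions=(11,), n=10)
        with pytest.raises(ValueError):
            KSInput(m=2, positions=(3, 3), n=10)

    @given(ks_inputs())
    @settings(max_examples=300, deadline=None)
    def test_matches_cdf_oracle_and_bounds(self, inp):
        cs = ks_score(inp)
        assert -1.0 <= cs <= 1.0
        assert cs == pytest.approx(ks_oracle(inp.positions, inp.n), abs=1e-12)

    @given(ks_inputs(max_n=40), st.integers(1, 10))
    @settings(max_examples=200, deadline=None)
    def test_monotone_reversal(self, inp, shift):
        """Pushing every query gene down the drug list never increases CS."""
        if inp.m == 0 or inp.positions[-1] + shift > inp.n:
            return
        shifted = KSInput(m=inp.m,
                          positions=tuple(v + shift for v in inp.positions),
                          n=inp.n)
        assert ks_score(shifted) <= ks_score(inp) + 1e-12


class TestIntersectAndRerank:
    @pytest.fixture
    def drug(self):
        # ranked order [D, B, E, A]
        return DrugInstanceProfile.from_values(
            "i1", "d", {"D": 3.0, "B": 2.0, "E": 1.0, "A": -1.0})

    def test_positions_of_common_genes(self, drug):
        inp = intersect_and_rerank({"A", "B"}, drug)
        assert (inp.m, inp.positions, inp.n) == (2, (2, 4), 4)

    def test_disjoint_set(self, drug):
        inp = intersect_and_rerank({"X", "Y"}, drug)
        assert (inp.m, inp.positions) == (0, ())

    def test_superset_covers_whole_list(self, drug):
        inp = intersect_and_rerank({"A", "B", "D", "E", "Z"}, drug)
        assert inp.positions == (1, 2, 3, 4)

    def test_profile_tie_broken_lexicographically(self):
        prof = DrugInstanceProfile.from_values(
            "i", "d", {"A": 2.0, "B": -1.0, "C": 2.0})
        assert prof.ranked_genes == ("A", "C", "B")

    def test_duplicate_gene_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            DrugInstanceProfile(instance_id="i", drug_name="d",
                                ranked_genes=("A", "A"),
                                value={"A": 1.0})


class TestScoreInstance:
    def test_reversal_pattern_is_negative(self):
        # disease-up gene at drug bottom, disease-down gene at drug top
        drug = DrugInstanceProfile.from_values(
            "i", "d", {f"g{i}": -float(i) for i in range(10)})
        sig = PathwaySignature(pathway_id="P", up_genes=("g9",),
                               down_genes=("g0",))
        rec = score_instance(sig, drug)
        assert rec.cs_up == pytest.approx(-1.0)
        assert rec.cs_down == pytest.approx(0.9)
        assert rec.cs == pytest.approx(-1.9)

    def test_antisymmetric_under_up_down_swap(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(30)]
        drug = DrugInstanceProfile.from_values(
            "i", "d", dict(zip(genes, rng.normal(size=30))))
        up, down = tuple(genes[:5]), tuple(genes[20:28])
        sig = PathwaySignature(pathway_id="P", up_genes=up, down_genes=down)
        swapped = PathwaySignature(pathway_id="P", up_genes=down,
                                   down_genes=up)
        assert score_instance(swapped, drug).cs == \
            pytest.approx(-score_instance(sig, drug).cs)

    def test_empty_signature_scores_zero(self):
        drug = DrugInstanceProfile.from_values("i", "d", {"A": 1.0})
        sig = PathwaySignature(pathway_id="P", up_genes=(), down_genes=())
        assert score_instance(sig, drug).cs == 0.0


class TestTherapeuticScore:
    def _bottom_gene_instance(self, iid):
        # gene X ranked last out of 10 -> CS for up=[X] is exactly -1
        values = {f"g{i}": float(10 - i) for i in range(9)}
        values["X"] = -5.0
        return DrugInstanceProfile.from_values(iid, "d", values)

    def test_sum_over_pathways_mean_over_instances(self):
        sigs = [PathwaySignature(pathway_id=p, up_genes=("X",),
                                 down_genes=()) for p in ("P1", "P2")]
        instances = [self._bottom_gene_instance("i1"),
                     self._bottom_gene_instance("i2")]
        res = therapeutic_score(instances, sigs)
        # 2 pathways x 2 instances, each CS = -1, divided by k = 2
        assert res.ts == pytest.approx(-2.0)
        assert res.k == 2
        assert len(res.records) == 4

    def test_duplicated_instances_leave_ts_unchanged(self):
        sigs = [PathwaySignature(pathway_id="P", up_genes=("X",),
                                 down_genes=())]
        one = therapeutic_score([self._bottom_gene_instance("i1")], sigs)
        three = therapeutic_score(
            [self._bottom_gene_instance(f"i{j}") for j in range(3)], sigs)
        assert three.ts == pytest.approx(one.ts)

    def test_single_pathway_single_instance_equals_cs(self):
        sig = PathwaySignature(pathway_id="P", up_genes=("X",), down_genes=())
        inst = self._bottom_gene_instance("i1")
        res = therapeutic_score([inst], [sig])
        assert res.ts == pytest.approx(score_instance(sig, inst).cs)

    def test_normalize_pathways_flag(self):
        sigs = [PathwaySignature(pathway_id=p, up_genes=("X",),
                                 down_genes=()) for p in ("P1", "P2")]
        inst = self._bottom_gene_instance("i1")
        plain = therapeutic_score([inst], sigs)
        normed = therapeutic_score([inst], sigs, normalize_pathways=True)
        assert normed.ts == pytest.approx(plain.ts / 2)

    def test_empty_instance_list_is_error(self):
        sig = PathwaySignature(pathway_id="P", up_genes=("X",), down_genes=())
        with pytest.raises(ValueError, match="no instances"):
            therapeutic_score([], [sig])


class TestDrugDrugScore:
    def _profile(self, iid, drug, values):
        return DrugInstanceProfile.from_values(iid, drug, values)

    def test_self_similarity_positive(self):
        values = {"g1": 2.0, "g2": 1.0, "g3": -1.0, "g4": -2.0}
        a = self._profile("a1", "A", values)
        assert drug_drug_score([a], [a]) > 0

    def test_reversed_profile_negative(self):
        values = {f"g{i}": float(i) - 4.5 for i in range(10)}
        a = self._profile("a1", "A", values)
        b = self._profile("b1", "B", {g: -v for g, v in values.items()})
        assert drug_drug_score([a], [b]) < 0
        # reflection of a ranking shifts each KS component by at most 1/n
        assert drug_drug_score([a], [b]) == pytest.approx(
            -drug_drug_score([a], [a]), abs=2 / 10)

    def test_no_target_instances_is_error(self):
        a = self._profile("a1", "A", {"g": 1.0, "h": -1.0})
        with pytest.raises(ValueError):
            drug_drug_score([a], [])
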