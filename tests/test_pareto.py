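import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from abpareto.features import PhysChemEncoder, OneHotSequenceEncoder
from abpareto.library import VHSequence
from abpareto.models import LDAProjector
from abpareto.pareto import (
    TrainedPair,
    blosum62,
    near_frontier,
    pareto_front,
    pareto_mask,
    scan_single_mutants,
    select_designs,
)
from abpareto.library import AMINO_ACIDS


def oracle_mask(aff, ns):
    """O(n^2) dominance check."""
    n = len(aff)
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        for j in range(n):
            if (
                aff[j] >= aff[i]
                and ns[j] <= ns[i]
                and (aff[j] > aff[i] or ns[j] < ns[i])
            ):
                keep[i] = False
                break
    return keep


def points_df(aff, ns):
    return pd.DataFrame(
        {"affinity": aff, "nonspec": ns},
        index=[f"p{i}" for i in range(len(aff))],
    )


class TestParetoFront:
    def test_worked_example(self):
        pts = points_df([1, 2, 0], [1, 2, 3])
        front = pareto_front(pts)
        assert set(front.index) == {"p0", "p1"}

    def test_single_point_and_monotone_curve(self):
        assert len(pareto_front(points_df([1.0], [0.5]))) == 1
        pts = points_df([0, 1, 2, 3], [0, 1, 2, 3])  # strict tradeoff curve
        assert len(pareto_front(pts)) == 4

    def test_duplicate_frontier_points_all_retained(self):
        pts = points_df([2, 2, 1], [1, 1, 2])
        front = pareto_front(pts)
        assert set(front.index) == {"p0", "p1"}

    @given(
        st.lists(
            st.tuples(
                st.integers(min_value=-5, max_value=5),
                st.integers(min_value=-5, max_value=5),
            ),
            min_size=1,
            max_size=40,
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_quadratic_oracle(self, pairs):
        aff = np.array([p[0] for p in pairs], dtype=float)
        ns = np.array([p[1] for p in pairs], dtype=float)
        np.testing.assert_array_equal(pareto_mask(aff, ns), oracle_mask(aff, ns))

    def test_idempotent_and_stable_under_dominated_points(self, rng):
        pts = points_df(rng.normal(size=50), rng.normal(size=50))
        front = pareto_front(pts)
        assert pareto_front(front).equals(front)
        # adding a dominated point never changes the frontier
        worst = pd.DataFrame(
            {"affinity": [pts["affinity"].min() - 1], "nonspec": [pts["nonspec"].max() + 1]},
            index=["dominated"],
        )
        front2 = pareto_front(pd.concat([pts, worst]))
        assert set(front2.index) == set(front.index)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            pareto_front(points_df([np.nan], [0.0]))
        with pytest.raises(ValueError):
            pareto_front(points_df([], []))


class TestNearFrontier:
    def test_k_equal_frontier_returns_exactly_frontier(self, rng):
        pts = points_df(rng.normal(size=30), rng.normal(size=30))
        front = pareto_front(pts)
        near = near_frontier(pts, k=len(front))
        assert set(near.index) == set(front.index)

    def test_k_equal_n_returns_all(self, rng):
        pts = points_df(rng.normal(size=15), rng.normal(size=15))
        assert set(near_frontier(pts, k=15).index) == set(pts.index)

    def test_matches_brute_force_distance_ranking(self, rng):
        pts = points_df(rng.normal(size=40), rng.normal(size=40))
        mask = pareto_mask(pts["affinity"], pts["nonspec"])
        k = mask.sum() + 5
        near = near_frontier(pts, k=k)
        # brute force: z-score, distance of each non-frontier point to frontier
        z = (pts - pts.mean()) / pts.std(ddof=0)
        zf = z[mask]
        d = {
            idx: min(np.hypot(*(z.loc[idx] - zf.loc[j])) for j in zf.index)
            for idx in pts.index[~mask]
        }
        expected = set(pts.index[mask]) | set(sorted(d, key=lambda i: (d[i], i))[:5])
        assert set(near.index) == expected

    def test_k_smaller_than_frontier_rejected(self, rng):
        pts = points_df([0, 1], [0, 1])
        with pytest.raises(ValueError):
            near_frontier(pts, k=1)


class TestBlosum:
    def test_conservative_and_nonconservative_pairs(self):
        assert blosum62("D", "E") == 2
        assert blosum62("W", "G") == -2

    def test_symmetry_over_all_pairs(self):
        for a in AMINO_ACIDS:
            for b in AMINO_ACIDS:
                assert blosum62(a, b) == blosum62(b, a)

    def test_non_canonical_rejected(self):
        with pytest.raises(ValueError):
            blosum62("X", "A")


def _trained_pair(seqs_for_fit):
    enc = PhysChemEncoder().fit()
    X = enc.transform(seqs_for_fit)
    y = np.arange(len(seqs_for_fit)) % 2
    m = LDAProjector().fit(X, y)
    return TrainedPair(enc, m, m)


class TestScan:
    @pytest.fixture()
    def pair(self):
        rng = np.random.default_rng(0)
        seqs = [
            "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=12)) for _ in range(30)
        ]
        return _trained_pair(seqs)

    def test_candidate_count_closed_form(self, toy_design, pair):
        base = toy_design.parent  # position 1 of the region is a cysteine
        cands = scan_single_mutants(
            [base], toy_design, pair, regions=("left",), blosum_min=None
        )
        # per site: 20 - parent - cysteine (unless the parent IS cysteine)
        closed_form = sum(
            20 - 1 - (1 if base.residues[i] != "C" else 0) for i in range(6)
        )
        assert len(cands) == closed_form
        assert (cands["proposed_residue"] != "C").all()
        assert (cands["proposed_residue"] != cands["parent_residue"]).all()

    def test_blosum_filter_keeps_only_conservative(self, toy_design, pair):
        cands = scan_single_mutants(
            [toy_design.parent], toy_design, pair, regions=("left",), blosum_min=0
        )
        assert (cands["blosum62"] >= 0).all()
        unfiltered = scan_single_mutants(
            [toy_design.parent], toy_design, pair, regions=("left",), blosum_min=None
        )
        assert len(cands) == (unfiltered["blosum62"] >= 0).sum()

    def test_cysteine_exclusion_is_configurable(self, toy_design, pair):
        with_c = scan_single_mutants(
            [toy_design.parent], toy_design, pair,
            regions=("left",), blosum_min=None, exclude=frozenset(),
        )
        assert len(with_c) == 6 * 19

    def test_empty_region_and_unknown_region(self, toy_design, pair):
        design2 = type(toy_design)(
            toy_design.parent, toy_design.sites, {"empty": (3, 3)}
        )
        assert scan_single_mutants(
            [toy_design.parent], design2, pair, regions=("empty",)
        ).empty
        with pytest.raises(KeyError):
            scan_single_mutants([toy_design.parent], toy_design, pair, regions=("nope",))

    def test_onehot_encoder_cannot_score_novel_residues(self, toy_design):
        p = toy_design.parent.residues
        seqs = [p, p[:-1] + "V", p[:-2] + "VN", p[:-2] + "NV"]
        enc = OneHotSequenceEncoder().fit(seqs)
        m = LDAProjector().fit(enc.transform(seqs), np.array([0, 1, 0, 1]))
        pair = TrainedPair(enc, m, m)
        with pytest.raises(ValueError):
            scan_single_mutants(
                [toy_design.parent], toy_design, pair, regions=("left",)
            )


class TestSelectDesigns:
    def test_globally_dominating_candidate_selected_first(self, rng):
        lib = points_df(rng.normal(size=30), rng.normal(size=30))
        cands = pd.DataFrame(
            {
                "affinity": [lib["affinity"].max() + 1, 0.0, 0.1],
                "nonspec": [lib["nonspec"].min() - 1, 0.0, 0.1],
            },
            index=["super", "meh1", "meh2"],
        )
        picked = select_designs(cands, n=1, library_points=lib)
        assert list(picked.index) == ["super"]
        picked3 = select_designs(cands, n=3, library_points=lib)
        assert picked3.index[0] == "super"

    def test_deterministic_rerun(self, rng):
        lib = points_df(rng.normal(size=40), rng.normal(size=40))
        cands = points_df(rng.normal(size=25), rng.normal(size=25))
        a = select_designs(cands, n=10, library_points=lib)
        b = select_designs(cands, n=10, library_points=lib)
        assert list(a.index) == list(b.index)

    def test_n_validation(self, rng):
        lib = points_df([0.0], [0.0])
        with pytest.raises(ValueError):
            select_designs(points_df([1.0], [1.0]), n=0, library_points=lib)
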