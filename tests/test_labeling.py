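import math

import numpy as np
import pandas as pd
import pytest

from abpareto.labeling import (
    SampleCounts,
    SortExperiment,
    assign_antigen_label,
    assign_specificity_label,
    build_labeled_dataset,
    enrichment_ratio,
    experiment_from_frame,
    experiment_to_frame,
    occurrence_frequency,
    read_counts_csv,
    select_master_dataset,
    site_enrichment_matrix,
    write_counts_csv,
)
from abpareto.library import LibraryDesign, SiteSpec, VHSequence

from conftest import make_experiment


def test_experiment_validation():
    with pytest.raises(ValueError, match="duplicate"):
        SortExperiment(
            [
                SampleCounts("a", 1, "input", {}),
                SampleCounts("b", 1, "input", {}),
            ]
        )
    with pytest.raises(ValueError, match="input"):
        SortExperiment([SampleCounts("a", 1, "antigen_pos", {})])
    with pytest.raises(ValueError, match="selection"):
        SampleCounts("a", 1, "weird", {})


@pytest.mark.parametrize(
    "pattern,expected",
    [
        # in both antigen-positive samples -> positive
        ({("antigen_pos", 1), ("antigen_pos", 2)}, "positive"),
        # in exactly one antigen-positive sample -> discarded
        ({("antigen_pos", 1)}, "discarded"),
        ({("antigen_pos", 2), ("input", 1)}, "discarded"),
        # in neither, but in an input sample -> negative
        ({("input", 1)}, "negative"),
        ({("input", 2)}, "negative"),
        # absent everywhere relevant -> dropped upstream (None)
        ({("psr_pos", 1)}, None),
    ],
)
def test_antigen_label_rule(pattern, expected):
    exp = make_experiment({"v": pattern})
    assert assign_antigen_label(exp, "v") == expected


@pytest.mark.parametrize(
    "pattern,expected",
    [
        # 3 of 4 positives, no negatives -> positive
        ({("psr_pos", 1), ("psr_pos", 2), ("ova_pos", 1)}, "positive"),
        ({("psr_pos", 1), ("psr_pos", 2), ("ova_pos", 1), ("ova_pos", 2)}, "positive"),
        # 3 of 4 negatives, no positives -> negative
        ({("psr_neg", 1), ("psr_neg", 2), ("ova_neg", 1)}, "negative"),
        # 3 positives but 1 negative -> fails the "none of the negatives" clause
        (
            {("psr_pos", 1), ("psr_pos", 2), ("ova_pos", 1), ("ova_neg", 2)},
            "unlabeled",
        ),
        # only 2 positives -> unlabeled
        ({("psr_pos", 1), ("ova_pos", 1)}, "unlabeled"),
    ],
)
def test_specificity_label_rule(pattern, expected):
    exp = make_experiment({"v": pattern})
    assert assign_specificity_label(exp, "v") == expected


def test_labels_invariant_under_sample_order_permutation():
    pattern = {("antigen_pos", 1), ("antigen_pos", 2), ("psr_pos", 1), ("ova_pos", 2), ("ova_pos", 1)}
    exp = make_experiment({"v": pattern})
    shuffled = SortExperiment(list(reversed(exp.samples)))
    assert assign_antigen_label(exp, "v") == assign_antigen_label(shuffled, "v")
    assert assign_specificity_label(exp, "v") == assign_specificity_label(shuffled, "v")


def test_occurrence_frequency_modes():
    exp = make_experiment({"v": {("input", 1), ("antigen_pos", 1), ("psr_pos", 1)}})
    assert occurrence_frequency(exp, "v") == 3 / 12
    subset = exp.select("input") + exp.select("antigen_pos") + exp.select("psr_pos")
    assert occurrence_frequency(exp, "v", samples=subset) == 0.5
    assert occurrence_frequency(exp, "v", samples=[exp.get("input", 1)]) == 1.0
    with pytest.raises(ValueError):
        occurrence_frequency(exp, "v", samples=[])


def test_relative_abundance_mode():
    s = SampleCounts("in_r1", 1, "input", {"v": 50, "w": 4950})
    exp = SortExperiment([s])
    ab = occurrence_frequency(exp, "v", samples=[s], mode="abundance")
    assert ab["in_r1"] == pytest.approx(0.01)


def _er_experiment(c_in, c_out, rep_counts=None):
    """Two-replicate experiment with explicit input/output counts for 'v'."""
    filler = {"z": 1000}
    samples = []
    for rep in (1, 2):
        ci, co = (c_in, c_out) if rep_counts is None else rep_counts[rep - 1]
        samples.append(SampleCounts(f"in{rep}", rep, "input", {"v": ci, **filler}))
        samples.append(SampleCounts(f"out{rep}", rep, "antigen_pos", {"v": co, **filler}))
    return SortExperiment(samples)


def test_enrichment_ratio_examples():
    # identical relative frequencies in both replicates -> 0
    assert enrichment_ratio(_er_experiment(10, 10), "v", "antigen_pos") == pytest.approx(0.0)
    # output frequency ~4x input in both replicates -> ~2  (totals nearly equal)
    exp = _er_experiment(10, 40)
    er = enrichment_ratio(exp, "v", "antigen_pos")
    f_in = 10 / 1010
    f_out = 40 / 1040
    assert er == pytest.approx(math.log2(f_out / f_in))
    # replicate mean: ER1 = 2, ER2 = 0 -> 1 (constructed on equal totals)
    exp = SortExperiment(
        [
            SampleCounts("in1", 1, "input", {"v": 10, "z": 990}),
            SampleCounts("out1", 1, "antigen_pos", {"v": 40, "z": 960}),
            SampleCounts("in2", 2, "input", {"v": 10, "z": 990}),
            SampleCounts("out2", 2, "antigen_pos", {"v": 10, "z": 990}),
        ]
    )
    assert enrichment_ratio(exp, "v", "antigen_pos") == pytest.approx(1.0)


def test_enrichment_missing_and_pseudocount():
    exp = _er_experiment(0, 40)
    assert math.isnan(enrichment_ratio(exp, "v", "antigen_pos"))
    with_pc = enrichment_ratio(exp, "v", "antigen_pos", pseudocount=0.5)
    assert math.isfinite(with_pc) and with_pc > 0


def test_enrichment_depth_invariance():
    """A variant whose counts scale with depth identically has ER 0."""
    shallow = SortExperiment(
        [
            SampleCounts("in1", 1, "input", {"v": 5, "z": 95}),
            SampleCounts("out1", 1, "antigen_pos", {"v": 5, "z": 95}),
        ]
    )
    deep = SortExperiment(
        [
            SampleCounts("in1", 1, "input", {"v": 500, "z": 9500}),
            SampleCounts("out1", 1, "antigen_pos", {"v": 500, "z": 9500}),
        ]
    )
    assert enrichment_ratio(shallow, "v", "antigen_pos") == pytest.approx(0.0)
    assert enrichment_ratio(deep, "v", "antigen_pos") == pytest.approx(0.0)


def test_counts_csv_round_trip(tmp_path):
    exp = make_experiment(
        {"v": {("input", 1), ("antigen_pos", 1)}, "w": {("input", 2)}}
    )
    path = tmp_path / "counts.csv"
    write_counts_csv(exp, path)
    back = read_counts_csv(path)
    assert experiment_to_frame(back).equals(experiment_to_frame(exp))
    with pytest.raises(ValueError, match="missing columns"):
        experiment_from_frame(pd.DataFrame({"sample_id": []}))


def test_site_enrichment_matrix_matches_direct_tally():
    parent = VHSequence("p", "AAAA")
    design = LibraryDesign(
        parent, (SiteSpec(1, "s2", frozenset("ADE")), SiteSpec(3, "s4", frozenset("AK")))
    )
    labeled = pd.DataFrame(
        {
            "sequence": ["ADAA", "ADAK", "AEAA", "AAAA", "ADAA", "AAAK"],
            "cls": ["a", "a", "a", "b", "b", "b"],
        },
        index=[f"v{i}" for i in range(6)],
    )
    m = site_enrichment_matrix(labeled, design, labeled["cls"] == "a", labeled["cls"] == "b")
    # residue D at site s2: 2/3 in class a, 1/3 in class b -> log2(2) = 1
    assert m.loc["s2", "D"] == pytest.approx(1.0)
    # residue K at site s4: 1/3 in each class -> 0
    assert m.loc["s4", "K"] == pytest.approx(0.0)
    # E at s2 absent in class b -> unavailable without pseudocount
    assert math.isnan(m.loc["s2", "E"])
    # residue never sampled at a site stays unavailable
    assert math.isnan(m.loc["s2", "W"])
    m_pc = site_enrichment_matrix(
        labeled, design, labeled["cls"] == "a", labeled["cls"] == "b", pseudocount=0.5
    )
    assert math.isfinite(m_pc.loc["s2", "E"])


def _labeled_frame(n_pos, n_neg, n_ag_pos_in_pos=0, n_ag_pos_in_neg=0):
    rows = []
    k = 0
    for spec, total, n_ag in (("positive", n_pos, n_ag_pos_in_pos), ("negative", n_neg, n_ag_pos_in_neg)):
        for i in range(total):
            rows.append(
                {
                    "antigen_label": "positive" if i < n_ag else "negative",
                    "specificity_label": spec,
                    "frequency": 1.0 - (k % 7) / 10,
                    "sequence": "ACDEF",
                }
            )
            k += 1
    return pd.DataFrame(rows, index=[f"v{i:04d}" for i in range(len(rows))])


def test_master_selection_stratifies_and_prioritizes_antigen_positives():
    labeled = _labeled_frame(1000, 3000, n_ag_pos_in_pos=300, n_ag_pos_in_neg=700)
    master = select_master_dataset(labeled, n=1000)
    by_spec = master["specificity_label"].value_counts()
    assert by_spec["positive"] == 500 and by_spec["negative"] == 500
    # every antigen-positive in the positive stratum (300 < 500) is retained
    pos_stratum = master[master["specificity_label"] == "positive"]
    assert (pos_stratum["antigen_label"] == "positive").sum() == 300
    neg_stratum = master[master["specificity_label"] == "negative"]
    assert (neg_stratum["antigen_label"] == "positive").sum() == 500


def test_master_selection_errors():
    labeled = _labeled_frame(10, 10)
    with pytest.raises(ValueError, match="stratum"):
        select_master_dataset(labeled, n=100)
    with pytest.raises(ValueError, match="even"):
        select_master_dataset(labeled, n=7)


def test_master_selection_is_deterministic(sim_bundle):
    a = select_master_dataset(sim_bundle["labeled"], n=800)
    b = select_master_dataset(sim_bundle["labeled"], n=800)
    assert list(a.index) == list(b.index)
    assert a.equals(b)


def test_labeled_dataset_consistency(sim_bundle):
    """Spot-check the assertable label invariants on a full simulated run."""
    labeled = sim_bundle["labeled"]
    exp = sim_bundle["experiment"]
    ag = {s.sample_id: s for s in exp.select("antigen_pos")}
    rng = np.random.default_rng(0)
    for vid in rng.choice(labeled.index, size=200, replace=False):
        row = labeled.loc[vid]
        if row["antigen_label"] == "positive":
            assert all(s.present(vid) for s in ag.values())
        if row["specificity_label"] == "positive":
            assert not any(
                s.present(vid)
                for sel in ("psr_neg", "ova_neg")
                for s in exp.select(sel)
            )
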