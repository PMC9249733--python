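import numpy as np
import pytest

from abpareto.labeling import SampleCounts, SortExperiment, build_labeled_dataset
from abpareto.library import LibraryDesign, SiteSpec, VHSequence
from abpareto.simulate import SortConfig, example_design, make_truth, simulate_sort


@pytest.fixture(scope="session")
def toy_design():
    """3-site design on a 12-residue parent, small enough to enumerate."""
    parent = VHSequence("parent", "ACDEFGHIKLMN")
    sites = (
        SiteSpec(2, "s3", frozenset("DEK")),
        SiteSpec(5, "s6", frozenset("GAST")),
        SiteSpec(9, "s10", frozenset("LV")),
    )
    return LibraryDesign(parent, sites, {"left": (0, 6), "right": (6, 12)})


@pytest.fixture(scope="session")
def default_design():
    return example_design()


def make_experiment(presence: dict, input_ids=None):
    """Build a 12-sample experiment from per-variant presence patterns.

    ``presence`` maps variant id -> set of (selection, replicate) pairs where
    the variant has one read. ``input_ids`` forces extra variants into the
    input samples.
    """
    selections = ("input", "antigen_pos", "psr_pos", "psr_neg", "ova_pos", "ova_neg")
    samples = []
    for rep in (1, 2):
        for sel in selections:
            counts = {
                vid: 1
                for vid, pat in presence.items()
                if (sel, rep) in pat
            }
            if sel == "input" and input_ids:
                for vid in input_ids:
                    counts.setdefault(vid, 1)
            samples.append(SampleCounts(f"{sel}_r{rep}", rep, sel, counts))
    return SortExperiment(samples)


@pytest.fixture(scope="session")
def sim_bundle(default_design):
    """One default-scale simulated campaign (seed 7) with its labels."""
    truth = make_truth(default_design, seed=7)
    config = SortConfig()
    experiment, truth_table, sequences = simulate_sort(
        default_design, truth, config, seed=8
    )
    labeled = build_labeled_dataset(experiment, sequences=sequences)
    return {
        "design": default_design,
        "truth": truth,
        "config": config,
        "experiment": experiment,
        "truth_table": truth_table,
        "sequences": sequences,
        "labeled": labeled,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(0)
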