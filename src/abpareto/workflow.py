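"""In-memory end-to-end workflow: simulate, label, train, evaluate, design.

This is the library counterpart of the file-based CLI pipeline, used for
ground-truth recovery studies. Each property model is trained on all
variants labeled for that property (an 80/20 train/holdout split); held-out
variants — everything outside the training split that the encoder can
represent — are scored against the simulator's latent truth. The master
subset enters only where the downstream analysis needs it (the Pareto
property plane).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import OneHotSequenceEncoder
from .labeling import build_labeled_dataset, select_master_dataset
from .models import LDAProjector
from .pareto import near_frontier, pareto_front
from .simulate import SortConfig, example_design, make_truth, simulate_sort
from .stats import spearman


@dataclass
class RecoveryResult:
    """Ground-truth recovery metrics of one simulated campaign."""

    affinity_spearman: float
    nonspec_spearman: float
    n_holdout_affinity: int
    n_holdout_nonspec: int
    affinity_cv_accuracy: float | None
    nonspec_cv_accuracy: float | None
    frontier_recovery: float
    n_frontier_projected: int
    n_frontier_latent: int
    n_labeled: int
    master_size: int


def _train_property(labeled, truth_table, label_col, latent_col, train_frac, rng):
    """Fit a one-hot LDA on one property's labeled variants; eval on holdout."""
    lab = labeled[labeled[label_col].isin(["positive", "negative"])]
    idx = lab.index.to_numpy()
    perm = rng.permutation(len(idx))
    train = lab.loc[idx[perm[: int(train_frac * len(idx))]]]
    enc = OneHotSequenceEncoder().fit(list(train["sequence"]))
    X = enc.transform(list(train["sequence"]))
    y = (train[label_col] == "positive").astype(int).to_numpy()
    model = LDAProjector().fit(X, y)
    held = truth_table.drop(index=train.index, errors="ignore")
    mask = enc.encodable_mask(list(held["sequence"]))
    held = held[mask]
    rho, _ = spearman(
        model.project(enc.transform(list(held["sequence"]))), held[latent_col]
    )
    return model, enc, float(rho), len(held)


def end_to_end_recovery(
    seed: int,
    config: SortConfig | None = None,
    master_n: int = 800,
    train_frac: float = 0.8,
    cv: bool = False,
) -> RecoveryResult:
    """Simulate a campaign, learn both property models, score recovery.

    Seeds are derived from ``seed``: truth effects use ``seed``, the sort
    uses ``seed + 1``, the train/holdout shuffle ``seed + 2``. Frontier
    recovery is the fraction of latent-truth Pareto-frontier variants (among
    the master subset) found inside the projection-space near-frontier set of
    size 2x the projected frontier.
    """
    from .models import cross_validate  # local import: avoids heavy import at module load

    design = example_design()
    config = config or SortConfig()
    truth = make_truth(design, seed=seed)
    experiment, truth_table, sequences = simulate_sort(design, truth, config, seed=seed + 1)
    labeled = build_labeled_dataset(experiment, sequences=sequences)

    rng = np.random.default_rng(seed + 2)
    aff_model, aff_enc, rho_a, n_a = _train_property(
        labeled, truth_table, "antigen_label", "latent_affinity", train_frac, rng
    )
    ns_model, ns_enc, rho_s, n_s = _train_property(
        labeled, truth_table, "specificity_label", "latent_nonspec", train_frac, rng
    )

    acc_a = acc_s = None
    if cv:
        lab_a = labeled[labeled["antigen_label"].isin(["positive", "negative"])]
        Xa = aff_enc.encodable_mask(list(lab_a["sequence"]))
        lab_a = lab_a[Xa]
        rep = cross_validate(
            LDAProjector(),
            aff_enc.transform(list(lab_a["sequence"])),
            (lab_a["antigen_label"] == "positive").astype(int).to_numpy(),
            seed=seed,
        )
        acc_a = rep.mean_test_accuracy
        lab_s = labeled[labeled["specificity_label"].isin(["positive", "negative"])]
        Xs = ns_enc.encodable_mask(list(lab_s["sequence"]))
        lab_s = lab_s[Xs]
        rep = cross_validate(
            LDAProjector(),
            ns_enc.transform(list(lab_s["sequence"])),
            (lab_s["specificity_label"] == "positive").astype(int).to_numpy(),
            seed=seed,
        )
        acc_s = rep.mean_test_accuracy

    # Pareto analysis over the master subset, as in the downstream design step
    master = select_master_dataset(labeled, n=master_n)
    ok = aff_enc.encodable_mask(list(master["sequence"])) & ns_enc.encodable_mask(
        list(master["sequence"])
    )
    master = master[ok]
    points = pd.DataFrame(
        {
            "affinity": aff_model.project(aff_enc.transform(list(master["sequence"]))),
            "nonspec": ns_model.project(ns_enc.transform(list(master["sequence"]))),
        },
        index=master.index,
    )
    latent = truth_table.loc[master.index, ["latent_affinity", "latent_nonspec"]]
    latent = latent.rename(
        columns={"latent_affinity": "affinity", "latent_nonspec": "nonspec"}
    )
    proj_front = pareto_front(points)
    latent_front = pareto_front(latent)
    near = near_frontier(points, k=2 * len(proj_front))
    recovery = float(latent_front.index.isin(near.index).mean())

    return RecoveryResult(
        affinity_spearman=rho_a,
        nonspec_spearman=rho_s,
        n_holdout_affinity=n_a,
        n_holdout_nonspec=n_s,
        affinity_cv_accuracy=acc_a,
        nonspec_cv_accuracy=acc_s,
        frontier_recovery=recovery,
        n_frontier_projected=len(proj_front),
        n_frontier_latent=len(latent_front),
        n_labeled=len(labeled),
        master_size=len(master),
    )
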