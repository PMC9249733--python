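"""Pareto-frontier identification and BLOSUM62-filtered mutational design.

Variants live in a two-objective property plane: an affinity metric
(maximize) and a non-specific-binding metric (minimize; higher = worse
specificity, matching the positive class of the specificity model). The
frontier is the set of non-dominated points; design proceeds by scanning
single mutations over named CDR regions, keeping evolutionarily conservative
substitutions (BLOSUM62 score >= 0 by default, cysteine excluded), scoring
them with the trained projection models, and selecting candidates at or
beyond the library frontier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from .library import AMINO_ACIDS, LibraryDesign, VHSequence

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def blosum62(a: str, b: str) -> int:
    """Symmetric BLOSUM62 substitution score for two canonical residues."""
    if a not in AMINO_ACIDS or b not in AMINO_ACIDS:
        raise ValueError(f"non-canonical residue pair ({a!r}, {b!r})")
    return int(_BLOSUM62[a, b])


def pareto_mask(affinity, nonspec) -> np.ndarray:
    """Boolean mask of non-dominated points under (affinity up, nonspec down).

    p dominates q iff p.affinity >= q.affinity and p.nonspec <= q.nonspec
    with at least one inequality strict; duplicated frontier points are all
    retained (neither dominates the other). Single sweep over points sorted
    by descending affinity.
    """
    aff = np.asarray(affinity, dtype=float)
    ns = np.asarray(nonspec, dtype=float)
    if aff.size == 0:
        raise ValueError("empty point set")
    if not (np.all(np.isfinite(aff)) and np.all(np.isfinite(ns))):
        raise ValueError("non-finite property metric")
    order = np.lexsort((ns, -aff))  # affinity desc, nonspec asc
    mask = np.zeros(aff.size, dtype=bool)
    best_ns_higher_aff = np.inf  # min nonspec among strictly higher affinity
    i = 0
    while i < aff.size:
        j = i
        while j < aff.size and aff[order[j]] == aff[order[i]]:
            j += 1
        group = order[i:j]
        group_min_ns = ns[group].min()
        for idx in group:
            # dominated by a strictly-higher-affinity point with <= nonspec,
            # or by an equal-affinity point with strictly lower nonspec
            if ns[idx] >= best_ns_higher_aff or ns[idx] > group_min_ns:
                continue
            mask[idx] = True
        best_ns_higher_aff = min(best_ns_higher_aff, group_min_ns)
        i = j
    return mask


def pareto_front(points: pd.DataFrame) -> pd.DataFrame:
    """Rows of ``points`` (columns ``affinity``, ``nonspec``) on the frontier."""
    return points[pareto_mask(points["affinity"], points["nonspec"])]


def _zscore(values, ref):
    ref = np.asarray(ref, dtype=float)
    sd = ref.std()
    return (np.asarray(values, dtype=float) - ref.mean()) / (sd if sd > 0 else 1.0)


def near_frontier(points: pd.DataFrame, k: int) -> pd.DataFrame:
    """The frontier plus the non-frontier points closest to it, ≤ k total.

    Distance is Euclidean in z-scored metric space (both axes standardized
    over all points) to the nearest frontier point; ties break by index so
    the selection is deterministic.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    mask = pareto_mask(points["affinity"], points["nonspec"])
    frontier = points[mask]
    if len(frontier) > k:
        raise ValueError(f"k={k} smaller than the frontier size {len(frontier)}")
    rest = points[~mask]
    n_extra = min(k - len(frontier), len(rest))
    if n_extra == 0:
        return frontier
    za = _zscore(points["affinity"], points["affinity"])
    zn = _zscore(points["nonspec"], points["nonspec"])
    zf = np.column_stack([za[mask], zn[mask]])
    zr = np.column_stack([za[~mask], zn[~mask]])
    d = np.sqrt(((zr[:, None, :] - zf[None, :, :]) ** 2).sum(axis=2)).min(axis=1)
    ranked = rest.assign(_d=d).sort_index(kind="mergesort").sort_values(
        "_d", kind="mergesort"
    )
    chosen = ranked.head(n_extra).drop(columns="_d")
    return pd.concat([frontier, chosen])


@dataclass
class TrainedPair:
    """Encoder shared by two projection models, one per property axis.

    ``score`` maps sequences into the property plane: the affinity model's
    projection (higher = stronger predicted antigen binding) and the
    specificity model's projection (higher = more predicted non-specific
    binding).
    """

    encoder: object
    affinity_model: object
    nonspec_model: object

    def score(self, sequences, ids=None) -> pd.DataFrame:
        X = self.encoder.transform(sequences)
        if ids is None:
            ids = [
                s.id if isinstance(s, VHSequence) else f"seq{i}"
                for i, s in enumerate(sequences)
            ]
        return pd.DataFrame(
            {
                "affinity": self.affinity_model.project(X),
                "nonspec": self.nonspec_model.project(X),
            },
            index=pd.Index(ids, name="sequence_id"),
        )


def scan_single_mutants(
    bases,
    design: LibraryDesign,
    trained: TrainedPair,
    regions=("HCDR2", "HCDR3"),
    blosum_min: int | None = 0,
    exclude: frozenset = frozenset("C"),
) -> pd.DataFrame:
    """Enumerate, filter, and score all single mutants over the given regions.

    For every base sequence, every site in the named regions, and every
    residue not the parent one and not excluded (cysteine by default), a
    candidate is emitted with its BLOSUM62 conservation score; candidates
    scoring below ``blosum_min`` are dropped when the filter is on
    (``blosum_min=None`` disables it). Survivors are scored by both models.
    HCDR1 is not scanned by default.
    """
    rows = []
    seqs = []
    for base in bases:
        for name in regions:
            if name not in design.region_map:
                raise KeyError(f"unknown region {name!r}")
            start, end = design.region_map[name]
            if end > len(base):
                raise ValueError(f"region {name} out of bounds for {base.id!r}")
            for i in range(start, end):
                parent_res = base.residues[i]
                for r in AMINO_ACIDS:
                    if r == parent_res or r in exclude:
                        continue
                    score = blosum62(parent_res, r)
                    if blosum_min is not None and score < blosum_min:
                        continue
                    mutant_id = f"{base.id}_{parent_res}{i + 1}{r}"
                    seqs.append(
                        VHSequence(
                            mutant_id,
                            base.residues[:i] + r + base.residues[i + 1 :],
                        )
                    )
                    rows.append(
                        {
                            "candidate_id": mutant_id,
                            "base_id": base.id,
                            "site": i,
                            "parent_residue": parent_res,
                            "proposed_residue": r,
                            "blosum62": score,
                        }
                    )
    out = pd.DataFrame(
        rows,
        columns=[
            "candidate_id", "base_id", "site",
            "parent_residue", "proposed_residue", "blosum62",
        ],
    )
    if not rows:
        out["affinity"] = pd.Series(dtype=float)
        out["nonspec"] = pd.Series(dtype=float)
        return out.set_index("candidate_id")
    scored = trained.score(seqs, ids=[r["candidate_id"] for r in rows])
    out = out.set_index("candidate_id").join(scored)
    return out


def select_designs(
    candidates: pd.DataFrame,
    n: int,
    library_points: pd.DataFrame,
) -> pd.DataFrame:
    """Pick up to ``n`` candidates along and beyond the library frontier.

    Priority: (i) candidates not dominated by any library frontier point come
    first — among those the first pick dominates the most library points
    (ties: larger affinity-minus-nonspec advance, then index) — then (ii)
    remaining picks greedily maximize the minimum distance to the already
    selected set in z-scored metric space (z stats from the library points),
    so the selection spreads across the frontier. Fully deterministic.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    lib_front = pareto_front(library_points)
    za_ref = library_points["affinity"]
    zn_ref = library_points["nonspec"]

    cand = candidates.copy()
    fa = lib_front["affinity"].to_numpy()
    fn = lib_front["nonspec"].to_numpy()
    ca = cand["affinity"].to_numpy()
    cn = cand["nonspec"].to_numpy()
    dominated = np.array(
        [np.any((fa >= a) & (fn <= s) & ((fa > a) | (fn < s))) for a, s in zip(ca, cn)]
    )
    la = library_points["affinity"].to_numpy()
    ln = library_points["nonspec"].to_numpy()
    n_dominates = np.array(
        [np.sum((a >= la) & (s <= ln) & ((a > la) | (s < ln))) for a, s in zip(ca, cn)]
    )
    cand["_nondominated"] = ~dominated
    cand["_ndom"] = n_dominates
    cand["_advance"] = _zscore(ca, za_ref) - _zscore(cn, zn_ref)
    z = np.column_stack([_zscore(ca, za_ref), _zscore(cn, zn_ref)])

    pool = cand.sort_index(kind="mergesort").sort_values(
        ["_nondominated", "_ndom", "_advance"],
        ascending=[False, False, False],
        kind="mergesort",
    )
    order = list(pool.index)
    pos = {cid: i for i, cid in enumerate(cand.index)}
    selected = [order.pop(0)]
    while order and len(selected) < n:
        sel_z = z[[pos[c] for c in selected]]
        # stay within the non-dominated tier while it has members
        tier = [c for c in order if cand.loc[c, "_nondominated"]] or order
        best, best_d = None, -1.0
        for c in tier:  # deterministic: first max wins, order is pre-sorted
            d = np.sqrt(((z[pos[c]] - sel_z) ** 2).sum(axis=1)).min()
            if d > best_d:
                best, best_d = c, d
        order.remove(best)
        selected.append(best)
    return candidates.loc[selected]
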