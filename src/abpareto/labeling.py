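"""Binary label assignment from replicated sorted-library deep sequencing.

The experiment bundles 12 samples (2 replicates x {input, antigen-positive,
PSR-positive, PSR-negative, OVA-positive, OVA-negative}). Labels are pure
functions of read presence/absence:

* antigen binding — positive iff a variant is read in *both* antigen-positive
  samples; discarded if in exactly one; negative if in neither but present in
  an input sample;
* non-specific binding ("specificity" axis) — positive iff present in at
  least 3 of the 4 non-specificity-positive samples and in none of the 4
  negative samples; symmetrically for negative; otherwise unlabeled.

Presence means read count >= ``min_count`` (default 1); the rules use no
abundance threshold beyond that.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .library import VHSequence

SELECTIONS = ("input", "antigen_pos", "psr_pos", "psr_neg", "ova_pos", "ova_neg")
NONSPEC_POS = ("psr_pos", "ova_pos")
NONSPEC_NEG = ("psr_neg", "ova_neg")


@dataclass
class SampleCounts:
    """Read counts of one deep-sequenced sample."""

    sample_id: str
    replicate: int
    selection: str
    counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.selection not in SELECTIONS:
            raise ValueError(f"unknown selection {self.selection!r}")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError(f"{self.sample_id}: negative read count")

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())

    def present(self, variant_id: str, min_count: int = 1) -> bool:
        return self.counts.get(variant_id, 0) >= min_count


@dataclass
class SortExperiment:
    """The full 12-sample bundle (at most one sample per replicate/selection)."""

    samples: list

    def __post_init__(self) -> None:
        keys = [(s.replicate, s.selection) for s in self.samples]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (replicate, selection) sample")
        if not any(s.selection == "input" for s in self.samples):
            raise ValueError("experiment needs at least one input sample")

    def get(self, selection: str, replicate: int) -> SampleCounts:
        for s in self.samples:
            if s.selection == selection and s.replicate == replicate:
                return s
        raise KeyError(f"no sample for selection={selection!r} replicate={replicate}")

    def select(self, selection: str) -> list:
        return sorted(
            (s for s in self.samples if s.selection == selection),
            key=lambda s: s.replicate,
        )

    def variant_ids(self) -> list:
        ids = set()
        for s in self.samples:
            ids.update(s.counts)
        return sorted(ids)

    @property
    def replicates(self) -> tuple:
        return tuple(sorted({s.replicate for s in self.samples}))


def experiment_to_frame(exp: SortExperiment) -> pd.DataFrame:
    rows = [
        (s.sample_id, s.replicate, s.selection, vid, c)
        for s in exp.samples
        for vid, c in sorted(s.counts.items())
    ]
    df = pd.DataFrame(
        rows, columns=["sample_id", "replicate", "selection", "sequence_id", "count"]
    )
    # canonical row order so writing and re-reading are byte-stable
    return df.sort_values(
        ["sample_id", "replicate", "selection", "sequence_id"], kind="mergesort"
    ).reset_index(drop=True)


def experiment_from_frame(df: pd.DataFrame) -> SortExperiment:
    required = {"sample_id", "replicate", "selection", "sequence_id", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"counts table missing columns {sorted(missing)}")
    samples = []
    for (sid, rep, sel), grp in df.groupby(
        ["sample_id", "replicate", "selection"], sort=True
    ):
        counts = dict(zip(grp["sequence_id"].astype(str), grp["count"].astype(int)))
        samples.append(SampleCounts(str(sid), int(rep), str(sel), counts))
    return SortExperiment(samples)


def read_counts_csv(path) -> SortExperiment:
    return experiment_from_frame(pd.read_csv(path))


def write_counts_csv(exp: SortExperiment, path) -> None:
    experiment_to_frame(exp).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Label rules


def assign_antigen_label(exp: SortExperiment, variant_id: str, min_count: int = 1):
    """Antigen-binding label: 'positive', 'negative', 'discarded', or None.

    ``None`` means the variant was seen nowhere relevant (absent from both
    antigen-positive samples and from every input sample); such variants are
    dropped upstream.
    """
    ag = exp.select("antigen_pos")
    if len(ag) != len(exp.replicates):
        raise ValueError("missing antigen_pos sample for a replicate")
    n_pos = sum(s.present(variant_id, min_count) for s in ag)
    if n_pos == len(ag):
        return "positive"
    if n_pos > 0:
        return "discarded"
    if any(s.present(variant_id, min_count) for s in exp.select("input")):
        return "negative"
    return None


def assign_specificity_label(exp: SortExperiment, variant_id: str, min_count: int = 1):
    """Non-specific-binding label: 'positive', 'negative', or 'unlabeled'.

    Positive = present in >=3 of the 4 non-specificity-positive samples
    (PSR/OVA x 2 replicates) and in none of the 4 negatives; negative is the
    mirror rule.
    """
    pos = [s for sel in NONSPEC_POS for s in exp.select(sel)]
    neg = [s for sel in NONSPEC_NEG for s in exp.select(sel)]
    if len(pos) != 4 or len(neg) != 4:
        raise ValueError("experiment must carry the 8 non-specific-binding samples")
    n_pos = sum(s.present(variant_id, min_count) for s in pos)
    n_neg = sum(s.present(variant_id, min_count) for s in neg)
    if n_pos >= 3 and n_neg == 0:
        return "positive"
    if n_neg >= 3 and n_pos == 0:
        return "negative"
    return "unlabeled"


def occurrence_frequency(
    exp: SortExperiment,
    variant_id: str,
    samples=None,
    mode: str = "occurrence",
    min_count: int = 1,
):
    """Cross-sample frequency of a variant.

    ``mode="occurrence"``: (number of samples where the variant is present) /
    (number of samples), over ``samples`` (default: all samples in the
    experiment). ``mode="abundance"``: per-sample relative abundance
    count/total_reads, returned as a dict keyed by sample_id (the quantity
    enrichment ratios are built from).
    """
    subset = list(samples) if samples is not None else list(exp.samples)
    if not subset:
        raise ValueError("empty sample subset")
    if mode == "occurrence":
        return sum(s.present(variant_id, min_count) for s in subset) / len(subset)
    if mode == "abundance":
        return {
            s.sample_id: (s.counts.get(variant_id, 0) / s.total_reads if s.total_reads else 0.0)
            for s in subset
        }
    raise ValueError(f"unknown frequency mode {mode!r}")


def enrichment_ratio(
    exp: SortExperiment,
    variant_id: str,
    output_selection: str,
    pseudocount: float = 0.0,
) -> float:
    """Replicate-averaged log2 output/input relative-frequency ratio.

    Per replicate i, ER_i = log2(f_out,i / f_in,i) with f the relative read
    abundance. A replicate contributes only when both frequencies are
    positive (or a pseudocount is configured, in which case ``pseudocount``
    reads are added to every numerator count). Returns NaN when no replicate
    has a defined ratio — a missing value, not an error.
    """
    ers = []
    for rep in exp.replicates:
        try:
            out = exp.get(output_selection, rep)
            inp = exp.get("input", rep)
        except KeyError:
            continue
        c_out = out.counts.get(variant_id, 0) + pseudocount
        c_in = inp.counts.get(variant_id, 0) + pseudocount
        tot_out = out.total_reads + pseudocount
        tot_in = inp.total_reads + pseudocount
        if c_out > 0 and c_in > 0 and tot_out > 0 and tot_in > 0:
            ers.append(math.log2((c_out / tot_out) / (c_in / tot_in)))
    return float(np.mean(ers)) if ers else float("nan")


# ---------------------------------------------------------------------------
# Labeled dataset


def build_labeled_dataset(
    exp: SortExperiment,
    sequences: dict | None = None,
    min_count: int = 1,
    enrichment_selections=(),
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Label every observed variant and tabulate frequencies/enrichments.

    Returns a DataFrame indexed by ``sequence_id`` with columns
    ``antigen_label``, ``specificity_label``, ``frequency`` (occurrence
    fraction over all samples), optional ``sequence``, and one
    ``enrichment_<selection>`` column per requested selection. Variants
    absent from the antigen samples *and* the input are dropped.
    """
    rows = {}
    for vid in exp.variant_ids():
        ag = assign_antigen_label(exp, vid, min_count)
        if ag is None:
            continue
        rows[vid] = {
            "antigen_label": ag,
            "specificity_label": assign_specificity_label(exp, vid, min_count),
            "frequency": occurrence_frequency(exp, vid, mode="occurrence", min_count=min_count),
        }
        for sel in enrichment_selections:
            rows[vid][f"enrichment_{sel}"] = enrichment_ratio(
                exp, vid, sel, pseudocount=pseudocount
            )
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "sequence_id"
    if sequences is not None:
        df["sequence"] = [
            sequences[vid].residues if isinstance(sequences[vid], VHSequence) else sequences[vid]
            for vid in df.index
        ]
    return df.sort_index()


def site_enrichment_matrix(
    labeled: pd.DataFrame,
    design,
    class_a,
    class_b,
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Per-site log2 residue-frequency ratios between two variant classes.

    ``class_a``/``class_b`` are boolean masks over ``labeled`` rows (e.g.
    specificity-positive vs -negative). Entry (site, residue) is
    log2(freq_A / freq_B) of that residue at that site; residues never seen
    at a site are NaN, as are zero-denominator entries when no pseudocount
    is configured.
    """
    if "sequence" not in labeled.columns:
        raise ValueError("labeled dataset must carry a 'sequence' column")
    seq_a = labeled.loc[class_a, "sequence"]
    seq_b = labeled.loc[class_b, "sequence"]
    if seq_a.empty or seq_b.empty:
        raise ValueError("both contrast classes must be non-empty")
    residues = sorted("ACDEFGHIKLMNPQRSTVWY")
    out = pd.DataFrame(
        np.nan, index=[s.label for s in design.sites], columns=residues
    )
    for s in design.sites:
        col_a = seq_a.str[s.index]
        col_b = seq_b.str[s.index]
        fa = col_a.value_counts()
        fb = col_b.value_counts()
        for r in residues:
            na, nb = fa.get(r, 0), fb.get(r, 0)
            if na == 0 and nb == 0:
                continue  # residue never sampled at this site
            num = (na + pseudocount) / (len(col_a) + pseudocount)
            den = (nb + pseudocount) / (len(col_b) + pseudocount)
            if num > 0 and den > 0:
                out.loc[s.label, r] = math.log2(num / den)
    return out


def select_master_dataset(labeled: pd.DataFrame, n: int = 4000) -> pd.DataFrame:
    """Pick the ``n`` master variants for model training.

    The selection is stratified evenly by specificity (n/2 positive, n/2
    negative). Within each stratum antigen-positive variants are taken first
    (they are the rarer class), then remaining slots are filled in order of
    descending occurrence frequency; ties break by (frequency desc, sequence
    id lexicographic) so the selection is deterministic.
    """
    if n % 2:
        raise ValueError("n must be even (even specificity stratification)")
    eligible = labeled[
        labeled["antigen_label"].isin(["positive", "negative"])
        & labeled["specificity_label"].isin(["positive", "negative"])
    ]
    parts = []
    for spec_class in ("positive", "negative"):
        stratum = eligible[eligible["specificity_label"] == spec_class]
        if len(stratum) < n // 2:
            raise ValueError(
                f"specificity-{spec_class} stratum has {len(stratum)} variants, "
                f"need {n // 2}"
            )
        stratum = stratum.copy()
        stratum["_ag"] = (stratum["antigen_label"] == "positive").astype(int)
        # stable sort: id lexicographic is the final tie-break
        stratum = stratum.sort_index(kind="mergesort").sort_values(
            ["_ag", "frequency"], ascending=[False, False], kind="mergesort"
        )
        parts.append(stratum.head(n // 2).drop(columns="_ag"))
    return pd.concat(parts).sort_index()
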