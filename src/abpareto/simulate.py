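"""Sort-and-sequence simulator with known ground truth.

The simulator stands in for a yeast-display campaign: a combinatorial CDR
library over a fixed parent VH sequence, two correlated latent properties
per variant (antigen-binding affinity and non-specific binding), quantile
FACS gates, and multinomial sequencing counts in duplicate.

Latent model: each non-parent residue at each mutagenized site carries a
pair of additive effects drawn from a bivariate normal with a configurable
cross-property correlation (high-affinity residues tend to raise
non-specific binding — the affinity/specificity tradeoff). Parent residues
have effect zero, so the parent variant sits at the origin. A variant's
latent value is the sum of its site effects plus one variant-level noise
draw.

Sorting: per replicate, a variant's gate signal is its latent value plus
display noise (per reagent and replicate — the two non-specificity
pseudo-reagents share the latent and differ only in this noise, emulating
PSR vs OVA). Gates keep the top 50% (antigen), top 25% and bottom 10%
(non-specific binding) of the abundance-weighted signal distribution.
Sequencing draws multinomial counts at a fixed depth from the renormalized
post-gate abundances; the input sample is sequenced ungated. The result is
the standard 12-sample bundle.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .labeling import SampleCounts, SortExperiment, write_counts_csv, read_counts_csv
from .library import (
    LibraryDesign,
    SiteSpec,
    VHSequence,
    design_from_dict,
    design_to_dict,
    theoretical_diversity,
)

# A synthetic 115-residue parent VH stand-in (the real parent sequence is not
# public). Framework positions are an arbitrary fixed sequence; the eight
# mutagenized sites carry the residues their Kabat-style labels imply.
_SYNTHETIC_PARENT_VH = (
    "EVQLVESGGGLVQPGGSLRLSCAASGFTFSDSYMSWVRQAPGKGLEWVS"  # 0-48, site 32 = Y
    "RISPSGGRRGTYYADSVKGRFTISRDNSKNTLYLQMNSLRAEDTAVYYC"  # 49-97
    "ARADWGSYDYWGQGTLV"                                  # 98-114
)


def example_design() -> LibraryDesign:
    """The default 8-site x 6-residue design on the synthetic parent.

    Site labels follow the Kabat-style names of the emibetuzumab campaign
    (Y33, R50, R54, R55, G56, A95, W97, Y102); indices are plain 0-based
    positions in the synthetic parent. Each site allows the parent residue
    plus five alternatives spanning a range of physicochemical character,
    giving a theoretical diversity of 6^8 = 1,679,616.
    """
    parent = VHSequence("parent", _SYNTHETIC_PARENT_VH)
    allowed = {
        32: "YADSTF",   # Y33
        49: "RAKQSE",   # R50
        56: "RAKQST",   # R54
        57: "RDKQSN",   # R55
        58: "GADSTN",   # G56
        100: "AGSTVD",  # A95
        102: "WAFSYL",  # W97
        107: "YADSTW",  # Y102
    }
    labels = ["H33", "H50", "H54", "H55", "H56", "H95", "H97", "H102"]
    sites = tuple(
        SiteSpec(idx, lab, frozenset(res))
        for (idx, res), lab in zip(sorted(allowed.items()), labels)
    )
    regions = {"HCDR1": (30, 36), "HCDR2": (49, 60), "HCDR3": (98, 110)}
    return LibraryDesign(parent, sites, regions)


@dataclass
class TruthModel:
    """Ground-truth additive effect maps for the two latent properties."""

    site_effects_affinity: dict
    site_effects_nonspec: dict
    effect_correlation: float
    noise_sd: float
    display_noise_sd: float
    epistasis: dict = field(default_factory=dict)

    def latent(self, seq: VHSequence, design: LibraryDesign, rng=None):
        """(affinity, nonspec) latent pair; noise added when an rng is given."""
        aff = ns = 0.0
        for s in design.sites:
            key = (s.index, seq.residues[s.index])
            aff += self.site_effects_affinity.get(key, 0.0)
            ns += self.site_effects_nonspec.get(key, 0.0)
        for (k1, k2), (ea, en) in self.epistasis.items():
            if (
                seq.residues[k1[0]] == k1[1]
                and seq.residues[k2[0]] == k2[1]
            ):
                aff += ea
                ns += en
        if rng is not None and self.noise_sd > 0:
            aff += rng.normal(0.0, self.noise_sd)
            ns += rng.normal(0.0, self.noise_sd)
        return aff, ns


@dataclass
class SortConfig:
    """Gate quantiles, sampling scale, and sequencing depth of a campaign."""

    antigen_keep_top: float = 0.50
    nonspec_pos_keep_top: float = 0.25
    nonspec_neg_keep_bottom: float = 0.10
    sequencing_depth: int = 100_000
    n_variants: int = 5_000
    abundance_sigma: float = 1.0   # log-normal sigma of initial abundances
    replicates: int = 2

    def __post_init__(self):
        for q in (self.antigen_keep_top, self.nonspec_pos_keep_top, self.nonspec_neg_keep_bottom):
            if not 0 < q < 1:
                raise ValueError(f"gate quantile {q} outside (0, 1)")
        if self.sequencing_depth < 0:
            raise ValueError("sequencing depth must be >= 0")


def make_truth(
    design: LibraryDesign,
    effect_sd: float = 1.0,
    effect_correlation: float = 0.6,
    noise_sd: float = 0.3,
    display_noise_sd: float = 0.3,
    seed: int = 0,
) -> TruthModel:
    """Draw per-(site, residue) effect pairs with the configured correlation.

    Effects for the two properties are bivariate normal (sd ``effect_sd``,
    correlation ``effect_correlation``); parent residues are the zero
    reference at every site.
    """
    if abs(effect_correlation) > 1:
        raise ValueError("|effect_correlation| must be <= 1")
    rng = np.random.default_rng(seed)
    cov = effect_sd**2 * np.array(
        [[1.0, effect_correlation], [effect_correlation, 1.0]]
    )
    eff_aff, eff_ns = {}, {}
    for s in design.sites:
        parent_res = design.parent.residues[s.index]
        for r in sorted(s.allowed_residues):
            if r == parent_res:
                eff_aff[(s.index, r)] = 0.0
                eff_ns[(s.index, r)] = 0.0
            else:
                a, n = rng.multivariate_normal([0.0, 0.0], cov)
                eff_aff[(s.index, r)] = float(a)
                eff_ns[(s.index, r)] = float(n)
    return TruthModel(eff_aff, eff_ns, effect_correlation, noise_sd, display_noise_sd)


def _sample_variants(design: LibraryDesign, n: int, rng) -> list:
    """Draw n distinct library members uniformly over the combinatorial space."""
    diversity = theoretical_diversity(design)
    if n > diversity:
        raise ValueError(f"n={n} exceeds theoretical diversity {diversity}")
    choices = [sorted(s.allowed_residues) for s in design.sites]
    parent = design.parent.residues
    seen = {}
    while len(seen) < n:
        batch = [
            "".join(c[i] for c, i in zip(choices, draw))
            for draw in rng.integers(0, [len(c) for c in choices], size=(n, len(choices)))
        ]
        for combo in batch:
            if len(seen) >= n:
                break
            if combo not in seen:
                res = list(parent)
                for s, r in zip(design.sites, combo):
                    res[s.index] = r
                seen[combo] = "".join(res)
    return [VHSequence(f"v{k:05d}", s) for k, s in enumerate(seen.values())]


def _weighted_quantile(values, weights, q):
    """Value at weighted quantile q (inclusive cumulative convention)."""
    order = np.argsort(values, kind="mergesort")
    cw = np.cumsum(weights[order])
    cw /= cw[-1]
    return values[order][np.searchsorted(cw, q, side="left")]


def simulate_sort(
    design: LibraryDesign,
    truth: TruthModel,
    config: SortConfig,
    seed: int = 0,
):
    """Run the full campaign; returns (SortExperiment, truth table, sequences).

    The truth table (one row per sampled variant: latent affinity and latent
    non-specific binding, initial abundance) is ground truth for tests and
    evaluation only — labeling and modeling consume the count tables alone.
    """
    rng = np.random.default_rng(seed)
    variants = _sample_variants(design, config.n_variants, rng)
    n = len(variants)
    abundance = rng.lognormal(0.0, config.abundance_sigma, size=n)
    abundance /= abundance.sum()
    latents = np.array([truth.latent(v, design, rng=rng) for v in variants])
    aff, ns = latents[:, 0], latents[:, 1]

    ids = np.array([v.id for v in variants])

    def counts_from(weights) -> dict:
        total = weights.sum()
        if config.sequencing_depth == 0 or total == 0:
            return {}
        draws = rng.multinomial(config.sequencing_depth, weights / total)
        return {vid: int(c) for vid, c in zip(ids, draws) if c > 0}

    samples = []
    for rep in range(1, config.replicates + 1):
        samples.append(
            SampleCounts(f"input_r{rep}", rep, "input", counts_from(abundance))
        )
        # antigen gate: top 50% of the abundance-weighted affinity signal
        sig = aff + (
            rng.normal(0.0, truth.display_noise_sd, size=n)
            if truth.display_noise_sd > 0
            else 0.0
        )
        thr = _weighted_quantile(sig, abundance, 1.0 - config.antigen_keep_top)
        samples.append(
            SampleCounts(
                f"antigen_pos_r{rep}", rep, "antigen_pos",
                counts_from(abundance * (sig >= thr)),
            )
        )
        # two pseudo-reagents sharing the non-specificity latent
        for reagent in ("psr", "ova"):
            sig = ns + (
                rng.normal(0.0, truth.display_noise_sd, size=n)
                if truth.display_noise_sd > 0
                else 0.0
            )
            thr_hi = _weighted_quantile(sig, abundance, 1.0 - config.nonspec_pos_keep_top)
            thr_lo = _weighted_quantile(sig, abundance, config.nonspec_neg_keep_bottom)
            samples.append(
                SampleCounts(
                    f"{reagent}_pos_r{rep}", rep, f"{reagent}_pos",
                    counts_from(abundance * (sig >= thr_hi)),
                )
            )
            samples.append(
                SampleCounts(
                    f"{reagent}_neg_r{rep}", rep, f"{reagent}_neg",
                    counts_from(abundance * (sig <= thr_lo)),
                )
            )
    experiment = SortExperiment(samples)
    truth_table = pd.DataFrame(
        {
            "sequence": [v.residues for v in variants],
            "latent_affinity": aff,
            "latent_nonspec": ns,
            "abundance": abundance,
        },
        index=pd.Index(ids, name="sequence_id"),
    )
    sequences = {v.id: v for v in variants}
    return experiment, truth_table, sequences


# ---------------------------------------------------------------------------
# Fixture I/O


def write_fixture(experiment, truth_table, design, out_dir, seed, config=None):
    """Write counts.csv, truth.csv, design.yaml, and a seed manifest.

    Downstream stages read counts.csv and design.yaml only; truth.csv exists
    for tests and evaluation against ground truth.
    """
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_counts_csv(experiment, out / "counts.csv")
    truth_table.to_csv(out / "truth.csv")
    with open(out / "design.yaml", "w") as fh:
        yaml.safe_dump(design_to_dict(design), fh, sort_keys=False)
    manifest = {
        "seed": int(seed),
        "config": asdict(config) if config is not None else None,
        "digests": {
            name: hashlib.sha256((out / name).read_bytes()).hexdigest()
            for name in ("counts.csv", "truth.csv", "design.yaml")
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out


def read_fixture(fix_dir):
    """Load (experiment, truth table, design, manifest) from a fixture dir."""
    import pathlib

    fix = pathlib.Path(fix_dir)
    experiment = read_counts_csv(fix / "counts.csv")
    truth_table = pd.read_csv(fix / "truth.csv", index_col="sequence_id")
    with open(fix / "design.yaml") as fh:
        design = design_from_dict(yaml.safe_load(fh))
    with open(fix / "manifest.json") as fh:
        manifest = json.load(fh)
    return experiment, truth_table, design, manifest
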