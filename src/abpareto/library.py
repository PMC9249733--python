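"""Sequence and library-design data model.

A combinatorial CDR library is described by a parent heavy-chain variable
(VH) sequence plus a set of mutagenized sites, each with a small set of
allowed residues (always including the parent residue). Positions are plain
0-based string indices; Kabat-style labels (e.g. ``"H33"``) are carried as
display metadata only.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)


@dataclass(frozen=True)
class VHSequence:
    """An immutable amino-acid sequence over the 20-canonical alphabet."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"{self.id!r}: empty sequence")
        bad = set(self.residues) - _AA_SET
        if bad:
            raise ValueError(
                f"{self.id!r}: non-canonical residues {sorted(bad)} "
                "(gaps and unidentified residues are rejected)"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, i):
        return self.residues[i]


@dataclass(frozen=True)
class SiteSpec:
    """One mutagenized site: 0-based index, display label, allowed residues."""

    index: int
    label: str
    allowed_residues: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(self, "allowed_residues", frozenset(self.allowed_residues))
        if not self.allowed_residues:
            raise ValueError(f"site {self.label}: empty allowed-residue set")
        bad = self.allowed_residues - _AA_SET
        if bad:
            raise ValueError(f"site {self.label}: non-canonical residues {sorted(bad)}")


@dataclass(frozen=True)
class LibraryDesign:
    """Parent sequence plus ordered mutagenized sites.

    ``region_map`` optionally names contiguous index ranges, e.g.
    ``{"HCDR2": (49, 59)}`` (half-open, 0-based), used by the mutational
    scan to restrict design regions.
    """

    parent: VHSequence
    sites: tuple
    region_map: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sites", tuple(self.sites))
        idx = [s.index for s in self.sites]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("site indices must be strictly increasing and unique")
        for s in self.sites:
            if s.index >= len(self.parent):
                raise ValueError(f"site {s.label}: index {s.index} beyond parent length")
            if self.parent[s.index] not in s.allowed_residues:
                raise ValueError(
                    f"site {s.label}: parent residue {self.parent[s.index]!r} "
                    "not in allowed set"
                )
        for name, (a, b) in self.region_map.items():
            if not (0 <= a <= b <= len(self.parent)):  # empty ranges are legal
                raise ValueError(f"region {name}: range ({a}, {b}) out of bounds")

    @property
    def site_indices(self) -> tuple:
        return tuple(s.index for s in self.sites)


@dataclass(frozen=True)
class Mutation:
    """A single substitution relative to the parent."""

    site: int
    parent_residue: str
    observed_residue: str
    in_design: bool


def theoretical_diversity(design: LibraryDesign) -> int:
    """Number of distinct library members: product of per-site allowed-set sizes."""
    n = 1
    for s in design.sites:
        n *= len(s.allowed_residues)
    return n


def mutations_from_parent(seq: VHSequence, design: LibraryDesign) -> list:
    """All positions where ``seq`` differs from the design parent.

    Off-design substitutions are flagged via ``Mutation.in_design``.
    """
    parent = design.parent
    if len(seq) != len(parent):
        raise ValueError(
            f"{seq.id!r}: length {len(seq)} != parent length {len(parent)} "
            "(malformed record)"
        )
    design_idx = set(design.site_indices)
    return [
        Mutation(i, p, o, i in design_idx)
        for i, (p, o) in enumerate(zip(parent.residues, seq.residues))
        if p != o
    ]


def consensus_sequence(sequences, id: str = "consensus") -> VHSequence:
    """Per-position majority residue (ties broken alphabetically)."""
    if not sequences:
        raise ValueError("empty dataset")
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise ValueError(f"sequences of unequal length: {sorted(lengths)}")
    cols = zip(*(s.residues for s in sequences))
    residues = "".join(
        max(sorted(set(col)), key=lambda r: sum(c == r for c in col)) for col in cols
    )
    return VHSequence(id, residues)


def off_design_fraction(sequences, design: LibraryDesign, reference="consensus") -> float:
    """Fraction of sequences mismatching the reference outside design sites.

    ``reference`` may be a :class:`VHSequence` or the string ``"consensus"``,
    in which case the per-position majority residue of the dataset is used
    (useful when the true parent sequence is unknown).
    """
    if not sequences:
        raise ValueError("empty dataset")
    ref = consensus_sequence(sequences) if reference == "consensus" else reference
    design_idx = set(design.site_indices)
    off = [i for i in range(len(ref)) if i not in design_idx]
    n_hit = sum(
        1
        for s in sequences
        if any(s.residues[i] != ref.residues[i] for i in off)
    )
    return n_hit / len(sequences)


def enumerate_variants(design: LibraryDesign, id_prefix: str = "v"):
    """Yield every library member (lexicographic over sorted allowed sets)."""
    choices = [sorted(s.allowed_residues) for s in design.sites]
    parent = list(design.parent.residues)
    for k, combo in enumerate(itertools.product(*choices)):
        res = parent[:]
        for site, r in zip(design.sites, combo):
            res[site.index] = r
        yield VHSequence(f"{id_prefix}{k}", "".join(res))


# ---------------------------------------------------------------------------
# I/O


def _detect_format(path) -> str:
    p = str(path).lower()
    return "csv" if p.endswith(".csv") else "fasta"


def read_sequences(path, format: str | None = None, on_invalid: str = "raise"):
    """Read sequences from FASTA or CSV (column ``sequence``, optional ``id``).

    Records with gaps or residues outside the canonical alphabet are either
    rejected with a :class:`ValueError` naming the record (``on_invalid=
    "raise"``) or dropped (``on_invalid="discard"``). With ``"discard"`` the
    return value is ``(sequences, discarded)`` where ``discarded`` is a list
    of ``(record_number, id, reason)`` tuples.
    """
    fmt = format or _detect_format(path)
    raw = []
    if fmt == "fasta":
        for rec in SeqIO.parse(str(path), "fasta"):
            raw.append((rec.id, str(rec.seq)))
    elif fmt == "csv":
        df = pd.read_csv(path, dtype=str)
        if "sequence" not in df.columns:
            raise ValueError(f"{path}: CSV must carry a 'sequence' column")
        ids = df["id"] if "id" in df.columns else (f"seq{i}" for i in range(len(df)))
        raw = list(zip(ids, df["sequence"]))
    else:
        raise ValueError(f"unknown sequence format {fmt!r}")

    seqs, discarded = [], []
    for lineno, (sid, s) in enumerate(raw, start=1):
        try:
            seqs.append(VHSequence(str(sid), str(s)))
        except ValueError as e:
            if on_invalid == "raise":
                raise ValueError(f"record {lineno}: {e}") from e
            discarded.append((lineno, str(sid), str(e)))
    if on_invalid == "discard":
        return seqs, discarded
    return seqs


def write_sequences(sequences, path, format: str | None = None) -> None:
    """Write sequences as single-line FASTA or a CSV with id/sequence columns."""
    fmt = format or _detect_format(path)
    if fmt == "fasta":
        records = [
            SeqRecord(Seq(s.residues), id=s.id, description="") for s in sequences
        ]
        with open(path, "w") as fh:
            SeqIO.write(records, fh, "fasta-2line")
    elif fmt == "csv":
        pd.DataFrame(
            {"id": [s.id for s in sequences], "sequence": [s.residues for s in sequences]}
        ).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown sequence format {fmt!r}")


def design_to_dict(design: LibraryDesign) -> dict:
    return {
        "parent": {"id": design.parent.id, "sequence": design.parent.residues},
        "sites": [
            {
                "index": s.index,
                "label": s.label,
                "allowed_residues": "".join(sorted(s.allowed_residues)),
            }
            for s in design.sites
        ],
        "regions": {k: list(v) for k, v in design.region_map.items()},
    }


def design_from_dict(d: dict) -> LibraryDesign:
    parent = VHSequence(d["parent"].get("id", "parent"), d["parent"]["sequence"])
    sites = [
        SiteSpec(s["index"], s.get("label", f"s{s['index']}"), frozenset(s["allowed_residues"]))
        for s in d["sites"]
    ]
    regions = {k: tuple(v) for k, v in d.get("regions", {}).items()}
    return LibraryDesign(parent, tuple(sites), regions)
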