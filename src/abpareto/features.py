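"""Sequence feature encoders behind a uniform sklearn-transformer interface.

Three encodings are provided:

* :class:`OneHotSequenceEncoder` — per-position indicator columns, with
  categories learned from the fitting set (a residue never seen at a
  position during fitting cannot be encoded later and raises);
* :class:`PhysChemEncoder` — a fixed 26-descriptor vector per sequence:
  the 20 residue counts, four residue-class counts (hydrophobic,
  amphipathic, polar, charged), the isoelectric point, and the mean
  Kyte–Doolittle hydropathy;
* :class:`MLSTMEmbedder` — the mean hidden state of a 64-unit multiplicative
  LSTM run over the sequence; weights come from a file or from a seeded
  random initialization (the latter is only for structural testing).

All transformers accept lists of :class:`~abpareto.library.VHSequence` or
plain strings and return numpy arrays; ``encode_frame`` wraps any of them
into a named-column DataFrame keyed by variant id.
"""

from __future__ import annotations

import hashlib

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.preprocessing import OneHotEncoder

from .library import AMINO_ACIDS, VHSequence

# Kyte–Doolittle hydropathy index.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Residue classes; note M belongs to both the amphipathic and polar sets.
HYDROPHOBIC = frozenset("AILFV")
AMPHIPATHIC = frozenset("WYM")
POLAR = frozenset("QNSTCM")
CHARGED = frozenset("KRDEH")

# Bjellqvist/ExPASy pKa constants for the net-charge/pI calculation.
PKA_BJELLQVIST = {
    "n_term": 7.5,
    "c_term": 3.55,
    "K": 10.0,
    "R": 12.0,
    "H": 5.98,
    "D": 4.05,
    "E": 4.45,
    "C": 9.0,
    "Y": 10.0,
}

PHYSCHEM_FEATURE_NAMES = (
    [f"count_{aa}" for aa in AMINO_ACIDS]
    + ["n_hydrophobic", "n_amphipathic", "n_polar", "n_charged", "pI", "mean_hydropathy"]
)


def _as_strings(sequences) -> list:
    return [s.residues if isinstance(s, VHSequence) else str(s) for s in sequences]


def net_charge(sequence: str, pH: float, pka: dict = PKA_BJELLQVIST) -> float:
    """Net charge of a sequence at a given pH (Henderson–Hasselbalch terms)."""
    pos = 10 ** -pH / (10 ** -pka["n_term"] + 10 ** -pH)
    for aa in ("K", "R", "H"):
        pos += sequence.count(aa) * 10 ** -pH / (10 ** -pka[aa] + 10 ** -pH)
    neg = 10 ** -pka["c_term"] / (10 ** -pka["c_term"] + 10 ** -pH)
    for aa in ("D", "E", "C", "Y"):
        neg += sequence.count(aa) * 10 ** -pka[aa] / (10 ** -pka[aa] + 10 ** -pH)
    return pos - neg


def isoelectric_point(
    sequence: str, pka: dict = PKA_BJELLQVIST, tol: float = 1e-4
) -> float:
    """pH at which the net charge vanishes, by bisection over [0, 14].

    Net charge is strictly decreasing in pH, so bisection converges; the
    iteration stops when |charge| < ``tol``.
    """
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = (lo + hi) / 2
        q = net_charge(sequence, mid, pka)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


class OneHotSequenceEncoder(BaseEstimator, TransformerMixin):
    """Per-position one-hot encoding with data-driven categories.

    Each position contributes one indicator column per residue observed
    there in the fitting set, so every encoded row sums to the sequence
    length. Transforming a residue unseen at its position raises — by
    design, since the model has no weight for it.
    """

    def fit(self, X, y=None):
        seqs = _as_strings(X)
        if not seqs:
            raise ValueError("empty fitting set")
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ValueError(f"sequences of unequal length: {sorted(lengths)}")
        self.sequence_length_ = lengths.pop()
        chars = np.array([list(s) for s in seqs], dtype="U1")
        self.encoder_ = OneHotEncoder(handle_unknown="error", sparse_output=False)
        self.encoder_.fit(chars)
        self.categories_ = self.encoder_.categories_
        self.n_features_out_ = sum(len(c) for c in self.categories_)
        return self

    def transform(self, X):
        seqs = _as_strings(X)
        if any(len(s) != self.sequence_length_ for s in seqs):
            raise ValueError("sequence length differs from the fitted length")
        chars = np.array([list(s) for s in seqs], dtype="U1")
        return self.encoder_.transform(chars)

    def encodable_mask(self, X) -> np.ndarray:
        """Which sequences can be encoded (no residue unseen at its position)."""
        seqs = _as_strings(X)
        sets = [set(c) for c in self.categories_]
        return np.array(
            [
                len(s) == self.sequence_length_
                and all(r in cs for r, cs in zip(s, sets))
                for s in seqs
            ],
            dtype=bool,
        )

    def get_feature_names_out(self, input_features=None):
        return np.array(
            [
                f"pos{i}_{aa}"
                for i, cats in enumerate(self.categories_)
                for aa in cats
            ]
        )

    @property
    def encoder_id(self) -> str:
        digest = hashlib.sha256(
            "|".join("".join(c) for c in self.categories_).encode()
        ).hexdigest()[:12]
        return f"onehot-{digest}"


class PhysChemEncoder(BaseEstimator, TransformerMixin):
    """26 physicochemical descriptors of the whole VH domain.

    Features 1–20: residue counts (alphabetical one-letter order);
    21–24: hydrophobic/amphipathic/polar/charged class counts;
    25: isoelectric point; 26: mean Kyte–Doolittle hydropathy.
    """

    def __init__(self, pka: dict | None = None):
        self.pka = pka

    def fit(self, X=None, y=None):
        self.pka_ = dict(self.pka or PKA_BJELLQVIST)
        self.n_features_out_ = 26
        return self

    def transform(self, X):
        if not hasattr(self, "pka_"):
            self.fit()
        seqs = _as_strings(X)
        out = np.empty((len(seqs), 26))
        for i, s in enumerate(seqs):
            if not s:
                raise ValueError("empty sequence")
            counts = [s.count(aa) for aa in AMINO_ACIDS]
            out[i, :20] = counts
            out[i, 20] = sum(1 for r in s if r in HYDROPHOBIC)
            out[i, 21] = sum(1 for r in s if r in AMPHIPATHIC)
            out[i, 22] = sum(1 for r in s if r in POLAR)
            out[i, 23] = sum(1 for r in s if r in CHARGED)
            out[i, 24] = isoelectric_point(s, self.pka_)
            out[i, 25] = sum(KYTE_DOOLITTLE[r] for r in s) / len(s)
        return out

    def get_feature_names_out(self, input_features=None):
        return np.array(PHYSCHEM_FEATURE_NAMES)

    @property
    def encoder_id(self) -> str:
        return "physchem-26"


class MLSTMEmbedder(BaseEstimator, TransformerMixin):
    """Mean hidden state of a multiplicative LSTM over the sequence.

    The cell follows the mLSTM parameterization: an intermediate
    multiplicative state ``m_t = (W_mx x_t) * (W_mh h_{t-1})`` feeds the
    input/forget/output gates together with the token embedding. The
    per-sequence representation is the mean of ``h_t`` over positions,
    giving ``n_units`` features (64 by default).

    ``weights_path`` loads a ``.npz`` with the cell parameters; without it,
    parameters are drawn from a seeded normal initialization — deterministic
    and order-sensitive, suitable for structural tests but carrying no
    learned information.
    """

    _PARAM_SHAPES = ("W_mx", "W_mh", "W_x", "W_m", "b", "E")

    def __init__(self, n_units: int = 64, weights_path=None, random_state: int = 0):
        self.n_units = n_units
        self.weights_path = weights_path
        self.random_state = random_state

    def _expected_shapes(self):
        n, e = self.n_units, self.n_units
        return {
            "E": (len(AMINO_ACIDS), e),     # token embedding
            "W_mx": (e, n),
            "W_mh": (n, n),
            "W_x": (e, 4 * n),              # gates i, f, o and candidate u
            "W_m": (n, 4 * n),
            "b": (4 * n,),
        }

    def fit(self, X=None, y=None):
        shapes = self._expected_shapes()
        if self.weights_path is not None:
            data = np.load(self.weights_path)
            self.params_ = {}
            for name, shape in shapes.items():
                if name not in data:
                    raise ValueError(f"weight file missing array {name!r}")
                if data[name].shape != shape:
                    raise ValueError(
                        f"weight {name!r}: shape {data[name].shape} != expected {shape}"
                    )
                self.params_[name] = np.asarray(data[name], dtype=float)
        else:
            rng = np.random.default_rng(self.random_state)
            self.params_ = {
                name: rng.normal(0.0, 1.0 / np.sqrt(max(shape[0], 1)), size=shape)
                for name, shape in shapes.items()
            }
        self._aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
        return self

    def save_weights(self, path) -> None:
        np.savez(path, **self.params_)

    def _embed_one(self, s: str) -> np.ndarray:
        p = self.params_
        n = self.n_units
        h = np.zeros(n)
        c = np.zeros(n)
        hs = np.empty((len(s), n))
        for t, aa in enumerate(s):
            x = p["E"][self._aa_index[aa]]
            m = (x @ p["W_mx"]) * (h @ p["W_mh"])
            z = x @ p["W_x"] + m @ p["W_m"] + p["b"]
            i = _sigmoid(z[:n])
            f = _sigmoid(z[n : 2 * n])
            o = _sigmoid(z[2 * n : 3 * n])
            u = np.tanh(z[3 * n :])
            c = f * c + i * u
            h = o * np.tanh(c)
            hs[t] = h
        return hs.mean(axis=0)

    def transform(self, X):
        if not hasattr(self, "params_"):
            self.fit()
        seqs = _as_strings(X)
        return np.vstack([self._embed_one(s) for s in seqs])

    def get_feature_names_out(self, input_features=None):
        return np.array([f"emb_{i}" for i in range(self.n_units)])

    @property
    def encoder_id(self) -> str:
        digest = hashlib.sha256(
            b"".join(np.ascontiguousarray(v).tobytes() for _, v in sorted(self.params_.items()))
        ).hexdigest()[:12]
        return f"mlstm{self.n_units}-{digest}"


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# Thin functional wrappers returning named feature tables


def encode_frame(encoder, sequences, ids=None) -> pd.DataFrame:
    """Transform sequences and wrap the result as a named-column DataFrame."""
    X = encoder.transform(sequences)
    if ids is None:
        ids = [
            s.id if isinstance(s, VHSequence) else f"seq{i}"
            for i, s in enumerate(sequences)
        ]
    return pd.DataFrame(X, index=pd.Index(ids, name="sequence_id"),
                        columns=encoder.get_feature_names_out())


def onehot_encode(sequences, fitted: OneHotSequenceEncoder | None = None):
    """One-hot encode sequences; fits a fresh encoder when none is given."""
    enc = fitted or OneHotSequenceEncoder().fit(sequences)
    return encode_frame(enc, sequences), enc


def physchem_encode(sequence) -> np.ndarray:
    """The 26-descriptor vector of a single sequence."""
    return PhysChemEncoder().fit().transform([sequence])[0]


def embed_sequences(sequences, embedder: MLSTMEmbedder | None = None):
    """64-dimensional mean-hidden-state embeddings of the sequences."""
    emb = embedder or MLSTMEmbedder().fit()
    if not hasattr(emb, "params_"):
        emb.fit()
    return encode_frame(emb, sequences), emb
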