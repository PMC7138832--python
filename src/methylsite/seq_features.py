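"""Sequence-derived feature encoders: LC, PWAA, EBGW, CKSAAP, KNN, AAindex.

All encoders are pure functions of the window (plus configuration): the same
input always yields bit-identical output.  The padding/unknown letter 'X' is
handled explicitly by every encoder — it contributes nothing to amino-acid
compositions, has zero similarity in the KNN metric, and maps to zero in
property encodings — so terminal windows encode without special cases.

Symbols: a window of size ``w = 2L + 1`` has offsets ``i = -L..L`` with the
candidate residue at ``i = 0``; ``k`` is the CKSAAP pair spacing; ``K`` the
neighbour count of the KNN score.
"""

from __future__ import annotations

import importlib.resources
import io
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

from .datasets import ALPHABET, STANDARD_AA, WindowFragment

AA_INDEX = {a: i for i, a in enumerate(STANDARD_AA)}
ALPHA_INDEX = {a: i for i, a in enumerate(ALPHABET)}

# EBGW physicochemical groups
_C1_NONPOLAR = set("GAVLIMPFW")
_C2_POLAR_UNCHARGED = set("QNSTYC")
_C3_POSITIVE = set("HKR")
_C4_NEGATIVE = set("DE")

SEQ_SUBTYPES = ("LC", "PWAA", "EBGW", "CKSAAP", "KNN", "AAindex")


@dataclass(frozen=True)
class FeatureBlock:
    """A named feature subtype with a fixed-dimension real vector."""

    subtype: str
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=float).ravel()
        )

    @property
    def dim(self) -> int:
        return self.values.size


def blosum62_similarity() -> np.ndarray:
    """21x21 similarity over the alphabet: BLOSUM62 min-max rescaled to [0, 1].

    The 'X' row/column is zero (unknown/padding carries no similarity).
    """
    blosum = substitution_matrices.load("BLOSUM62")
    m = np.zeros((21, 21))
    raw = np.array(
        [[blosum[a, b] for b in STANDARD_AA] for a in STANDARD_AA], dtype=float
    )
    lo, hi = raw.min(), raw.max()
    m[:20, :20] = (raw - lo) / (hi - lo)
    return m


@dataclass
class SeqEncoderConfig:
    """Configuration shared by the sequence encoders.

    ebgw_segments
        number of nested prefixes (``L_seg``) per EBGW binary sequence.
    cksaap_gaps
        spacings ``k``; every k must satisfy ``k <= w - 2``.
    knn_k
        neighbour counts for the KNN score.
    """

    ebgw_segments: int = 5
    cksaap_gaps: tuple = (0, 1, 2, 3, 4, 5)
    knn_k: tuple = (2, 4, 8, 16, 32)
    aaindex_table: "AAIndexTable | None" = None
    similarity_matrix: np.ndarray = field(default_factory=blosum62_similarity)

    def __post_init__(self):
        if self.ebgw_segments < 1:
            raise ValueError("ebgw_segments must be >= 1")
        if any(k < 0 for k in self.cksaap_gaps):
            raise ValueError("CKSAAP gaps must be non-negative")
        if self.aaindex_table is None:
            self.aaindex_table = load_default_aaindex()


# ---------------------------------------------------------------------------
# AAindex property table


@dataclass
class AAIndexTable:
    """Physicochemical properties: one row of 20 values per property id."""

    ids: list
    values: np.ndarray  # (n_props, 20) in alphabetical one-letter order

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), 20):
            raise ValueError("property table must be (n_props, 20)")

    @property
    def n_props(self) -> int:
        return len(self.ids)

    def znormalized(self) -> np.ndarray:
        mu = self.values.mean(axis=1, keepdims=True)
        sd = self.values.std(axis=1, keepdims=True)
        if np.any(sd == 0):
            flat = [self.ids[i] for i in np.where(sd.ravel() == 0)[0]]
            raise ValueError(f"zero-variance property: {flat}")
        return (self.values - mu) / sd


def parse_aaindex_table(source) -> AAIndexTable:
    """Rows: property id + 20 whitespace-separated reals (alphabetical AA order)."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = str(source)
        if "\n" not in text:
            with open(text, "r", encoding="utf-8") as fh:
                text = fh.read()
    ids, rows = [], []
    for raw in io.StringIO(text):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 21:
            raise ValueError(
                f"property row needs id + 20 values, got {len(parts)} fields"
            )
        ids.append(parts[0])
        rows.append([float(v) for v in parts[1:]])
    return AAIndexTable(ids=ids, values=np.array(rows))


def load_default_aaindex() -> AAIndexTable:
    text = (
        importlib.resources.files("methylsite.data")
        .joinpath("aaindex_demo.txt")
        .read_text(encoding="utf-8")
    )
    return parse_aaindex_table(io.StringIO(text))


# ---------------------------------------------------------------------------
# Encoders


def encode_LC(position: int, seq_len: int) -> FeatureBlock:
    """Location coding: relative position of the residue in the chain (dim 3)."""
    if not 1 <= position <= seq_len:
        raise ValueError("position out of range")
    L = float(seq_len)
    return FeatureBlock(
        "LC", [position / L, (position - 1) / L, (seq_len - position) / L]
    )


def encode_PWAA(window: WindowFragment) -> FeatureBlock:
    """Position-weighted amino-acid composition (dim 20).

    ``C(a) = (1 / (L(L+1))) * sum_i x_i(a) * (i + |i|/L)`` over offsets
    ``i = -L..L``; 'X' contributes nothing.
    """
    L = (window.w - 1) // 2
    if L < 1:
        raise ValueError("PWAA requires w >= 3")
    c = np.zeros(20)
    for i in range(-L, L + 1):
        aa = window.text[i + L]
        if aa in AA_INDEX:
            c[AA_INDEX[aa]] += i + abs(i) / L
    return FeatureBlock("PWAA", c / (L * (L + 1)))


def encode_EBGW(window: WindowFragment, L_seg: int = 5) -> FeatureBlock:
    """Encoding based on grouped weight (dim 3 * L_seg).

    Residues fall into nonpolar, polar-uncharged, positive and negative
    groups; three binary profiles (nonpolar+polar, nonpolar+positive,
    nonpolar+negative) are summarised as ones-densities over nested prefixes
    of length ``round(j * w / L_seg)``.
    """
    if L_seg < 1:
        raise ValueError("L_seg must be >= 1")
    w = window.w
    h1 = np.array([c in _C1_NONPOLAR or c in _C2_POLAR_UNCHARGED for c in window.text])
    h2 = np.array([c in _C1_NONPOLAR or c in _C3_POSITIVE for c in window.text])
    h3 = np.array([c in _C1_NONPOLAR or c in _C4_NEGATIVE for c in window.text])
    out = []
    for h in (h1, h2, h3):
        for j in range(1, L_seg + 1):
            plen = int(round(j * w / L_seg))
            out.append(h[:plen].sum() / plen if plen > 0 else 0.0)
    return FeatureBlock("EBGW", out)


def cksaap_pair_index(a: str, b: str) -> int:
    return ALPHA_INDEX[a] * 21 + ALPHA_INDEX[b]


def encode_CKSAAP(window: WindowFragment, gaps=(0, 1, 2, 3, 4, 5)) -> FeatureBlock:
    """Composition of k-spaced amino-acid pairs over the 21-letter alphabet.

    For each spacing ``k`` a 441-dim block counts ordered pairs
    ``(window[i], window[i+k+1])`` normalised by ``w - k - 1`` (so each
    k-block sums to exactly 1).
    """
    w = window.w
    blocks = []
    for k in gaps:
        if k > w - 2:
            raise ValueError(f"gap k={k} too large for window size {w}")
        vec = np.zeros(441)
        for i in range(w - k - 1):
            vec[cksaap_pair_index(window.text[i], window.text[i + k + 1])] += 1
        blocks.append(vec / (w - k - 1))
    return FeatureBlock("CKSAAP", np.concatenate(blocks))


def _windows_to_codes(windows) -> np.ndarray:
    return np.array(
        [[ALPHA_INDEX[c] for c in w.text] for w in windows], dtype=np.intp
    )


class KnnScorer:
    """KNN feature: fraction of positives among the K most similar references.

    Distance between equal-length windows ``a, b`` is
    ``1 - (1/w) * sum_i sim(a_i, b_i)`` with ``sim`` the min-max rescaled
    BLOSUM62 similarity (``sim(., 'X') = 0``).  Ties are broken by reference
    insertion order (positives first, then negatives, each in given order).
    With ``exclude_self`` one exact text match in the references is skipped —
    used when encoding the training set itself to avoid label leakage.
    """

    def __init__(self, ref_pos, ref_neg, k_set=(2, 4, 8, 16, 32),
                 similarity: np.ndarray | None = None):
        if not ref_pos or not ref_neg:
            raise ValueError("reference sets must be non-empty")
        ws = {w.w for w in ref_pos} | {w.w for w in ref_neg}
        if len(ws) != 1:
            raise ValueError("all reference windows must share one size")
        self.w = ws.pop()
        self.k_set = tuple(k_set)
        self.sim = blosum62_similarity() if similarity is None else similarity
        self.refs = list(ref_pos) + list(ref_neg)
        self.labels = np.array([1] * len(ref_pos) + [0] * len(ref_neg))
        self.codes = _windows_to_codes(self.refs)
        self._first_match: dict[str, int] = {}
        for i, r in enumerate(self.refs):
            self._first_match.setdefault(r.text, i)

    def distances(self, windows) -> np.ndarray:
        q = _windows_to_codes(windows)
        if q.shape[1] != self.w:
            raise ValueError("query window size mismatch")
        acc = np.zeros((q.shape[0], len(self.refs)))
        for pos in range(self.w):
            acc += self.sim[q[:, pos]][:, self.codes[:, pos]]
        return 1.0 - acc / self.w

    def transform(self, windows, exclude_self: bool = False) -> np.ndarray:
        d = self.distances(windows)
        n_q = d.shape[0]
        out = np.zeros((n_q, len(self.k_set)))
        for qi in range(n_q):
            mask = np.ones(len(self.refs), dtype=bool)
            if exclude_self:
                hit = self._first_match.get(windows[qi].text)
                if hit is not None:
                    mask[hit] = False
            order = np.argsort(d[qi, mask], kind="stable")
            labs = self.labels[mask][order]
            n_ref = labs.size
            for kj, K in enumerate(self.k_set):
                kc = min(K, n_ref)
                out[qi, kj] = labs[:kc].sum() / kc
        return out


def knn_scores(window: WindowFragment, ref_pos, ref_neg,
               k_set=(2, 4, 8, 16, 32), exclude_self: bool = False,
               similarity: np.ndarray | None = None) -> FeatureBlock:
    scorer = KnnScorer(ref_pos, ref_neg, k_set=k_set, similarity=similarity)
    return FeatureBlock("KNN", scorer.transform([window], exclude_self)[0])


def encode_AAindex(window: WindowFragment, table: AAIndexTable | None = None) -> FeatureBlock:
    """Physicochemical property encoding (dim w * n_props).

    Each property is z-normalised over the 20 amino acids; 'X' maps to 0.
    Values are concatenated position-major.
    """
    table = table or load_default_aaindex()
    z = table.znormalized()  # (n_props, 20)
    out = np.zeros((window.w, table.n_props))
    for i, c in enumerate(window.text):
        if c in AA_INDEX:
            out[i] = z[:, AA_INDEX[c]]
    return FeatureBlock("AAindex", out.ravel())
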