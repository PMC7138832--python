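"""Parsers for third-party per-residue predictor profiles.

The pipeline does not run PSI-BLAST, PSIPRED, DISOPRED, SPINE-X, SPIDER-HSE
or HHblits itself; it consumes their per-residue output files:

* PSI-BLAST ASCII PSSM — 20 log-odds channels, squashed through a sigmoid
  ``s(x) = 1 / (1 + e^(-x))``;
* PSIPRED ``.ss2`` — 3 state probabilities (coil, helix, strand);
* generic per-residue tables — disorder probability (1 channel), SPINE-X
  RSA/phi/psi (3 channels, angles scaled by 1/180), sequence-predicted HSE
  (2 channels);
* HHsuite ``.hhm`` — 20 match emissions + 10 transition/diversity values,
  decoded as ``2^(-x/1000)`` with '*' mapping to 0.

All transforms land in [0, 1].  A profile matrix is sliced into a
window-aligned feature block around a site; rows beyond the chain contribute
zeros, and a per-block "missing" flag lets the pipeline degrade gracefully
to sequence-only input when a profile file is absent.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass

import numpy as np

from .seq_features import FeatureBlock

PROFILE_SUBTYPES = ("SS", "seqRSA", "Disorder", "seqHSE", "PSSM", "HH")

#: channel counts per profile source
PROFILE_CHANNELS = {
    "PSSM": 20,
    "SS": 3,
    "Disorder": 1,
    "seqRSA": 3,
    "seqHSE": 2,
    "HH": 30,
}

# PSI-BLAST PSSM column order (also used by the mock writer)
PSSM_ALPHABET = "ARNDCQEGHILKMFPSTWYV"


@dataclass
class ProfileMatrix:
    """Per-residue profile: ``n_res`` rows by ``n_ch`` channels."""

    source: str
    rows: np.ndarray
    residue_letters: str

    def __post_init__(self):
        self.rows = np.atleast_2d(np.asarray(self.rows, dtype=float))
        if self.rows.size == 0:
            self.rows = self.rows.reshape(0, PROFILE_CHANNELS[self.source])
        if self.rows.shape[0] != len(self.residue_letters):
            raise ValueError("row count must match residue letters")

    @property
    def n_res(self) -> int:
        return self.rows.shape[0]

    @property
    def n_ch(self) -> int:
        return self.rows.shape[1]


def _lines(source):
    if hasattr(source, "read"):
        return source.read().splitlines()
    text = str(source)
    if "\n" not in text:
        with open(text, "r", encoding="utf-8") as fh:
            return fh.read().splitlines()
    return text.splitlines()


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def parse_pssm(source) -> ProfileMatrix:
    """Parse a PSI-BLAST ASCII PSSM; channels are sigmoid-squashed log-odds."""
    letters = []
    rows = []
    for lineno, line in enumerate(_lines(source), start=1):
        parts = line.split()
        if len(parts) < 2 or not parts[0].isdigit() or len(parts[1]) != 1:
            continue
        if not parts[1].isalpha():
            continue
        if len(parts) < 22:
            raise ValueError(f"PSSM line {lineno}: expected 20 log-odds columns")
        try:
            scores = [float(v) for v in parts[2:22]]
        except ValueError as exc:
            raise ValueError(f"PSSM line {lineno}: {exc}") from None
        letters.append(parts[1])
        rows.append(scores)
    return ProfileMatrix("PSSM", _sigmoid(np.array(rows)), "".join(letters))


def parse_ss2(source) -> ProfileMatrix:
    """Parse PSIPRED ``.ss2``: rows ``idx letter state pC pH pE``."""
    letters = []
    rows = []
    for lineno, line in enumerate(_lines(source), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split()
        if len(parts) != 6:
            raise ValueError(f"ss2 line {lineno}: expected 6 fields")
        probs = [float(v) for v in parts[3:6]]
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError(f"ss2 line {lineno}: probability outside [0, 1]")
        letters.append(parts[1])
        rows.append(probs)
    return ProfileMatrix("SS", np.array(rows), "".join(letters))


def parse_per_residue_table(source, profile_source: str,
                            n_ch: int | None = None) -> ProfileMatrix:
    """Generic whitespace table: idx, letter, then ``n_ch`` reals.

    '#' comment lines are ignored.  For ``seqRSA`` (SPINE-X) the second and
    third channels are backbone torsion angles in degrees and are scaled by
    1/180.
    """
    if profile_source not in ("Disorder", "seqRSA", "seqHSE"):
        raise ValueError(f"unsupported per-residue source {profile_source!r}")
    n_ch = PROFILE_CHANNELS[profile_source] if n_ch is None else n_ch
    letters = []
    rows = []
    for lineno, line in enumerate(_lines(source), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split()
        if len(parts) != 2 + n_ch:
            raise ValueError(
                f"{profile_source} line {lineno}: expected {2 + n_ch} fields, "
                f"got {len(parts)}"
            )
        letters.append(parts[1])
        rows.append([float(v) for v in parts[2:]])
    mat = np.array(rows, dtype=float)
    if profile_source == "seqRSA" and mat.size:
        mat[:, 1:3] = mat[:, 1:3] / 180.0
    out = ProfileMatrix(profile_source, mat, "".join(letters))
    if out.rows.shape[1] != n_ch and out.n_res:
        raise ValueError("channel count mismatch")
    return out


_HHM_GROUP_RE = re.compile(r"^[A-Z]\s+\d+\s")


def _decode_hhm(token: str) -> float:
    if token == "*":
        return 0.0
    return float(2.0 ** (-int(token) / 1000.0))


def parse_hhm(source) -> ProfileMatrix:
    """Parse an HHsuite ``.hhm`` model into 30 channels per residue.

    Channels: 20 match-emission scores followed by 10 transition/diversity
    scores, each decoded as ``2^(-x/1000)`` ('*' -> 0).
    """
    lines = _lines(source)
    try:
        start = next(
            i for i, ln in enumerate(lines) if ln.startswith("HMM")
        )
    except StopIteration:
        raise ValueError("no HMM block found") from None
    letters = []
    rows = []
    i = start + 1
    # skip transition-name header and any null-model line
    while i < len(lines) and not _HHM_GROUP_RE.match(lines[i]):
        if lines[i].startswith("//"):
            break
        i += 1
    while i < len(lines):
        line = lines[i]
        if line.startswith("//"):
            break
        if not _HHM_GROUP_RE.match(line):
            i += 1
            continue
        parts = line.split()
        if len(parts) < 22:
            raise ValueError(f"hhm line {i + 1}: truncated emission row")
        letter = parts[0]
        emissions = [_decode_hhm(t) for t in parts[2:22]]
        if i + 1 >= len(lines):
            raise ValueError("hhm: truncated model block (missing transitions)")
        trans_parts = lines[i + 1].split()
        if len(trans_parts) < 10:
            raise ValueError(f"hhm line {i + 2}: truncated transition row")
        transitions = [_decode_hhm(t) for t in trans_parts[:10]]
        letters.append(letter)
        rows.append(emissions + transitions)
        i += 2
    else:
        raise ValueError("hhm: truncated model block (missing //)")
    return ProfileMatrix("HH", np.array(rows), "".join(letters))


def slice_profile_window(matrix: ProfileMatrix, position: int, w: int) -> FeatureBlock:
    """Window-aligned slice: rows ``position +/- (w-1)/2`` concatenated
    row-major; out-of-range rows contribute zeros."""
    if w % 2 == 0 or w < 1:
        raise ValueError("window size must be odd and positive")
    if not 1 <= position <= matrix.n_res:
        raise ValueError("position out of range")
    half = (w - 1) // 2
    out = np.zeros((w, matrix.n_ch))
    for slot, pos in enumerate(range(position - half, position + half + 1)):
        if 1 <= pos <= matrix.n_res:
            out[slot] = matrix.rows[pos - 1]
    return FeatureBlock(matrix.source, out.ravel())


def profile_block(matrix: ProfileMatrix | None, position: int, w: int,
                  source: str) -> FeatureBlock:
    """Profile block with a trailing missing flag (dim ``w * n_ch + 1``).

    A missing profile yields an all-zero block with flag 1; a present one
    the sliced values with flag 0.  Dimensions stay constant either way.
    """
    n_ch = PROFILE_CHANNELS[source]
    if matrix is None or matrix.n_res == 0:
        return FeatureBlock(source, np.concatenate([np.zeros(w * n_ch), [1.0]]))
    sliced = slice_profile_window(matrix, position, w)
    return FeatureBlock(source, np.concatenate([sliced.values, [0.0]]))
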