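"""Data model and dataset plumbing for methylation-site prediction.

Protein sequences arrive as FASTA, experimentally verified methylation sites
as a TSV table (protein id, 1-based position, residue K/R, comma-joined type
labels among mono/di/tri).  Candidate negatives are lysines/arginines on the
same proteins that carry no methylation annotation, sampled 1:1 against the
positives by default.  A separate, structure-level filter reproduces the
rules used to assemble an experimental-structure analysis set: X-ray
resolution better than 3 A, chain length >= 50, at least one annotated site,
and the methyl-accepting side-chain nitrogen(s) (NZ for Lys, NH1 and NH2 for
Arg) present for every annotated site.

Coordinates are 1-based inclusive throughout.  'X' doubles as the
unknown-residue letter and the window padding character.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
PAD = "X"
ALPHABET = STANDARD_AA + PAD
METHYL_TYPES = ("mono", "di", "tri")

__all__ = [
    "STANDARD_AA",
    "PAD",
    "ALPHABET",
    "METHYL_TYPES",
    "SiteAnnotation",
    "ProteinRecord",
    "SiteInstance",
    "WindowFragment",
    "AtomRecord",
    "StructureEntry",
    "read_fasta",
    "write_fasta",
    "read_site_table",
    "write_site_table",
    "extract_window",
    "positive_instances",
    "sample_negatives",
    "build_instances",
    "filter_structure_entries",
    "cluster_representatives",
    "split_proteins",
]


@dataclass(frozen=True)
class SiteAnnotation:
    """One annotated methylation site: 1-based position, residue, type set."""

    position: int
    residue: str
    types: frozenset = frozenset()

    def __post_init__(self):
        if self.residue not in ("K", "R"):
            raise ValueError(f"site residue must be K or R, got {self.residue!r}")
        object.__setattr__(self, "types", frozenset(self.types))
        bad = self.types - set(METHYL_TYPES)
        if bad:
            raise ValueError(f"unknown methylation types: {sorted(bad)}")
        if self.residue == "R" and "tri" in self.types:
            raise ValueError("tri-methylation is not defined for arginine")
        if self.position < 1:
            raise ValueError("positions are 1-based")


@dataclass
class ProteinRecord:
    """A protein sequence with its methylation-site annotations."""

    id: str
    sequence: str
    sites: list = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        bad = set(self.sequence) - set(ALPHABET)
        if bad:
            raise ValueError(f"{self.id}: letters outside alphabet: {sorted(bad)}")
        for s in self.sites:
            if not 1 <= s.position <= len(self.sequence):
                raise ValueError(f"{self.id}: site position {s.position} out of range")
            if self.sequence[s.position - 1] != s.residue:
                raise ValueError(
                    f"{self.id}: residue mismatch at {s.position}: "
                    f"sequence has {self.sequence[s.position - 1]}, site says {s.residue}"
                )

    def annotated_positions(self) -> set:
        return {s.position for s in self.sites}


@dataclass(frozen=True)
class SiteInstance:
    """A labelled candidate site (positive = methylated)."""

    protein_id: str
    position: int
    residue: str
    label: str
    types: frozenset = frozenset()

    def __post_init__(self):
        if self.label not in ("positive", "negative"):
            raise ValueError(f"label must be positive/negative, got {self.label!r}")
        object.__setattr__(self, "types", frozenset(self.types))
        if self.label == "negative" and self.types:
            raise ValueError("negative instances carry no methylation types")

    @property
    def is_positive(self) -> bool:
        return self.label == "positive"


@dataclass(frozen=True)
class WindowFragment:
    """Odd-length residue window centred on a candidate site, 'X'-padded."""

    text: str
    center_offset: int
    pad_left: int = 0
    pad_right: int = 0

    def __post_init__(self):
        w = len(self.text)
        if w % 2 == 0:
            raise ValueError("window length must be odd")
        if self.center_offset != (w - 1) // 2:
            raise ValueError("center_offset must be (w-1)/2")
        if self.pad_left < 0 or self.pad_right < 0:
            raise ValueError("pad counts are non-negative")

    @property
    def w(self) -> int:
        return len(self.text)


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom of a structure model."""

    serial: int
    name: str
    element: str
    chain: str
    res_seq: int
    res_name: str
    coord: tuple
    vdw_radius: float

    def __post_init__(self):
        if self.vdw_radius <= 0:
            raise ValueError("van der Waals radius must be positive")
        if not np.all(np.isfinite(self.coord)):
            raise ValueError("atom coordinates must be finite")


@dataclass
class StructureEntry:
    """An experimental structure with mapped methylation annotations.

    ``mapped_sites`` positions are 1-based into the representative chain's
    sequence; ``res_seq`` numbering of ``atoms`` is assumed to follow the
    same 1-based indexing for these curated entries.
    """

    pdb_id: str
    resolution: float | None
    chain_sequences: dict
    atoms: list
    mapped_sites: list

    def __post_init__(self):
        if self.resolution is not None and self.resolution <= 0:
            raise ValueError("resolution must be positive when present")

    def representative_chain(self) -> str:
        return max(self.chain_sequences, key=lambda c: (len(self.chain_sequences[c]), c))


# ---------------------------------------------------------------------------
# File I/O


def _as_text_handle(source):
    if hasattr(source, "read"):
        return source
    text = str(source)
    if "\n" in text or text.startswith(">") or text == "":
        return io.StringIO(text)
    return open(text, "r", encoding="utf-8")


def read_fasta(source) -> list:
    """Read FASTA into :class:`ProteinRecord` objects (no sites attached).

    Sequences are uppercased; letters outside the 21-letter alphabet are
    replaced by 'X' with a warning.  Duplicate ids raise ``ValueError``.
    """
    handle = _as_text_handle(source)
    records: list[ProteinRecord] = []
    seen = set()
    for rec in SeqIO.parse(handle, "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id: {rec.id}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        cleaned = "".join(c if c in ALPHABET else PAD for c in seq)
        n_repl = sum(a != b for a, b in zip(seq, cleaned))
        if n_repl:
            logger.warning(
                "%s: replaced %d non-standard letter(s) with 'X'", rec.id, n_repl
            )
        records.append(ProteinRecord(id=rec.id, sequence=cleaned))
    return records


def write_fasta(records, dest, width: int = 60) -> None:
    close = False
    if not hasattr(dest, "write"):
        dest = open(dest, "w", encoding="utf-8")
        close = True
    try:
        for rec in records:
            dest.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                dest.write(rec.sequence[i : i + width] + "\n")
    finally:
        if close:
            dest.close()


def read_site_table(source, proteins) -> list:
    """Attach site annotations from a TSV table to protein records.

    Columns: protein_id, position (1-based), residue (K/R), types
    (comma-joined subset of mono/di/tri; may be empty).  Rows referencing
    unknown ids, out-of-range positions, or mismatching residues are
    rejected with a per-row diagnostic; valid annotations are merged
    (types union) per position.  Returns new records; inputs untouched.
    """
    handle = _as_text_handle(source)
    by_id = {p.id: p for p in proteins}
    # per protein: position -> (residue, set of types)
    pending: dict[str, dict[int, tuple]] = {pid: {} for pid in by_id}
    n_rejected = 0
    for lineno, raw in enumerate(handle, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            logger.warning("site table line %d: expected >=3 columns", lineno)
            n_rejected += 1
            continue
        pid, pos_s, residue = parts[0], parts[1], parts[2].strip()
        types_s = parts[3].strip() if len(parts) > 3 else ""
        try:
            position = int(pos_s)
        except ValueError:
            if lineno == 1:
                continue  # header line
            logger.warning("site table line %d: bad position %r", lineno, pos_s)
            n_rejected += 1
            continue
        prot = by_id.get(pid)
        if prot is None:
            logger.warning("site table line %d: unknown protein %r", lineno, pid)
            n_rejected += 1
            continue
        if not 1 <= position <= len(prot.sequence):
            logger.warning(
                "site table line %d: position %d out of range for %s",
                lineno, position, pid,
            )
            n_rejected += 1
            continue
        if prot.sequence[position - 1] != residue:
            logger.warning(
                "site table line %d: residue mismatch at %s:%d (sequence %s, row %s)",
                lineno, pid, position, prot.sequence[position - 1], residue,
            )
            n_rejected += 1
            continue
        types = frozenset(t for t in types_s.split(",") if t)
        try:
            SiteAnnotation(position, residue, types)
        except ValueError as exc:
            logger.warning("site table line %d: %s", lineno, exc)
            n_rejected += 1
            continue
        old = pending[pid].get(position)
        merged = types | (old[1] if old else frozenset())
        pending[pid][position] = (residue, merged)
    if n_rejected:
        logger.warning("site table: rejected %d row(s)", n_rejected)
    out = []
    for p in proteins:
        sites = [
            SiteAnnotation(pos, res, ty)
            for pos, (res, ty) in sorted(pending[p.id].items())
        ]
        out.append(ProteinRecord(id=p.id, sequence=p.sequence, sites=sites))
    return out


def write_site_table(records, dest) -> None:
    close = False
    if not hasattr(dest, "write"):
        dest = open(dest, "w", encoding="utf-8")
        close = True
    try:
        dest.write("protein_id\tposition\tresidue\ttypes\n")
        for rec in records:
            for s in sorted(rec.sites, key=lambda s: s.position):
                dest.write(
                    f"{rec.id}\t{s.position}\t{s.residue}\t"
                    f"{','.join(sorted(s.types))}\n"
                )
    finally:
        if close:
            dest.close()


# ---------------------------------------------------------------------------
# Windows and instances


def extract_window(sequence: str, position: int, w: int) -> WindowFragment:
    """Extract the odd-length window of size ``w`` centred at ``position``.

    Positions beyond either terminus are filled with 'X'.
    """
    if w % 2 == 0 or w < 1:
        raise ValueError(f"window size must be odd and positive, got {w}")
    if not 1 <= position <= len(sequence):
        raise ValueError(f"position {position} out of range 1..{len(sequence)}")
    half = (w - 1) // 2
    lo = position - 1 - half  # 0-based inclusive
    hi = position - 1 + half  # 0-based inclusive
    pad_left = max(0, -lo)
    pad_right = max(0, hi - (len(sequence) - 1))
    core = sequence[max(lo, 0) : min(hi, len(sequence) - 1) + 1]
    return WindowFragment(
        text=PAD * pad_left + core + PAD * pad_right,
        center_offset=half,
        pad_left=pad_left,
        pad_right=pad_right,
    )


def positive_instances(proteins, target_residue: str) -> list:
    """All annotated sites of ``target_residue`` as positive instances."""
    out = []
    for p in proteins:
        for s in sorted(p.sites, key=lambda s: s.position):
            if s.residue == target_residue:
                out.append(
                    SiteInstance(p.id, s.position, s.residue, "positive", s.types)
                )
    return out


def sample_negatives(proteins, target_residue: str, ratio: float = 1.0,
                     seed: int = 0) -> list:
    """Sample unannotated target residues as negatives, ``ratio`` : 1 vs positives.

    Candidates are residues of ``target_residue`` type carrying no methylation
    annotation on the same proteins; drawn uniformly without replacement,
    deterministically for a given ``seed``.  The count is
    ``round(ratio * n_positives)`` capped at the number of candidates.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    n_pos = sum(
        1 for p in proteins for s in p.sites if s.residue == target_residue
    )
    candidates = []
    for ip, p in enumerate(proteins):
        annotated = p.annotated_positions()
        for i, c in enumerate(p.sequence):
            pos = i + 1
            if c == target_residue and pos not in annotated:
                candidates.append((ip, pos))
    if not candidates:
        logger.warning("no candidate negatives for residue %s", target_residue)
        return []
    n_draw = min(int(round(ratio * n_pos)), len(candidates))
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(candidates), size=n_draw, replace=False)
    picked = sorted(candidates[i] for i in chosen)
    return [
        SiteInstance(proteins[ip].id, pos, target_residue, "negative")
        for ip, pos in picked
    ]


def build_instances(proteins, target_residue: str, ratio: float = 1.0,
                    seed: int = 0) -> list:
    """Positives plus sampled negatives, in deterministic order."""
    return positive_instances(proteins, target_residue) + sample_negatives(
        proteins, target_residue, ratio=ratio, seed=seed
    )


# ---------------------------------------------------------------------------
# Structure-dataset filtering


def _key_atoms_present(entry: StructureEntry, site: SiteAnnotation) -> bool:
    names = {
        a.name for a in entry.atoms if a.res_seq == site.position
    }
    if site.residue == "K":
        return "NZ" in names
    return "NH1" in names and "NH2" in names


def filter_structure_entries(entries, residue: str, min_len: int = 50,
                             max_resolution: float = 3.0) -> list:
    """Apply the experimental-structure curation rules.

    Keeps entries with X-ray resolution strictly better than
    ``max_resolution``, representative chain length >= ``min_len``, at least
    one annotated site surviving mutation screening (structure residue still
    K/R), and the required side-chain atom(s) present for every surviving
    site (NZ for Lys; both NH1 and NH2 for Arg).
    """
    kept = []
    for e in entries:
        if e.resolution is None or e.resolution >= max_resolution:
            continue
        chain = e.representative_chain()
        seq = e.chain_sequences[chain]
        if len(seq) < min_len:
            continue
        sites = [
            s
            for s in e.mapped_sites
            if s.residue == residue
            and 1 <= s.position <= len(seq)
            and seq[s.position - 1] == s.residue
        ]
        if not sites:
            continue
        if not all(_key_atoms_present(e, s) for s in sites):
            continue
        kept.append(replace_sites(e, sites))
    return kept


def replace_sites(entry: StructureEntry, sites) -> StructureEntry:
    return StructureEntry(
        pdb_id=entry.pdb_id,
        resolution=entry.resolution,
        chain_sequences=dict(entry.chain_sequences),
        atoms=list(entry.atoms),
        mapped_sites=list(sites),
    )


# ---------------------------------------------------------------------------
# Redundancy and splitting utilities


def cluster_representatives(proteins, cluster_map: dict) -> list:
    """Keep one representative (longest sequence, then lexicographic id) per cluster.

    ``cluster_map`` maps protein_id -> cluster_id (e.g. from an external
    30%-identity clustering run).  Proteins absent from the map are kept.
    """
    best: dict[str, ProteinRecord] = {}
    unkeyed = []
    for p in proteins:
        cid = cluster_map.get(p.id)
        if cid is None:
            unkeyed.append(p)
            continue
        cur = best.get(cid)
        if cur is None or len(p.sequence) > len(cur.sequence) or (
            len(p.sequence) == len(cur.sequence) and p.id < cur.id
        ):
            best[cid] = p
    order = {p.id: i for i, p in enumerate(proteins)}
    kept = unkeyed + list(best.values())
    return sorted(kept, key=lambda p: order[p.id])


def read_cluster_file(source) -> dict:
    """Two-column TSV: protein_id, cluster_id."""
    handle = _as_text_handle(source)
    out = {}
    for raw in handle:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        pid, cid = line.split("\t")[:2]
        out[pid] = cid
    return out


def split_proteins(proteins, test_fraction: float = 0.2, seed: int = 0):
    """Seeded protein-level train/test split (homology control: whole
    proteins, never individual sites, go to one side)."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n = len(proteins)
    n_test = max(1, int(round(test_fraction * n))) if n else 0
    idx = rng.permutation(n)
    test_idx = set(idx[:n_test].tolist())
    train = [p for i, p in enumerate(proteins) if i not in test_idx]
    test = [p for i, p in enumerate(proteins) if i in test_idx]
    return train, test
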