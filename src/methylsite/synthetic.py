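"""Seeded generators for fully self-contained test data.

Three generators make every other module testable without downloads:

* :func:`gen_sequence_dataset` — proteins with planted methylation sites.
  Background residues are i.i.d. uniform over the 20 amino acids (uniform
  rather than natural frequencies, so planted effects are unambiguous; a
  natural-frequency mode is available).  Flanks of positive sites are
  re-drawn from motif-tilted frequencies, emulating the compositional bias
  observed around real methylation sites (e.g. lysine enrichment downstream
  of methyllysine).
* :func:`gen_toy_structure` — a compact superhelical backbone in PDB format
  with controllable side-chain burial: exposed targets stick their
  methyl-accepting nitrogen radially outward (first convex hull by
  construction), buried targets point it at the centroid.  Geometric
  verifiability is favoured over physical realism.
* :func:`gen_mock_profiles` — per-residue predictor files in all six
  supported dialects, formatted so the profile parsers round-trip them.

All generators are byte-deterministic in their seed.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np

from .datasets import (
    METHYL_TYPES,
    ProteinRecord,
    SiteAnnotation,
    SiteInstance,
    STANDARD_AA,
)
from .profile_features import PSSM_ALPHABET

#: natural amino-acid background frequencies (UniProt-like), alphabetical order
NATURAL_FREQS = {
    "A": 0.083, "C": 0.014, "D": 0.055, "E": 0.067, "F": 0.039, "G": 0.071,
    "H": 0.023, "I": 0.059, "K": 0.058, "L": 0.097, "M": 0.024, "N": 0.041,
    "P": 0.047, "Q": 0.039, "R": 0.055, "S": 0.066, "T": 0.053, "V": 0.069,
    "W": 0.011, "Y": 0.029,
}


def default_motif(residue: str, factor: float = 10.0) -> dict:
    """Default planted motif: a strong, asymmetric enrichment pattern.

    For lysine: K enriched at +1..+5 and G at -5..-1; for arginine: G
    enriched at -3..+3 and R at +/-4, +/-5 — mirroring the field's
    observation that methyllysine flanks are K-rich downstream while
    methylarginine sits in G/R-rich context.
    """
    motif = {}
    if residue == "K":
        for o in range(1, 6):
            motif[(o, "K")] = factor
        for o in range(-5, 0):
            motif[(o, "G")] = factor
    else:
        for o in list(range(-3, 0)) + list(range(1, 4)):
            motif[(o, "G")] = factor
        for o in (-5, -4, 4, 5):
            motif[(o, "R")] = factor
    return motif


@dataclass
class SynthConfig:
    """Study conditions for the synthetic sequence dataset.

    Defaults are the conditions under which the pipeline's recovery
    properties are demonstrated: 400 proteins of 60-100 residues, three
    candidate sites per protein, half of them methylated, a strong planted
    flank motif, and a 0.9-strength association between methylation and
    surface exposure in the companion toy structures.
    """

    n_proteins: int = 400
    length_range: tuple = (60, 100)
    residue: str = "K"
    sites_per_protein: int = 3
    positive_rate: float = 0.5
    motif_effect: dict | None = None
    type_mixture: dict | None = None
    structure_signal: float = 0.9
    background: str = "uniform"  # or "natural"
    seed: int = 0

    def __post_init__(self):
        if self.residue not in ("K", "R"):
            raise ValueError("residue must be K or R")
        if not 0 < self.positive_rate < 1:
            raise ValueError("positive_rate must be in (0, 1)")
        if self.structure_signal < 0:
            raise ValueError("structure_signal must be >= 0")
        if self.motif_effect is None:
            self.motif_effect = default_motif(self.residue)
        if self.type_mixture is None:
            self.type_mixture = (
                {"mono": 0.5, "di": 0.3, "tri": 0.2}
                if self.residue == "K"
                else {"mono": 0.6, "di": 0.4}
            )
        tot = sum(self.type_mixture.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError("type_mixture must sum to 1")
        if self.residue == "R" and self.type_mixture.get("tri", 0) > 0:
            raise ValueError("tri-methylation is not defined for arginine")


def _background_probs(config: SynthConfig) -> np.ndarray:
    if config.background == "natural":
        p = np.array([NATURAL_FREQS[a] for a in STANDARD_AA])
        return p / p.sum()
    return np.full(20, 1.0 / 20.0)


def gen_sequence_dataset(config: SynthConfig | None = None):
    """Generate (proteins with sites, ground-truth candidate instances).

    The truth table lists every planted candidate site with its label —
    positives carry sampled methylation types, planted negatives are
    guaranteed unannotated target residues.
    """
    config = config or SynthConfig()
    min_len, max_len = config.length_range
    margin = 6
    if max_len < 2 * margin + config.sites_per_protein * 11:
        raise ValueError("length_range too small to host the planted sites")
    rng = np.random.default_rng(config.seed)
    bg = _background_probs(config)
    aa = np.array(list(STANDARD_AA))
    type_names = [t for t in METHYL_TYPES if config.type_mixture.get(t, 0) > 0]
    type_p = np.array([config.type_mixture[t] for t in type_names])

    # per-offset tilted distributions
    offsets = sorted({o for o, _ in config.motif_effect})
    tilted = {}
    for o in offsets:
        w = bg.copy()
        for (oo, a), factor in config.motif_effect.items():
            if oo == o:
                w[STANDARD_AA.index(a)] *= factor
        tilted[o] = w / w.sum()

    proteins = []
    truth = []
    for pi in range(config.n_proteins):
        pid = f"syn{pi:04d}"
        L = int(rng.integers(min_len, max_len + 1))
        seq = aa[rng.choice(20, size=L, p=bg)]
        # spaced candidate positions
        positions = []
        tries = 0
        while len(positions) < config.sites_per_protein and tries < 500:
            pos = int(rng.integers(margin + 1, L - margin + 1))
            if all(abs(pos - q) >= 11 for q in positions):
                positions.append(pos)
            tries += 1
        positions.sort()
        sites = []
        for pos in positions:
            seq[pos - 1] = config.residue
            is_pos = bool(rng.random() < config.positive_rate)
            if is_pos:
                for o in offsets:
                    j = pos + o
                    if 1 <= j <= L and (j not in positions):
                        seq[j - 1] = aa[rng.choice(20, p=tilted[o])]
                types = frozenset([str(rng.choice(type_names, p=type_p))])
                sites.append(SiteAnnotation(pos, config.residue, types))
                truth.append(
                    SiteInstance(pid, pos, config.residue, "positive", types)
                )
            else:
                truth.append(SiteInstance(pid, pos, config.residue, "negative"))
        # planted negatives must stay unannotated: nothing to do, they are
        # ordinary target residues without a SiteAnnotation
        proteins.append(ProteinRecord(id=pid, sequence="".join(seq), sites=sites))
    return proteins, truth


def gen_selection_benchmark(n_samples: int = 300, n_informative: int = 10,
                            n_noise: int = 200, shift: float = 4.0,
                            seed: int = 7):
    """Planted-feature benchmark for stepwise selection.

    Each informative feature separates the classes on its own disjoint block
    of samples (complementary signal), so a correct forward selection keeps
    adding informative features; noise features are i.i.d. standard normal.
    Columns are shuffled.  Returns ``(X, y, informative_column_indices)``.
    """
    rng = np.random.default_rng(seed)
    y = rng.permutation(np.array([0, 1] * (n_samples // 2)))
    X = rng.normal(size=(len(y), n_informative + n_noise))
    block = rng.integers(0, n_informative, size=len(y))
    for j in range(n_informative):
        m = block == j
        X[m, j] += shift * y[m]
    perm = rng.permutation(n_informative + n_noise)
    informative = {int(np.where(perm == j)[0][0]) for j in range(n_informative)}
    return X[:, perm], y, informative


# ---------------------------------------------------------------------------
# Toy structures


_RES3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR", "X": "ALA",
}


def _pdb_atom_line(serial, name, res_name, chain, res_seq, xyz, element):
    name_f = name if len(name) == 4 else f" {name:<3s}"
    return (
        f"ATOM  {serial:5d} {name_f}{'':1s}{res_name:>3s} {chain}{res_seq:4d}"
        f"{'':1s}   {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


def gen_toy_structure(n_res: int, target_positions=(), burial=(),
                      seed: int = 0, residue: str = "K",
                      sequence: str | None = None) -> str:
    """PDB text for a compact superhelical toy protein.

    The C-alpha trace winds a multi-turn helix whose height matches its
    diameter, giving a roughly globular cloud.  Per target (1-based
    positions, parallel ``burial`` entries 'exposed'/'buried') the
    methyl-accepting side-chain atoms are placed radially outward beyond
    every other atom (exposed: first convex hull by construction) or pulled
    toward the centroid (buried: interior of the hull).  Non-target K/R
    residues get neutral outward side chains.
    """
    if sequence is not None:
        n_res = len(sequence)
    if n_res < 8:
        raise ValueError("need at least 8 residues")
    targets = list(target_positions)
    burial = list(burial)
    if len(burial) != len(targets):
        raise ValueError("burial must parallel target_positions")
    for pos in targets:
        if not 1 <= pos <= n_res:
            raise ValueError(f"target position {pos} out of range 1..{n_res}")
    if sequence is None:
        seq = ["A"] * n_res
        for pos in targets:
            seq[pos - 1] = residue
        sequence = "".join(seq)
    bur = dict(zip(targets, burial))
    rng = np.random.default_rng(seed)

    # tight multi-turn coil: small fixed radius, adjacent turns ~3.6 A apart,
    # so the wall is dense and the inner core is narrow (buried side chains
    # are genuinely crowded)
    turns = max(2.0, n_res / 12.0)
    alpha = 2.0 * math.pi * turns / n_res
    rise = 0.30
    r_major = math.sqrt(max(1.0, 3.8**2 - rise**2)) / alpha
    height = rise * n_res
    ca = np.zeros((n_res, 3))
    for i in range(n_res):
        t = alpha * i
        ca[i] = (
            r_major * math.cos(t),
            r_major * math.sin(t),
            rise * i,
        )
    ca += rng.normal(0.0, 0.08, size=ca.shape)  # break exact degeneracies
    centroid = np.array([0.0, 0.0, height / 2.0])

    def radial_out(i):
        v = ca[i].copy()
        v[2] = 0.0
        n = np.linalg.norm(v)
        return v / n if n > 0 else np.array([1.0, 0.0, 0.0])

    lines = []
    serial = 1
    for i in range(n_res):
        pos = i + 1
        letter = sequence[i].upper()
        rn = _RES3.get(letter, "ALA")
        out = radial_out(i)
        atoms = {"CA": ca[i]}
        if i > 0:
            u = ca[i - 1] - ca[i]
            atoms["N"] = ca[i] + 1.45 * u / np.linalg.norm(u)
        else:
            u = ca[i] - ca[i + 1]
            atoms["N"] = ca[i] + 1.45 * u / np.linalg.norm(u)
        if i + 1 < n_res:
            u = ca[i + 1] - ca[i]
            atoms["C"] = ca[i] + 1.52 * u / np.linalg.norm(u)
        else:
            u = ca[i] - ca[i - 1]
            atoms["C"] = ca[i] + 1.52 * u / np.linalg.norm(u)
        atoms["O"] = atoms["C"] + 1.23 * out
        if rn != "GLY":
            side_dir = out
            if pos in bur and bur[pos] == "buried":
                side_dir = centroid - ca[i]
                side_dir = side_dir / np.linalg.norm(side_dir)
            atoms["CB"] = ca[i] + 1.53 * side_dir
        if rn in ("LYS", "ARG"):
            if pos in bur:
                if bur[pos] == "exposed":
                    tip = ca[i] + 4.5 * out
                else:
                    # tuck the tip against the nearest non-adjacent backbone
                    # CA: strongly occluded (low SASA, interior hull layer)
                    d = np.linalg.norm(ca - ca[i], axis=1)
                    d[max(0, i - 2) : i + 3] = np.inf
                    j = int(np.argmin(d))
                    tip = ca[i] + 0.75 * (ca[j] - ca[i])
            else:
                tip = ca[i] + 2.5 * out
            if rn == "LYS":
                atoms["NZ"] = tip
            else:
                perp = np.cross(out, [0.0, 0.0, 1.0])
                nperp = np.linalg.norm(perp)
                perp = perp / nperp if nperp > 0 else np.array([0.0, 1.0, 0.0])
                atoms["NH1"] = tip + 0.9 * perp
                atoms["NH2"] = tip - 0.9 * perp
        for name in ("N", "CA", "C", "O", "CB", "NZ", "NH1", "NH2"):
            if name not in atoms:
                continue
            lines.append(
                _pdb_atom_line(serial, name, rn, "A", pos, atoms[name], name[0])
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def gen_structures_for_proteins(proteins, structure_signal: float = 0.9,
                                seed: int = 0, residue: str = "K") -> dict:
    """Toy structures whose side-chain burial encodes the methylation label.

    Every target residue becomes exposed (if methylated) or buried (if not)
    with probability ``0.5 + structure_signal / 2``, and the opposite
    otherwise — ``structure_signal = 0`` decouples geometry from labels,
    ``1`` makes exposure a perfect reporter.  Returns protein_id -> PDB text
    with ``res_seq`` equal to the 1-based sequence position.
    """
    p_match = 0.5 + min(structure_signal, 1.0) / 2.0
    rng = np.random.default_rng(seed)
    out = {}
    for prot in proteins:
        annotated = prot.annotated_positions()
        targets, burial = [], []
        for i, c in enumerate(prot.sequence):
            if c != residue:
                continue
            pos = i + 1
            match = rng.random() < p_match
            if pos in annotated:
                burial.append("exposed" if match else "buried")
            else:
                burial.append("buried" if match else "exposed")
            targets.append(pos)
        out[prot.id] = gen_toy_structure(
            len(prot.sequence),
            targets,
            burial,
            seed=int(rng.integers(0, 2**31 - 1)),
            residue=residue,
            sequence=prot.sequence,
        )
    return out


# ---------------------------------------------------------------------------
# Mock third-party profiles


def mock_profile_texts(protein: ProteinRecord, seed: int = 0) -> dict:
    """Per-residue predictor output in all six dialects, as text."""
    rng = np.random.default_rng(seed)
    seq = protein.sequence
    n = len(seq)

    # PSSM: PSI-BLAST ASCII dialect
    header = (
        "\nLast position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts\n"
        "            " + "   ".join(PSSM_ALPHABET) + "   "
        + "   ".join(PSSM_ALPHABET) + "\n"
    )
    pssm_rows = []
    for i in range(n):
        logodds = rng.integers(-6, 10, size=20)
        pcts = rng.integers(0, 101, size=20)
        pssm_rows.append(
            f"{i + 1:5d} {seq[i]}  "
            + " ".join(f"{v:3d}" for v in logodds)
            + "  "
            + " ".join(f"{v:3d}" for v in pcts)
            + f"  {rng.random() * 2:4.2f} {rng.random() * 2:4.2f}"
        )
    pssm = header + "\n".join(pssm_rows) + "\n\n                      K         Lambda\n"

    # PSIPRED .ss2
    states = "CHE"
    ss2_lines = ["# PSF format file (mock PSIPRED VFORMAT)", ""]
    for i in range(n):
        probs = rng.dirichlet([2.0, 2.0, 2.0])
        st = states[int(np.argmax(probs))]
        ss2_lines.append(
            f"{i + 1:4d} {seq[i]} {st}  {probs[0]:6.3f} {probs[1]:6.3f} {probs[2]:6.3f}"
        )
    ss2 = "\n".join(ss2_lines) + "\n"

    # Disorder (1 channel)
    diso_lines = ["# mock disorder predictor output"]
    for i in range(n):
        diso_lines.append(f"{i + 1} {seq[i]} {rng.random():.4f}")
    diso = "\n".join(diso_lines) + "\n"

    # SPINE-X style: RSA, phi, psi (degrees)
    spx_lines = ["# idx AA RSA phi psi"]
    for i in range(n):
        spx_lines.append(
            f"{i + 1} {seq[i]} {rng.random():.4f} "
            f"{rng.uniform(-180, 180):.1f} {rng.uniform(-180, 180):.1f}"
        )
    spx = "\n".join(spx_lines) + "\n"

    # sequence-predicted HSE: up, down
    hse_lines = ["# idx AA HSEu HSEd"]
    for i in range(n):
        hse_lines.append(
            f"{i + 1} {seq[i]} {rng.uniform(0, 40):.2f} {rng.uniform(0, 40):.2f}"
        )
    hse = "\n".join(hse_lines) + "\n"

    # HHsuite .hhm
    hhm_lines = [
        "HHsearch 1.5",
        f"NAME  {protein.id}",
        f"LENG  {n} match states",
        "HMM    " + "\t".join("ACDEFGHIKLMNPQRSTVWY"),
        "       M->M\tM->I\tM->D\tI->M\tI->I\tD->M\tD->D\tNeff\tNeffI\tNeffD",
    ]
    for i in range(n):
        em = []
        for _ in range(20):
            em.append("*" if rng.random() < 0.1 else str(int(rng.integers(0, 6000))))
        hhm_lines.append(f"{seq[i]} {i + 1}\t" + "\t".join(em))
        tr = [str(int(v)) for v in rng.integers(0, 5000, size=10)]
        hhm_lines.append("       " + "\t".join(tr))
    hhm_lines.append("//")
    hhm = "\n".join(hhm_lines) + "\n"

    return {
        "PSSM": pssm,
        "SS": ss2,
        "Disorder": diso,
        "seqRSA": spx,
        "seqHSE": hse,
        "HH": hhm,
    }


PROFILE_EXTENSIONS = {
    "PSSM": ".pssm",
    "SS": ".ss2",
    "Disorder": ".diso",
    "seqRSA": ".spx",
    "seqHSE": ".hse",
    "HH": ".hhm",
}


def gen_mock_profiles(protein: ProteinRecord, out_dir, seed: int = 0) -> dict:
    """Write mock profile files for one protein; returns source -> path."""
    os.makedirs(out_dir, exist_ok=True)
    texts = mock_profile_texts(protein, seed)
    paths = {}
    for source, text in texts.items():
        path = os.path.join(out_dir, protein.id + PROFILE_EXTENSIONS[source])
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
        paths[source] = path
    return paths
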