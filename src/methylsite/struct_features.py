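"""Geometric descriptors from protein structure models.

Four descriptor families are computed from PDB-format coordinates around a
candidate methylation site:

* **CHOPS** — convex-hull peeling layer ("onion" index) of the
  methyl-accepting side-chain nitrogen: the convex hull of all heavy atoms
  is layer 1; hull atoms are removed and peeling repeats.  Surface-exposed
  atoms therefore get low values, pocketed/buried atoms high values.
* **HSE** — half-sphere exposure: the number of C-alpha neighbours within a
  cutoff radius, split into the half-sphere on the side-chain side ("up")
  and the opposite one ("down"); A-variants derive the up direction from
  C-alpha neighbours along the chain, B-variants from the CA->CB vector.
* **Depth** — distance to the solvent-accessible surface (a point cloud at
  van der Waals + probe radius stands in for "nearest surface water", which
  predicted models do not contain), plus the L1 depth
  ``1 - || mean_i (s_i - x)/||s_i - x|| ||`` over neighbours within a cutoff
  (1 = centrally surrounded, -> 0 = peripheral).
* **RSA** — Shrake-Rupley solvent-accessible surface area of the residue
  (total and side-chain) relative to its value in an extended Ala-X-Ala
  tripeptide built with the same reduced-atom geometry.

Structures are reduced to heavy atoms with per-element van der Waals radii
(C 1.70, N 1.55, O 1.52, S 1.80 A; default 1.70).
"""

from __future__ import annotations

import io
import logging
import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.spatial import ConvexHull, QhullError, cKDTree
from Bio.Align import PairwiseAligner
from Bio.PDB import PDBParser
from Bio.SeqUtils import seq1

from .datasets import AtomRecord
from .seq_features import FeatureBlock

logger = logging.getLogger(__name__)

STRUCT_SUBTYPES = ("CHOPS", "strHSE", "Depth", "strRSA")

VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
DEFAULT_VDW = 1.70
BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}
HSE_VARIANTS = ("AU", "AD", "BU", "BD")


@dataclass
class GeometryConfig:
    """Tunable geometry parameters.

    radii
        cutoff radii (A) for HSE and L1-depth neighbourhoods.
    probe_radius
        solvent probe radius (A) for the accessible surface.
    sphere_points
        quasi-uniform test points per atom for Shrake-Rupley.
    """

    radii: tuple = (5.0, 10.0, 15.0, 20.0, 25.0, 30.0)
    probe_radius: float = 1.4
    sphere_points: int = 960
    max_asa_table: dict | None = None

    def __post_init__(self):
        r = tuple(float(x) for x in self.radii)
        if any(b <= a for a, b in zip(r, r[1:])):
            raise ValueError("radii must be strictly increasing")
        self.radii = r
        if self.sphere_points < 92:
            raise ValueError("sphere_points must be >= 92")


@dataclass
class ResidueGeometryFeatures:
    """All geometric descriptors for one residue."""

    chops_layer: int
    hse: dict  # (variant, radius) -> count
    res_depth: float
    atom_depth: float
    l1_depth_res: dict  # radius -> value in [0, 1] (nan if undefined)
    l1_depth_atom: dict
    rsa_total: float
    rsa_sidechain: float


class Structure:
    """Heavy-atom structure indexed by chain and residue."""

    def __init__(self, atoms):
        if not atoms:
            raise ValueError("structure has no atoms")
        self.atoms = list(atoms)
        self.coords = np.array([a.coord for a in self.atoms], dtype=float)
        self.radii = np.array([a.vdw_radius for a in self.atoms], dtype=float)
        self._residues: dict = {}
        self._chain_order: list = []
        for i, a in enumerate(self.atoms):
            key = (a.chain, a.res_seq)
            if key not in self._residues:
                self._residues[key] = {}
                if a.chain not in self._chain_order:
                    self._chain_order.append(a.chain)
            self._residues[key][a.name] = i

    @property
    def chains(self):
        return list(self._chain_order)

    def residue_keys(self, chain=None):
        keys = [k for k in self._residues if chain is None or k[0] == chain]
        return sorted(keys, key=lambda k: (self._chain_order.index(k[0]), k[1]))

    def residue_atoms(self, chain, res_seq) -> dict:
        try:
            return self._residues[(chain, res_seq)]
        except KeyError:
            raise KeyError(f"no residue {chain}:{res_seq}") from None

    def res_name(self, chain, res_seq) -> str:
        idx = next(iter(self.residue_atoms(chain, res_seq).values()))
        return self.atoms[idx].res_name

    def chain_sequence(self, chain) -> str:
        letters = []
        for _, res_seq in self.residue_keys(chain):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                letters.append(seq1(self.res_name(chain, res_seq).capitalize()))
        return "".join(c if c.isalpha() else "X" for c in letters).upper()

    def ca_index(self, chain, res_seq):
        return self.residue_atoms(chain, res_seq).get("CA")

    def key_atom_index(self, chain, res_seq):
        """Index (or index pair) of the methyl-accepting side-chain atom.

        NZ for Lys; (NH1, NH2) for Arg; CA as fallback for other residues.
        Raises ``ValueError`` when the required atom is missing, mirroring
        the structure-dataset filter.
        """
        atoms = self.residue_atoms(chain, res_seq)
        name = self.res_name(chain, res_seq).upper()
        if name == "LYS":
            if "NZ" not in atoms:
                raise ValueError(f"{chain}:{res_seq} LYS lacks NZ")
            return (atoms["NZ"],)
        if name == "ARG":
            if "NH1" not in atoms or "NH2" not in atoms:
                raise ValueError(f"{chain}:{res_seq} ARG lacks NH1/NH2")
            return (atoms["NH1"], atoms["NH2"])
        if "CA" not in atoms:
            raise ValueError(f"{chain}:{res_seq} lacks CA")
        return (atoms["CA"],)

    def key_atom_point(self, chain, res_seq) -> np.ndarray:
        idx = self.key_atom_index(chain, res_seq)
        return self.coords[list(idx)].mean(axis=0)


def parse_pdb(source) -> Structure:
    """Parse PDB-format text into a heavy-atom :class:`Structure`.

    HETATM records, hydrogens/deuteriums, and alternate locations other
    than ' '/'A' are discarded.
    """
    if hasattr(source, "read"):
        handle = source
    else:
        text = str(source)
        handle = io.StringIO(text) if "\n" in text else open(text, "r")
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("model", handle)
    atoms = []
    for model in structure:
        for chain in model:
            for residue in chain:
                if residue.id[0] != " ":
                    continue  # HETATM / water
                for atom in residue.get_unpacked_list():
                    element = (atom.element or "").strip().upper()
                    if element in ("H", "D"):
                        continue
                    if atom.get_altloc() not in (" ", "A"):
                        continue
                    atoms.append(
                        AtomRecord(
                            serial=atom.serial_number or len(atoms) + 1,
                            name=atom.get_name(),
                            element=element or atom.get_name()[0],
                            chain=chain.id,
                            res_seq=residue.id[1],
                            res_name=residue.get_resname(),
                            coord=tuple(float(x) for x in atom.coord),
                            vdw_radius=VDW_RADII.get(element, DEFAULT_VDW),
                        )
                    )
        break  # first model only
    if not atoms:
        raise ValueError("no ATOM records found")
    return Structure(atoms)


# ---------------------------------------------------------------------------
# Convex-hull peeling (CHOPS)


def _degenerate(points: np.ndarray) -> bool:
    if len(points) < 4:
        return True
    return np.linalg.matrix_rank(points - points[0]) < 3


def chops_layers(points) -> np.ndarray:
    """Iterative convex-hull peeling: layer index (1 = outermost) per point.

    When fewer than 4 points remain or the remainder is affinely dependent,
    all remaining points receive the current layer.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) == 0:
        raise ValueError("need at least one point")
    layers = np.zeros(len(pts), dtype=int)
    remaining = np.arange(len(pts))
    layer = 1
    while remaining.size:
        sub = pts[remaining]
        if _degenerate(sub):
            layers[remaining] = layer
            break
        try:
            hull = ConvexHull(sub)
        except QhullError:
            layers[remaining] = layer
            break
        on_hull = np.zeros(len(sub), dtype=bool)
        on_hull[hull.vertices] = True
        layers[remaining[on_hull]] = layer
        remaining = remaining[~on_hull]
        layer += 1
    return layers


def structure_chops(structure: Structure) -> np.ndarray:
    """Peeling layers for every heavy atom of the structure."""
    return chops_layers(structure.coords)


def residue_chops(structure: Structure, chain, res_seq,
                  layers: np.ndarray | None = None) -> int:
    """CHOPS layer of the residue's key side-chain atom.

    NZ for Lys; min(layer(NH1), layer(NH2)) for Arg; CA otherwise.
    """
    if layers is None:
        layers = structure_chops(structure)
    idx = structure.key_atom_index(chain, res_seq)
    return int(min(layers[i] for i in idx))


# ---------------------------------------------------------------------------
# Half-sphere exposure


def _chain_neighbours_ca(structure: Structure, chain, res_seq):
    keys = structure.residue_keys(chain)
    pos = keys.index((chain, res_seq))
    prev_idx = structure.ca_index(*keys[pos - 1]) if pos > 0 else None
    next_idx = (
        structure.ca_index(*keys[pos + 1]) if pos + 1 < len(keys) else None
    )
    return prev_idx, next_idx


def _hse_direction(structure: Structure, chain, res_seq, variant: str) -> np.ndarray:
    ca_idx = structure.ca_index(chain, res_seq)
    if ca_idx is None:
        raise ValueError(f"{chain}:{res_seq} lacks CA")
    ca = structure.coords[ca_idx]
    atoms = structure.residue_atoms(chain, res_seq)
    if variant[0] == "B" and "CB" in atoms:
        u = structure.coords[atoms["CB"]] - ca
    else:
        # A-variant, or pseudo-CB for Gly: u = (CA - CAprev) + (CA - CAnext)
        prev_idx, next_idx = _chain_neighbours_ca(structure, chain, res_seq)
        parts = []
        if prev_idx is not None:
            parts.append(ca - structure.coords[prev_idx])
        if next_idx is not None:
            parts.append(ca - structure.coords[next_idx])
        if not parts:
            raise ValueError(
                f"{chain}:{res_seq}: no chain neighbours to define the "
                f"half-sphere direction"
            )
        u = np.sum(parts, axis=0)
    norm = np.linalg.norm(u)
    if norm == 0:
        raise ValueError(f"{chain}:{res_seq}: degenerate half-sphere direction")
    return u / norm


def half_sphere_exposure(structure: Structure, chain, res_seq,
                         radius: float, variant: str) -> int:
    """Count C-alpha neighbours in the up or down half-sphere.

    Neighbours are CA atoms of *other* residues within ``radius`` of this
    residue's CA.  ``variant`` is one of AU/AD/BU/BD.
    """
    if variant not in HSE_VARIANTS:
        raise ValueError(f"variant must be one of {HSE_VARIANTS}")
    ca_idx = structure.ca_index(chain, res_seq)
    if ca_idx is None:
        raise ValueError(f"{chain}:{res_seq} lacks CA")
    ca = structure.coords[ca_idx]
    u = _hse_direction(structure, chain, res_seq, variant)
    up = down = 0
    for key in structure.residue_keys():
        if key == (chain, res_seq):
            continue
        other = structure.ca_index(*key)
        if other is None:
            continue
        v = structure.coords[other] - ca
        if np.linalg.norm(v) <= radius:
            if float(np.dot(v, u)) > 0:
                up += 1
            else:
                down += 1
    return up if variant[1] == "U" else down


def hse_all(structure: Structure, chain, res_seq, radii) -> dict:
    """All four HSE variants at every radius; counts are shared-work computed."""
    out = {}
    for variant in HSE_VARIANTS:
        for r in radii:
            out[(variant, r)] = half_sphere_exposure(
                structure, chain, res_seq, r, variant
            )
    return out


# ---------------------------------------------------------------------------
# Accessible surface (Shrake-Rupley) and depth


@lru_cache(maxsize=8)
def unit_sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (Fibonacci spiral)."""
    i = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0))  # golden angle
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    theta = phi * i
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


class SurfaceModel:
    """Solvent-accessible surface of a structure.

    Carries the kept surface points plus per-atom kept fractions (the
    Shrake-Rupley accessibility), shared by the depth and RSA features.
    """

    def __init__(self, structure: Structure, probe: float = 1.4,
                 n_sphere: int = 960):
        self.structure = structure
        self.probe = float(probe)
        self.n_sphere = int(n_sphere)
        sphere = unit_sphere_points(self.n_sphere)
        centers = structure.coords
        exp_radii = structure.radii + self.probe
        tree = cKDTree(centers)
        max_r = exp_radii.max()
        points = []
        kept_counts = np.zeros(len(centers), dtype=int)
        for ai in range(len(centers)):
            pts = centers[ai] + exp_radii[ai] * sphere
            neigh = tree.query_ball_point(centers[ai], exp_radii[ai] + max_r)
            neigh = [j for j in neigh if j != ai]
            keep = np.ones(len(pts), dtype=bool)
            for j in neigh:
                d2 = np.sum((pts - centers[j]) ** 2, axis=1)
                keep &= d2 > exp_radii[j] ** 2
            kept_counts[ai] = int(keep.sum())
            if kept_counts[ai]:
                points.append(pts[keep])
        self.kept_fraction = kept_counts / self.n_sphere
        self.points = (
            np.concatenate(points) if points else np.empty((0, 3))
        )
        self._tree = cKDTree(self.points) if len(self.points) else None

    def atom_sasa(self) -> np.ndarray:
        """Per-atom SASA (A^2): kept fraction x sphere area at vdw+probe."""
        r = self.structure.radii + self.probe
        return self.kept_fraction * 4.0 * math.pi * r * r

    def min_distance(self, xs: np.ndarray) -> np.ndarray:
        if self._tree is None:
            raise ValueError("surface has no points")
        d, _ = self._tree.query(np.atleast_2d(xs))
        return np.atleast_1d(d)


def surface_points(structure: Structure, probe: float = 1.4,
                   n_sphere: int = 960) -> np.ndarray:
    """Accessible-surface point cloud (see :class:`SurfaceModel`)."""
    return SurfaceModel(structure, probe, n_sphere).points


def depth(structure: Structure, chain, res_seq, surface) -> tuple:
    """(residue depth, key-atom depth) in Angstrom.

    Atom depth is the minimum distance from the key side-chain atom
    (NZ / NH1-NH2 midpoint / CA fallback) to any surface point; residue
    depth averages each heavy atom's minimum distance.
    """
    if isinstance(surface, SurfaceModel):
        model = surface
    else:
        pts = np.asarray(surface, dtype=float).reshape(-1, 3)
        if len(pts) == 0:
            raise ValueError("surface must be non-empty")
        model = _PointsOnly(pts)
    key_point = structure.key_atom_point(chain, res_seq)
    atom_depth = float(model.min_distance(key_point)[0])
    res_idx = list(structure.residue_atoms(chain, res_seq).values())
    res_depth = float(model.min_distance(structure.coords[res_idx]).mean())
    return res_depth, atom_depth


class _PointsOnly:
    def __init__(self, pts):
        self._tree = cKDTree(pts)

    def min_distance(self, xs):
        d, _ = self._tree.query(np.atleast_2d(xs))
        return np.atleast_1d(d)


def l1_depth(x, structure: Structure, radius: float, level: str = "res",
             exclude_residue=None) -> float:
    """L1 depth of point ``x``: ``1 - ||mean unit vector to neighbours||``.

    Neighbours are CA atoms (``level='res'``) or all heavy atoms
    (``level='atom'``) of residues other than ``exclude_residue`` within
    ``radius`` of ``x``.  Returns NaN when no neighbour exists.
    """
    if level not in ("res", "atom"):
        raise ValueError("level must be 'res' or 'atom'")
    x = np.asarray(x, dtype=float)
    idxs = []
    for i, a in enumerate(structure.atoms):
        if exclude_residue is not None and (a.chain, a.res_seq) == tuple(exclude_residue):
            continue
        if level == "res" and a.name != "CA":
            continue
        idxs.append(i)
    if not idxs:
        return float("nan")
    coords = structure.coords[idxs]
    d = coords - x
    norms = np.linalg.norm(d, axis=1)
    mask = (norms <= radius) & (norms > 0)
    if not mask.any():
        return float("nan")
    units = d[mask] / norms[mask, None]
    return float(1.0 - np.linalg.norm(units.mean(axis=0)))


# ---------------------------------------------------------------------------
# Relative solvent accessibility


def residue_sasa(structure: Structure, chain, res_seq,
                 surface: SurfaceModel) -> tuple:
    """(total, side-chain) SASA of a residue in A^2."""
    atom_sasa = surface.atom_sasa()
    atoms = structure.residue_atoms(chain, res_seq)
    total = float(sum(atom_sasa[i] for i in atoms.values()))
    side = float(
        sum(atom_sasa[i] for n, i in atoms.items() if n not in BACKBONE_ATOMS)
    )
    return total, side


def relative_sasa(structure: Structure, chain, res_seq,
                  config: GeometryConfig | None = None,
                  surface: SurfaceModel | None = None) -> tuple:
    """(rsa_total, rsa_sidechain): residue SASA over its extended-tripeptide
    reference areas."""
    config = config or GeometryConfig()
    if surface is None:
        surface = SurfaceModel(structure, config.probe_radius, config.sphere_points)
    total, side = residue_sasa(structure, chain, res_seq, surface)
    res_name = structure.res_name(chain, res_seq).upper()
    table = config.max_asa_table or max_asa_reference(
        config.probe_radius, config.sphere_points
    )
    if res_name not in table:
        raise ValueError(f"no reference area for residue type {res_name!r}")
    ref_total, ref_side = table[res_name]
    rsa_total = total / ref_total if ref_total > 0 else float("nan")
    rsa_side = side / ref_side if ref_side > 0 else float("nan")
    return rsa_total, rsa_side


# Reduced-atom residue geometry: local offsets (A) from CA for the extended
# builder; side chains point "up" (+y/+z).  Shared with the toy-structure
# generator so reference areas and generated structures agree.
def residue_atom_offsets(res_name: str) -> dict:
    offsets = {
        "N": np.array([-1.20, -0.80, 0.0]),
        "C": np.array([1.20, -0.80, 0.0]),
        "O": np.array([1.20, -2.03, 0.0]),
    }
    if res_name != "GLY":
        offsets["CB"] = np.array([0.0, 1.08, 1.08])
    if res_name == "LYS":
        offsets["NZ"] = np.array([0.0, 3.30, 3.30])
    elif res_name == "ARG":
        offsets["NH1"] = np.array([-0.90, 3.20, 3.20])
        offsets["NH2"] = np.array([0.90, 3.20, 3.20])
    return offsets


def _element_of(atom_name: str) -> str:
    return atom_name[0]


def build_extended_tripeptide(res_name: str) -> Structure:
    """Ala-X-Ala in an extended (straight-chain) reduced-atom conformation."""
    atoms = []
    serial = 1
    names3 = ("ALA", res_name.upper(), "ALA")
    for ri, rn in enumerate(names3):
        ca = np.array([3.8 * ri, 0.0, 0.0])
        coords = {"CA": ca}
        for name, off in residue_atom_offsets(rn).items():
            coords[name] = ca + off
        for name in ("N", "CA", "C", "O", "CB", "NZ", "NH1", "NH2"):
            if name not in coords:
                continue
            el = _element_of(name)
            atoms.append(
                AtomRecord(
                    serial=serial,
                    name=name,
                    element=el,
                    chain="A",
                    res_seq=ri + 1,
                    res_name=rn,
                    coord=tuple(coords[name]),
                    vdw_radius=VDW_RADII.get(el, DEFAULT_VDW),
                )
            )
            serial += 1
    return Structure(atoms)


_STANDARD_RES3 = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR "
    "TRP TYR VAL"
).split()


@lru_cache(maxsize=8)
def max_asa_reference(probe: float = 1.4, n_sphere: int = 960) -> dict:
    """Reference (total, side-chain) areas per residue type, computed from
    the extended Ala-X-Ala tripeptide with the same reduced-atom model and
    Shrake-Rupley routine used everywhere else."""
    table = {}
    for rn in _STANDARD_RES3:
        tri = build_extended_tripeptide(rn)
        surf = SurfaceModel(tri, probe, n_sphere)
        table[rn] = residue_sasa(tri, "A", 2, surf)
    return table


def load_max_asa_table(source) -> dict:
    """NACCESS-style TSV: res_name, total area, side-chain area."""
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        with open(source, "r", encoding="utf-8") as fh:
            lines = fh.read().splitlines()
    out = {}
    for line in lines:
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        parts = s.split()
        out[parts[0].upper()] = (float(parts[1]), float(parts[2]))
    return out


# ---------------------------------------------------------------------------
# Structure <-> sequence mapping


def map_structure_to_sequence(structure: Structure, sequence: str,
                              chain=None) -> dict:
    """Map structure ``res_seq`` numbers to 1-based sequence positions.

    Global pairwise alignment (match 1, mismatch 0, gap -1) of the chain's
    one-letter sequence against the target; only aligned identical letters
    are mapped.  Identity below 30% of the chain length yields a warning and
    an empty map.
    """
    if chain is None:
        chain = max(structure.chains, key=lambda c: len(structure.residue_keys(c)))
    keys = structure.residue_keys(chain)
    chain_seq = structure.chain_sequence(chain)
    if not chain_seq or not sequence:
        return {}
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    aln = aligner.align(chain_seq, sequence)[0]
    mapping = {}
    n_ident = 0
    for (a_start, a_end), (b_start, b_end) in zip(*aln.aligned):
        for off in range(a_end - a_start):
            ai, bi = a_start + off, b_start + off
            if chain_seq[ai] == sequence[bi]:
                n_ident += 1
                mapping[keys[ai][1]] = bi + 1
    if n_ident < 0.3 * len(chain_seq):
        logger.warning(
            "structure/sequence identity %.0f%% below 30%%; mapping discarded",
            100.0 * n_ident / len(chain_seq),
        )
        return {}
    return mapping


# ---------------------------------------------------------------------------
# Per-residue feature assembly


def residue_geometry(structure: Structure, chain, res_seq,
                     config: GeometryConfig | None = None,
                     layers: np.ndarray | None = None,
                     surface: SurfaceModel | None = None) -> ResidueGeometryFeatures:
    """All geometric descriptors for one residue (caches shareable)."""
    config = config or GeometryConfig()
    if layers is None:
        layers = structure_chops(structure)
    if surface is None:
        surface = SurfaceModel(structure, config.probe_radius, config.sphere_points)
    chops = residue_chops(structure, chain, res_seq, layers)
    hse = hse_all(structure, chain, res_seq, config.radii)
    res_d, atom_d = depth(structure, chain, res_seq, surface)
    key_point = structure.key_atom_point(chain, res_seq)
    l1_res = {
        r: l1_depth(key_point, structure, r, "res", (chain, res_seq))
        for r in config.radii
    }
    l1_atom = {
        r: l1_depth(key_point, structure, r, "atom", (chain, res_seq))
        for r in config.radii
    }
    rsa_t, rsa_s = relative_sasa(structure, chain, res_seq, config, surface)
    return ResidueGeometryFeatures(
        chops_layer=chops,
        hse=hse,
        res_depth=res_d,
        atom_depth=atom_d,
        l1_depth_res=l1_res,
        l1_depth_atom=l1_atom,
        rsa_total=rsa_t,
        rsa_sidechain=rsa_s,
    )


def geometry_feature_blocks(geo: ResidueGeometryFeatures | None,
                            radii) -> dict:
    """Fixed-dimension feature blocks for the four structure subtypes.

    Each block carries a trailing missing flag (0 = computed, 1 = structure
    absent); a missing structure yields all-zero values.  Undefined L1
    depths become 0 (peripheral limit).
    """
    n_r = len(radii)
    if geo is None:
        return {
            "CHOPS": FeatureBlock("CHOPS", np.concatenate([np.zeros(1), [1.0]])),
            "strHSE": FeatureBlock(
                "strHSE", np.concatenate([np.zeros(4 * n_r), [1.0]])
            ),
            "Depth": FeatureBlock(
                "Depth", np.concatenate([np.zeros(2 + 2 * n_r), [1.0]])
            ),
            "strRSA": FeatureBlock("strRSA", np.concatenate([np.zeros(2), [1.0]])),
        }
    hse_vals = [
        float(geo.hse[(v, r)]) for v in HSE_VARIANTS for r in radii
    ]
    def _clean(x):
        return 0.0 if (x is None or not np.isfinite(x)) else float(x)
    depth_vals = (
        [geo.res_depth, geo.atom_depth]
        + [_clean(geo.l1_depth_res[r]) for r in radii]
        + [_clean(geo.l1_depth_atom[r]) for r in radii]
    )
    return {
        "CHOPS": FeatureBlock(
            "CHOPS", np.concatenate([[float(geo.chops_layer)], [0.0]])
        ),
        "strHSE": FeatureBlock("strHSE", np.concatenate([hse_vals, [0.0]])),
        "Depth": FeatureBlock("Depth", np.concatenate([depth_vals, [0.0]])),
        "strRSA": FeatureBlock(
            "strRSA",
            np.concatenate([[geo.rsa_total, geo.rsa_sidechain], [0.0]]),
        ),
    }


def geometry_table(structure: Structure, config: GeometryConfig | None = None):
    """Per-residue geometry as TSV-ready rows (list of dicts)."""
    config = config or GeometryConfig()
    layers = structure_chops(structure)
    surface = SurfaceModel(structure, config.probe_radius, config.sphere_points)
    rows = []
    for chain, res_seq in structure.residue_keys():
        try:
            geo = residue_geometry(
                structure, chain, res_seq, config, layers, surface
            )
        except ValueError:
            continue
        row = {
            "chain": chain,
            "res_seq": res_seq,
            "res_name": structure.res_name(chain, res_seq),
            "chops_layer": geo.chops_layer,
            "res_depth": geo.res_depth,
            "atom_depth": geo.atom_depth,
            "rsa_total": geo.rsa_total,
            "rsa_sidechain": geo.rsa_sidechain,
        }
        for v in HSE_VARIANTS:
            for r in config.radii:
                row[f"hse_{v}_{r:g}"] = geo.hse[(v, r)]
        for r in config.radii:
            row[f"l1_res_{r:g}"] = geo.l1_depth_res[r]
            row[f"l1_atom_{r:g}"] = geo.l1_depth_atom[r]
        rows.append(row)
    return rows
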