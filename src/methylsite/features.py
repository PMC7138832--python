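"""Assembly of per-instance feature matrices from the 16 feature subtypes.

The :class:`FeatureAssembler` turns labelled candidate sites into a numeric
matrix with a named column-group per subtype (LC, PWAA, EBGW, CKSAAP, KNN,
AAindex; SS, seqRSA, Disorder, seqHSE, PSSM, HH; CHOPS, strHSE, Depth,
strRSA).  Profile and structure blocks carry a trailing missing flag so a
protein without third-party profiles or a structure model still encodes —
the pipeline degrades gracefully to sequence-only features.

KNN is the one subtype that depends on the training set itself: the
assembler memorises training windows as references in ``fit`` and, when
producing the training matrix (``fit_transform``), excludes each window's
own exact match to avoid label leakage.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import profile_features as pf
from . import struct_features as sf
from .datasets import extract_window
from .seq_features import (
    SEQ_SUBTYPES,
    KnnScorer,
    SeqEncoderConfig,
    encode_AAindex,
    encode_CKSAAP,
    encode_EBGW,
    encode_LC,
    encode_PWAA,
)

logger = logging.getLogger(__name__)

ALL_SUBTYPES = SEQ_SUBTYPES + pf.PROFILE_SUBTYPES + sf.STRUCT_SUBTYPES


@dataclass
class FeatureSources:
    """Optional per-protein third-party inputs.

    profiles
        protein_id -> {source name -> :class:`~methylsite.profile_features.ProfileMatrix`}
    structures
        protein_id -> :class:`~methylsite.struct_features.Structure`
    """

    profiles: dict = field(default_factory=dict)
    structures: dict = field(default_factory=dict)
    #: protein_id -> {sequence position -> (chain, res_seq)}; when absent the
    #: structure is assumed to number residues by 1-based sequence position
    #: (true for the synthetic generator; use
    #: :func:`methylsite.struct_features.map_structure_to_sequence` otherwise)
    residue_maps: dict = field(default_factory=dict)

    @classmethod
    def from_directories(cls, protein_ids, profile_dir=None, structure_dir=None):
        """Load ``{id}.pssm/.ss2/.diso/.spx/.hse/.hhm`` and ``{id}.pdb`` files."""
        parsers = {
            "PSSM": pf.parse_pssm,
            "SS": pf.parse_ss2,
            "Disorder": lambda s: pf.parse_per_residue_table(s, "Disorder"),
            "seqRSA": lambda s: pf.parse_per_residue_table(s, "seqRSA"),
            "seqHSE": lambda s: pf.parse_per_residue_table(s, "seqHSE"),
            "HH": pf.parse_hhm,
        }
        from .synthetic import PROFILE_EXTENSIONS

        profiles = {}
        structures = {}
        for pid in protein_ids:
            if profile_dir is not None:
                found = {}
                for source, ext in PROFILE_EXTENSIONS.items():
                    path = os.path.join(profile_dir, pid + ext)
                    if os.path.exists(path):
                        found[source] = parsers[source](path)
                if found:
                    profiles[pid] = found
            if structure_dir is not None:
                path = os.path.join(structure_dir, pid + ".pdb")
                if os.path.exists(path):
                    structures[pid] = sf.parse_pdb(path)
        return cls(profiles=profiles, structures=structures)


class _StructureCache:
    """Per-structure shared computations (peeling layers, surface)."""

    def __init__(self, config: sf.GeometryConfig):
        self.config = config
        self._cache: dict = {}

    def geometry(self, pid, structure, chain, res_seq):
        if pid not in self._cache:
            layers = sf.structure_chops(structure)
            surface = sf.SurfaceModel(
                structure, self.config.probe_radius, self.config.sphere_points
            )
            self._cache[pid] = (layers, surface)
        layers, surface = self._cache[pid]
        return sf.residue_geometry(
            structure, chain, res_seq, self.config, layers, surface
        )


class FeatureAssembler(BaseEstimator, TransformerMixin):
    """Encode candidate sites into a feature matrix with named column groups.

    Parameters
    ----------
    proteins
        mapping protein_id -> :class:`~methylsite.datasets.ProteinRecord`.
    w
        sliding-window size (odd).
    subtypes
        feature subtypes to include; profile/structure subtypes are skipped
        automatically when ``sources`` provides no data at all for them.
    """

    def __init__(self, proteins, w=17, subtypes=SEQ_SUBTYPES,
                 seq_config=None, geometry_config=None, sources=None):
        self.proteins = dict(proteins) if not isinstance(proteins, dict) else proteins
        self.w = w
        self.subtypes = tuple(subtypes)
        self.seq_config = seq_config or SeqEncoderConfig()
        self.geometry_config = geometry_config or sf.GeometryConfig()
        self.sources = sources or FeatureSources()
        unknown = set(self.subtypes) - set(ALL_SUBTYPES)
        if unknown:
            raise ValueError(f"unknown subtypes: {sorted(unknown)}")

    # -- sklearn API -------------------------------------------------------

    def fit(self, instances, y=None):
        """Memorise KNN references (training windows and task labels).

        ``y`` is the task's binary label vector; when omitted, the
        instances' own site labels are used.
        """
        if self.w % 2 == 0:
            raise ValueError("window size must be odd")
        self._knn = None
        if "KNN" in self.subtypes:
            labels = (
                [int(v) for v in y] if y is not None
                else [1 if i.is_positive else 0 for i in instances]
            )
            pos_w, neg_w = [], []
            for inst, lab in zip(instances, labels):
                win = self._window(inst)
                (pos_w if lab == 1 else neg_w).append(win)
            if pos_w and neg_w:
                self._knn = KnnScorer(
                    pos_w, neg_w,
                    k_set=self.seq_config.knn_k,
                    similarity=self.seq_config.similarity_matrix,
                )
            else:
                logger.warning("KNN subtype disabled: need both classes in fit")
        self._struct_cache = _StructureCache(self.geometry_config)
        self.fitted_ = True
        return self

    def transform(self, instances, exclude_self: bool = False) -> np.ndarray:
        if not getattr(self, "fitted_", False):
            raise RuntimeError("assembler not fitted")
        rows = []
        groups: dict[str, np.ndarray] | None = None
        for inst in instances:
            blocks = self._encode_instance(inst, exclude_self)
            vec = np.concatenate([b.values for b in blocks])
            if groups is None:
                groups = {}
                start = 0
                for b in blocks:
                    groups[b.subtype] = np.arange(start, start + b.dim)
                    start += b.dim
            rows.append(vec)
        self.feature_groups_ = groups or {}
        return np.array(rows) if rows else np.empty((0, 0))

    def fit_transform(self, instances, y=None):
        """Training-set encoding: KNN skips each window's own reference."""
        return self.fit(instances, y).transform(instances, exclude_self=True)

    # -- encoding ----------------------------------------------------------

    def _window(self, inst):
        prot = self.proteins[inst.protein_id]
        return extract_window(prot.sequence, inst.position, self.w)

    def _encode_instance(self, inst, exclude_self):
        prot = self.proteins[inst.protein_id]
        win = self._window(inst)
        blocks = []
        for subtype in self.subtypes:
            if subtype == "LC":
                blocks.append(encode_LC(inst.position, len(prot.sequence)))
            elif subtype == "PWAA":
                blocks.append(encode_PWAA(win))
            elif subtype == "EBGW":
                blocks.append(encode_EBGW(win, self.seq_config.ebgw_segments))
            elif subtype == "CKSAAP":
                blocks.append(encode_CKSAAP(win, self.seq_config.cksaap_gaps))
            elif subtype == "KNN":
                if self._knn is None:
                    continue
                from .seq_features import FeatureBlock

                vals = self._knn.transform([win], exclude_self=exclude_self)[0]
                blocks.append(FeatureBlock("KNN", vals))
            elif subtype == "AAindex":
                blocks.append(encode_AAindex(win, self.seq_config.aaindex_table))
            elif subtype in pf.PROFILE_SUBTYPES:
                matrix = self.sources.profiles.get(inst.protein_id, {}).get(subtype)
                blocks.append(
                    pf.profile_block(matrix, inst.position, self.w, subtype)
                )
            elif subtype in sf.STRUCT_SUBTYPES:
                blocks.append(self._struct_block(inst, subtype))
        return blocks

    def _struct_block(self, inst, subtype):
        structure = self.sources.structures.get(inst.protein_id)
        geo = None
        if structure is not None:
            try:
                geo = self._geo(inst, structure)
            except (ValueError, KeyError) as exc:
                logger.warning(
                    "structure features missing for %s:%d (%s)",
                    inst.protein_id, inst.position, exc,
                )
        return sf.geometry_feature_blocks(geo, self.geometry_config.radii)[subtype]

    def _geo(self, inst, structure):
        key = (inst.protein_id, inst.position)
        if not hasattr(self, "_geo_cache"):
            self._geo_cache = {}
        if key not in self._geo_cache:
            res_map = self.sources.residue_maps.get(inst.protein_id)
            if res_map is not None:
                chain, res_seq = res_map[inst.position]
            else:
                chain, res_seq = structure.chains[0], inst.position
            self._geo_cache[key] = self._struct_cache.geometry(
                inst.protein_id, structure, chain, res_seq
            )
        return self._geo_cache[key]

    def windows(self, instances):
        return [self._window(i) for i in instances]


def labels_for(instances) -> np.ndarray:
    """Site-task label vector: 1 = methylated, 0 = not."""
    return np.array([1 if i.is_positive else 0 for i in instances], dtype=int)


def type_labels_for(instances, methyl_type: str) -> np.ndarray:
    """One-vs-rest label vector for a methylation type among positives."""
    return np.array(
        [1 if methyl_type in i.types else 0 for i in instances], dtype=int
    )
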