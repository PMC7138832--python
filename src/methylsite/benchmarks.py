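"""Self-contained recovery benchmarks on synthetic data.

These routines drive the whole pipeline on generated datasets with known
ground truth and measure how well it recovers the planted signal.  They are
shared by the test suite and the reproduction script, and double as usage
examples: each returns plain dictionaries of numbers computed at run time.
"""

from __future__ import annotations

import numpy as np

from . import evaluation as ev
from .datasets import build_instances, extract_window, split_proteins
from .features import FeatureSources, labels_for
from .network import TrainConfig, predict, train_two_level
from .selection import StepwiseSubtypeSelector
from .seq_features import SEQ_SUBTYPES
from .struct_features import STRUCT_SUBTYPES, GeometryConfig, parse_pdb
from .synthetic import (
    SynthConfig,
    gen_selection_benchmark,
    gen_sequence_dataset,
    gen_structures_for_proteins,
)


def _heldout_report(net, test_proteins, residue, sources, seed):
    insts = build_instances(test_proteins, residue, seed=seed)
    pm = {p.id: p for p in test_proteins}
    scores = np.array(
        [
            predict(net, pm[i.protein_id], i.position, sources=sources).site_prob
            for i in insts
        ]
    )
    return ev.evaluate_scores(scores, labels_for(insts))


def end_to_end_recovery(seed: int = 0, n_proteins: int = 400,
                        max_candidates: int = 40,
                        sphere_points: int = 96) -> dict:
    """Train on a planted-motif dataset; measure held-out site AUC/ACC with
    sequence features alone and with structure-model features added.

    The dataset uses the synthetic module's default study conditions
    (``n_proteins`` proteins, 60-100 residues, three candidate sites each,
    positive rate 0.5, default motif, structure signal 0.9); training and
    evaluation follow a seeded 80/20 protein-level split.
    """
    cfg = SynthConfig(n_proteins=n_proteins, seed=seed)
    proteins, _ = gen_sequence_dataset(cfg)
    train_p, test_p = split_proteins(proteins, 0.2, seed=seed + 1)
    geom = GeometryConfig(sphere_points=sphere_points)

    tc_seq = TrainConfig(subtypes=SEQ_SUBTYPES, max_candidates=max_candidates)
    net_seq = train_two_level(train_p, cfg.residue, tc_seq, seed=seed + 2)
    rep_seq = _heldout_report(net_seq, test_p, cfg.residue, None, seed + 3)

    pdbs = gen_structures_for_proteins(
        proteins, cfg.structure_signal, seed=seed + 4, residue=cfg.residue
    )
    sources = FeatureSources(
        structures={pid: parse_pdb(text) for pid, text in pdbs.items()}
    )
    tc_str = TrainConfig(
        subtypes=SEQ_SUBTYPES + STRUCT_SUBTYPES,
        max_candidates=max_candidates,
        geometry_config=geom,
    )
    net_str = train_two_level(
        train_p, cfg.residue, tc_str, seed=seed + 2, sources=sources
    )
    rep_str = _heldout_report(net_str, test_p, cfg.residue, sources, seed + 3)

    return {
        "heldout_auc_seq": rep_seq.AUC,
        "heldout_acc_seq": rep_seq.ACC,
        "heldout_auc_seqstr": rep_str.AUC,
        "heldout_acc_seqstr": rep_str.ACC,
        "auc_gain_structure": rep_str.AUC - rep_seq.AUC,
        "n_test_instances": len(build_instances(test_p, cfg.residue, seed=seed + 3)),
    }


def selection_recovery(seed: int = 7) -> dict:
    """Stepwise selection on 10 planted informative + 200 noise features."""
    X, y, informative = gen_selection_benchmark(seed=seed)
    sel = StepwiseSubtypeSelector(random_state=seed).fit(X, y)
    picked = set(int(j) for j in sel.selected_)
    accepted = [acc for _, acc, ok in sel.trace_ if ok]
    return {
        "informative_recovered": len(picked & informative),
        "noise_selected": len(picked - informative),
        "trace_strictly_increasing": float(
            all(b > a for a, b in zip(accepted, accepted[1:]))
        ),
        "n": X.shape[0],
    }


def gated_test_type1_rate(seed: int = 0, n_reps: int = 2000, n: int = 20,
                          alpha: float = 0.05) -> dict:
    """Empirical type-I error of the Shapiro-gated difference test under the
    null (both samples standard normal)."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        res = ev.gated_difference_test(a, b, paired=False, alpha=alpha)
        rejections += res.p_two_tailed < alpha
    return {"type1_rate": rejections / n_reps, "n": n_reps, "alpha": alpha}


def composition_bias_calibration(seed: int = 0, n_reps: int = 500,
                                 n_windows: int = 60, w: int = 9,
                                 alpha: float = 0.05) -> dict:
    """Familywise error of the composition-bias grid under the null, plus
    recovery of a planted 3x enrichment."""
    rng = np.random.default_rng(seed)
    aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

    def random_windows(n, tilt_offsets=()):
        out = []
        for _ in range(n):
            t = list(aa[rng.integers(0, 20, w)])
            t[w // 2] = "K"
            for off in tilt_offsets:
                # 3x enrichment of K: P(K) = 3 / 22
                if rng.random() < 3.0 / 22.0:
                    t[w // 2 + off] = "K"
                else:
                    t[w // 2 + off] = str(aa[rng.integers(0, 20)])
            out.append(extract_window("".join(t), (w + 1) // 2, w))
        return out

    false_alarms = 0
    for _ in range(n_reps):
        grid = ev.composition_bias(
            random_windows(n_windows), random_windows(n_windows), alpha=alpha
        )
        false_alarms += int((grid["call"] != "ns").any())

    # planted 3x K-enrichment at +1..+3 with a larger sample
    pos = random_windows(500, tilt_offsets=(1, 2, 3))
    neg = random_windows(500)
    grid = ev.composition_bias(pos, neg, alpha=alpha)
    hits = grid[(grid["call"] == "enriched") & (grid["aa"] == "K")]
    planted_found = len(set(hits["position"]) & {1, 2, 3})
    null_cells = grid[~((grid["aa"] == "K") & grid["position"].isin([1, 2, 3]))]
    return {
        "fwe_rate": false_alarms / n_reps,
        "planted_cells_detected": planted_found,
        "null_cells_ns_fraction": float((null_cells["call"] == "ns").mean()),
        "n": n_reps,
        "alpha": alpha,
    }


def cpre_identity_deviation(seed: int = 0, n_tables: int = 1000) -> dict:
    """Max |CPRE - PRE| over random confusion tables with r = N/P (exact 0)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_tables):
        tp, tn, fp, fn = (int(v) for v in rng.integers(1, 100, 4))
        c = ev.ConfusionCounts(tp, tn, fp, fn)
        rep = ev.confusion_metrics(c, r=(tn + fp) / (tp + fn))
        worst = max(worst, abs(rep.CPRE - rep.PRE))
    return {"max_abs_deviation": worst, "n": n_tables}


def auc_oracle_deviation(seed: int = 0, n_reps: int = 20, n: int = 200) -> dict:
    """Max deviation of the ROC AUC from the O(n^2) concordance oracle."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_reps):
        scores = np.round(rng.random(n), 2)
        labels = rng.integers(0, 2, n)
        if labels.sum() in (0, n):
            continue
        auc, _ = ev.roc_pr_auc(scores, labels)
        pos = scores[labels == 1][:, None]
        neg = scores[labels == 0][None, :]
        brute = (
            (pos > neg).sum() + 0.5 * (pos == neg).sum()
        ) / (pos.size * neg.size)
        worst = max(worst, abs(auc - brute))
    return {"max_abs_deviation": worst, "n": n}


def chops_oracle_agreement(seed: int = 0, n_clouds: int = 100,
                           max_points: int = 60) -> dict:
    """Fraction of random clouds where peeling matches an independent
    repeated-hull oracle."""
    from scipy.spatial import ConvexHull, QhullError

    from .struct_features import chops_layers

    def oracle(pts):
        layers = np.zeros(len(pts), dtype=int)
        alive = list(range(len(pts)))
        layer = 1
        while alive:
            sub = pts[alive]
            if len(sub) < 4 or np.linalg.matrix_rank(sub - sub[0]) < 3:
                for i in alive:
                    layers[i] = layer
                break
            try:
                hull = ConvexHull(sub)
            except QhullError:
                for i in alive:
                    layers[i] = layer
                break
            on = {alive[v] for v in hull.vertices}
            for i in on:
                layers[i] = layer
            alive = [i for i in alive if i not in on]
            layer += 1
        return layers

    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_clouds):
        n = int(rng.integers(5, max_points + 1))
        pts = rng.normal(size=(n, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        pts *= rng.random((n, 1)) ** (1 / 3)
        agree += int(np.array_equal(chops_layers(pts), oracle(pts)))
    return {"agreement_fraction": agree / n_clouds, "n": n_clouds}
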