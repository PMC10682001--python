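"""End-to-end benchmark workflows on generator-truth data.

Each function generates synthetic inputs with a known ground truth, runs the
corresponding pipeline stages, and measures recovery. They are the backbone of
the acceptance checks and of the numbered analysis scripts.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np

from . import clustering, dynamics, imaging, normalize, sgls
from .network import greedy_communities, modularity, network_metrics
from .quant import IntensityMatrix, ProteinRecord, SampleDesign
from .seqprops import compare_groups_categorical
from .simulate import SimulationConfig, simulate_movie, simulate_network, simulate_timecourse

__all__ = [
    "classification_recovery",
    "clustering_recovery",
    "inflection_recovery",
    "combat_benchmark",
    "tmm_benchmark",
    "modularity_benchmark",
    "fusion_table_chi_square",
    "sgls_sign_pattern",
    "imaging_recovery",
]


def _normalized_pair(cfg: SimulationConfig):
    g3, cap, truth = simulate_timecourse(cfg)
    ng, _, _ = normalize.normalize_pipeline(g3)
    nc, _, _ = normalize.normalize_pipeline(cap)
    return g3, cap, ng, nc, truth


def classification_recovery(seed: int = 7, cfg: SimulationConfig | None = None) -> dict:
    """Dynamic-vs-invariable calls on generator defaults, scored against truth.

    Runs the full normalization chain (scaling -> ComBat -> TMM) on both
    pull-down matrices, applies the both-baits >1.2-fold rule, and reports
    accuracy / sensitivity / specificity.
    """
    cfg = cfg or SimulationConfig(seed=seed)
    _, _, ng, nc, truth = _normalized_pair(cfg)
    fcg, _ = dynamics.fold_changes(ng, "G3BP1")
    fcc, _ = dynamics.fold_changes(nc, "CAPRIN1")
    calls = dynamics.classify_dynamic(fcg, fcc)
    cls = truth["class_of"]
    dyn_truth = {p for p, c in cls.items() if c != "invariable"}
    tp = sum(1 for c in calls if c.protein in dyn_truth and c.label == "dynamic")
    tn = sum(1 for c in calls if c.protein not in dyn_truth and c.label == "invariable")
    n_dyn = len(dyn_truth & {c.protein for c in calls})
    n_inv = len(calls) - n_dyn
    return {
        "accuracy": (tp + tn) / len(calls),
        "sensitivity": tp / n_dyn if n_dyn else float("nan"),
        "specificity": tn / n_inv if n_inv else float("nan"),
        "n": len(calls),
        "calls": calls,
        "truth": truth,
        "normalized_caprin1": nc,
    }


def clustering_recovery(seed: int = 7, cfg: SimulationConfig | None = None) -> dict:
    """Early/late temporal clustering scored against planted classes, plus
    group-average sigmoid inflection fits.

    Clustering uses the fully normalized CAPRIN1 matrix; the kinetic fits use
    batch-corrected (pre-ratio-normalization) profiles, whose shapes are not
    warped by composition-sensitive column factors.
    """
    cfg = cfg or SimulationConfig(seed=seed)
    res = classification_recovery(seed=seed, cfg=cfg)
    truth, nc = res["truth"], res["normalized_caprin1"]
    cls = truth["class_of"]
    dyn = {c.protein for c in res["calls"] if c.label == "dynamic"}

    keep = [i for i, r in enumerate(nc.records) if r.accession in dyn]
    profiles = clustering.zscore_profiles(nc.subset_records(keep))
    _, labels = clustering.hierarchical_cluster(profiles, k=2)
    assignments, warnings = clustering.assign_early_late(labels, profiles)
    scored = [a for a in assignments if cls[a.protein] != "invariable"]
    accuracy = float(np.mean([a.cluster == cls[a.protein] for a in scored]))

    # kinetic fits on batch-corrected profiles of the same dynamic proteins
    _, cap, truth2 = simulate_timecourse(cfg)
    corrected, _ = normalize.combat_adjust(cap)
    keep2 = [i for i, r in enumerate(corrected.records) if r.accession in dyn]
    fit_profiles = {p.protein: p for p in clustering.zscore_profiles(corrected.subset_records(keep2))}
    hs_t = np.asarray(clustering.TIMECOURSE_MINUTES)
    inflections = {}
    for grp in ("early", "late"):
        zs = np.vstack([fit_profiles[a.protein].z for a in assignments if a.cluster == grp])
        fit = clustering.fit_sigmoid(hs_t, zs.mean(axis=0)[: hs_t.size])
        inflections[grp] = fit
    return {
        "early_late_accuracy": accuracy,
        "n_dynamic": len(assignments),
        "inflection_early": inflections["early"].t0,
        "inflection_late": inflections["late"].t0,
        "fits": inflections,
        "warnings": warnings,
        "truth": truth,
    }


def inflection_recovery(seeds) -> dict:
    """Worst-case inflection error over several generator seeds."""
    err_early, err_late = [], []
    for s in seeds:
        out = clustering_recovery(seed=int(s))
        planted = out["truth"]
        err_early.append(abs(out["inflection_early"] - planted["inflection_early"]))
        err_late.append(abs(out["inflection_late"] - planted["inflection_late"]))
    return {
        "max_error_early_min": float(max(err_early)),
        "max_error_late_min": float(max(err_late)),
        "n_seeds": len(err_early),
    }


def combat_benchmark(seed: int = 5, n_proteins: int = 200, shift: float = 0.8) -> dict:
    """Injected batch shift: residual between-batch mean difference after
    adjustment, and the zero-shift identity error."""
    cfg = SimulationConfig(n_early=0, n_late=0, n_invariable=n_proteins,
                           batch_shifts=(0.0, shift, 0.0), seed=seed)
    _, cap, _ = simulate_timecourse(cfg)
    adj, _ = normalize.combat_adjust(cap)
    lv = np.log2(adj.values)
    b1 = [j for j, s in enumerate(adj.samples) if s.replicate == 1]
    b2 = [j for j, s in enumerate(adj.samples) if s.replicate == 2]
    resid = float(np.median(np.abs(lv[:, b2].mean(axis=1) - lv[:, b1].mean(axis=1))))

    cfg0 = SimulationConfig(n_early=0, n_late=0, n_invariable=n_proteins,
                            noise_sd=0.0, channel_noise_sd=0.0,
                            batch_shifts=(0.0, 0.0, 0.0), seed=seed)
    _, cap0, _ = simulate_timecourse(cfg0)
    adj0, _ = normalize.combat_adjust(cap0)
    ident = float(np.max(np.abs(np.log2(adj0.values) - np.log2(cap0.values))))
    return {"median_residual_shift": resid, "zero_shift_max_error": ident, "n": n_proteins}


def tmm_benchmark(seed: int = 2, n_proteins: int = 100) -> dict:
    """Uniform x2 column factor and the worst reciprocal-property error."""
    rng = np.random.default_rng(seed)
    samples = [SampleDesign("a", "HS0", 1, "CAPRIN1"), SampleDesign("b", "HS10", 1, "CAPRIN1")]
    records = [ProteinRecord(f"P{i}", f"G{i}") for i in range(n_proteins)]
    ref = rng.lognormal(10, 1, n_proteins)
    m2 = IntensityMatrix(records, samples, np.column_stack([ref, 2.0 * ref]))
    doubling = normalize.tmm_factors(m2, reference="a").factor_of_sample["b"]

    recip_err = 0.0
    for k in range(5):
        x = ref * 1.3 * np.exp(rng.normal(0, 0.25, n_proteins))
        f_fwd = normalize.tmm_factors(
            IntensityMatrix(records, samples, np.column_stack([ref, x])), reference="a"
        ).factor_of_sample["b"]
        f_rev = normalize.tmm_factors(
            IntensityMatrix(records, samples, np.column_stack([x, ref])), reference="a"
        ).factor_of_sample["b"]
        recip_err = max(recip_err, abs(f_fwd * f_rev - 1.0))
    return {"doubling_factor": float(doubling), "max_reciprocal_error": float(recip_err),
            "n": n_proteins}


def modularity_benchmark(seed: int = 0, n_graphs: int = 50) -> dict:
    """Q on two disjoint triangles and the worst |Q - brute force| discrepancy
    over random 20-node graphs with random 4-way partitions."""
    tri = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
    q_tri = modularity(tri, [{0, 1, 2}, {3, 4, 5}])

    rng = np.random.default_rng(seed)
    worst = 0.0
    for k in range(n_graphs):
        g = nx.gnp_random_graph(20, 0.2, seed=int(rng.integers(0, 2**31 - 1)))
        com_of = {n: int(rng.integers(0, 4)) for n in g.nodes}
        m = g.number_of_edges()
        if m == 0:
            continue
        deg = dict(g.degree())
        intra = sum(1 for u, v in g.edges() if com_of[u] == com_of[v]) / m
        expect = sum(
            (sum(deg[n] for n in g if com_of[n] == c) / (2 * m)) ** 2
            for c in set(com_of.values())
        )
        worst = max(worst, abs(modularity(g, com_of) - (intra - expect)))
    return {"q_two_triangles": float(q_tri), "max_brute_force_discrepancy": float(worst),
            "n_graphs": n_graphs}


def fusion_table_chi_square() -> dict:
    """Chi-square on the fusion-scoring contingency table: 46 of 50 vehicle
    ROIs vs 14 of 50 blebbistatin ROIs showed a fusion event."""
    comp = compare_groups_categorical([[46, 14], [4, 36]])
    return {"chi_square": comp.statistic, "df": comp.df, "p_value": comp.p_value}


def sgls_sign_pattern(seed: int = 7, cfg: SimulationConfig | None = None) -> dict:
    """Median SG-ls enrichment z per planted class (and the ribosomal-like
    early subset), from the fully normalized G3BP1 matrix."""
    cfg = cfg or SimulationConfig(seed=seed)
    g3, _, truth = simulate_timecourse(cfg)
    ng, _, _ = normalize.normalize_pipeline(g3)
    scores, _ = sgls.sgls_scores(ng)
    z = {s.protein: s.z for s in scores}
    cls = truth["class_of"]
    ribo = truth["ribosomal_like"]

    def med(accs):
        vals = [z[a] for a in accs if a in z]
        return float(np.median(vals)) if vals else float("nan")

    return {
        "median_z_early": med([a for a, c in cls.items() if c == "early" and a not in ribo]),
        "median_z_late": med([a for a, c in cls.items() if c == "late"]),
        "median_z_ribosomal": med(ribo),
        "median_z_invariable": med([a for a, c in cls.items() if c == "invariable"]),
        "n_scored": len(z),
    }


def detect_movie(movie: np.ndarray, masks: np.ndarray, min_area: int = 4,
                 max_disp: float = 8.0, merge_radius: float = 14.0) -> dict:
    """Segment every frame, link detections, and count fusion events."""
    per_frame = []
    for t in range(movie.shape[0]):
        sets_t = imaging.segment_and_measure(movie[t], masks, min_area=min_area)
        per_frame.append(sets_t)
    detections = [
        [(r, c, a) for g in sets_t for (r, c), a in zip(g.centroids, g.areas)]
        for sets_t in per_frame
    ]
    tracks, mean_disp = imaging.track_particles(detections, max_disp=max_disp)
    events = imaging.count_fusion_events(tracks, merge_radius=merge_radius,
                                         image_shape=movie.shape[1:])
    return {
        "counts_first": [g.count for g in per_frame[0]],
        "counts_last": [g.count for g in per_frame[-1]],
        "n_fusions": len(events),
        "mean_displacement": mean_disp,
        "tracks": tracks,
    }


def imaging_recovery(seed: int = 3, planted_fusions: int = 2) -> dict:
    """Planted granule counts and fusion events recovered from a synthetic
    movie by the segmentation/tracking pipeline."""
    movie, masks, truth = simulate_movie(planted_fusions=planted_fusions, seed=seed)
    out = detect_movie(movie, masks)
    return {
        "counts_match_first": out["counts_first"] == truth["initial_counts"],
        "counts_match_last": out["counts_last"] == truth["final_counts"],
        "recovered_fusions": out["n_fusions"],
        "planted_fusions": truth["n_fusions"],
        "recovered_counts_first": out["counts_first"],
        "planted_counts_first": truth["initial_counts"],
    }
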