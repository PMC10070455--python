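"""End-to-end synthetic experiments: planted-truth recovery and calibration.

These drivers wire the full comparative pipeline together on generated data
with recorded ground truth — the same experiments the test suite and the
reproduction script run. All randomness flows from explicit seeds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import compartments as comp
from . import contact_map as cm
from . import integration as integ
from . import loops_tads as lt
from . import synthetic_data as sd
from . import variants as var


def recovery_experiment(seed: int, n_bins: int = 2000, depth: float = 1e6,
                        compartment_effect: float = 0.4, n_loops: int = 20,
                        loop_boost: float = 3.0, n_loop_replicates: int = 3) -> dict:
    """Planted-truth recovery on one synthetic chromosome.

    Plants a checkerboard (block length 40 bins), ``n_loops`` focal loops at
    ``loop_boost``x, and three CNV segments (x2, x0.5, x3); measures
    compartment sign agreement, loop recall/precision at FDR 0.05 (averaged
    over ``n_loop_replicates`` independent Poisson draws), CBS breakpoint
    error, and the fitted decay exponent.
    """
    rng = np.random.default_rng(seed)
    signs = sd.checkerboard_signs(n_bins, 40)
    cnv_list = [(200, 300, 2.0), (800, 900, 0.5), (1500, 1600, 3.0)]

    # --- loop recall / precision over independent replicates
    recalls, precisions = [], []
    for rep in range(n_loop_replicates):
        loops = sd.random_loop_positions(n_loops, n_bins, rng, boost=loop_boost,
                                         signs=signs)
        spec = sd.SimulationSpec(n_bins=n_bins, depth=depth,
                                 compartment_effect=compartment_effect,
                                 loop_list=loops, seed=int(rng.integers(2 ** 31)))
        rew = sd.RewiringSpec(flip_block_fraction=0.2, cnv_list=cnv_list,
                              seed=int(rng.integers(2 ** 31)))
        map_pr, map_cr, truth = sd.simulate_condition_pair(spec, rew)
        calls = lt.call_loops(map_pr, fdr_threshold=0.05)
        truthset = [(i, j) for i, j, _ in truth.loops_pr]
        called = list(zip(calls["bin1"].astype(int), calls["bin2"].astype(int)))
        recalls.append(np.mean([any(abs(a - i) <= 1 and abs(b - j) <= 1
                                    for a, b in called) for i, j in truthset]))
        precisions.append(np.mean([any(abs(a - i) <= 1 and abs(b - j) <= 1
                                       for i, j in truthset) for a, b in called])
                          if called else 0.0)

    # --- compartments, decay, switches on the last replicate
    bal = cm.balance(map_pr, method="ICE")
    genes, motifs, gc = sd.simulate_annotation_tracks(spec, truth,
                                                      seed=int(rng.integers(2 ** 31)))
    gd = sd.gene_density_track(genes, n_bins, spec.resolution)
    track = comp.call_compartments(bal, gd, gc)
    valid = np.isfinite(track.scores)
    sign_agreement = float(np.mean(np.sign(track.scores[valid]) == truth.signs_pr[valid]))

    curve = cm.decay_curve(map_pr)
    exponent, _ = cm.fit_power_law(curve, fit_range=(2e4, 5e6))

    bal_cr = cm.balance(map_cr, method="ICE")
    track_cr = comp.call_compartments(bal_cr, gd, gc)
    _, fractions = comp.classify_switches(track.scores, track_cr.scores)

    saddle_pr = comp.saddle_summary(bal, track, n_groups=20)
    saddle_cr = comp.saddle_summary(bal_cr, track_cr, n_groups=20)

    # --- CNV recovery
    cov_pr, cov_cr = sd.simulate_coverage_tracks(spec, truth,
                                                 seed=int(rng.integers(2 ** 31)))
    log2_track = var.coverage_log2_ratio(cov_cr, cov_pr)
    segs = var.cbs_segment(log2_track, alpha=0.01, n_perm=200,
                           seed=int(rng.integers(2 ** 31)))
    found = sorted(set(segs["start_bin"]) | set(segs["end_bin"]))
    true_breaks = sorted({b for a, bnd, _ in cnv_list for b in (a, bnd)})
    bp_err = max(min(abs(f - t) for f in found) for t in true_breaks)

    # --- SV consensus over three imperfect callers
    callsets = sd.simulate_sv_callsets(truth.sv_truth, fp_rate=0.5,
                                       breakpoint_jitter_sd=100.0, support_mean=10,
                                       sensitivity=0.95,
                                       span_bp=n_bins * spec.resolution,
                                       seed=int(rng.integers(2 ** 31)))
    cons = var.consensus_sv(callsets)
    sv_recovered = 0
    for _, t in truth.sv_truth.iterrows():
        if any(c["type"] == t["type"] and abs(c["pos1"] - t["start"]) <= 500
               and abs(c["pos2"] - t["end"]) <= 500 for _, c in cons.iterrows()):
            sv_recovered += 1
    sv_recall = sv_recovered / max(1, len(truth.sv_truth))

    # --- coupled expression vs coverage correlation after the 1-SD filter
    expr = sd.simulate_expression_table(genes, truth, spec.resolution,
                                        coupling=0.5, noise_sd=0.5,
                                        seed=int(rng.integers(2 ** 31)))
    cov_change = var.coverage_log2_ratio(cov_cr, cov_pr)
    gene_bins = truth.genes["bin"].to_numpy()
    r_expr_cov, _, _ = integ.filtered_correlation(expr["log2FC"].to_numpy(),
                                                  cov_change[gene_bins])

    return {
        "sign_agreement": sign_agreement,
        "loop_recall": float(np.mean(recalls)),
        "loop_precision": float(np.mean(precisions)),
        "decay_exponent": float(exponent),
        "cbs_breakpoint_max_error_bins": int(bp_err),
        "switch_ab_ba_fraction": float(fractions["all"]["AB"] + fractions["all"]["BA"]),
        "compartmentalization_score_pr": float(saddle_pr.score),
        "compartmentalization_score_cr": float(saddle_cr.score),
        "aa_strength_pr": float(saddle_pr.aa_strength),
        "sv_consensus_recall": float(sv_recall),
        "expression_coverage_correlation": float(r_expr_cov),
        "n_bins": n_bins,
    }


def null_calibration(seed: int, n_reps: int = 200) -> dict:
    """Empirical type-I error at nominal 0.05 for the four testing stages.

    Differential compartments (replicate noise only), circular-permutation
    region enrichment, pre-ranked GSEA on random sets, and the CBS root split
    on flat tracks.
    """
    rng = np.random.default_rng(seed)

    # differential compartments: pooled over bins and replicates
    rates = []
    for _ in range(max(10, n_reps // 10)):
        tracks = [rng.normal(size=2000) for _ in range(4)]
        tab = comp.differential_compartments(tracks[:2], tracks[2:])
        rates.append(np.mean(tab["p"] < 0.05))
    diffcomp_rate = float(np.mean(rates))

    # permutation enrichment: independent region sets
    hits = 0
    for rep in range(n_reps):
        r = np.random.default_rng(rng.integers(2 ** 31))
        L = 2_000_000
        q = [(int(s), int(s) + 5000) for s in sorted(r.integers(0, L - 10_000, 60))]
        f = [(int(s), int(s) + 5000) for s in sorted(r.integers(0, L - 10_000, 60))]
        _, p, d = lt.permutation_enrichment(q, f, L, n_perm=199,
                                            seed=int(rng.integers(2 ** 31)))
        hits += (d == "enriched" and p < 0.05)
    perm_rate = hits / n_reps

    # pre-ranked GSEA: random sets against a random metric
    genes = [f"g{i}" for i in range(1000)]
    metric = np.sort(rng.normal(size=1000))[::-1]
    ranked = pd.DataFrame({"gene": genes, "metric": metric})
    sets = {f"s{k}": set(rng.choice(genes, 20, replace=False)) for k in range(500)}
    res = integ.preranked_gsea(ranked, sets, n_perm=200,
                               seed=int(rng.integers(2 ** 31)))
    gsea_rate = float(np.mean(res["p"] < 0.05))

    # CBS root split on flat Gaussian tracks at alpha = 0.05
    splits = 0
    for rep in range(n_reps):
        x = np.random.default_rng(rng.integers(2 ** 31)).normal(size=150)
        segs = var.cbs_segment(x, alpha=0.05, n_perm=199,
                               seed=int(rng.integers(2 ** 31)))
        splits += len(segs) > 1
    cbs_rate = splits / n_reps

    return {
        "diffcomp_type1": diffcomp_rate,
        "permutation_type1": float(perm_rate),
        "gsea_type1": gsea_rate,
        "cbs_type1": float(cbs_rate),
        "n_reps": n_reps,
    }
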