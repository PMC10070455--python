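"""Coverage-ratio segmentation, SV consensus calling and gene-level CNV.

Segmentation follows circular binary segmentation (CBS): at each recursion
level the split — a contiguous arc of the (circularized) signal — maximizing
the between-segment t-statistic is accepted when its permutation p-value
falls below ``alpha``. Consensus structural variants require support from at
least two callers with both breakpoints inside a type-specific window.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# Coverage log2 ratio
# ---------------------------------------------------------------------------

def coverage_log2_ratio(cov_cr: np.ndarray, cov_pr: np.ndarray, pseudocount: float = 1.0,
                        scale_to_equal_totals: bool = True) -> np.ndarray:
    """Binned ``log2((cr + pc) / (pr + pc))``, optionally after scaling the
    CR track so both totals match (removes library-size differences)."""
    cr = np.asarray(cov_cr, dtype=float)
    pr = np.asarray(cov_pr, dtype=float)
    if cr.shape != pr.shape:
        raise ValueError("coverage tracks must share binning")
    if scale_to_equal_totals and cr.sum() > 0:
        cr = cr * (pr.sum() / cr.sum())
    return np.log2((cr + pseudocount) / (pr + pseudocount))


# ---------------------------------------------------------------------------
# Circular binary segmentation
# ---------------------------------------------------------------------------

class _ArcScanner:
    """Cached geometry for the circular max-t scan at one segment length.

    For a segment of length n the candidate arcs [i, j) and the weight
    1/sqrt(1/m + 1/(n-m)) depend only on n and ``min_seg``; per evaluation
    only the windowed sums change, so those grids are prepared once.
    """

    def __init__(self, n: int, min_seg: int):
        self.n = n
        i_idx, j_idx = np.meshgrid(np.arange(n + 1), np.arange(n + 1), indexing="ij")
        m = (j_idx - i_idx).astype(float)
        ok = (m >= min_seg) & ((n - m) >= min_seg)
        self.flat_ok = ok.ravel()
        self.i_flat = i_idx.ravel()[self.flat_ok]
        self.j_flat = j_idx.ravel()[self.flat_ok]
        mf = m.ravel()[self.flat_ok]
        self.m = mf
        self.m_out = n - mf
        self.coef = 1.0 / np.sqrt(1.0 / mf + 1.0 / self.m_out)

    def tmax(self, x: np.ndarray):
        if self.m.size == 0:
            return 0.0, 0, 0
        s = np.concatenate([[0.0], np.cumsum(x)])
        total = s[-1]
        sum_in = s[self.j_flat] - s[self.i_flat]
        t = np.abs(sum_in / self.m - (total - sum_in) / self.m_out) * self.coef
        k = int(np.argmax(t))
        return float(t[k]), int(self.i_flat[k]), int(self.j_flat[k])


def _permutation_reject(scanner: _ArcScanner, x: np.ndarray, tmax: float, alpha: float,
                        n_perm: int, rng: np.random.Generator, batch: int = 25) -> bool:
    """Sequential permutation test of the max-t split.

    Draws permutations in batches and stops early once the exceedance count
    guarantees p = (1 + count) / (1 + n_perm) >= alpha (the accept decision
    is then already determined); otherwise runs all ``n_perm``.
    """
    bound = alpha * (1 + n_perm) - 1  # accept as soon as count > bound
    count = 0
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        for _ in range(b):
            if scanner.tmax(rng.permutation(x))[0] >= tmax:
                count += 1
        done += b
        if count > bound:
            return False
    return (1 + count) / (1 + n_perm) < alpha


def _cbs_recurse(x: np.ndarray, offset: int, alpha: float, n_perm: int,
                 min_seg: int, rng: np.random.Generator, out: list) -> None:
    n = x.size
    if n < 2 * min_seg:
        out.append((offset, offset + n))
        return
    scanner = _ArcScanner(n, min_seg)
    tmax, i, j = scanner.tmax(x)
    if tmax <= 0:
        out.append((offset, offset + n))
        return
    if not _permutation_reject(scanner, x, tmax, alpha, n_perm, rng):
        out.append((offset, offset + n))
        return
    pieces = []
    if i > 0:
        pieces.append((0, i))
    pieces.append((i, j))
    if j < n:
        pieces.append((j, n))
    for a, b in pieces:
        _cbs_recurse(x[a:b], offset + a, alpha, n_perm, min_seg, rng, out)


def cbs_segment(log2_track: np.ndarray, alpha: float = 0.01, n_perm: int = 1000,
                min_seg_bins: int = 3, seed: int = 0,
                loss_threshold: float = -0.3, gain_threshold: float = 0.3) -> pd.DataFrame:
    """Circular binary segmentation of a log2 coverage-ratio track.

    Returns sorted, disjoint segments tiling the track, with per-segment
    mean, length, and class (loss / neutral / gain by the mean against the
    thresholds).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    x = np.asarray(log2_track, dtype=float)
    if x.size < 2 * min_seg_bins:
        raise ValueError("track too short for the minimum segment size")
    rng = np.random.default_rng(seed)
    out: list[tuple[int, int]] = []
    _cbs_recurse(x, 0, alpha, n_perm, min_seg_bins, rng, out)
    out.sort()
    rows = []
    for a, b in out:
        mean = float(x[a:b].mean())
        cls = "loss" if mean < loss_threshold else ("gain" if mean > gain_threshold
                                                    else "neutral")
        rows.append((a, b, mean, b - a, cls))
    return pd.DataFrame(rows, columns=["start_bin", "end_bin", "mean", "n_bins", "class"])


# ---------------------------------------------------------------------------
# SV consensus
# ---------------------------------------------------------------------------

def _window_for(svtype: str, window_tra: int, window_other: int) -> int:
    return window_tra if svtype == "TRA" else window_other


def _calls_match(a, b, window: int) -> bool:
    return (a["type"] == b["type"] and a["chrom1"] == b["chrom1"]
            and a["chrom2"] == b["chrom2"]
            and abs(a["pos1"] - b["pos1"]) <= window
            and abs(a["pos2"] - b["pos2"]) <= window)


def consensus_sv(callsets: list[pd.DataFrame], min_support: int = 5,
                 window_tra: int = 1000, window_other: int = 500,
                 min_callers: int = 2) -> pd.DataFrame:
    """Multi-caller consensus SV set.

    Calls with fewer than ``min_support`` paired-end reads are dropped; the
    survivors are clustered greedily in genomic order within (type, chrom
    pair) groups — a call joins the first cluster whose seed call matches it
    (same type, both breakpoints within the type-specific window). Clusters
    holding calls from at least ``min_callers`` distinct callers are emitted
    with median breakpoint coordinates.
    """
    if len(callsets) < 2:
        raise ValueError("need at least two callers")
    allc = pd.concat(callsets, ignore_index=True)
    allc = allc[allc["support"] >= min_support]
    rows = []
    for (svtype, c1, c2), grp in allc.groupby(["type", "chrom1", "chrom2"], sort=True):
        window = _window_for(svtype, window_tra, window_other)
        grp = grp.sort_values(["pos1", "pos2", "caller"]).reset_index(drop=True)
        clusters: list[dict] = []
        for _, call in grp.iterrows():
            placed = False
            for cl in clusters:
                if _calls_match(call, cl["seed"], window):
                    cl["members"].append(call)
                    placed = True
                    break
            if not placed:
                clusters.append({"seed": call, "members": [call]})
        for cl in clusters:
            callers = {m["caller"] for m in cl["members"]}
            if len(callers) < min_callers:
                continue
            p1 = int(np.median([m["pos1"] for m in cl["members"]]))
            p2 = int(np.median([m["pos2"] for m in cl["members"]]))
            rows.append((c1, p1, c2, p2, svtype, len(callers),
                         ",".join(sorted(callers))))
    out = pd.DataFrame(rows, columns=["chrom1", "pos1", "chrom2", "pos2", "type",
                                      "n_callers", "callers"])
    return out.sort_values(["chrom1", "pos1"]).reset_index(drop=True)


def condition_specific_sv(consensus_pr: pd.DataFrame, consensus_cr: pd.DataFrame,
                          window_tra: int = 1000, window_other: int = 500):
    """Cross-condition intersection of two consensus sets.

    A call is *shared* when the other condition holds a call of the same
    type with both breakpoints inside the type-specific window; otherwise it
    is condition-specific. Per side, shared + specific = total.
    """
    def matched(df_a, df_b):
        flags = np.zeros(len(df_a), dtype=bool)
        for i, (_, a) in enumerate(df_a.iterrows()):
            w = _window_for(a["type"], window_tra, window_other)
            for _, b in df_b.iterrows():
                if _calls_match(a, b, w):
                    flags[i] = True
                    break
        return flags

    pr_shared = matched(consensus_pr, consensus_cr)
    cr_shared = matched(consensus_cr, consensus_pr)
    return {
        "pr_specific": consensus_pr[~pr_shared].reset_index(drop=True),
        "cr_specific": consensus_cr[~cr_shared].reset_index(drop=True),
        "shared_pr": consensus_pr[pr_shared].reset_index(drop=True),
        "shared_cr": consensus_cr[cr_shared].reset_index(drop=True),
    }


# ---------------------------------------------------------------------------
# Gene-level CNV annotation
# ---------------------------------------------------------------------------

def annotate_genes_cnv(genes: pd.DataFrame, segments: pd.DataFrame, resolution: int,
                       genome_size_bp: float):
    """Per-gene CNV class and genome-wide loss/gain totals.

    Each gene takes the class of the segment with maximal bp overlap (``None``
    with no overlap). Totals are the summed lengths of loss and gain
    segments; percentages are totals over ``genome_size_bp`` x 100.
    """
    seg_bp = [(int(r["start_bin"]) * resolution, int(r["end_bin"]) * resolution,
               r["class"]) for _, r in segments.iterrows()]
    classes = []
    for _, g in genes.iterrows():
        s, e = int(g["start"]), int(g["end"])
        best, best_ov = None, 0
        for a, b, cls in seg_bp:
            ov = max(0, min(e, b) - max(s, a))
            if ov > best_ov:
                best, best_ov = cls, ov
        classes.append(best)
    out = genes.copy()
    out["cnv_class"] = classes

    loss_bp = sum(b - a for a, b, c in seg_bp if c == "loss")
    gain_bp = sum(b - a for a, b, c in seg_bp if c == "gain")
    summary = {
        "deleted_mb": loss_bp / 1e6,
        "duplicated_mb": gain_bp / 1e6,
        "deleted_pct": 100.0 * loss_bp / genome_size_bp,
        "duplicated_pct": 100.0 * gain_bp / genome_size_bp,
    }
    classified = [c for c in classes if c in ("loss", "gain")]
    if classified:
        summary["genes_loss_fraction"] = classified.count("loss") / len(classified)
        summary["genes_gain_fraction"] = classified.count("gain") / len(classified)
    return out, summary


def cnv_totals_from_lengths(loss_mb: float, gain_mb: float, genome_size_mb: float):
    """Deleted/duplicated genome percentages from region totals in Mb."""
    return 100.0 * loss_mb / genome_size_mb, 100.0 * gain_mb / genome_size_mb
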