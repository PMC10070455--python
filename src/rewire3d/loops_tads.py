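"""Loop calling, loop/anchor set algebra, APA, insulation-score TADs, CTCF.

The loop caller is a donut-style local-enrichment caller: a pixel is a
candidate when its observed count exceeds the expectation formed by the
distance-decay profile times the local donut background of the O/E surface;
significance is a Poisson upper tail with Benjamini-Hochberg control, and
overlapping candidates are reduced by non-maximum suppression.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal, stats
from statsmodels.stats.multitest import multipletests

from ._regions import build_tree, overlaps_any
from .contact_map import ContactMap


# ---------------------------------------------------------------------------
# Loop calling
# ---------------------------------------------------------------------------

def _donut_background(ratio: np.ndarray, valid: np.ndarray, outer: int, inner: int):
    """Local background of the O/E ratio around each pixel, edge-aware.

    Takes the maximum of three estimators — the donut (outer square minus
    inner square) and the horizontal and vertical stripes through the pixel
    (inner square excluded) — so that background inhomogeneity along either
    axis (e.g. a compartment-block edge crossing the ring) does not deflate
    the expectation.
    """
    size_o, size_i = 2 * outer + 1, 2 * inner + 1
    r = np.where(valid, ratio, 0.0)
    v = valid.astype(float)

    def _box(x, shape):
        return signal.fftconvolve(x, np.ones(shape), mode="same")

    ests = []
    for shape in ((size_o, size_o), (size_i, size_o), (size_o, size_i)):
        num = _box(r, shape) - _box(r, (size_i, size_i))
        den = np.round(_box(v, shape) - _box(v, (size_i, size_i)))
        ests.append((num, den))
    bg = np.full(ratio.shape, np.nan)
    for num, den in ests:
        with np.errstate(invalid="ignore", divide="ignore"):
            e = num / den
        e[den <= 0] = np.nan
        bg = np.where(np.isnan(bg), e, np.fmax(bg, e))
    return bg


def call_loops(cmap: ContactMap, p_threshold: float = 0.1, fdr_threshold: float = 0.05,
               donut_radius_bins: int = 5, inner_radius_bins: int = 1,
               min_distance_bins: int = 2, max_distance_bins: int | None = 150,
               min_count: int = 4) -> pd.DataFrame:
    """Call focal contact peaks on a raw-count map.

    Works on raw counts with the per-diagonal mean as the decay expectation;
    the local expected count for a pixel is ``decay(d) * donut_mean(O/E)``.
    Upper-tail Poisson p-values over all tested pixels are BH-corrected;
    calls must satisfy ``p <= p_threshold`` and ``FDR < fdr_threshold``.
    Non-maximum suppression keeps the most enriched pixel within the donut
    radius. Returns a BEDPE-like frame sorted by position.
    """
    n = cmap.n_bins
    if donut_radius_bins * 2 + 1 > n:
        raise ValueError("donut larger than matrix")
    if max_distance_bins is None:
        max_distance_bins = n - 1
    counts = cmap.counts
    idx = np.arange(n)
    dist = np.abs(idx[:, None] - idx[None, :])

    expected = np.zeros(n)
    for d in range(n):
        diag = np.diag(counts, k=d)
        expected[d] = diag.mean() if diag.size else 0.0
    exp_mat = expected[dist]
    valid = exp_mat > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(valid, counts / exp_mat, 0.0)
    bg = _donut_background(ratio, valid, donut_radius_bins, inner_radius_bins)

    lam = exp_mat * np.where(np.isfinite(bg) & (bg > 0), bg, 1.0)
    tested = valid & (dist >= min_distance_bins) & (dist <= max_distance_bins)
    tested &= idx[:, None] < idx[None, :]  # upper triangle only
    ti, tj = np.where(tested)
    obs = counts[ti, tj]
    lamv = lam[ti, tj]
    p = stats.poisson.sf(obs - 1, lamv)

    fdr = multipletests(p, method="fdr_bh")[1] if p.size else np.array([])
    keep = (p <= p_threshold) & (fdr < fdr_threshold) & (obs >= min_count) & (obs > lamv)
    if not keep.any():
        return _empty_loop_frame()

    enr = obs[keep] / lamv[keep]
    cand = pd.DataFrame({
        "bin1": ti[keep], "bin2": tj[keep], "count": obs[keep],
        "expected": lamv[keep], "enrichment": enr, "p": p[keep], "fdr": fdr[keep],
    }).sort_values(["p", "bin1", "bin2"]).reset_index(drop=True)

    # non-maximum suppression within Chebyshev distance <= donut radius
    kept_rows = []
    taken: list[tuple[int, int]] = []
    r = donut_radius_bins
    for row in cand.itertuples(index=False):
        if all(max(abs(row.bin1 - a), abs(row.bin2 - b)) > r for a, b in taken):
            taken.append((row.bin1, row.bin2))
            kept_rows.append(row)
    out = pd.DataFrame(kept_rows)
    res = cmap.resolution
    out["chrom"] = cmap.chrom
    out["a1_start"] = out["bin1"] * res
    out["a1_end"] = (out["bin1"] + 1) * res
    out["a2_start"] = out["bin2"] * res
    out["a2_end"] = (out["bin2"] + 1) * res
    out["size"] = (out["bin2"] - out["bin1"]) * res
    cols = ["chrom", "a1_start", "a1_end", "a2_start", "a2_end", "bin1", "bin2",
            "count", "expected", "enrichment", "p", "fdr", "size"]
    return out[cols].sort_values(["a1_start", "a2_start"]).reset_index(drop=True)


def _empty_loop_frame() -> pd.DataFrame:
    cols = ["chrom", "a1_start", "a1_end", "a2_start", "a2_end", "bin1", "bin2",
            "count", "expected", "enrichment", "p", "fdr", "size"]
    return pd.DataFrame(columns=cols)


# ---------------------------------------------------------------------------
# Loop / anchor set algebra
# ---------------------------------------------------------------------------

def _intervals_within_flank(s1, e1, s2, e2, flank_bp: int) -> bool:
    """Overlap allowing a flank: true when the gap between the half-open
    intervals is smaller than ``flank_bp`` (a one-bin flank joins anchors in
    adjacent bins but not two bins apart)."""
    return min(e1, e2) + flank_bp > max(s1, s2)


def _loops_match(l1, l2, flank_bp: int) -> bool:
    """Both anchor intervals overlap within the flank allowance."""
    return (_intervals_within_flank(l1[0], l1[1], l2[0], l2[1], flank_bp)
            and _intervals_within_flank(l1[2], l1[3], l2[2], l2[3], flank_bp))


def classify_loop_sets(loops_pr: pd.DataFrame, loops_cr: pd.DataFrame,
                       resolution: int, flank_bins: int = 1):
    """Partition loops into common and condition-specific sets.

    A PR loop is *common* when any CR loop matches it (both anchors overlap
    after each interval is expanded by ``flank_bins * resolution`` on both
    sides) and vice versa; otherwise it is condition-specific. Returns a dict
    of frames ``{"common_pr", "common_cr", "pr_specific", "cr_specific"}``
    and a count dict; per condition, specific + common = total.
    """
    flank = flank_bins * resolution
    pr = loops_pr.reset_index(drop=True)
    cr = loops_cr.reset_index(drop=True)
    pr_t = [tuple(r) for r in pr[["a1_start", "a1_end", "a2_start", "a2_end"]].to_numpy()]
    cr_t = [tuple(r) for r in cr[["a1_start", "a1_end", "a2_start", "a2_end"]].to_numpy()]

    # interval index on flank-expanded CR anchor1 for pruning
    tree = build_tree([(l[0] - flank, l[1] + flank) for l in cr_t]) if cr_t else None
    cr_by_a1: dict[tuple[int, int], list[int]] = {}
    for k, l in enumerate(cr_t):
        cr_by_a1.setdefault((l[0] - flank, l[1] + flank), []).append(k)

    pr_common = np.zeros(len(pr_t), dtype=bool)
    cr_common = np.zeros(len(cr_t), dtype=bool)
    for i, l1 in enumerate(pr_t):
        hits = tree.overlap(l1[0], l1[1]) if tree is not None else []
        for h in hits:
            for k in cr_by_a1[(h.begin, h.end)]:
                if _loops_match(l1, cr_t[k], flank):
                    pr_common[i] = True
                    cr_common[k] = True
    sets = {
        "common_pr": pr[pr_common], "common_cr": cr[cr_common],
        "pr_specific": pr[~pr_common], "cr_specific": cr[~cr_common],
    }
    counts = {k: len(v) for k, v in sets.items()}
    counts["pr_total"] = len(pr)
    counts["cr_total"] = len(cr)
    return sets, counts


def classify_anchor_sets(loops_pr: pd.DataFrame, loops_cr: pd.DataFrame,
                         resolution: int, flank_bins: int = 1,
                         excluded_regions=None) -> pd.DataFrame:
    """Pool, filter, merge and categorize loop anchors.

    Anchors overlapping ``excluded_regions`` are removed first; the rest are
    clustered by single-linkage overlap of flank-expanded intervals (so
    anchors within ``flank_bins`` bins, including abutting ones, share a
    cluster). A merged anchor is *common* when its cluster contains anchors
    from loops of both conditions, else condition-specific. Returns a frame
    with columns (start, end, category, n_pr, n_cr).
    """
    flank = flank_bins * resolution
    anchors = []  # (start, end, condition)
    for df, cond in ((loops_pr, "PR"), (loops_cr, "CR")):
        for _, r in df.iterrows():
            anchors.append((int(r["a1_start"]), int(r["a1_end"]), cond))
            anchors.append((int(r["a2_start"]), int(r["a2_end"]), cond))
    if excluded_regions is not None and len(excluded_regions):
        keep_mask = ~overlaps_any([(s, e) for s, e, _ in anchors], excluded_regions)
        anchors = [a for a, k in zip(anchors, keep_mask) if k]
    if not anchors:
        return pd.DataFrame(columns=["start", "end", "category", "n_pr", "n_cr"])
    anchors.sort()
    rows = []
    cur_start, cur_end, cur_cond = anchors[0][0], anchors[0][1], {anchors[0][2]: 1}
    cur_reach = cur_end + flank
    for s, e, cond in anchors[1:]:
        if s < cur_reach:  # within the flank allowance of the cluster
            cur_end = max(cur_end, e)
            cur_reach = max(cur_reach, e + flank)
            cur_cond[cond] = cur_cond.get(cond, 0) + 1
        else:
            rows.append((cur_start, cur_end, cur_cond))
            cur_start, cur_end, cur_cond = s, e, {cond: 1}
            cur_reach = e + flank
    rows.append((cur_start, cur_end, cur_cond))
    out = []
    for s, e, conds in rows:
        n_pr, n_cr = conds.get("PR", 0), conds.get("CR", 0)
        cat = "common" if n_pr and n_cr else ("PR-specific" if n_pr else "CR-specific")
        out.append((s, e, cat, n_pr, n_cr))
    return pd.DataFrame(out, columns=["start", "end", "category", "n_pr", "n_cr"])


# ---------------------------------------------------------------------------
# APA
# ---------------------------------------------------------------------------

def apa(cmap: ContactMap, loops: pd.DataFrame, window_bins: int = 10,
        corner_size: int | None = None):
    """Aggregate peak analysis on the O/E surface.

    Averages (2w+1)-sized submatrices centered on each loop pixel and reports
    the center-to-corner ratio, corner = mean of the lower-left quadrant
    block of size ``corner_size`` (default ``max(1, w // 2)``). Loops whose
    window does not fit inside the matrix are skipped.
    """
    from .contact_map import observed_over_expected
    w = window_bins
    if corner_size is None:
        corner_size = max(1, w // 2)
    oe, _ = observed_over_expected(cmap)
    oe = np.where(np.isfinite(oe), oe, np.nan)
    n = cmap.n_bins
    stack = []
    for _, r in loops.iterrows():
        i, j = int(r["bin1"]), int(r["bin2"])
        if i - w < 0 or j - w < 0 or i + w >= n or j + w >= n:
            continue
        stack.append(oe[i - w:i + w + 1, j - w:j + w + 1])
    if not stack:
        raise ValueError("no loops with a full window inside the matrix")
    agg = np.nanmean(np.stack(stack), axis=0)
    center = agg[w, w]
    corner = np.nanmean(agg[2 * w + 1 - corner_size:, :corner_size])
    return agg, float(center / corner)


# ---------------------------------------------------------------------------
# Insulation score and TAD boundaries
# ---------------------------------------------------------------------------

def insulation_track(cmap: ContactMap, window_bins: int = 10) -> np.ndarray:
    """Per-bin log2 of the mean contact in the window x window square
    straddling the bin, relative to the chromosome-wide mean of such squares.
    NaN within ``window_bins`` of the chromosome ends."""
    if window_bins < 1:
        raise ValueError("window must be >= 1")
    n = cmap.n_bins
    c = cmap.counts
    w = window_bins
    means = np.full(n, np.nan)
    for i in range(w, n - w):
        means[i] = c[i - w:i, i + 1:i + 1 + w].mean()
    valid = np.isfinite(means) & (means > 0)
    chrom_mean = means[valid].mean() if valid.any() else np.nan
    track = np.full(n, np.nan)
    track[valid] = np.log2(means[valid] / chrom_mean)
    return track


def call_tad_boundaries(track: np.ndarray, delta_threshold: float = 0.1,
                        min_separation_bins: int = 3,
                        prominence_window_bins: int = 25) -> pd.DataFrame:
    """Boundaries = local minima of the insulation track with local prominence
    >= ``delta_threshold``, at least ``min_separation_bins`` apart.

    Prominence is evaluated within ``prominence_window_bins`` of each minimum
    so that shallow dips in flat background far from any domain do not borrow
    prominence from distant high-insulation plateaus.
    """
    x = np.asarray(track, dtype=float)
    if not np.isfinite(x).any():
        return pd.DataFrame({"bin": [], "strength": []})
    # fill edge NaNs with the nearest valid value to avoid edge artifacts
    valid_idx = np.where(np.isfinite(x))[0]
    filled = x.copy()
    filled[:valid_idx[0]] = x[valid_idx[0]]
    filled[valid_idx[-1] + 1:] = x[valid_idx[-1]]
    inner = np.isnan(filled)
    if inner.any():
        filled[inner] = np.interp(np.where(inner)[0], valid_idx, x[valid_idx])
    peaks, props = signal.find_peaks(-filled, prominence=delta_threshold,
                                     distance=min_separation_bins,
                                     wlen=2 * prominence_window_bins + 1)
    keep = np.isfinite(x[peaks])
    return pd.DataFrame({"bin": peaks[keep], "strength": props["prominences"][keep]})


def tads_from_boundaries(boundaries: pd.DataFrame, n_bins: int) -> list[tuple[int, int]]:
    """Consecutive-boundary intervals (including chromosome ends)."""
    bs = [0] + sorted(int(b) for b in boundaries["bin"]) + [n_bins]
    return [(a, b) for a, b in zip(bs[:-1], bs[1:]) if b > a]


# ---------------------------------------------------------------------------
# CTCF annotation
# ---------------------------------------------------------------------------

def annotate_ctcf(anchors: pd.DataFrame, motifs: pd.DataFrame, resolution: int) -> pd.DataFrame:
    """Per-anchor CTCF category: multiple (>=2 motifs), single (1),
    adjacent-only (0 inside but >=1 within one bin flank), or none."""
    mot = motifs.sort_values("start").reset_index(drop=True)
    starts = mot["start"].to_numpy()
    ends = mot["end"].to_numpy()
    cats = []
    for _, r in anchors.iterrows():
        s, e = int(r["start"]), int(r["end"])
        inside = int(np.sum((starts < e) & (ends > s)))
        if inside >= 2:
            cats.append("multiple")
        elif inside == 1:
            cats.append("single")
        else:
            near = int(np.sum((starts < e + resolution) & (ends > s - resolution)))
            cats.append("adjacent-only" if near else "none")
    out = anchors.copy()
    out["ctcf_category"] = cats
    return out


def _anchor_motif_strand(s: int, e: int, motifs: pd.DataFrame, resolution: int):
    """Strand of the motif nearest the anchor midpoint (falling back to the
    one-bin flank); None when no motif is found."""
    starts = motifs["start"].to_numpy()
    ends = motifs["end"].to_numpy()
    for lo, hi in ((s, e), (s - resolution, e + resolution)):
        hit = (starts < hi) & (ends > lo)
        if hit.any():
            mids = (starts[hit] + ends[hit]) / 2
            k = int(np.argmin(np.abs(mids - (s + e) / 2)))
            return motifs["strand"].to_numpy()[hit][k]
    return None


def loop_convergence(loops: pd.DataFrame, motifs: pd.DataFrame,
                     resolution: int) -> pd.Series:
    """Per-loop CTCF convergence class.

    '+' at the left anchor with '-' at the right is *convergent*; same
    strands, *tandem*; '-' then '+', *divergent*; a motif at exactly one
    anchor, *one-sided*; neither, *none*. When an anchor holds several
    motifs, the one nearest the anchor midpoint decides.
    """
    classes = []
    for _, r in loops.iterrows():
        left = _anchor_motif_strand(int(r["a1_start"]), int(r["a1_end"]), motifs, resolution)
        right = _anchor_motif_strand(int(r["a2_start"]), int(r["a2_end"]), motifs, resolution)
        if left is None and right is None:
            classes.append("none")
        elif left is None or right is None:
            classes.append("one-sided")
        elif left == "+" and right == "-":
            classes.append("convergent")
        elif left == "-" and right == "+":
            classes.append("divergent")
        else:
            classes.append("tandem")
    return pd.Series(classes, index=loops.index, name="convergence")


# ---------------------------------------------------------------------------
# Permutation enrichment and size stats
# ---------------------------------------------------------------------------

def permutation_enrichment(query_regions, reference_regions, universe_bp: int,
                           n_perm: int = 10_000, seed: int = 0):
    """Circular-permutation association test between two region sets.

    Statistic: number of query regions overlapping any reference region. The
    null shifts all query regions by a common random offset modulo the
    universe length (preserving lengths and spacing). Returns
    ``(z, empirical_p, direction)`` with
    ``p = (1 + #{null >= obs}) / (1 + n_perm)`` for enrichment and the
    mirrored tail for depletion.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    query = [(int(s), int(e)) for s, e in query_regions]
    ref = [(int(s), int(e)) for s, e in reference_regions]
    tree = build_tree(ref)

    def count(regs):
        return sum(bool(tree.overlap(s, e)) for s, e in regs if e > s)

    def shifted(offset):
        out = []
        for s, e in query:
            length = e - s
            ns = (s + offset) % universe_bp
            ne = ns + length
            if ne <= universe_bp:
                out.append((ns, ne))
            else:  # wrap: split across the origin
                out.append((ns, universe_bp))
                out.append((0, ne - universe_bp))
        return out

    obs = count(query)
    rng = np.random.default_rng(seed)
    null = np.array([count(shifted(int(rng.integers(1, universe_bp))))
                     for _ in range(n_perm)])
    p_enrich = (1 + np.sum(null >= obs)) / (1 + n_perm)
    p_deplete = (1 + np.sum(null <= obs)) / (1 + n_perm)
    sd = null.std()
    z = (obs - null.mean()) / sd if sd > 0 else 0.0
    if p_enrich < p_deplete or (p_enrich == p_deplete and obs > null.mean()):
        return float(z), float(p_enrich), "enriched"
    return float(z), float(p_deplete), "depleted"


def loop_size_stats(partitioned: dict[str, pd.DataFrame],
                    compare: tuple[str, str] | None = None):
    """Median loop sizes per category, size-range histogram, and a two-sided
    Wilcoxon rank-sum p between two categories (exact for small samples).

    Size-range bins: < 100 kb, 100 kb - 1 Mb, > 1 Mb.
    """
    medians = {}
    hist = {}
    for name, df in partitioned.items():
        sizes = df["size"].to_numpy(dtype=float)
        if sizes.size == 0:
            raise ValueError(f"category {name!r} has no loops")
        medians[name] = float(np.median(sizes))
        hist[name] = {
            "<100kb": int(np.sum(sizes < 100_000)),
            "100kb-1Mb": int(np.sum((sizes >= 100_000) & (sizes <= 1_000_000))),
            ">1Mb": int(np.sum(sizes > 1_000_000)),
        }
    p = None
    if compare is not None:
        a = partitioned[compare[0]]["size"].to_numpy(dtype=float)
        b = partitioned[compare[1]]["size"].to_numpy(dtype=float)
        if np.array_equal(np.sort(a), np.sort(b)):
            p = 1.0
        else:
            method = "exact" if max(len(a), len(b)) <= 25 else "asymptotic"
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                         method=method).pvalue)
    return medians, hist, p
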