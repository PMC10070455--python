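"""A/B compartment calling, saddle strength, differential compartments, switches.

The compartment signal is the eigenvector of the distance-normalized
(observed/expected) contact correlation matrix whose magnitude of correlation
with gene density is maximal among the leading components; its sign is
oriented so that correlation with gene density is positive (A = positive
score, the transcriptionally active state).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._regions import build_tree, merge_intervals
from .contact_map import ContactMap, observed_over_expected


class OrientationAmbiguousError(ValueError):
    """No leading eigenvector correlates usably with gene density."""


@dataclass
class CompartmentTrack:
    chrom: str
    resolution: int
    scores: np.ndarray  # signed, A = positive, NaN on masked bins
    component_index: int = 0
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_bins(self) -> int:
        return self.scores.size


@dataclass
class SaddleSummary:
    matrix: np.ndarray  # n_groups x n_groups mean log2 obs/exp, B->A order
    aa_strength: float = np.nan  # ratio scale
    bb_strength: float = np.nan
    ab_strength: float = np.nan
    score: float = np.nan  # compartmentalization score


def call_compartments(cmap: ContactMap, gene_density_track: np.ndarray,
                      gc_track: np.ndarray | None = None, n_components: int = 3,
                      min_abs_corr: float = 0.1, tiebreak_margin: float = 0.02,
                      orientation_smooth_bins: int = 5) -> CompartmentTrack:
    """Compartment score from the O/E correlation-matrix eigendecomposition.

    Among the ``n_components`` leading eigenvectors, selects the one with
    maximal |Pearson correlation| with gene density (GC content, when given,
    breaks near-ties within ``tiebreak_margin``), then flips its sign so the
    gene-density correlation is positive. Orientation tracks are mean-
    smoothed over ``orientation_smooth_bins`` first: compartments are broad,
    and smoothing suppresses the Poisson sparseness of per-bin gene counts
    at fine resolution. Raises :class:`OrientationAmbiguousError` when no
    component reaches ``min_abs_corr``, rather than silently choosing.
    """
    if not cmap.balanced:
        raise ValueError("call_compartments expects a balanced map")
    oe, _ = observed_over_expected(cmap)
    valid = np.isfinite(oe).any(axis=0)
    if not valid.any():
        raise ValueError("all bins masked on this chromosome")
    sub = oe[np.ix_(valid, valid)]
    sub = np.where(np.isfinite(sub), sub, 1.0)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(sub)
    corr = np.where(np.isfinite(corr), corr, 0.0)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1][:n_components]

    from scipy.ndimage import uniform_filter1d
    gd = np.asarray(gene_density_track, dtype=float)
    gc = None if gc_track is None else np.asarray(gc_track, dtype=float)
    if orientation_smooth_bins > 1:
        gd = uniform_filter1d(gd, size=orientation_smooth_bins, mode="nearest")
        if gc is not None:
            gc = uniform_filter1d(gc, size=orientation_smooth_bins, mode="nearest")
    gd = gd[valid]
    gc = None if gc is None else gc[valid]
    cors, cors_gc = [], []
    for k in order:
        v = evecs[:, k]
        cors.append(_safe_corr(v, gd))
        cors_gc.append(_safe_corr(v, gc) if gc is not None else np.nan)
    cors = np.array(cors)
    if not np.isfinite(cors).any():
        raise OrientationAmbiguousError(
            "orientation ambiguous: gene density has no usable correlation "
            "with any leading component")
    best = int(np.nanargmax(np.abs(cors)))
    if gc is not None:
        near = np.abs(np.abs(cors) - np.abs(cors[best])) <= tiebreak_margin
        if near.sum() > 1:
            cand = np.where(near, np.abs(cors_gc), -np.inf)
            best = int(np.argmax(cand))
    if not np.isfinite(cors[best]) or abs(cors[best]) < min_abs_corr:
        raise OrientationAmbiguousError(
            f"orientation ambiguous: max |corr with gene density| = {abs(cors[best]):.3f}")
    vec = evecs[:, order[best]] * np.sign(cors[best])
    scores = np.full(cmap.n_bins, np.nan)
    scores[valid] = vec * np.sqrt(max(evals[order[best]], 0.0))
    diag = {"corr_gene_density": abs(cors[best]),
            "corr_gc": cors_gc[best] * np.sign(cors[best]) if gc is not None else np.nan,
            "candidate_corrs": cors.tolist()}
    return CompartmentTrack(chrom=cmap.chrom, resolution=cmap.resolution,
                            scores=scores, component_index=best, diagnostics=diag)


def _safe_corr(a, b) -> float:
    if b is None or np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


# ---------------------------------------------------------------------------
# Saddle and strengths
# ---------------------------------------------------------------------------

def saddle(cmap: ContactMap, track: CompartmentTrack, n_groups: int = 50) -> SaddleSummary:
    """Mean log2 observed/expected between compartment-score quantile groups.

    Bins are ranked by score (ties broken by position) into ``n_groups``
    equal-size groups ordered from most-B to most-A; cell (g, h) is the log2
    aggregate enrichment sum(observed) / sum(expected) over all off-diagonal
    bin pairs in groups g and h. Aggregating before the ratio keeps sparse
    long-range pixels from dominating the cell noise.
    """
    _, expected = observed_over_expected(cmap)
    scores = track.scores
    n = cmap.n_bins
    idx_all = np.arange(n)
    dist = np.abs(idx_all[:, None] - idx_all[None, :])
    exp_mat = expected[dist]
    masked = np.zeros(n, dtype=bool)
    if cmap.weights is not None:
        masked = ~np.isfinite(cmap.weights)
    valid = np.isfinite(scores) & ~masked
    idx = np.where(valid)[0]
    if idx.size < n_groups:
        raise ValueError("fewer valid bins than saddle groups")
    order = idx[np.argsort(scores[idx], kind="stable")]
    groups = np.array_split(order, n_groups)
    obs = cmap.counts.copy()
    np.fill_diagonal(obs, 0.0)
    exp_nd = exp_mat.copy()
    np.fill_diagonal(exp_nd, 0.0)
    mat = np.full((n_groups, n_groups), np.nan)
    for g in range(n_groups):
        for h in range(g, n_groups):
            ix = np.ix_(groups[g], groups[h])
            e = exp_nd[ix].sum()
            o = obs[ix].sum()
            mat[g, h] = mat[h, g] = np.log2(o / e) if e > 0 and o > 0 else np.nan
    return SaddleSummary(matrix=mat)


def compartment_strength(saddle_matrix: np.ndarray, top_fraction: float = 0.2):
    """Corner means of the saddle on the enrichment (ratio) scale.

    AA = exp2(mean log2 cell) over the top ``top_fraction`` of score groups,
    BB over the bottom, AB over the cross block. Returns ``(AA, BB, AB)``.
    """
    n = saddle_matrix.shape[0]
    k = max(1, int(round(top_fraction * n)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        bb = np.nanmean(saddle_matrix[:k, :k])
        aa = np.nanmean(saddle_matrix[n - k:, n - k:])
        ab = np.nanmean(saddle_matrix[:k, n - k:])
    return float(2.0 ** aa), float(2.0 ** bb), float(2.0 ** ab)


def compartmentalization_score(aa: float, bb: float, ab: float, base: float = 2.0) -> float:
    """``log((AA * BB) / AB**2)`` in the configured base (default 2).

    Zero when AA = BB = AB and invariant under joint scaling of the three
    strengths.
    """
    if aa <= 0 or bb <= 0 or ab <= 0:
        raise ValueError("strengths must be positive")
    return float(np.log(aa * bb / ab ** 2) / np.log(base))


def saddle_summary(cmap: ContactMap, track: CompartmentTrack, n_groups: int = 50,
                   top_fraction: float = 0.2) -> SaddleSummary:
    """Saddle matrix plus corner strengths and compartmentalization score."""
    s = saddle(cmap, track, n_groups=n_groups)
    aa, bb, ab = compartment_strength(s.matrix, top_fraction=top_fraction)
    s.aa_strength, s.bb_strength, s.ab_strength = aa, bb, ab
    s.score = compartmentalization_score(aa, bb, ab)
    return s


# ---------------------------------------------------------------------------
# Differential compartments
# ---------------------------------------------------------------------------

def quantile_normalize(columns: np.ndarray) -> np.ndarray:
    """Quantile-normalize columns to the mean of sorted vectors; ties averaged.

    ``columns`` is (n_bins, n_samples); NaN rows are preserved.
    """
    x = np.asarray(columns, dtype=float)
    finite = np.isfinite(x).all(axis=1)
    sub = x[finite]
    if sub.size == 0:
        return x.copy()
    target = np.sort(sub, axis=0).mean(axis=1)
    out = x.copy()
    for j in range(sub.shape[1]):
        ranks = stats.rankdata(sub[:, j], method="average")
        out[finite, j] = np.interp(ranks, np.arange(1, len(target) + 1), target)
    return out


def differential_compartments(tracks_pr: list[np.ndarray], tracks_cr: list[np.ndarray],
                              chrom: str = "chrS", resolution: int = 10_000,
                              fdr_threshold: float = 0.3,
                              ridge: float = 1e-12) -> pd.DataFrame:
    """Replicate-aware test for per-bin compartment-score differences.

    Scores from all samples are quantile-normalized; per bin, the squared
    Mahalanobis distance of the between-condition mean difference is computed
    against a variance pooled from within-condition replicate deviations,
    p-values come from the chi-square distribution with 1 degree of freedom
    (the score is one-dimensional per bin), and Benjamini-Hochberg FDR flags
    bins below ``fdr_threshold``. A (near-)singular pooled variance is
    regularized with ``ridge`` and a warning.
    """
    if len(tracks_pr) + len(tracks_cr) < 2:
        raise ValueError("need at least two samples")
    if max(len(tracks_pr), len(tracks_cr)) < 2:
        raise ValueError("need replicates in at least one condition to estimate variance")
    cols = np.column_stack(list(tracks_pr) + list(tracks_cr))
    qn = quantile_normalize(cols)
    n_pr = len(tracks_pr)
    pr = qn[:, :n_pr]
    cr = qn[:, n_pr:]
    mean_pr, mean_cr = pr.mean(axis=1), cr.mean(axis=1)
    delta = mean_cr - mean_pr

    dev = []
    for block in (pr, cr):
        if block.shape[1] >= 2:
            d = block - block.mean(axis=1, keepdims=True)
            # scale so each deviation has unit-variance weight: var of (x - mean) is
            # sigma^2 * (m-1)/m for m replicates
            m = block.shape[1]
            dev.append(d.ravel() * np.sqrt(m / (m - 1)))
    pooled_var = np.nanvar(np.concatenate(dev), ddof=0)
    if pooled_var <= ridge:
        warnings.warn(f"pooled replicate variance ~0; regularizing with ridge={ridge}",
                      stacklevel=2)
        pooled_var = max(pooled_var, ridge)
    var_delta = pooled_var * (1.0 / pr.shape[1] + 1.0 / cr.shape[1])
    md2 = delta ** 2 / var_delta
    finite = np.isfinite(md2)
    p = np.full(md2.shape, np.nan)
    p[finite] = stats.chi2.sf(md2[finite], df=1)
    fdr = np.full_like(p, np.nan)
    if finite.any():
        fdr[finite] = multipletests(p[finite], method="fdr_bh")[1]

    classes = classify_bin_pair(mean_pr, mean_cr)
    starts = np.arange(len(delta)) * resolution
    return pd.DataFrame({
        "chrom": chrom, "start": starts, "end": starts + resolution,
        "score_pr": mean_pr, "score_cr": mean_cr, "mdist": np.sqrt(md2),
        "p": p, "fdr": fdr, "significant": fdr < fdr_threshold, "class": classes,
    })


def classify_bin_pair(score_pr: np.ndarray, score_cr: np.ndarray) -> np.ndarray:
    """Per-bin switch class from sign pairs: A->A, A->B, B->A, B->B."""
    a_pr = np.asarray(score_pr) > 0
    a_cr = np.asarray(score_cr) > 0
    out = np.where(a_pr, np.where(a_cr, "AA", "AB"), np.where(a_cr, "BA", "BB"))
    nan = ~(np.isfinite(score_pr) & np.isfinite(score_cr))
    out = out.astype(object)
    out[nan] = None
    return out


def classify_switches(track_pr: np.ndarray, track_cr: np.ndarray,
                      significance_flags: np.ndarray | None = None):
    """Switch classes and genome fractions (all classified bins and
    significant-only). Fractions in each reporting mode sum to 1."""
    classes = classify_bin_pair(np.asarray(track_pr), np.asarray(track_cr))
    valid = np.array([c is not None for c in classes])
    modes = {"all": valid}
    if significance_flags is not None:
        modes["significant"] = valid & np.asarray(significance_flags, dtype=bool)
    fractions = {}
    for mode, sel in modes.items():
        n = sel.sum()
        fractions[mode] = {
            cls: (float(np.sum(classes[sel] == cls) / n) if n else np.nan)
            for cls in ("AA", "AB", "BA", "BB")
        }
    return classes, fractions


def significant_class_regions(table: pd.DataFrame) -> dict[str, list[tuple[int, int]]]:
    """Merge adjacent same-class significant bins into bp regions per class."""
    regions: dict[str, list[tuple[int, int]]] = {}
    sig = table[table["significant"].fillna(False)]
    for cls, grp in sig.groupby("class"):
        ivs = list(zip(grp["start"].astype(int), grp["end"].astype(int)))
        regions[str(cls)] = merge_intervals(ivs, gap=0)
    return regions


def genes_in_switch_categories(genes: pd.DataFrame,
                               class_regions: dict[str, list[tuple[int, int]]]):
    """Count genes overlapping (>= 1 bp) each switch class's regions.

    Returns ``(per_class_counts, active_total, inactive_total)`` where active
    = AA + BA (ends in A) and inactive = BB + AB (ends in B). A gene may
    count toward several classes but each class at most once.
    """
    counts = {}
    for cls in ("AA", "AB", "BA", "BB"):
        tree = build_tree(class_regions.get(cls, []))
        counts[cls] = int(sum(bool(tree.overlap(int(s), int(e)))
                              for s, e in zip(genes["start"], genes["end"])))
    active = counts["AA"] + counts["BA"]
    inactive = counts["BB"] + counts["AB"]
    return counts, active, inactive
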