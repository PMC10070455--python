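"""Contact-matrix container, I/O, balancing, distance decay and reproducibility.

A :class:`ContactMap` holds one chromosome's binned, symmetric, intra-chromosomal
contact matrix. Matrices are stored dense (desk-scale chromosomes, up to a few
thousand bins); on disk the canonical form is sparse upper-triangle text
(``bin1 bin2 count``, 0-based bins, bin1 <= bin2).

Conventions: bins are 0-based; genomic intervals are 0-based half-open (BED).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, stats


class ContactMapError(ValueError):
    """Malformed contact data or invalid operation on a contact map."""


@dataclass
class ContactMap:
    """One chromosome's binned symmetric contact matrix.

    Parameters
    ----------
    chrom : str
        Chromosome label.
    resolution : int
        Bin size in bp.
    counts : ndarray of shape (n_bins, n_bins)
        Symmetric, non-negative matrix. Raw maps hold integers (stored as
        float for uniformity); balanced maps hold corrected values.
    weights : ndarray or None
        Per-bin balancing factors (NaN on masked bins) set by :func:`balance`.
    balanced : bool
        Whether ``counts`` has been normalized.
    """

    chrom: str
    resolution: int
    counts: np.ndarray
    weights: np.ndarray | None = None
    balanced: bool = False

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ContactMapError(f"counts must be square, got shape {c.shape}")
        if not np.allclose(c, c.T, equal_nan=True):
            raise ContactMapError("counts matrix is not symmetric")
        if np.nanmin(c) < 0:
            raise ContactMapError("counts matrix has negative entries")
        self.counts = c

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    def bin_sums(self) -> np.ndarray:
        """Per-bin marginal (row) sums."""
        return np.nansum(self.counts, axis=0)

    def copy(self) -> "ContactMap":
        return replace(
            self,
            counts=self.counts.copy(),
            weights=None if self.weights is None else self.weights.copy(),
        )


@dataclass
class DecayCurve:
    """Mean contact per log-spaced genomic-distance stratum."""

    distances: np.ndarray  # bp, strictly increasing stratum centers
    values: np.ndarray  # mean contact per stratum, >= 0
    condition: str = ""
    edges_bins: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.distances) <= 0):
            raise ValueError("distance strata must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("decay values must be non-negative")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_contact_map(path, n_bins: int, chrom: str = "chrS", resolution: int = 10_000,
                     format: str = "sparse-text") -> ContactMap:
    """Read a contact map from sparse (``bin1 bin2 count``) or dense text.

    Mirrored duplicate records (``i j c`` and ``j i c``) collapse to a single
    entry; conflicting duplicates, negative counts and out-of-range bins are
    rejected with the offending line number.
    """
    if format == "dense-text":
        mat = np.loadtxt(path, dtype=float)
        return ContactMap(chrom=chrom, resolution=resolution, counts=mat)
    if format != "sparse-text":
        raise ValueError(f"unknown format {format!r}")
    mat = np.zeros((n_bins, n_bins), dtype=float)
    seen: dict[tuple[int, int], float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ContactMapError(f"line {lineno}: expected 3 fields, got {len(parts)}")
            i, j = int(parts[0]), int(parts[1])
            c = float(parts[2])
            if c < 0:
                raise ContactMapError(f"line {lineno}: negative count {c}")
            for b in (i, j):
                if not 0 <= b < n_bins:
                    raise ContactMapError(f"line {lineno}: bin {b} out of range for {n_bins}-bin map")
            key = (min(i, j), max(i, j))
            if key in seen:
                if seen[key] != c:
                    raise ContactMapError(
                        f"line {lineno}: conflicting duplicate for bins {key}: {seen[key]} vs {c}")
                continue
            seen[key] = c
            mat[key[0], key[1]] = c
            mat[key[1], key[0]] = c
    return ContactMap(chrom=chrom, resolution=resolution, counts=mat)


def write_contact_map(cmap: ContactMap, path, format: str = "sparse-text") -> None:
    """Write canonical form: sorted upper triangle, nonzero entries only."""
    if format == "dense-text":
        np.savetxt(path, cmap.counts, fmt="%.10g")
        return
    if format != "sparse-text":
        raise ValueError(f"unknown format {format!r}")
    iu = np.triu_indices(cmap.n_bins)
    vals = cmap.counts[iu]
    nz = vals != 0
    with open(path, "w") as fh:
        for i, j, c in zip(iu[0][nz], iu[1][nz], vals[nz]):
            fh.write(f"{i}\t{j}\t{c:.10g}\n")


def write_bedgraph(path, chrom: str, resolution: int, values: np.ndarray) -> None:
    """Write a per-bin track as headerless bedGraph (0-based half-open)."""
    with open(path, "w") as fh:
        for i, v in enumerate(np.asarray(values)):
            if np.isnan(v):
                continue
            fh.write(f"{chrom}\t{i * resolution}\t{(i + 1) * resolution}\t{v:.6g}\n")


def read_bedgraph(path, n_bins: int, resolution: int) -> np.ndarray:
    """Read a bedGraph into a per-bin array (NaN where absent)."""
    out = np.full(n_bins, np.nan)
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            _, start, _end, val = line.split("\t")[:4]
            out[int(start) // resolution] = float(val)
    return out


# ---------------------------------------------------------------------------
# Balancing
# ---------------------------------------------------------------------------

def _low_coverage_mask(counts: np.ndarray, frac: float) -> np.ndarray:
    """True for bins to mask: zero-sum bins plus the bottom `frac` of positive sums."""
    sums = counts.sum(axis=0)
    mask = sums == 0
    pos = sums[~mask]
    if frac > 0 and pos.size:
        cutoff = np.quantile(pos, frac)
        mask = (sums == 0) | (sums < cutoff)
    return mask


def balance(cmap: ContactMap, method: str = "ICE", max_iter: int = 200, tol: float = 1e-5,
            mask_low_coverage_frac: float = 0.02) -> ContactMap:
    """Balance a raw map by vanilla-coverage (VC) or iterative correction (ICE).

    VC divides each entry by the product of its two marginal sums and rescales
    to preserve the total. ICE iterates per-bin correction factors until the
    coefficient of variation of non-masked row sums falls below ``tol``.
    The bottom ``mask_low_coverage_frac`` of positive-coverage bins (and all
    zero bins) are masked (NaN weights, zeroed rows).
    """
    if cmap.balanced:
        raise ContactMapError("map already balanced")
    counts = cmap.counts
    total = counts.sum()
    if total == 0:
        raise ContactMapError("cannot balance an all-zero matrix")
    mask = _low_coverage_mask(counts, mask_low_coverage_frac)
    work = counts.copy()
    work[mask, :] = 0.0
    work[:, mask] = 0.0
    kept_total = work.sum()
    if kept_total == 0:
        raise ContactMapError("all bins masked; cannot balance")

    method = method.upper()
    if method == "VC":
        sums = work.sum(axis=0)
        b = np.where(mask, np.nan, sums)
        with np.errstate(divide="ignore", invalid="ignore"):
            bal = work / np.outer(b, b)
        bal[~np.isfinite(bal)] = 0.0
        bal *= kept_total / bal.sum()
        weights = b
    elif method == "ICE":
        bal = work.astype(float)
        weights = np.ones(cmap.n_bins)
        active = ~mask
        converged = False
        last_cv = np.inf
        for _ in range(max_iter):
            s = bal.sum(axis=0)
            sa = s[active]
            mean_s = sa.mean()
            last_cv = sa.std() / mean_s if mean_s > 0 else np.inf
            if last_cv < tol:
                converged = True
                break
            f = np.where(active & (s > 0), s / mean_s, 1.0)
            bal /= np.outer(f, f)
            weights *= f
        if not converged:
            raise ContactMapError(
                f"ICE did not converge in {max_iter} iterations (residual CV {last_cv:.3g})")
        bal *= kept_total / bal.sum()
        weights = np.where(mask, np.nan, weights)
    else:
        raise ValueError(f"unknown balancing method {method!r}")

    return ContactMap(chrom=cmap.chrom, resolution=cmap.resolution, counts=bal,
                      weights=weights, balanced=True)


# ---------------------------------------------------------------------------
# Distance decay
# ---------------------------------------------------------------------------

def _log_strata_edges(n_bins: int, log_bin_factor: float) -> np.ndarray:
    """Distance-stratum edges in bins: single-distance strata until the
    geometric factor exceeds one bin, then log-spaced."""
    edges = [1]
    while edges[-1] < n_bins:
        nxt = max(edges[-1] + 1, int(round(edges[-1] * log_bin_factor)))
        edges.append(min(nxt, n_bins))
    return np.array(edges)


def decay_curve(cmap: ContactMap, log_bin_factor: float = 1.15, condition: str = "") -> DecayCurve:
    """Mean contact per log-spaced genomic-distance stratum (diagonal excluded).

    Strata at short range contain a single bin distance, so there the curve
    equals the per-diagonal mean exactly; zero-contact strata are reported as 0.
    """
    n = cmap.n_bins
    diag_means = np.array([np.nanmean(np.diag(cmap.counts, k=d)) for d in range(1, n)])
    diag_n = np.arange(n - 1, 0, -1)
    edges = _log_strata_edges(n, log_bin_factor)
    dists, vals = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sl = slice(lo - 1, hi - 1)
        w = diag_n[sl]
        m = diag_means[sl]
        ok = np.isfinite(m)
        if not ok.any() or w[ok].sum() == 0:
            continue
        vals.append(float(np.average(m[ok], weights=w[ok])))
        center = np.sqrt(lo * (hi - 1)) if hi - 1 > lo else float(lo)
        dists.append(center * cmap.resolution)
    return DecayCurve(distances=np.array(dists), values=np.array(vals), condition=condition)


def differential_decay(curve_a: DecayCurve, curve_b: DecayCurve,
                       pseudocount: float | None = None) -> np.ndarray:
    """Per-stratum log2 ratio of two decay curves, ``log2((a+pc)/(b+pc))``.

    Default pseudocount = smallest positive stratum mean across both curves.
    """
    if curve_a.distances.shape != curve_b.distances.shape or \
            not np.allclose(curve_a.distances, curve_b.distances):
        raise ValueError("decay curves have mismatched distance strata")
    if pseudocount is None:
        pos = np.concatenate([curve_a.values[curve_a.values > 0],
                              curve_b.values[curve_b.values > 0]])
        pseudocount = float(pos.min()) if pos.size else 1.0
    return np.log2((curve_a.values + pseudocount) / (curve_b.values + pseudocount))


def fit_power_law(curve: DecayCurve, fit_range: tuple[float, float] | None = None,
                  distance_offset_bp: float = 0.0):
    """Least-squares power-law fit of a decay curve on log10-log10 axes.

    Returns ``(exponent, stderr)`` where contact ~ (distance + offset)^(-exponent).
    ``distance_offset_bp`` linearizes families that decay in (d + c) rather
    than d — e.g. one bin for curves that are exactly (1 + d/res)^(-alpha) —
    which matters only at very short range. Requires at least 5 strata with
    positive values in ``fit_range`` (bp).
    """
    d, v = curve.distances, curve.values
    keep = v > 0
    if fit_range is not None:
        keep &= (d >= fit_range[0]) & (d <= fit_range[1])
    if keep.sum() < 5:
        raise ValueError("need >=5 positive strata within the fit range")
    res = stats.linregress(np.log10(d[keep] + distance_offset_bp), np.log10(v[keep]))
    return -res.slope, res.stderr


def estimate_resolution(cmap: ContactMap, count_threshold: int = 1000,
                        pass_fraction: float = 0.8):
    """Map-resolution adequacy rule: pass iff the fraction of bins with more
    than ``count_threshold`` total raw contacts is at least ``pass_fraction``.

    Returns ``(passed, fraction)``.
    """
    if cmap.balanced:
        raise ContactMapError("resolution rule applies to raw counts")
    sums = cmap.bin_sums()
    frac = float(np.mean(sums > count_threshold))
    return frac >= pass_fraction, frac


# ---------------------------------------------------------------------------
# Reproducibility
# ---------------------------------------------------------------------------

def scc(map_a: ContactMap, map_b: ContactMap, smoothing_half_window_bins: int = 1,
        max_distance_bp: int = 5_000_000) -> float:
    """Stratum-adjusted correlation of two maps.

    Both matrices are smoothed with a 2D mean filter of half-window ``h``; the
    Pearson correlation is computed per genomic-distance stratum (diagonal)
    and averaged with weights ``N_d * sd(x_d) * sd(y_d)``. Degenerate strata
    (zero variance in either map) are skipped with a warning. The result is
    symmetric in its arguments and invariant to global scaling of either map.
    """
    if map_a.n_bins != map_b.n_bins or map_a.resolution != map_b.resolution:
        raise ValueError("maps must share bin grid")
    h = smoothing_half_window_bins
    a = ndimage.uniform_filter(map_a.counts, size=2 * h + 1, mode="constant")
    b = ndimage.uniform_filter(map_b.counts, size=2 * h + 1, mode="constant")
    max_d = min(map_a.n_bins - 1, int(max_distance_bp // map_a.resolution))
    num = den = 0.0
    n_skipped = 0
    for d in range(0, max_d + 1):
        xa, xb = np.diag(a, k=d), np.diag(b, k=d)
        if xa.size < 3:
            continue
        sa, sb = xa.std(), xb.std()
        if sa == 0 or sb == 0:
            n_skipped += 1
            continue
        r = float(np.corrcoef(xa, xb)[0, 1])
        w = xa.size * sa * sb
        num += w * r
        den += w
    if n_skipped:
        warnings.warn(f"scc: skipped {n_skipped} zero-variance strata", stacklevel=2)
    if den == 0:
        raise ValueError("no informative distance strata for scc")
    return num / den


def mds_embed(distance_matrix: np.ndarray, k: int = 2) -> np.ndarray:
    """Classical (Torgerson) multidimensional scaling.

    ``distance_matrix`` must be symmetric with a zero diagonal (e.g. built as
    ``1 - scc``). Double-centers the squared distances, eigendecomposes, and
    returns the top-``k`` coordinates. Orientation is fixed so that in each
    dimension the first sample with nonzero coordinate is positive.
    """
    D = np.asarray(distance_matrix, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1][:k]
    lam = np.clip(evals[order], 0, None)
    coords = evecs[:, order] * np.sqrt(lam)
    for j in range(coords.shape[1]):
        col = coords[:, j]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if nz.size and col[nz[0]] < 0:
            coords[:, j] = -col
    return coords


def observed_over_expected(cmap: ContactMap) -> tuple[np.ndarray, np.ndarray]:
    """Distance-normalized matrix and the per-distance expected vector.

    Expected at distance d = mean of all entries on that diagonal over
    non-masked bins. Returns ``(oe, expected)`` with NaN on masked rows.
    """
    n = cmap.n_bins
    c = cmap.counts
    masked = np.zeros(n, dtype=bool)
    if cmap.weights is not None:
        masked = ~np.isfinite(cmap.weights)
    expected = np.zeros(n)
    oe = np.full_like(c, np.nan)
    valid = ~masked
    for d in range(n):
        i = np.arange(n - d)
        j = i + d
        ok = valid[i] & valid[j]
        vals = c[i[ok], j[ok]]
        e = vals.mean() if vals.size else 0.0
        expected[d] = e
        if e > 0:
            oe[i[ok], j[ok]] = c[i[ok], j[ok]] / e
            oe[j[ok], i[ok]] = oe[i[ok], j[ok]]
    return oe, expected
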