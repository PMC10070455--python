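"""Synthetic paired-condition multi-omics generator with recorded ground truth.

Generates everything the comparative pipeline consumes for one chromosome:
paired contact maps (primary "PR" vs rewired "CR" condition), coverage tracks
with planted copy-number distortion, per-caller structural-variant call sets,
a differential-expression table coupled to the planted compartment/CNV truth,
and annotation tracks (genes, stranded CTCF motifs, GC).

The generative model for a contact between bins i and j is Poisson with mean

    lambda(i, j) ∝ (1 + |i-j|)^(-alpha)                 power-law distance decay
                   * exp(eps * s_i * s_j)               A/B checkerboard (s = ±1)
                   * tad_boost(i, j) * loop_boost(i, j) nested domains, focal loops
                   * c_i * c_j                          multiplicative copy ratio

scaled so the expected total count over the upper triangle equals ``depth``.
Counts are sampled independently per bin pair and mirrored, so maps are
symmetric with non-negative integer counts, and a fixed seed reproduces
bitwise-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .contact_map import ContactMap


@dataclass
class SimulationSpec:
    """Baseline (PR) chromosome model."""

    chrom_name: str = "chrS"
    n_bins: int = 2000
    resolution: int = 10_000
    decay_exponent: float = 1.0
    compartment_block_len: int = 40
    compartment_effect: float = 0.4
    tad_list: list = field(default_factory=list)  # (start_bin, end_bin, boost)
    loop_list: list = field(default_factory=list)  # (bin1, bin2, boost)
    depth: float = 1e6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bins < 10:
            raise ValueError("n_bins must be >= 10")
        if self.decay_exponent <= 0:
            raise ValueError("decay_exponent must be > 0")
        if self.compartment_effect < 0:
            raise ValueError("compartment_effect must be >= 0")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if self.compartment_block_len < 1:
            raise ValueError("compartment_block_len must be >= 1")
        for a, b, boost in self.tad_list:
            if not (0 <= a < b <= self.n_bins):
                raise ValueError(f"TAD ({a},{b}) outside [0,{self.n_bins})")
            if boost < 1:
                raise ValueError("TAD boost factors must be >= 1")
        for i, j, boost in self.loop_list:
            if not (0 <= i < self.n_bins and 0 <= j < self.n_bins):
                raise ValueError(f"loop ({i},{j}) outside [0,{self.n_bins})")
            if boost < 1:
                raise ValueError("loop boost factors must be >= 1")


@dataclass
class RewiringSpec:
    """Condition-specific (CR) departures from the baseline model."""

    flip_block_fraction: float = 0.0
    loops_added: list = field(default_factory=list)  # (bin1, bin2, boost)
    loops_removed: list = field(default_factory=list)  # (bin1, bin2)
    tad_splits: list = field(default_factory=list)  # boundary bin positions
    cnv_list: list = field(default_factory=list)  # (start_bin, end_bin, copy_ratio)
    expression_coupling: float = 0.5
    seed: int = 1

    def __post_init__(self) -> None:
        if not 0 <= self.flip_block_fraction <= 1:
            raise ValueError("flip_block_fraction must be in [0, 1]")
        for a, b, ratio in self.cnv_list:
            if ratio <= 0:
                raise ValueError("copy ratio must be > 0")
            if b <= a:
                raise ValueError(f"empty CNV interval ({a},{b})")
        ivs = sorted((a, b) for a, b, _ in self.cnv_list)
        for (a1, b1), (a2, b2) in zip(ivs[:-1], ivs[1:]):
            if a2 < b1:
                raise ValueError(f"overlapping CNV intervals ({a1},{b1}) and ({a2},{b2})")


@dataclass
class GroundTruth:
    """Everything that was planted, per condition."""

    signs_pr: np.ndarray
    signs_cr: np.ndarray
    flipped_blocks: list
    loops_pr: list
    loops_cr: list
    tads_pr: list
    tads_cr: list
    cnv_list: list  # (start_bin, end_bin, copy_ratio), CR relative to PR
    copy_ratio: np.ndarray  # per-bin c_i in the CR condition
    sv_truth: pd.DataFrame  # chrom, start, end (bp), type
    genes: pd.DataFrame | None = None  # filled by simulate_expression_table


# ---------------------------------------------------------------------------
# Contact-map pair
# ---------------------------------------------------------------------------

def _block_signs(n_bins: int, block_len: int) -> tuple[np.ndarray, list]:
    """Alternating ±1 checkerboard; returns per-bin signs and block intervals."""
    signs = np.empty(n_bins)
    blocks = []
    s = 1.0
    for k, a in enumerate(range(0, n_bins, block_len)):
        b = min(a + block_len, n_bins)
        signs[a:b] = s
        blocks.append((a, b))
        s = -s
    return signs, blocks


def _lambda_matrix(n: int, alpha: float, signs: np.ndarray, eps: float,
                   tads, loops, copy_ratio: np.ndarray) -> np.ndarray:
    idx = np.arange(n)
    dist = np.abs(idx[:, None] - idx[None, :])
    lam = (1.0 + dist) ** (-alpha)
    if eps > 0:
        lam *= np.exp(eps * np.outer(signs, signs))
    for a, b, boost in tads:
        lam[a:b, a:b] *= boost
    for i, j, boost in loops:
        lam[i, j] *= boost
        if i != j:
            lam[j, i] *= boost
    lam *= np.outer(copy_ratio, copy_ratio)
    return lam


def _sample_map(lam: np.ndarray, depth: float, rng: np.random.Generator,
                chrom: str, resolution: int) -> ContactMap:
    n = lam.shape[0]
    upper_total = (lam.sum() + np.trace(lam)) / 2.0
    lam = lam * (depth / upper_total)
    iu = np.triu_indices(n)
    draws = rng.poisson(lam[iu])
    mat = np.zeros((n, n))
    mat[iu] = draws
    mat = mat + np.triu(mat, k=1).T
    return ContactMap(chrom=chrom, resolution=resolution, counts=mat)


def apply_rewiring(spec: SimulationSpec, rewiring: RewiringSpec) -> GroundTruth:
    """Resolve the planted truth (both conditions) without sampling counts."""
    signs_pr, blocks = _block_signs(spec.n_bins, spec.compartment_block_len)
    rng = np.random.default_rng(rewiring.seed)
    n_flip = int(round(rewiring.flip_block_fraction * len(blocks)))
    flipped = sorted(rng.choice(len(blocks), size=n_flip, replace=False).tolist()) \
        if n_flip else []
    signs_cr = signs_pr.copy()
    for k in flipped:
        a, b = blocks[k]
        signs_cr[a:b] *= -1

    removed = {(min(i, j), max(i, j)) for i, j in
               [(l[0], l[1]) for l in rewiring.loops_removed]}
    loops_pr = [(min(i, j), max(i, j), boost) for i, j, boost in spec.loop_list]
    loops_cr = [l for l in loops_pr if (l[0], l[1]) not in removed]
    loops_cr += [(min(i, j), max(i, j), boost) for i, j, boost in rewiring.loops_added]

    tads_pr = list(spec.tad_list)
    tads_cr = []
    splits = sorted(rewiring.tad_splits)
    for a, b, boost in tads_pr:
        inner = [s for s in splits if a < s < b]
        edges = [a] + inner + [b]
        for lo, hi in zip(edges[:-1], edges[1:]):
            tads_cr.append((lo, hi, boost))

    copy_ratio = np.ones(spec.n_bins)
    rows = []
    for a, b, ratio in rewiring.cnv_list:
        copy_ratio[a:b] = ratio
        svtype = "DEL" if ratio < 1 else "DUP"
        rows.append((spec.chrom_name, a * spec.resolution, b * spec.resolution, svtype))
    sv_truth = pd.DataFrame(rows, columns=["chrom", "start", "end", "type"])

    return GroundTruth(signs_pr=signs_pr, signs_cr=signs_cr, flipped_blocks=flipped,
                       loops_pr=loops_pr, loops_cr=loops_cr,
                       tads_pr=tads_pr, tads_cr=tads_cr,
                       cnv_list=list(rewiring.cnv_list), copy_ratio=copy_ratio,
                       sv_truth=sv_truth)


def simulate_condition_pair(spec: SimulationSpec, rewiring: RewiringSpec):
    """Sample the (PR, CR) contact-map pair and return it with the truth.

    PR uses the baseline checkerboard/TAD/loop model with unit copy number;
    CR applies the rewiring (flipped blocks, loop gains/losses, TAD splits,
    multiplicative CNV). Both conditions are depth-matched to ``spec.depth``
    expected upper-triangle contacts.
    """
    truth = apply_rewiring(spec, rewiring)
    ones = np.ones(spec.n_bins)
    lam_pr = _lambda_matrix(spec.n_bins, spec.decay_exponent, truth.signs_pr,
                            spec.compartment_effect, truth.tads_pr, truth.loops_pr, ones)
    lam_cr = _lambda_matrix(spec.n_bins, spec.decay_exponent, truth.signs_cr,
                            spec.compartment_effect, truth.tads_cr, truth.loops_cr,
                            truth.copy_ratio)
    rng = np.random.default_rng(spec.seed)
    map_pr = _sample_map(lam_pr, spec.depth, rng, spec.chrom_name, spec.resolution)
    map_cr = _sample_map(lam_cr, spec.depth, rng, spec.chrom_name, spec.resolution)
    return map_pr, map_cr, truth


def simulate_replicate(spec: SimulationSpec, rewiring: RewiringSpec, condition: str,
                       seed: int) -> ContactMap:
    """An independent Poisson replicate of one condition's map."""
    truth = apply_rewiring(spec, rewiring)
    ones = np.ones(spec.n_bins)
    if condition == "PR":
        lam = _lambda_matrix(spec.n_bins, spec.decay_exponent, truth.signs_pr,
                             spec.compartment_effect, truth.tads_pr, truth.loops_pr, ones)
    elif condition == "CR":
        lam = _lambda_matrix(spec.n_bins, spec.decay_exponent, truth.signs_cr,
                             spec.compartment_effect, truth.tads_cr, truth.loops_cr,
                             truth.copy_ratio)
    else:
        raise ValueError("condition must be 'PR' or 'CR'")
    rng = np.random.default_rng(seed)
    return _sample_map(lam, spec.depth, rng, spec.chrom_name, spec.resolution)


def checkerboard_signs(n_bins: int, block_len: int) -> np.ndarray:
    """The deterministic baseline (PR) per-bin compartment signs."""
    return _block_signs(n_bins, block_len)[0]


def random_loop_positions(n_loops: int, n_bins: int, rng: np.random.Generator,
                          distance_range: tuple[int, int] = (2, 5),
                          boost: float = 3.0, min_gap: int = 5,
                          signs: np.ndarray | None = None) -> list:
    """Sample well-separated focal loop pixels at short genomic distances.

    The default distance range keeps planted pixels in the count-rich band
    near the diagonal so single-pixel enrichments are detectable at
    desk-scale sequencing depth. When ``signs`` is given, loops are placed
    entirely inside one compartment block (no boundary crossing), mirroring
    loops nested within compartment domains.
    """
    loops: list[tuple[int, int, float]] = []
    attempts = 0
    while len(loops) < n_loops and attempts < 1000 * n_loops:
        attempts += 1
        d = int(rng.integers(distance_range[0], distance_range[1] + 1))
        i = int(rng.integers(1, n_bins - d - 1))
        j = i + d
        if signs is not None and not np.all(signs[i:j + 1] == signs[i]):
            continue
        if all(max(abs(i - a), abs(j - b)) > min_gap for a, b, _ in loops):
            loops.append((i, j, boost))
    if len(loops) < n_loops:
        raise RuntimeError("could not place the requested number of loops")
    return loops


# ---------------------------------------------------------------------------
# Coverage, SV call sets, expression, annotation
# ---------------------------------------------------------------------------

def simulate_coverage_tracks(spec: SimulationSpec, truth: GroundTruth,
                             mean_depth_per_bin: float = 200.0, seed: int = 0):
    """Binned sequencing coverage per condition; CR scaled by the copy ratio."""
    rng = np.random.default_rng(seed)
    cov_pr = rng.poisson(mean_depth_per_bin, size=spec.n_bins).astype(float)
    cov_cr = rng.poisson(mean_depth_per_bin * truth.copy_ratio).astype(float)
    return cov_pr, cov_cr


def simulate_sv_callsets(truth_svs: pd.DataFrame, fp_rate: float,
                         breakpoint_jitter_sd: float, support_mean: float,
                         n_callers: int = 3, sensitivity: float = 0.9,
                         span_bp: int | None = None, seed: int = 0,
                         condition: str = "CR") -> list[pd.DataFrame]:
    """Per-caller SV tables (chrom1,pos1,chrom2,pos2,type,support,caller).

    Each true SV is emitted by each caller with probability ``sensitivity``,
    with Normal breakpoint jitter and Poisson paired-end read support; false
    positives are appended at ``fp_rate`` per Mb of ``span_bp``.
    """
    if fp_rate < 0 or breakpoint_jitter_sd < 0 or support_mean < 0:
        raise ValueError("rates must be non-negative")
    if not 0 <= sensitivity <= 1:
        raise ValueError("sensitivity must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if span_bp is None:
        span_bp = int(truth_svs["end"].max()) if len(truth_svs) else 1_000_000
    out = []
    sv_types = np.array(["DEL", "DUP", "INV"])
    for c in range(n_callers):
        rows = []
        for _, sv in truth_svs.iterrows():
            if rng.random() > sensitivity:
                continue
            p1 = max(0, int(round(sv["start"] + rng.normal(0, breakpoint_jitter_sd)))) \
                if breakpoint_jitter_sd else int(sv["start"])
            p2 = max(p1 + 1, int(round(sv["end"] + rng.normal(0, breakpoint_jitter_sd)))) \
                if breakpoint_jitter_sd else int(sv["end"])
            rows.append((sv["chrom"], p1, sv["chrom"], p2, sv["type"],
                         int(rng.poisson(support_mean)), f"caller{c + 1}"))
        n_fp = rng.poisson(fp_rate * span_bp / 1e6)
        for _ in range(n_fp):
            p1 = int(rng.integers(0, max(1, span_bp - 10_000)))
            p2 = p1 + int(rng.integers(1_000, 10_000))
            rows.append(("chrS" if len(truth_svs) == 0 else truth_svs["chrom"].iloc[0],
                         p1, "chrS" if len(truth_svs) == 0 else truth_svs["chrom"].iloc[0],
                         p2, str(rng.choice(sv_types)),
                         int(rng.poisson(support_mean)), f"caller{c + 1}"))
        df = pd.DataFrame(rows, columns=["chrom1", "pos1", "chrom2", "pos2",
                                         "type", "support", "caller"])
        df["condition"] = condition
        out.append(df)
    return out


def simulate_expression_table(genes: pd.DataFrame, truth: GroundTruth,
                              resolution: int, coupling: float = 0.5,
                              noise_sd: float = 0.5, seed: int = 0) -> pd.DataFrame:
    """Differential-expression table coupled to compartment and CNV truth.

    ``log2FC = coupling * (s_cr - s_pr) + coupling * log2(copy ratio) + noise``
    evaluated at each gene's midpoint bin; two-sided z p-value against
    ``noise_sd`` and Benjamini-Hochberg FDR. Also records the per-gene truth
    on ``truth.genes``.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    rng = np.random.default_rng(seed)
    mid_bin = ((genes["start"] + genes["end"]) // 2 // resolution).astype(int)
    mid_bin = mid_bin.clip(0, len(truth.signs_pr) - 1)
    comp_delta = truth.signs_cr[mid_bin] - truth.signs_pr[mid_bin]
    cnv_log2 = np.log2(truth.copy_ratio[mid_bin])
    true_fc = coupling * comp_delta + coupling * cnv_log2
    log2fc = true_fc + rng.normal(0, noise_sd, size=len(genes))
    p = 2 * stats.norm.sf(np.abs(log2fc) / noise_sd)
    from statsmodels.stats.multitest import multipletests
    fdr = multipletests(p, method="fdr_bh")[1] if len(p) else np.array([])
    table = pd.DataFrame({
        "gene": genes["gene"].values, "log2FC": log2fc, "p": p, "FDR": fdr,
    })
    truth.genes = pd.DataFrame({
        "gene": genes["gene"].values, "bin": mid_bin.values,
        "true_log2FC": true_fc, "cnv_log2": cnv_log2, "comp_delta": comp_delta,
    })
    return table


def simulate_annotation_tracks(spec: SimulationSpec, truth: GroundTruth,
                               gene_density_per_mb: float = 10.0,
                               motif_density_per_mb: float = 10.0,
                               a_bias: float = 3.0, gc_rho: float = 0.5,
                               seed: int = 0):
    """Gene BED table, stranded CTCF motif BED6 table, and a per-bin GC track.

    Genes are placed with ``a_bias``-fold preference for A (sign +1 in PR)
    bins; motifs are uniform with balanced strands; GC is a Gaussian-copula
    construction achieving correlation ``gc_rho`` with the planted PR signs.
    """
    if gene_density_per_mb < 0 or motif_density_per_mb < 0:
        raise ValueError("densities must be >= 0")
    rng = np.random.default_rng(seed)
    span = spec.n_bins * spec.resolution
    span_mb = span / 1e6

    w = np.where(truth.signs_pr > 0, a_bias, 1.0)
    w = w / w.sum()
    n_genes = rng.poisson(gene_density_per_mb * span_mb)
    rows = []
    for g in range(n_genes):
        b = int(rng.choice(spec.n_bins, p=w))
        start = b * spec.resolution + int(rng.integers(0, spec.resolution))
        length = int(rng.integers(2_000, 3 * spec.resolution))
        rows.append((spec.chrom_name, start, min(start + length, span), f"gene{g:05d}"))
    genes = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene"])

    n_motifs = rng.poisson(motif_density_per_mb * span_mb)
    starts = rng.integers(0, span - 19, size=n_motifs) if n_motifs else np.array([], dtype=int)
    strands = rng.choice(["+", "-"], size=n_motifs)
    motifs = pd.DataFrame({
        "chrom": spec.chrom_name, "start": np.sort(starts),
        "end": np.sort(starts) + 19, "name": [f"CTCF{m}" for m in range(n_motifs)],
        "score": 0, "strand": strands,
    })

    z = rng.normal(size=spec.n_bins)
    gc = 0.41 + 0.05 * (gc_rho * truth.signs_pr + np.sqrt(max(0.0, 1 - gc_rho ** 2)) * z)
    return genes, motifs, gc


def gene_density_track(genes: pd.DataFrame, n_bins: int, resolution: int) -> np.ndarray:
    """Number of gene midpoints per bin (orientation reference for eigenvectors)."""
    track = np.zeros(n_bins)
    if len(genes):
        mids = ((genes["start"] + genes["end"]) // 2 // resolution).astype(int)
        mids = mids.clip(0, n_bins - 1)
        np.add.at(track, mids.values, 1.0)
    return track


def write_bed(df: pd.DataFrame, path, columns=("chrom", "start", "end")) -> None:
    """Headerless BED-style writer (works for BED3/4/6 column subsets)."""
    df.loc[:, list(columns)].to_csv(path, sep="\t", header=False, index=False)
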