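"""Cross-omics correlation, gene ranking, enrichment tests, importance score.

The importance score is an integer sum of five binary per-gene evidence
flags — differential expression, copy-number state, compartment switch,
condition-specific loop-anchor overlap, condition-specific TAD-boundary
overlap — computed in a chosen direction (gained-in-CR or, mirrored,
lost-in-CR). Genes reaching the evidence threshold (default 4 of 5) are the
prioritized set.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._regions import build_tree


# ---------------------------------------------------------------------------
# Gene rankings
# ---------------------------------------------------------------------------

def build_gene_ranking(table: pd.DataFrame, kind: str) -> pd.DataFrame:
    """Signed ranking metric per gene.

    ``de_signed_logp``: sign(log2FC) * (-log10 p) from columns (gene, log2FC, p).
    ``coverage_weighted``: log2 coverage difference * mean coverage from
    columns (gene, log2_ratio, mean_coverage).
    ``eigen_delta``: CR - PR compartment score from columns (gene, score_pr,
    score_cr).
    Ties sort by gene label for determinism.
    """
    t = table.copy()
    if kind == "de_signed_logp":
        metric = np.sign(t["log2FC"]) * (-np.log10(t["p"].clip(lower=1e-300)))
        metric = np.where(t["p"] >= 1.0, 0.0, metric)
    elif kind == "coverage_weighted":
        metric = t["log2_ratio"] * t["mean_coverage"]
    elif kind == "eigen_delta":
        metric = t["score_cr"] - t["score_pr"]
    else:
        raise ValueError(f"unknown ranking kind {kind!r}")
    out = pd.DataFrame({"gene": t["gene"].values, "metric": np.asarray(metric, dtype=float)})
    if out["gene"].duplicated().any():
        raise ValueError("genes must be unique in a ranking")
    if not np.isfinite(out["metric"]).all():
        raise ValueError("ranking metric contains non-finite values")
    return out.sort_values(["metric", "gene"], ascending=[False, True],
                           kind="stable").reset_index(drop=True)


def filtered_correlation(x_changes: np.ndarray, y_changes: np.ndarray,
                         sd_filter: float = 1.0):
    """Pearson correlation of paired change vectors after removing genes with
    small changes (|value| below ``sd_filter`` sample SDs of its own
    distribution) in either measure.

    Returns ``(r, p, n_retained)``; raises when fewer than 3 genes survive.
    """
    x = np.asarray(x_changes, dtype=float)
    y = np.asarray(y_changes, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors required")
    keep = (np.abs(x) >= sd_filter * np.std(x, ddof=1)) & \
           (np.abs(y) >= sd_filter * np.std(y, ddof=1))
    n = int(keep.sum())
    if n < 3:
        raise ValueError(f"only {n} genes survive the {sd_filter}-SD filter; need >= 3")
    r, p = stats.pearsonr(x[keep], y[keep])
    return float(r), float(p), n


# ---------------------------------------------------------------------------
# Pre-ranked GSEA
# ---------------------------------------------------------------------------

def _enrichment_score(metric_sorted: np.ndarray, in_set: np.ndarray,
                      weight_exponent: float) -> float:
    """Weighted Kolmogorov-Smirnov running-sum enrichment score in [-1, 1]."""
    w = np.abs(metric_sorted) ** weight_exponent
    hit = np.where(in_set, w, 0.0)
    total_hit = hit.sum()
    n_miss = in_set.size - in_set.sum()
    if total_hit == 0 or n_miss == 0:
        return 0.0
    running = np.cumsum(hit / total_hit - np.where(in_set, 0.0, 1.0 / n_miss))
    k = int(np.argmax(np.abs(running)))
    return float(running[k])


def preranked_gsea(ranked: pd.DataFrame, gene_sets: dict[str, set], n_perm: int = 1000,
                   weight_exponent: float = 1.0, seed: int = 0,
                   min_size: int = 5, max_size: int = 500) -> pd.DataFrame:
    """Pre-ranked GSEA with gene-label permutation.

    ``ranked`` must come from :func:`build_gene_ranking` (descending metric).
    For each admissible set (size within bounds after intersection with the
    ranked genes) computes the weighted KS enrichment score, a sign-matched
    permutation p-value, the NES (ES normalized by the mean same-sign
    permutation |ES|), and a permutation-ratio FDR.
    """
    genes = ranked["gene"].to_numpy()
    metric = ranked["metric"].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    pos = {g: i for i, g in enumerate(genes)}

    admissible = {}
    for name, members in gene_sets.items():
        idx = np.array(sorted(pos[g] for g in members if g in pos), dtype=int)
        if min_size <= idx.size <= max_size:
            admissible[name] = idx
    if not admissible:
        return pd.DataFrame(columns=["set", "size", "es", "nes", "p", "fdr"])

    results = {}
    perm_nes_all = []
    for name, idx in admissible.items():
        in_set = np.zeros(genes.size, dtype=bool)
        in_set[idx] = True
        es = _enrichment_score(metric, in_set, weight_exponent)
        perm_es = np.empty(n_perm)
        k = idx.size
        for b in range(n_perm):
            sel = rng.choice(genes.size, size=k, replace=False)
            mask = np.zeros(genes.size, dtype=bool)
            mask[sel] = True
            perm_es[b] = _enrichment_score(metric, mask, weight_exponent)
        same = perm_es >= 0 if es >= 0 else perm_es <= 0
        n_same = int(same.sum())
        if n_same == 0:
            p = 1.0 / (1 + n_perm)
            nes = 0.0
            perm_nes = np.array([])
        else:
            p = (1 + np.sum(np.abs(perm_es[same]) >= abs(es))) / (1 + n_same)
            mean_same = np.abs(perm_es[same]).mean()
            nes = es / mean_same if mean_same > 0 else 0.0
            pos_mean = np.abs(perm_es[perm_es >= 0]).mean() if (perm_es >= 0).any() else 1.0
            neg_mean = np.abs(perm_es[perm_es < 0]).mean() if (perm_es < 0).any() else 1.0
            perm_nes = np.where(perm_es >= 0, perm_es / pos_mean, perm_es / neg_mean)
        results[name] = (idx.size, es, nes, p)
        perm_nes_all.append(perm_nes)

    all_perm_nes = np.concatenate(perm_nes_all) if perm_nes_all else np.array([])
    obs_nes = np.array([v[2] for v in results.values()])
    rows = []
    for (name, (size, es, nes, p)) in results.items():
        if nes >= 0:
            num = np.mean(all_perm_nes >= nes) if all_perm_nes.size else 1.0
            den = np.mean(obs_nes >= nes)
        else:
            num = np.mean(all_perm_nes <= nes) if all_perm_nes.size else 1.0
            den = np.mean(obs_nes <= nes)
        fdr = min(1.0, num / den) if den > 0 else 1.0
        rows.append((name, size, es, nes, p, fdr))
    return pd.DataFrame(rows, columns=["set", "size", "es", "nes", "p", "fdr"]) \
        .sort_values("p", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Hypergeometric enrichment
# ---------------------------------------------------------------------------

def hypergeometric_enrichment(query_genes, gene_sets: dict[str, set],
                              universe_genes) -> pd.DataFrame:
    """Upper-tail hypergeometric overlap test per set with BH correction.

    ``p = P[X >= overlap]`` drawing |query| genes from a universe containing
    |set ∩ universe| successes; an empty overlap gives p = 1 by the
    P[X >= 0] convention. Fold enrichment = (k/|query|) / (|set|/|universe|).
    """
    universe = set(universe_genes)
    query = set(query_genes)
    if not query <= universe:
        raise ValueError("query genes must be a subset of the universe")
    rows = []
    for name, members in gene_sets.items():
        inset = set(members) & universe
        k = len(query & inset)
        M, n, N = len(universe), len(inset), len(query)
        p = float(stats.hypergeom.sf(k - 1, M, n, N))
        fold = (k / N) / (n / M) if n and N else np.nan
        rows.append((name, k, n, fold, p))
    out = pd.DataFrame(rows, columns=["set", "overlap", "set_size", "fold", "p"])
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1] if len(out) else []
    return out


def read_gmt(path) -> dict[str, set]:
    """Read a GMT gene-set file: name <tab> description <tab> genes..."""
    sets: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


# ---------------------------------------------------------------------------
# Importance score
# ---------------------------------------------------------------------------

def _genes_overlapping(genes: pd.DataFrame, regions) -> np.ndarray:
    tree = build_tree(regions)
    return np.array([bool(tree.overlap(int(s), int(e)))
                     for s, e in zip(genes["start"], genes["end"])])


def evidence_matrix(genes: pd.DataFrame, de_table: pd.DataFrame,
                    cnv_classes: pd.DataFrame, switch_regions: dict,
                    anchor_regions, boundary_regions, direction: str = "CR",
                    de_fdr: float = 0.1) -> pd.DataFrame:
    """Per-gene binary evidence flags across the five omics layers.

    Direction ``"CR"`` (regulation gained in the resistant state) flags:
    upregulated at DE FDR, copy-number gain, compartment switch ending in A
    (AA or BA significant regions), CR-specific loop-anchor overlap, and
    CR-specific TAD-boundary overlap. Direction ``"PR"`` mirrors every layer
    (down, loss, switch ending in B, PR-specific anchors/boundaries).
    All overlaps are >= 1 bp against the gene body. The importance score is
    the exact flag sum in {0..5}.
    """
    if direction not in ("CR", "PR"):
        raise ValueError("direction must be 'CR' or 'PR'")
    g = genes.reset_index(drop=True)
    de = de_table.set_index("gene")
    fc = g["gene"].map(de["log2FC"])
    fdr = g["gene"].map(de["FDR"])
    if direction == "CR":
        de_flag = (fc > 0) & (fdr < de_fdr)
        cnv_target = "gain"
        switch_classes = ("AA", "BA")
    else:
        de_flag = (fc < 0) & (fdr < de_fdr)
        cnv_target = "loss"
        switch_classes = ("AB", "BB")
    cnv = g["gene"].map(cnv_classes.set_index("gene")["cnv_class"])
    cnv_flag = cnv == cnv_target
    switch_ivs = [iv for cls in switch_classes for iv in switch_regions.get(cls, [])]
    switch_flag = _genes_overlapping(g, switch_ivs)
    anchor_flag = _genes_overlapping(g, anchor_regions)
    boundary_flag = _genes_overlapping(g, boundary_regions)

    out = pd.DataFrame({
        "gene": g["gene"],
        "flag_de": de_flag.fillna(False).to_numpy(dtype=bool),
        "flag_cnv": cnv_flag.fillna(False).to_numpy(dtype=bool),
        "flag_compartment": switch_flag,
        "flag_anchor": anchor_flag,
        "flag_boundary": boundary_flag,
    })
    out["importance"] = out[["flag_de", "flag_cnv", "flag_compartment",
                             "flag_anchor", "flag_boundary"]].sum(axis=1).astype(int)
    return out


def select_important(matrix: pd.DataFrame, min_evidence: int = 4) -> pd.DataFrame:
    """Genes whose importance score reaches ``min_evidence`` (default 4 of 5)."""
    return matrix[matrix["importance"] >= min_evidence].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Optical density
# ---------------------------------------------------------------------------

def optical_density(mean_intensity) -> np.ndarray:
    """``OD = log10(255 / mean intensity)`` per measurement; intensities must
    lie in (0, 255]."""
    x = np.asarray(mean_intensity, dtype=float)
    if np.any(x <= 0) or np.any(x > 255):
        raise ValueError("mean intensities must be in (0, 255]")
    return np.log10(255.0 / x)


def optical_density_stats(intensities_a, intensities_b):
    """Per-group optical densities and a Welch two-sided t-test p-value.

    Identical groups (zero t) report p = 1.
    """
    od_a = optical_density(intensities_a)
    od_b = optical_density(intensities_b)
    if np.allclose(od_a.mean(), od_b.mean()) and od_a.std() == 0 and od_b.std() == 0:
        return od_a, od_b, 1.0
    t, p = stats.ttest_ind(od_a, od_b, equal_var=False)
    if np.isnan(p):
        p = 1.0 if np.isclose(od_a.mean(), od_b.mean()) else 0.0
    return od_a, od_b, float(p)
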