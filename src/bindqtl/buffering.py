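"""Buffering analyses: when does a motif change *not* change occupancy?

Four views of context dependence: the per-substitution effect grid
(position x allele pair), the occupancy-decile curve (effects are depleted
at the weakest and strongest sites), perturbation magnitude vs motif
strength among significant SNPs, mutual information between core sequence
context and whether a SNP elsewhere in the core affects occupancy (with a
resampling null), and a 3-cluster view of standardized occupancy.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .assoc import AssociationResult, estimate_fdr

DEFAULT_MIN_OBS = 3
DEFAULT_FDR = 0.01
MI_FDR_FLAGS = 0.05
MI_MIN_ROW = 5
DEFAULT_N_BOOT = 2000


def substitution_table(
    positions: Sequence[int],
    allele_pairs: Sequence[tuple],
    significant: Sequence[bool],
    min_obs: int = DEFAULT_MIN_OBS,
) -> pd.DataFrame:
    """Effect proportion per (motif position, unordered allele pair).

    Cells observed at fewer than ``min_obs`` sites are suppressed.  The
    returned grid conserves counts: total n_observed equals the number of
    input SNPs.
    """
    rows: Dict[tuple, list] = {}
    for pos, pair, sig in zip(positions, allele_pairs, significant):
        key = (pos, "/".join(sorted(pair)))
        rows.setdefault(key, [0, 0])
        rows[key][0] += 1
        rows[key][1] += bool(sig)
    out = pd.DataFrame(
        [(k[0], k[1], v[0], v[1], v[1] / v[0]) for k, v in sorted(rows.items())],
        columns=["position", "alleles", "n_observed", "n_significant", "proportion"],
    )
    out["suppressed"] = out["n_observed"] < min_obs
    return out


def decile_curve(results: Sequence[AssociationResult], fdr: float = DEFAULT_FDR,
                 n_bins: int = 10) -> pd.DataFrame:
    """Proportion of significant SNPs per decile of fitted heterozygote signal.

    Sites are ranked by the regression's heterozygote signal and cut into
    ``n_bins`` equal-count bins (ties broken by stable site order); a
    saturating occupancy mechanism predicts an interior maximum.
    """
    res = [r for r in results if np.isfinite(r.het_signal) and np.isfinite(r.q)]
    if len(res) < n_bins:
        raise ValueError(f"need at least {n_bins} sites for a decile curve")
    order = np.argsort([r.het_signal for r in res], kind="mergesort")
    edges = np.linspace(0, len(res), n_bins + 1).astype(int)
    rows = []
    for b in range(n_bins):
        idx = order[edges[b]:edges[b + 1]]
        sig = [res[i].q < fdr for i in idx]
        sigs = [res[i].het_signal for i in idx]
        rows.append((b + 1, len(idx), int(np.sum(sig)),
                     float(np.mean(sig)) if len(idx) else np.nan,
                     float(np.median(sigs)) if len(idx) else np.nan))
    return pd.DataFrame(rows, columns=["decile", "n", "n_significant",
                                       "proportion", "median_signal"])


def strength_vs_perturbation(
    motif_scores: Sequence[float],
    deltas: Sequence[float],
    significant: Sequence[bool],
    n_bins: int = 6,
) -> dict:
    """Mean |allele delta| by motif-score bin, for significant and
    non-significant SNPs, plus a linear trend test on the significant set.

    Stronger motifs tolerate mild perturbations, so among SNPs that *do*
    change occupancy the delta should rise with motif score; the
    non-significant stratum should show no such trend.
    """
    ms = np.asarray(motif_scores, float)
    dl = np.asarray(deltas, float)
    sg = np.asarray(significant, bool)
    edges = np.quantile(ms, np.linspace(0, 1, n_bins + 1))
    edges[-1] += 1e-9
    tables = {}
    for name, mask in (("significant", sg), ("nonsignificant", ~sg)):
        rows = []
        for b in range(n_bins):
            sel = mask & (ms >= edges[b]) & (ms < edges[b + 1])
            if sel.sum() == 0:
                continue
            rows.append((float(edges[b]), int(sel.sum()), float(dl[sel].mean()),
                         float(dl[sel].std(ddof=0))))
        tables[name] = pd.DataFrame(rows, columns=["bin_lower", "n",
                                                   "mean_delta", "sd_delta"])
    trends = {}
    for name, mask in (("significant", sg), ("nonsignificant", ~sg)):
        if mask.sum() >= 3 and np.ptp(ms[mask]) > 0:
            lr = stats.linregress(ms[mask], dl[mask])
            trends[name] = {"slope": float(lr.slope), "p": float(lr.pvalue)}
        else:
            trends[name] = {"slope": np.nan, "p": np.nan}
    return {"tables": tables, "trend": trends}


# -- mutual information ----------------------------------------------------

def mutual_information_bits(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information (bits) between two discrete variables."""
    xv, xi = np.unique(x, return_inverse=True)
    yv, yi = np.unique(y, return_inverse=True)
    tab = np.zeros((len(xv), len(yv)))
    np.add.at(tab, (xi, yi), 1.0)
    p = tab / tab.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = p * np.log2(p / (px * py))
    return float(np.where(p > 0, t, 0.0).sum())


def _mi_perm_null(bases: np.ndarray, flags: np.ndarray, n_boot: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Null MI values from permuting the affected/unaffected flags."""
    n = len(flags)
    perm = rng.permuted(np.tile(flags.astype(np.int8), (n_boot, 1)), axis=1)
    cats = np.unique(bases)
    n_tot = float(n)
    n1 = perm.sum(axis=1).astype(float)           # affected count (fixed)
    mi = np.zeros(n_boot)
    p1 = n1 / n_tot
    p0 = 1.0 - p1
    for c in cats:
        sel = bases == c
        nc = float(sel.sum())
        c1 = perm[:, sel].sum(axis=1).astype(float)
        c0 = nc - c1
        pc = nc / n_tot
        for cnt, pf in ((c1, p1), (c0, p0)):
            pj = cnt / n_tot
            with np.errstate(divide="ignore", invalid="ignore"):
                term = pj * np.log2(pj / (pc * pf))
            mi += np.where((pj > 0) & (pf > 0), term, 0.0)
    return mi


def mutual_info_context(
    core_seqs: np.ndarray,        # (n_snp_sites, core_width) int codes
    snp_positions: np.ndarray,    # (n_snp_sites,) core position of the site's SNP
    affected: np.ndarray,         # (n_snp_sites,) bool, FDR-5% significance flag
    n_boot: int = DEFAULT_N_BOOT,
    min_row: int = MI_MIN_ROW,
    rng: Optional[np.random.Generator] = None,
    case_bootstrap: bool = False,
    fdr_method: str = "storey",
) -> pd.DataFrame:
    """MI between context base at position j and the affected flag of SNPs
    at position k, for all ordered core position pairs (j != k).

    Rows (SNP positions) with fewer than ``min_row`` SNPs are suppressed.
    Null p-values permute the flags among the row's sites (``case_bootstrap``
    instead resamples sites with replacement); q-values span all pairs.
    """
    if rng is None:
        rng = np.random.default_rng()
    width = core_seqs.shape[1]
    rows = []
    for k in range(width):
        sel = snp_positions == k
        n = int(sel.sum())
        if n < min_row:
            continue
        flags = affected[sel].astype(np.int8)
        if flags.min() == flags.max():
            continue  # constant flag: MI trivially 0 with a degenerate null
        for j in range(width):
            if j == k:
                continue
            bases = core_seqs[sel, j]
            mi = mutual_information_bits(bases, flags)
            if case_bootstrap:
                null = np.empty(n_boot)
                for t in range(n_boot):
                    idx = rng.integers(n, size=n)
                    null[t] = mutual_information_bits(bases[idx],
                                                      np.random.permutation(flags)[idx])
            else:
                null = _mi_perm_null(bases, flags, n_boot, rng)
            p = (1.0 + float((null >= mi - 1e-12).sum())) / (n_boot + 1.0)
            rows.append((k, j, n, mi, p))
    out = pd.DataFrame(rows, columns=["snp_position", "context_position",
                                      "n_snps", "mi_bits", "p"])
    out["q"] = (estimate_fdr(out["p"].to_numpy(), method=fdr_method)
                if len(out) else np.nan)
    return out


def cluster_occupancy(standardized: pd.DataFrame, k: int = 3,
                      significant: Optional[Dict[str, bool]] = None,
                      intensity: Optional[Dict[str, float]] = None) -> dict:
    """Ward-linkage hierarchical clustering of standardized occupancy.

    Cuts the dendrogram at ``k`` clusters and summarises each cluster's mean
    intensity and significant-SNP proportion.  The partition is invariant to
    row order.
    """
    if k > len(standardized):
        raise ValueError(f"k={k} exceeds the number of sites {len(standardized)}")
    # canonical row order so that the partition ignores input ordering
    mat = standardized.sort_index(kind="mergesort")
    if k == 1:
        labels = np.ones(len(mat), dtype=int)
    else:
        Z = linkage(mat.to_numpy(), method="ward", metric="euclidean")
        labels = fcluster(Z, t=k, criterion="maxclust")
    assign = pd.Series(labels, index=mat.index, name="cluster")
    summary = []
    for c in sorted(set(labels)):
        ids = assign.index[assign == c]
        row = {"cluster": int(c), "n_sites": int(len(ids))}
        if intensity is not None:
            vals = [intensity[s] for s in ids if s in intensity]
            row["mean_intensity"] = float(np.mean(vals)) if vals else np.nan
        if significant is not None:
            flags = [significant[s] for s in ids if s in significant]
            row["frac_significant"] = float(np.mean(flags)) if flags else np.nan
        summary.append(row)
    return {"labels": assign, "summary": pd.DataFrame(summary)}
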