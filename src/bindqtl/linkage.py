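"""Aggregate Haseman-Elston sib-pair linkage on differential occupancy.

Differentially occupied sites are found with an in-house negative-binomial
likelihood-ratio test (sample effect vs replicate-only null, pooled trended
dispersion).  Counts are then variance-stabilised, standardised per site,
replicate-averaged, and squared sib-pair trait differences are regressed on
truth IBD (0/0.5/1) pooled over all sites and all 15 pairs.  A negative
slope evidences heritability; significance comes from a structure-preserving
permutation that reassigns whole per-site IBD vectors to random per-site
difference vectors.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .nbglm import fit_nbglm, nb_lrt, robust_log_trend

IBD_UNCERTAINTY_MAX = 0.05


# -- differential occupancy ------------------------------------------------

@dataclass
class DifferentialResult:
    table: pd.DataFrame          # site_id, mean, theta_trend, lrt_stat, p, q, excluded
    alpha: float

    @property
    def significant_sites(self) -> list:
        t = self.table
        return t.loc[(~t["excluded"]) & (t["q"] < self.alpha), "site_id"].tolist()


def _design_matrices(samples: np.ndarray, replicates: np.ndarray):
    s_levels = sorted(set(samples))
    r_levels = sorted(set(replicates))
    n = len(samples)
    X_null = [np.ones(n)]
    for lev in r_levels[1:]:
        X_null.append((replicates == lev).astype(float))
    X_full = list(X_null)
    for lev in s_levels[1:]:
        X_full.append((samples == lev).astype(float))
    return np.column_stack(X_full), np.column_stack(X_null), len(s_levels)


def differential_sites(
    counts: pd.DataFrame,
    samples: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
) -> DifferentialResult:
    """Per-site NB LRT of a sample effect against a replicate-only null.

    Dispersion is estimated per site by ML under the full model, then
    replaced by a trended value (log-linear fit of dispersion on mean across
    sites) so that low-count sites borrow strength; the LRT at each site
    uses its trended dispersion.  Requires >=2 replicates in at least half
    the samples for a dispersion estimate; all-zero sites are excluded.
    BH-adjusted q-values at level ``alpha``.
    """
    df = counts if samples is None else counts[counts["sample"].isin(samples)]
    rows = []
    per_site = []
    for site_id, grp in df.groupby("site_id", sort=False):
        y = grp["count"].to_numpy(float)
        s = grp["sample"].to_numpy()
        r = grp["replicate"].to_numpy()
        n_multi = sum(1 for _, g in grp.groupby("sample") if len(g) >= 2)
        n_samp = grp["sample"].nunique()
        if n_multi < max(1, n_samp // 2):
            per_site.append((site_id, y, s, r, "no dispersion estimate"))
            continue
        if y.sum() == 0:
            per_site.append((site_id, y, s, r, "all-zero"))
            continue
        per_site.append((site_id, y, s, r, None))

    # pass 1: per-site moment dispersion from within-sample replicate
    # variability on size-factor-normalized counts.  Sample-to-sample shifts
    # do not enter this estimator, so genuinely differential sites keep an
    # honest dispersion; the residual degrees of freedom (points - samples)
    # correct the small-sample bias.
    lib = df.groupby(["sample", "replicate"])["count"].sum()
    geo = np.exp(np.log(lib[lib > 0]).mean())
    size = (lib / geo).to_dict()
    means, alphas = [], []
    for site_id, y, s, r, reason in per_site:
        if reason is not None:
            continue
        sf = np.array([size.get((si, ri), 1.0) for si, ri in zip(s, r)])
        yn = y / np.maximum(sf, 1e-9)
        ss = 0.0
        ndf = len(y) - len(set(s))
        for samp in set(s):
            sel = s == samp
            ss += float(((yn[sel] - yn[sel].mean()) ** 2).sum())
        if ndf <= 0:
            continue
        w = ss / ndf
        mu_bar = float(yn.mean())
        xi = float(np.mean(1.0 / np.maximum(sf, 1e-9)))
        if mu_bar <= 0:
            continue
        alphas.append(max(1e-4, (w - xi * mu_bar) / mu_bar ** 2))
        means.append(mu_bar)
    thetas = [1.0 / a for a in alphas]
    if not means:
        return DifferentialResult(pd.DataFrame(
            columns=["site_id", "mean", "theta_trend", "lrt_stat", "p", "q",
                     "excluded", "reason"]), alpha)
    # robust trend through binned medians ignores the heavy right tail of
    # per-site moment estimates
    trend = robust_log_trend(means, np.clip(np.asarray(thetas), 1e-2, 1e4))

    # pass 2: LRT at the trended dispersion
    for site_id, y, s, r, reason in per_site:
        if reason is not None:
            rows.append((site_id, float(np.mean(y)), np.nan, np.nan, np.nan,
                         True, reason))
            continue
        X_full, X_null, _ = _design_matrices(s, r)
        th = trend(float(y.mean()))
        try:
            stat, dfree, p = nb_lrt(y, X_full, X_null, theta=th)
        except Exception:
            rows.append((site_id, float(np.mean(y)), th, np.nan, np.nan,
                         True, "fit failure"))
            continue
        rows.append((site_id, float(np.mean(y)), th, stat, p, False, ""))
    table = pd.DataFrame(rows, columns=["site_id", "mean", "theta_trend",
                                        "lrt_stat", "p", "excluded", "reason"])
    table["q"] = np.nan
    ok = ~table["excluded"]
    if ok.any():
        from .assoc import bh_qvalues
        table.loc[ok, "q"] = bh_qvalues(table.loc[ok, "p"].to_numpy())
    return DifferentialResult(table, alpha)


# -- variance stabilisation ------------------------------------------------

def vst(counts, theta: float):
    """NB variance-stabilising map (inverse-hyperbolic-sine family):
    v(x) = 2*sqrt(theta)*asinh(sqrt(x/theta)), constant-variance for
    Var = mu + mu^2/theta."""
    x = np.asarray(counts, dtype=float)
    return 2.0 * np.sqrt(theta) * np.arcsinh(np.sqrt(x / theta))


def vst_standardize(counts: pd.DataFrame, theta: float,
                    samples: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Transform, standardise per site, then average replicates.

    Each site's transformed values are centred to mean 0 / sd 1 across all
    its data points, then replicates are averaged per sample.  Zero-variance
    sites are dropped.  Returns a site x sample DataFrame.
    """
    df = counts if samples is None else counts[counts["sample"].isin(samples)]
    out = {}
    for site_id, grp in df.groupby("site_id", sort=False):
        v = vst(grp["count"].to_numpy(), theta)
        sd = v.std(ddof=0)
        if sd <= 1e-10 * (1.0 + abs(float(v.mean()))):  # constant site
            continue
        z = (v - v.mean()) / sd
        out[site_id] = pd.Series(z, index=grp["sample"].to_numpy()).groupby(level=0).mean()
    return pd.DataFrame(out).T  # sites x samples


# -- Haseman-Elston --------------------------------------------------------

def sibpair_records(
    trait: pd.DataFrame,          # site x sample standardized trait
    ibd: np.ndarray,              # (n_all_sites, n_pairs) truth IBD
    ibd_uncertainty: np.ndarray,
    sib_pairs: Sequence[tuple],
    site_index: dict,             # site_id -> row of ibd
) -> pd.DataFrame:
    """Squared sib-pair trait differences joined to per-site IBD bins.

    Pairs whose IBD uncertainty exceeds 0.05 at a site are excluded.
    """
    rows = []
    for site_id, tr in trait.iterrows():
        si = site_index[site_id]
        for pi, (a, b) in enumerate(sib_pairs):
            if a not in tr.index or b not in tr.index:
                continue
            excl = ibd_uncertainty[si, pi] > IBD_UNCERTAINTY_MAX
            rows.append((site_id, f"{a}-{b}", float((tr[a] - tr[b]) ** 2),
                         float(ibd[si, pi]), excl))
    return pd.DataFrame(rows, columns=["site_id", "pair", "sq_diff", "ibd",
                                       "excluded"])


def he_regress(records: pd.DataFrame):
    """OLS of squared trait differences on the IBD bin, pooled over all
    sites and pairs.  Returns (slope, intercept); negative slope indicates
    heritability.  Raises when only one IBD bin is present."""
    df = records[~records["excluded"]]
    x, y = df["ibd"].to_numpy(float), df["sq_diff"].to_numpy(float)
    if np.unique(x).size < 2:
        raise ValueError("Haseman-Elston slope undefined with a single IBD bin")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def permutation_pvalue(records: pd.DataFrame, n_perm: int = 10000,
                       rng: Optional[np.random.Generator] = None,
                       with_replacement: bool = False):
    """One-sided permutation p for a negative HE slope.

    Each permutation reassigns whole per-site IBD vectors (all pair values
    kept together, preserving the correlation structure of measuring 15
    pairs from one family) to randomly chosen per-site squared-difference
    vectors.  p = (1 + #{perm slope <= observed}) / (n_perm + 1).
    """
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations gives a coarse p-value")
    if rng is None:
        rng = np.random.default_rng()
    df = records[~records["excluded"]]
    sites = df["site_id"].unique()
    if len(sites) < 2:
        raise ValueError("permutation requires >=2 sites")
    obs, _ = he_regress(records)
    # per-site aligned arrays over pairs
    piv_sq = df.pivot_table(index="site_id", columns="pair", values="sq_diff")
    piv_ibd = df.pivot_table(index="site_id", columns="pair", values="ibd")
    sq = piv_sq.to_numpy()
    ib = piv_ibd.to_numpy()
    n_sites = sq.shape[0]
    count = 0
    slopes = np.empty(n_perm)
    for t in range(n_perm):
        if with_replacement:
            perm = rng.integers(n_sites, size=n_sites)
        else:
            perm = rng.permutation(n_sites)
        x = ib[perm].ravel()
        y = sq.ravel()
        ok = ~(np.isnan(x) | np.isnan(y))
        s = np.polyfit(x[ok], y[ok], 1)[0]
        slopes[t] = s
        count += s <= obs
    p = (1.0 + count) / (n_perm + 1.0)
    return float(p), slopes


def stratified_he(
    trait: pd.DataFrame,
    ibd: np.ndarray,
    ibd_uncertainty: np.ndarray,
    sib_pairs: Sequence[tuple],
    site_index: dict,
    associated_sites: set,
    n_perm: int = 10000,
    rng: Optional[np.random.Generator] = None,
) -> dict:
    """HE regression run separately on SNP-associated and unassociated
    differential sites (the positive-control / residual-heritability split)."""
    out = {}
    for label, keep in (("associated", lambda s: s in associated_sites),
                        ("unassociated", lambda s: s not in associated_sites)):
        sub = trait.loc[[s for s in trait.index if keep(s)]]
        if len(sub) < 2:
            out[label] = {"slope": np.nan, "intercept": np.nan, "p": np.nan,
                          "n_sites": len(sub)}
            continue
        rec = sibpair_records(sub, ibd, ibd_uncertainty, sib_pairs, site_index)
        slope, intercept = he_regress(rec)
        p, _ = permutation_pvalue(rec, n_perm=n_perm, rng=rng)
        out[label] = {"slope": slope, "intercept": intercept, "p": p,
                      "n_sites": len(sub)}
    return out
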