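"""Allele-specific occupancy at heterozygous sites.

Within a heterozygote, reads informative for the two alleles are compared
against a 50:50 null with a one-degree-of-freedom chi-squared test (no
continuity correction).  Records need >=13 pooled reads and equal allele
mappability; when several samples are testable at one site, the sample with
the most reads represents the site.
"""
from __future__ import annotations

from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import estimate_fdr

DEFAULT_MIN_COV = 13
#: FDR presets: 0.1% headline, 0.005% conservative alternative
FDR_PRESETS = {"default": 1e-3, "conservative": 5e-5}


def select_het_testable(
    allele_counts: pd.DataFrame,
    mappability_pass: Optional[Dict[str, bool]] = None,
    allele_differential: Optional[Dict[str, bool]] = None,
    min_cov: int = DEFAULT_MIN_COV,
) -> pd.DataFrame:
    """Filter allele-count records to the testable set.

    Requires pooled coverage >= ``min_cov``, a passing site mappability
    report, and non-differential allele mappability.
    """
    df = allele_counts.copy()
    df["total"] = df["reads_a"] + df["reads_b"]
    keep = df["total"] >= min_cov
    if mappability_pass is not None:
        keep &= df["site_id"].map(lambda s: mappability_pass.get(s, True))
    if allele_differential is not None:
        keep &= ~df["site_id"].map(lambda s: allele_differential.get(s, False))
    return df[keep].reset_index(drop=True)


def allele_chisq(reads_a: int, reads_b: int) -> float:
    """Two-sided chi-squared (1 df) p-value against a 50:50 read split."""
    total = reads_a + reads_b
    if total <= 0:
        raise ValueError("allele_chisq requires at least one read")
    e = total / 2.0
    stat = (reads_a - e) ** 2 / e + (reads_b - e) ** 2 / e
    return float(stats.chi2.sf(stat, 1))


def representative_sample(site_records: pd.DataFrame) -> pd.Series:
    """The record with the most total reads; ties go to the first sample id."""
    df = site_records
    totals = df["reads_a"] + df["reads_b"]
    best = totals == totals.max()
    sub = df[best].sort_values("sample", kind="mergesort")
    return sub.iloc[0]


def analyze(
    allele_counts: pd.DataFrame,
    mappability_pass: Optional[Dict[str, bool]] = None,
    allele_differential: Optional[Dict[str, bool]] = None,
    min_cov: int = DEFAULT_MIN_COV,
    fdr_method: str = "storey",
) -> pd.DataFrame:
    """Test every testable record, mark site representatives, attach
    q-values (computed over the representative records, one per site)."""
    df = select_het_testable(allele_counts, mappability_pass,
                             allele_differential, min_cov)
    if df.empty:
        return df.assign(p=[], q=[], representative=[])
    df["p"] = [allele_chisq(a, b) for a, b in zip(df["reads_a"], df["reads_b"])]
    rep_idx = []
    for _, grp in df.groupby("site_id", sort=False):
        rep_idx.append(representative_sample(grp).name)
    df["representative"] = df.index.isin(rep_idx)
    df["q"] = np.nan
    reps = df["representative"]
    df.loc[reps, "q"] = estimate_fdr(df.loc[reps, "p"].to_numpy(), method=fdr_method)
    return df
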