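"""SNP calling from resequencing pileups and pedigree consistency screens.

Calls are biallelic with the study's filters: >=8x coverage per sample,
Phred-scaled site quality >=30, heterozygotes require >=20% of reads on the
minor allele, and every site must segregate Mendelianly through the
three-generation pedigree.  Genotypes are coded as copies of allele B (the
alphabetically later allele); missing is -1.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from ._util import BASES
from .synth import Pedigree, PedigreeSpec

MISSING = -1
DEFAULT_MIN_COV = 8
DEFAULT_MIN_QUAL = 30.0
DEFAULT_MIN_MINOR_FRAC = 0.2
# fraction of pooled reads above which a third allele voids the site
MULTIALLELIC_FLOOR = 0.05
# assumed per-base miscall rate of the quality model (synthetic stand-in for
# a sequencing-caller's site quality; labelled as such in outputs)
QUAL_ERROR_RATE = 0.01


@dataclass
class SnpCall:
    snp_id: str
    allele_a: str                  # alphabetically first
    allele_b: str
    quality: float                 # Phred-scaled site quality (synthetic model)
    genotypes: Dict[str, int]      # sample -> 0/1/2 copies of allele_b, -1 missing
    filters_failed: List[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.filters_failed


def _site_quality(n_minor: int, n_total: int,
                  error_rate: float = QUAL_ERROR_RATE) -> float:
    """Phred-scaled confidence that the minor allele is not miscall noise.

    -10*log10 of the binomial tail P(X >= n_minor | n_total, error_rate/3),
    capped at 99; grows with both depth and allele purity.
    """
    if n_total == 0 or n_minor == 0:
        return 0.0
    p = stats.binom.sf(n_minor - 1, n_total, error_rate / 3.0)
    if p <= 0:
        return 99.0
    return float(min(99.0, -10.0 * np.log10(p)))


def call_snps(
    pileups: pd.DataFrame,
    min_cov: int = DEFAULT_MIN_COV,
    min_qual: float = DEFAULT_MIN_QUAL,
    min_minor_frac: float = DEFAULT_MIN_MINOR_FRAC,
) -> List[SnpCall]:
    """Call biallelic SNPs from per-sample base-count pileups.

    ``pileups`` columns: snp_id, sample, nA, nC, nG, nT.  Per sample:
    coverage < ``min_cov`` -> missing; a heterozygote is called when the
    minor allele carries >= ``min_minor_frac`` of that sample's two-allele
    reads, otherwise the majority homozygote.  Sites with a third allele
    above the noise floor are flagged multi-allelic; sites below
    ``min_qual`` fail the quality filter.
    """
    calls: List[SnpCall] = []
    base_cols = [f"n{b}" for b in BASES]
    for snp_id, grp in pileups.groupby("snp_id", sort=False):
        pooled = grp[base_cols].to_numpy().sum(axis=0)
        order = np.argsort(pooled)[::-1]
        total = int(pooled.sum())
        failed = []
        if total == 0:
            continue
        a1, a2 = int(order[0]), int(order[1])
        third = int(pooled[order[2]])
        if third >= 2 and third > MULTIALLELIC_FLOOR * total:
            failed.append("multi-allelic")
        # orient alphabetically: allele A first, B later
        ia, ib = sorted((a1, a2))
        quality = _site_quality(int(pooled[[ia, ib]].min()), int(pooled[ia] + pooled[ib]))
        if quality < min_qual:
            failed.append("quality")
        genotypes = {}
        for _, row in grp.iterrows():
            na, nb = int(row[base_cols[ia]]), int(row[base_cols[ib]])
            cov = int(sum(row[c] for c in base_cols))
            if cov < min_cov or na + nb == 0:
                genotypes[row["sample"]] = MISSING
                continue
            minor = min(na, nb)
            if minor / (na + nb) >= min_minor_frac:
                genotypes[row["sample"]] = 1
            else:
                genotypes[row["sample"]] = 0 if na > nb else 2
        calls.append(SnpCall(snp_id=snp_id, allele_a=BASES[ia], allele_b=BASES[ib],
                             quality=quality, genotypes=genotypes,
                             filters_failed=failed))
    return calls


# -- Mendelian screen ------------------------------------------------------

def _gametes(genotype: int) -> set:
    """Possible transmitted allele counts (0 or 1 copies of B) for a parent."""
    if genotype == MISSING:
        return {0, 1}
    return {0: {0}, 1: {0, 1}, 2: {1}}[genotype]


def trio_consistent(child: int, father: int, mother: int) -> bool:
    """Whether a biallelic genotype triple is reachable under Mendelian
    transmission; missing genotypes are unconstrained."""
    if child == MISSING:
        return True
    return any(child == a + b for a in _gametes(father) for b in _gametes(mother))


def mendelian_consistent(genotypes: Dict[str, int],
                         spec: PedigreeSpec) -> Tuple[bool, List[tuple]]:
    """Screen one site's genotypes against every trio in the pedigree.

    Returns (pass, offending trios); a site fails if any child with at least
    one genotyped parent is incompatible with transmission.
    """
    bad = []
    for m in spec.members:
        if m.father is None and m.mother is None:
            continue
        c = genotypes.get(m.id, MISSING)
        f = genotypes.get(m.father, MISSING)
        mo = genotypes.get(m.mother, MISSING)
        if not trio_consistent(c, f, mo):
            bad.append((m.id, m.father, m.mother))
    return (len(bad) == 0), bad


def polarize_ancestral(allele_a: str, allele_b: str,
                       outgroup: Optional[str]):
    """Polarize a SNP by an outgroup (chimpanzee-like) allele.

    Returns (ancestral, derived) when the outgroup allele matches one of the
    two alleles, else None (unpolarized).
    """
    if outgroup is None or outgroup not in (allele_a, allele_b):
        return None
    derived = allele_b if outgroup == allele_a else allele_a
    return outgroup, derived


def concordance(calls: Sequence[SnpCall], truth_genotypes: np.ndarray,
                snps, member_ids: Sequence[str]) -> dict:
    """Genotype discordance of calls vs simulator truth.

    Truth genotypes count copies of the alt allele; called genotypes count
    copies of allele B and are re-oriented per site.  Only pairs where both
    are non-missing are compared.  Raises ``ValueError`` when no loci
    overlap.
    """
    truth_by_id = {snp.snp_id: (j, snp) for j, snp in enumerate(snps)}
    per_sample = {m: [0, 0] for m in member_ids}  # mismatches, compared
    compared = mismatched = 0
    for call in calls:
        if call.snp_id not in truth_by_id:
            continue
        j, snp = truth_by_id[call.snp_id]
        if {call.allele_a, call.allele_b} != {snp.ref, snp.alt}:
            # allele set itself is wrong: every non-missing genotype mismatches
            flip = None
        else:
            flip = call.allele_b != snp.alt
        for mi, m in enumerate(member_ids):
            g = call.genotypes.get(m, MISSING)
            if g == MISSING:
                continue
            t = int(truth_genotypes[mi, j])
            g_oriented = (2 - g) if flip else g
            compared += 1
            per_sample[m][1] += 1
            if flip is None or g_oriented != t:
                mismatched += 1
                per_sample[m][0] += 1
    if compared == 0:
        raise ValueError("no overlapping non-missing genotype pairs to compare")
    return {
        "overall": mismatched / compared,
        "n_compared": compared,
        "per_sample": {m: (v[0] / v[1] if v[1] else np.nan)
                       for m, v in per_sample.items()},
    }


def screen_calls(calls: Iterable[SnpCall], spec: PedigreeSpec) -> List[SnpCall]:
    """Append the Mendelian filter to each call; returns the same list."""
    out = []
    for call in calls:
        ok, bad = mendelian_consistent(call.genotypes, spec)
        if not ok:
            call.filters_failed.append("mendelian")
        out.append(call)
    return out
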