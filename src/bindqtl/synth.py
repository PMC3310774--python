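"""Synthetic study generator.

Emulates the full data substrate of a pedigree occupancy-QTL study of a
transcription factor (CTCF-like) so that every downstream stage is testable
without any external download:

* a 12-member three-generation pedigree (4 founders, 2 second-generation
  parents, 6 full sibs) with Mendelian transmission, recombination on a
  single chromosome, and exact truth identity-by-descent per site;
* binding sites carrying a 14 bp PWM-sampled core motif centred in a 134 bp
  resequencing window, embedded in a synthetic genome;
* SNPs planted uniformly over each window, with truth genotypes derived from
  founder haplotypes;
* negative-binomially dispersed ChIP-seq counts whose mean follows a
  saturating (logistic) function of allele binding energy -- the threshold
  mechanism behind buffering;
* allele-partitioned read counts at heterozygous sites;
* resequencing pileups with base-call error; and
* a per-base conservation-like score correlated with motif information
  content.

All randomness flows from a single master seed through named substreams
(one per stage), so toggling one stage never perturbs another.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._util import BASES, decode_seq, encode_seq, revcomp, substream
from .motifs import CORE_WIDTH, PWM, default_core_pwm

DEFAULT_WINDOW = 134


class PedigreeError(ValueError):
    """Invalid pedigree topology."""


@dataclass(frozen=True)
class MemberSpec:
    id: str
    sex: str  # 'M' or 'F'
    father: Optional[str] = None
    mother: Optional[str] = None


@dataclass(frozen=True)
class PedigreeSpec:
    """Three-generation pedigree: 4 founders, 2 parents, their children."""

    members: tuple[MemberSpec, ...]

    @classmethod
    def default(cls, n_sibs: int = 6) -> "PedigreeSpec":
        """The study layout: two founder couples, one couple of their
        children, and ``n_sibs`` grandchildren (default 12 members)."""
        m = [
            MemberSpec("gf_p", "M"), MemberSpec("gm_p", "F"),
            MemberSpec("gf_m", "M"), MemberSpec("gm_m", "F"),
            MemberSpec("father", "M", "gf_p", "gm_p"),
            MemberSpec("mother", "F", "gf_m", "gm_m"),
        ]
        for i in range(n_sibs):
            m.append(MemberSpec(f"c{i + 1}", "MF"[i % 2], "father", "mother"))
        return cls(tuple(m))

    def validate(self) -> None:
        ids = [m.id for m in self.members]
        if len(set(ids)) != len(ids):
            raise PedigreeError("duplicate member ids")
        by_id = {m.id: m for m in self.members}
        founders = [m for m in self.members if m.father is None and m.mother is None]
        if len(founders) != 4:
            raise PedigreeError(f"expected exactly 4 founders, got {len(founders)}")
        founder_ids = {m.id for m in founders}
        gen2 = [m for m in self.members
                if m.father in founder_ids and m.mother in founder_ids]
        if len(gen2) != 2:
            raise PedigreeError(f"expected exactly 2 second-generation members, got {len(gen2)}")
        gen2_ids = {m.id for m in gen2}
        for m in self.members:
            if m.id in founder_ids or m.id in gen2_ids:
                continue
            if m.father not in gen2_ids or m.mother not in gen2_ids:
                raise PedigreeError(
                    f"member {m.id} is not a child of the second-generation couple")
            if by_id[m.father].sex != "M" or by_id[m.mother].sex != "F":
                raise PedigreeError(f"member {m.id} has mis-sexed parents")


@dataclass
class SimConfig:
    """Knobs of the synthetic study; defaults are the study conditions.

    ``occ_midpoint``/``occ_slope`` parameterise the saturating occupancy
    curve p(a) = 1/(1+exp(-(a-a0)/s)) on PWM log-odds a (bits): sites whose
    allele scores straddle the midpoint respond to sequence change, saturated
    sites are buffered.  ``dispersion`` is the NB size parameter theta
    (variance mu + mu^2/theta).
    """

    seed: int = 0
    n_sites: int = 500
    window_bp: int = DEFAULT_WINDOW
    read_len: int = 36
    depth: float = 50.0              # expected reads/site/replicate at full occupancy
    dispersion: float = 10.0         # NB theta
    batch_factors: tuple = (1.0, 0.8)
    occ_midpoint: float = 14.0       # a0, bits
    occ_slope: float = 1.5           # s, bits
    snp_rate: float = 0.9            # per-site probability of >=1 planted SNP
    extra_snp_rate: float = 0.15     # probability of a second SNP given one
    recomb_rate: float = 1e-8        # Morgans per bp
    site_spacing: int = 3000         # bp between site window starts (synthetic contig)
    #: genetic distance between adjacent sites (Morgans).  Binding sites in a
    #: real survey are scattered genome-wide, so adjacent catalog entries are
    #: near-independent meioses; None falls back to site_spacing*recomb_rate
    #: (a single physically contiguous region).
    site_genetic_spacing: Optional[float] = 0.05
    pileup_depth: float = 50.0       # mean resequencing coverage
    base_error: float = 0.01
    conservation_noise_sd: float = 1.5
    truth_threshold: float = 0.2     # relative occupancy difference -> functional
    ibd_uncertainty_rate: float = 0.0
    outgroup_missing_rate: float = 0.05
    single_replicate_sample: Optional[str] = "c6"

    def validate(self) -> None:
        for name in ("snp_rate", "extra_snp_rate", "base_error",
                     "ibd_uncertainty_rate", "outgroup_missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0,1]")
        if self.depth <= 0 or self.dispersion <= 0 or self.pileup_depth <= 0:
            raise ValueError("depth, dispersion and pileup_depth must be > 0")
        if self.window_bp < CORE_WIDTH:
            raise ValueError("window_bp must be at least the motif width")
        if self.recomb_rate < 0:
            raise ValueError("recomb_rate must be >= 0")


@dataclass
class Pedigree:
    """Realised pedigree: haplotype labels per member/site and truth IBD.

    ``labels[i, s, k]`` is the founder-haplotype label (0-7) of member i's
    paternal (k=0) / maternal (k=1) chromosome at site s.  Sib-pair IBD at a
    site is the number of shared labels / 2.
    """

    spec: PedigreeSpec
    member_ids: list
    labels: np.ndarray               # (n_members, n_sites, 2) int8
    sib_ids: list
    sib_pairs: list                  # 15 (id, id) tuples
    ibd: np.ndarray                  # (n_sites, n_pairs) in {0, .5, 1}
    ibd_uncertainty: np.ndarray      # (n_sites, n_pairs) in [0,1]

    def index(self, member_id: str) -> int:
        return self.member_ids.index(member_id)


def _meiosis(parent_labels: np.ndarray, rng: np.random.Generator,
             switch_p: float) -> np.ndarray:
    """One gamete: a Markov chain over the parent's two chromosomes.

    ``switch_p`` is the Haldane recombination probability between adjacent
    sites; 0.5 means free recombination.
    """
    n = parent_labels.shape[0]
    chrom = np.empty(n, dtype=np.int8)
    chrom[0] = rng.integers(2)
    if n > 1:
        flips = rng.random(n - 1) < switch_p
        chrom[1:] = (chrom[0] + np.cumsum(flips)) % 2
    return parent_labels[np.arange(n), chrom]


def simulate_pedigree(spec: PedigreeSpec, cfg: SimConfig,
                      rng: Optional[np.random.Generator] = None) -> Pedigree:
    """Drop founder haplotype labels through the pedigree with recombination.

    Returns exact truth IBD for all sib pairs; optional per-value uncertainty
    (``cfg.ibd_uncertainty_rate``) marks a random subset of entries as
    uncertain to exercise the downstream >0.05 exclusion rule.
    """
    spec.validate()
    cfg.validate()
    if rng is None:
        rng = substream(cfg.seed, "pedigree")
    n_sites = cfg.n_sites
    # Haldane map: adjacent-site recombination fraction
    d = (cfg.site_genetic_spacing if cfg.site_genetic_spacing is not None
         else cfg.site_spacing * cfg.recomb_rate)  # Morgans
    switch_p = 0.5 * (1.0 - np.exp(-2.0 * d))

    ids = [m.id for m in spec.members]
    by_id = {m.id: m for m in spec.members}
    labels = np.zeros((len(ids), n_sites, 2), dtype=np.int8)
    founders = [m.id for m in spec.members if m.father is None]
    for fi, fid in enumerate(founders):
        labels[ids.index(fid), :, 0] = 2 * fi
        labels[ids.index(fid), :, 1] = 2 * fi + 1

    # resolve in generation order (parents before children)
    resolved = set(founders)
    pending = [m for m in spec.members if m.id not in resolved]
    while pending:
        progressed = False
        for m in list(pending):
            if m.father in resolved and m.mother in resolved:
                i = ids.index(m.id)
                labels[i, :, 0] = _meiosis(labels[ids.index(m.father)], rng, switch_p)
                labels[i, :, 1] = _meiosis(labels[ids.index(m.mother)], rng, switch_p)
                resolved.add(m.id)
                pending.remove(m)
                progressed = True
        if not progressed:  # pragma: no cover - blocked by validate()
            raise PedigreeError(f"unresolvable parentage for {pending[0].id}")

    sib_ids = [m.id for m in spec.members
               if m.father is not None and by_id[m.father].father is not None]
    sib_pairs = [(a, b) for ai, a in enumerate(sib_ids) for b in sib_ids[ai + 1:]]
    ibd = np.zeros((n_sites, len(sib_pairs)))
    for pi, (a, b) in enumerate(sib_pairs):
        la, lb = labels[ids.index(a)], labels[ids.index(b)]
        ibd[:, pi] = ((la[:, 0] == lb[:, 0]).astype(float)
                      + (la[:, 1] == lb[:, 1])) / 2.0
    unc = np.zeros_like(ibd)
    if cfg.ibd_uncertainty_rate > 0:
        mask = rng.random(ibd.shape) < cfg.ibd_uncertainty_rate
        unc[mask] = 0.05 + 0.45 * rng.random(int(mask.sum()))
    return Pedigree(spec=spec, member_ids=ids, labels=labels, sib_ids=sib_ids,
                    sib_pairs=sib_pairs, ibd=ibd, ibd_uncertainty=unc)


@dataclass
class Site:
    site_id: str
    chrom: str
    genome_start: int        # 0-based start of the window in the synthetic genome
    strand: str              # strand on which the core motif was planted
    seq: str                 # window sequence (+ genomic strand)
    core_start: int          # window coordinate of the core's leftmost base
    center: int              # window centre


@dataclass
class Snp:
    snp_id: str
    site_id: str
    site_index: int
    window_pos: int          # 0-based within the window
    genome_pos: int          # 0-based genomic
    ref: str                 # allele A (in the reference/window sequence)
    alt: str                 # allele B
    ancestral: Optional[str]
    hap_has_alt: np.ndarray  # (8,) bool, founder haplotypes carrying B
    effect_label: Optional[str] = None   # 'functional' | 'silent'
    rel_occ_diff: float = 0.0


@dataclass
class SynthStudy:
    """Everything the pipeline consumes, plus the truth tables."""

    cfg: SimConfig
    pwm: PWM
    pedigree: Pedigree
    genome: str
    chrom: str
    sites: list
    snps: list
    genotypes: np.ndarray            # (n_members, n_snps) int8, copies of alt
    counts: pd.DataFrame             # site_id, sample, replicate, count
    allele_counts: pd.DataFrame      # snp_id, site_id, sample, reads_a, reads_b
    pileups: pd.DataFrame            # snp_id, sample, nA, nC, nG, nT
    conservation: np.ndarray         # (n_sites, window) float
    samples: list
    replicates: dict                 # sample -> list of replicate labels
    site_mu: np.ndarray              # (n_sites, n_members) expected per-replicate mean (batch 1)
    hap_scores: np.ndarray           # (n_sites, 8) PWM score of each founder haplotype

    @property
    def snp_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": [s.snp_id for s in self.snps],
                "site_id": [s.site_id for s in self.snps],
                "window_pos": [s.window_pos for s in self.snps],
                "genome_pos": [s.genome_pos for s in self.snps],
                "ref": [s.ref for s in self.snps],
                "alt": [s.alt for s in self.snps],
                "ancestral": [s.ancestral for s in self.snps],
                "effect_label": [s.effect_label for s in self.snps],
                "rel_occ_diff": [s.rel_occ_diff for s in self.snps],
            }
        )


def occupancy(score, midpoint: float, slope: float):
    """Saturating occupancy p(a) = 1/(1+exp(-(a-a0)/s)); slope 0 is a step."""
    score = np.asarray(score, dtype=float)
    if slope <= 0:
        return (score > midpoint).astype(float) + 0.5 * (score == midpoint)
    return 1.0 / (1.0 + np.exp(-(score - midpoint) / slope))


def generate_sites(cfg: SimConfig, pwm: Optional[PWM] = None,
                   rng: Optional[np.random.Generator] = None):
    """Synthesise the genome, site catalog and planted SNPs.

    Each site's 14 bp core is sampled from the PWM frequency model (random
    strand) and embedded at the centre of a ``window_bp`` window in random
    flanking sequence; SNP positions are uniform over the window.  Alt
    alleles are assigned to the 8 founder haplotypes with probability 0.5
    each, which fixes every member's genotype via transmission.
    """
    cfg.validate()
    pwm = pwm or default_core_pwm()
    if rng is None:
        rng = substream(cfg.seed, "sites")
    w = cfg.window_bp
    center = w // 2
    core_start = center - CORE_WIDTH // 2
    spacing = max(cfg.site_spacing, w + 2 * cfg.read_len)
    genome_codes = rng.integers(0, 4, size=cfg.n_sites * spacing + spacing,
                                dtype=np.int8)
    sites: list[Site] = []
    snps: list[Snp] = []
    cum = pwm.freqs.cumsum(axis=1)
    for i in range(cfg.n_sites):
        gstart = spacing // 2 + i * spacing
        u = rng.random(CORE_WIDTH)
        core = (u[:, None] > cum).sum(axis=1).astype(np.int8)
        strand = "+" if rng.random() < 0.5 else "-"
        placed = core if strand == "+" else revcomp(core)
        genome_codes[gstart + core_start:gstart + core_start + CORE_WIDTH] = placed
        n_snp = 0
        if rng.random() < cfg.snp_rate:
            n_snp = 1 + (rng.random() < cfg.extra_snp_rate)
        pos = sorted(rng.choice(w, size=n_snp, replace=False)) if n_snp else []
        site = Site(site_id=f"site{i:05d}", chrom="chrS", genome_start=gstart,
                    strand=strand, seq="", core_start=core_start, center=center)
        for p in pos:
            ref_code = int(genome_codes[gstart + p])
            alt_code = int((ref_code + rng.integers(1, 4)) % 4)
            anc = None
            if rng.random() >= cfg.outgroup_missing_rate:
                anc = BASES[ref_code] if rng.random() < 0.7 else BASES[alt_code]
            snps.append(Snp(
                snp_id=f"snp{len(snps):05d}", site_id=site.site_id, site_index=i,
                window_pos=int(p), genome_pos=gstart + int(p),
                ref=BASES[ref_code], alt=BASES[alt_code], ancestral=anc,
                hap_has_alt=rng.random(8) < 0.5,
            ))
        sites.append(site)
    genome = decode_seq(genome_codes)
    for s in sites:
        s.seq = genome[s.genome_start:s.genome_start + w]
    return genome, sites, snps


def _haplotype_scores(sites: Sequence[Site], snps: Sequence[Snp], pwm: PWM):
    """PWM score of each founder haplotype's core sequence at each site.

    The reference core is scored once; each SNP falling inside the core
    shifts the score of alt-carrying haplotypes by the (strand-oriented)
    column log-odds difference.
    """
    n_sites = len(sites)
    ref_scores = np.zeros(n_sites)
    for i, site in enumerate(sites):
        codes = encode_seq(site.seq[site.core_start:site.core_start + CORE_WIDTH])
        if site.strand == "-":
            codes = revcomp(codes)
        ref_scores[i] = pwm.score(codes)
    scores = np.repeat(ref_scores[:, None], 8, axis=1)
    for snp in snps:
        site = sites[snp.site_index]
        col = snp.window_pos - site.core_start
        if not 0 <= col < CORE_WIDTH:
            continue
        ref, alt = encode_seq(snp.ref)[0], encode_seq(snp.alt)[0]
        if site.strand == "-":
            col = CORE_WIDTH - 1 - col
            ref, alt = 3 - ref, 3 - alt
        shift = float(pwm.logodds[col, alt] - pwm.logodds[col, ref])
        scores[snp.site_index, snp.hap_has_alt] += shift
    return scores, ref_scores


def simulate_counts(cfg: SimConfig, pedigree: Pedigree, sites, snps, pwm: PWM,
                    rng: Optional[np.random.Generator] = None):
    """NB ChIP-seq counts under the saturating occupancy model.

    Expected count for a member is depth * batch * (p(a1)+p(a2))/2 over the
    occupancies of its two haplotype scores; counts are NB(mu, theta).  At
    heterozygous SNPs, pooled reads are partitioned between alleles with
    probability p(a_alt)/(p(a_ref)+p(a_alt)) for the alt allele.  SNP truth
    labels ('functional' when the single-SNP relative occupancy difference
    exceeds ``cfg.truth_threshold``, else 'silent') are filled in here.
    """
    if rng is None:
        rng = substream(cfg.seed, "counts")
    hap_scores, ref_scores = _haplotype_scores(sites, snps, pwm)
    n_members = len(pedigree.member_ids)
    n_sites = len(sites)
    theta = cfg.dispersion
    a0, s = cfg.occ_midpoint, cfg.occ_slope

    # member haplotype scores and occupancies, (n_sites, n_members, 2)
    lab = np.transpose(pedigree.labels, (1, 0, 2))      # (n_sites, n_members, 2)
    mem_scores = np.take_along_axis(
        hap_scores[:, None, :].repeat(n_members, axis=1), lab.astype(np.intp), axis=2)
    occ = occupancy(mem_scores, a0, s)
    site_mu = cfg.depth * occ.mean(axis=2)              # (n_sites, n_members)

    samples = list(pedigree.member_ids)
    replicates = {}
    rows = []
    for mi, sample in enumerate(samples):
        n_rep = len(cfg.batch_factors)
        if sample == cfg.single_replicate_sample:
            n_rep = 1
        replicates[sample] = [f"r{r + 1}" for r in range(n_rep)]
        for r in range(n_rep):
            mu = np.maximum(site_mu[:, mi] * cfg.batch_factors[r], 1e-9)
            counts = rng.negative_binomial(theta, theta / (theta + mu))
            rows.append(pd.DataFrame({
                "site_id": [st.site_id for st in sites],
                "sample": sample, "replicate": f"r{r + 1}", "count": counts,
            }))
    counts = pd.concat(rows, ignore_index=True)
    pooled = counts.groupby(["site_id", "sample"], sort=False)["count"].sum()

    # truth labels and allele-partitioned counts
    arows = []
    for snp in snps:
        i = snp.site_index
        site = sites[i]
        col = snp.window_pos - site.core_start
        if 0 <= col < CORE_WIDTH:
            refc, altc = encode_seq(snp.ref)[0], encode_seq(snp.alt)[0]
            c = col
            if site.strand == "-":
                c = CORE_WIDTH - 1 - col
                refc, altc = 3 - refc, 3 - altc
            shift = float(pwm.logodds[c, altc] - pwm.logodds[c, refc])
        else:
            shift = 0.0
        # single-SNP toggle against the site's reference core
        a_ref = float(ref_scores[i])
        a_alt = a_ref + shift
        p_ref, p_alt = occupancy([a_ref, a_alt], a0, s)
        pmax = max(p_ref, p_alt)
        snp.rel_occ_diff = abs(p_ref - p_alt) / pmax if pmax > 0 else 0.0
        snp.effect_label = ("functional"
                            if snp.rel_occ_diff > cfg.truth_threshold else "silent")
        # allele-partitioned pooled counts at heterozygous members
        gt = snp.hap_has_alt[pedigree.labels[:, i, 0].astype(np.intp)].astype(int) + \
            snp.hap_has_alt[pedigree.labels[:, i, 1].astype(np.intp)].astype(int)
        denom = p_ref + p_alt
        frac_alt = 0.5 if denom <= 0 else p_alt / denom
        for mi, sample in enumerate(samples):
            if gt[mi] != 1:
                continue
            n = int(pooled.get((snp.site_id, sample), 0))
            nb = int(rng.binomial(n, frac_alt)) if n > 0 else 0
            arows.append((snp.snp_id, snp.site_id, sample, n - nb, nb))
    allele_counts = pd.DataFrame(
        arows, columns=["snp_id", "site_id", "sample", "reads_a", "reads_b"])
    return counts, allele_counts, site_mu, hap_scores


def genotype_matrix(pedigree: Pedigree, snps) -> np.ndarray:
    """(n_members, n_snps) copies of the alt allele, from haplotype labels."""
    n_members = len(pedigree.member_ids)
    g = np.zeros((n_members, len(snps)), dtype=np.int8)
    for j, snp in enumerate(snps):
        lab = pedigree.labels[:, snp.site_index, :].astype(np.intp)
        g[:, j] = (snp.hap_has_alt[lab[:, 0]].astype(np.int8)
                   + snp.hap_has_alt[lab[:, 1]])
    return g


def simulate_pileups(cfg: SimConfig, pedigree: Pedigree, snps,
                     genotypes: np.ndarray,
                     rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Resequencing pileups: Poisson coverage, per-read base-call error.

    Each read samples one of the member's two chromosomes uniformly and
    reports its allele correctly with probability 1 - base_error, otherwise
    one of the three other bases uniformly.
    """
    if rng is None:
        rng = substream(cfg.seed, "pileups")
    rows = []
    for j, snp in enumerate(snps):
        ref, alt = encode_seq(snp.ref)[0], encode_seq(snp.alt)[0]
        for mi, sample in enumerate(pedigree.member_ids):
            depth = int(rng.poisson(cfg.pileup_depth))
            counts = np.zeros(4, dtype=int)
            if depth > 0:
                g = int(genotypes[mi, j])
                n_alt_chrom = rng.binomial(depth, g / 2.0) if g in (1,) else (
                    depth if g == 2 else 0)
                true = np.full(depth, ref, dtype=np.int8)
                true[:n_alt_chrom] = alt
                err = rng.random(depth) < cfg.base_error
                if err.any():
                    true[err] = (true[err] + rng.integers(1, 4, size=int(err.sum()))) % 4
                counts = np.bincount(true, minlength=4)
            rows.append((snp.snp_id, sample, *counts.tolist()))
    return pd.DataFrame(rows, columns=["snp_id", "sample", "nA", "nC", "nG", "nT"])


def emit_conservation(cfg: SimConfig, sites, pwm: PWM,
                      noise_sd: Optional[float] = None,
                      rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Conservation-like track: core information content + Gaussian noise.

    Core position j (motif strand) scores IC_j + N(0, sd); flank positions
    are pure noise -- a stand-in for a purifying-selection score whose
    fidelity is controlled by ``noise_sd``.
    """
    if rng is None:
        rng = substream(cfg.seed, "conservation")
    if noise_sd is None:
        noise_sd = cfg.conservation_noise_sd
    ic = pwm.information_content()[-CORE_WIDTH:]
    track = rng.normal(0.0, noise_sd, size=(len(sites), cfg.window_bp)) \
        if noise_sd > 0 else np.zeros((len(sites), cfg.window_bp))
    for i, site in enumerate(sites):
        prof = ic if site.strand == "+" else ic[::-1]
        track[i, site.core_start:site.core_start + CORE_WIDTH] += prof
    return track


def generate_study(cfg: SimConfig, pwm: Optional[PWM] = None,
                   spec: Optional[PedigreeSpec] = None) -> SynthStudy:
    """Run every generator stage and bundle data plus truth."""
    cfg.validate()
    pwm = pwm or default_core_pwm()
    spec = spec or PedigreeSpec.default()
    pedigree = simulate_pedigree(spec, cfg)
    genome, sites, snps = generate_sites(cfg, pwm)
    genotypes = genotype_matrix(pedigree, snps)
    counts, allele_counts, site_mu, hap_scores = simulate_counts(
        cfg, pedigree, sites, snps, pwm)
    pileups = simulate_pileups(cfg, pedigree, snps, genotypes)
    conservation = emit_conservation(cfg, sites, pwm)
    replicates = {s: sorted(counts.loc[counts["sample"] == s, "replicate"].unique())
                  for s in pedigree.member_ids}
    return SynthStudy(
        cfg=cfg, pwm=pwm, pedigree=pedigree, genome=genome, chrom="chrS",
        sites=sites, snps=snps, genotypes=genotypes, counts=counts,
        allele_counts=allele_counts, pileups=pileups, conservation=conservation,
        samples=list(pedigree.member_ids), replicates=replicates,
        site_mu=site_mu, hap_scores=hap_scores,
    )


def emit_tags(study: SynthStudy, spread_sd: float = 30.0,
              sites: Optional[Sequence[Site]] = None,
              rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Scatter each site/sample/replicate count into read-extent tags.

    Read starts are normal around the site centre (minus half a read length)
    so the density track peaks over the motif; used to exercise the signal
    stage on realistic inputs.
    """
    if rng is None:
        rng = substream(study.cfg.seed, "tags")
    L = study.cfg.read_len
    sites = study.sites if sites is None else sites
    centers = {s.site_id: s.genome_start + s.center for s in sites}
    rows = []
    for (site_id, sample, rep), grp in study.counts.groupby(
            ["site_id", "sample", "replicate"], sort=True):
        if site_id not in centers:
            continue
        n = int(grp["count"].sum())
        if n == 0:
            continue
        starts = np.rint(rng.normal(centers[site_id] - L / 2.0, spread_sd,
                                    size=n)).astype(int)
        for st in starts:
            rows.append((study.chrom, int(st), int(st) + L, sample, rep, site_id))
    return pd.DataFrame(rows, columns=["chrom", "start", "end",
                                       "sample", "replicate", "site_id"])
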