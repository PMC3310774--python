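"""Position weight matrix models of the CTCF recognition sequence.

The binding-energetics core of the pipeline: PWM construction from base
frequencies (log-odds vs. an i.i.d. background, with a pseudo-frequency
floor), an exact score p-value by dynamic programming over a discretised
score distribution, multivalent scanning with up to three motif models, and
allele log-odds deltas for SNPs falling inside a matched motif.

Log-odds are in bits throughout.  The 14 bp core motif is indexed 0-13 from
its 5' end on the motif strand; flanking positions are negative (5') or
>= 14 (3').  The region of protein-DNA contact extends 20 bp 5' and 10 bp 3'
of the core by default (44 bp total), both offsets configurable.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._util import BASES, encode_seq, revcomp

CORE_WIDTH = 14
DEFAULT_PSEUDO = 0.01
DEFAULT_SCAN_RADIUS = 15
DEFAULT_MAX_PVALUE = 1e-2
DEFAULT_BIN_BITS = 1e-3
#: contact region spans [core_start - 20, core_end + 10] -> 44 bp
CONTACT_5P = 20
CONTACT_3P = 10

UNIFORM_BG = np.full(4, 0.25)


@dataclass(frozen=True)
class PWM:
    """A position weight matrix with frequencies and log-odds (bits).

    ``freqs`` rows are motif positions, columns are bases in ACGT order.
    Frequencies have already been floored at the pseudo-frequency and
    renormalised; ``logodds = log2(freqs / background)`` is finite.
    """

    model_id: str
    freqs: np.ndarray
    logodds: np.ndarray
    background: np.ndarray
    bin_bits: float = DEFAULT_BIN_BITS
    # lazily built survival function of the background score distribution
    _sf: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def width(self) -> int:
        return self.freqs.shape[0]

    def score(self, codes: np.ndarray) -> float:
        """Log-odds score (bits) of an encoded sequence of length ``width``."""
        return float(self.logodds[np.arange(self.width), codes].sum())

    def information_content(self) -> np.ndarray:
        """Per-position information content in bits (relative entropy vs background)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            t = self.freqs * np.log2(self.freqs / self.background)
        return np.where(self.freqs > 0, t, 0.0).sum(axis=1)

    # -- exact p-values ----------------------------------------------------

    def _score_sf(self):
        """(offset, sf) of the discretised background score distribution.

        ``sf[k]`` = P(binned score >= k + offset) for a random sequence drawn
        i.i.d. from the background, computed by per-position convolution of
        the four binned log-odds contributions.
        """
        if "sf" not in self._sf:
            binned = np.rint(self.logodds / self.bin_bits).astype(np.int64)
            dist = np.ones(1)
            cur_lo = 0  # binned score of dist[0]
            for i in range(self.width):
                b_lo, b_hi = int(binned[i].min()), int(binned[i].max())
                new_lo = cur_lo + b_lo
                new = np.zeros(len(dist) + (b_hi - b_lo))
                for b in range(4):
                    s = int(binned[i, b])
                    off = (cur_lo + s) - new_lo
                    new[off:off + len(dist)] += self.background[b] * dist
                dist, cur_lo = new, new_lo
            sf = np.cumsum(dist[::-1])[::-1]
            self._sf["sf"] = (cur_lo, sf)
        return self._sf["sf"]

    def score_pvalue(self, threshold: float) -> float:
        """Exact P(score >= threshold) under the i.i.d. background.

        Computed on scores discretised to ``bin_bits`` (default 1e-3 bits);
        thresholds beyond the achievable range give 1.0 or 0.0.
        """
        lo, sf = self._score_sf()
        k = int(np.rint(threshold / self.bin_bits)) - lo
        if k <= 0:
            return 1.0
        if k >= len(sf):
            return 0.0
        return float(sf[k])


def build_pwm(
    freq_matrix: np.ndarray,
    background: Optional[np.ndarray] = None,
    pseudo: float = DEFAULT_PSEUDO,
    model_id: str = "core",
    bin_bits: float = DEFAULT_BIN_BITS,
) -> PWM:
    """Build a PWM from a position x ACGT frequency matrix.

    Frequencies below ``pseudo`` are floored at ``pseudo`` and each position
    renormalised, then converted to log-odds (bits) against ``background``
    (uniform by default).

    Raises ``ValueError`` for negative frequencies or positions whose
    frequencies do not sum to 1 within 1e-6 before flooring.
    """
    f = np.asarray(freq_matrix, dtype=float)
    if f.ndim != 2 or f.shape[1] != 4 or f.shape[0] < 1:
        raise ValueError("frequency matrix must be (width, 4) with width >= 1")
    if (f < 0).any():
        raise ValueError("negative frequencies in PWM input")
    sums = f.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        bad = int(np.argmax(np.abs(sums - 1.0)))
        raise ValueError(f"frequencies at position {bad} sum to {sums[bad]:.6g}, not 1")
    bg = UNIFORM_BG if background is None else np.asarray(background, dtype=float)
    if bg.shape != (4,) or (bg <= 0).any():
        raise ValueError("background must be 4 positive probabilities")
    bg = bg / bg.sum()
    floored = np.maximum(f, pseudo)
    floored = floored / floored.sum(axis=1, keepdims=True)
    logodds = np.log2(floored / bg)
    return PWM(model_id=model_id, freqs=floored, logodds=logodds, background=bg,
               bin_bits=bin_bits)


def read_pwm(path, **kwargs) -> PWM:
    """Read a tab-delimited position x {A,C,G,T} frequency matrix with header."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    cols = [c for c in df.columns if c.upper() in ("A", "C", "G", "T")]
    if len(cols) != 4:
        raise ValueError(f"expected A/C/G/T columns in {path}")
    order = sorted(cols, key=lambda c: BASES.index(c.upper()))
    return build_pwm(df[order].to_numpy(), **kwargs)


def write_pwm(pwm: PWM, path) -> None:
    import pandas as pd

    pd.DataFrame(pwm.freqs, columns=list(BASES)).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class MotifMatch:
    """Best motif match at one site (single winner across models/strands)."""

    site_id: str
    offset: int          # motif-centre displacement from the window centre
    strand: str          # '+' or '-'
    score: float         # bits
    pvalue: float
    model_id: str
    start: int           # window coordinate of the motif's leftmost base (+ strand)
    width: int
    core_start: int      # window coordinate of the 14 bp core's leftmost base
    core_width: int = CORE_WIDTH


def _model_core_offset(pwm: PWM) -> int:
    """Offset of the 14 bp core within the model (variants carry an upstream module)."""
    return pwm.width - CORE_WIDTH


def scan_site(
    seq: str,
    pwms: Sequence[PWM],
    center: Optional[int] = None,
    radius: int = DEFAULT_SCAN_RADIUS,
    max_pvalue: float = DEFAULT_MAX_PVALUE,
    site_id: str = "",
) -> Optional[MotifMatch]:
    """Scan both strands of ``seq`` with every model within ``radius`` bp of centre.

    The single best match (smallest p-value) is returned, or ``None`` if the
    best p-value is >= ``max_pvalue``.  Ties at equal p-value are broken by
    higher raw score, then smaller |offset|, then the + strand.
    Offsets are displacements of the *core* centre from the window centre.
    """
    codes = encode_seq(seq)
    n = len(codes)
    if center is None:
        center = n // 2
    best = None
    best_key = None
    n_evaluated = 0
    for pwm in pwms:
        w = pwm.width
        core_off = _model_core_offset(pwm)
        idx = np.arange(w)
        for offset in range(-radius, radius + 1):
            core_start = center - CORE_WIDTH // 2 + offset
            for strand in "+-":
                if strand == "+":
                    start = core_start - core_off
                else:
                    # the upstream module sits 3' of the core in + coordinates
                    start = core_start + CORE_WIDTH + core_off - w
                if start < 0 or start + w > n:
                    continue
                n_evaluated += 1
                sub = codes[start:start + w]
                if strand == "-":
                    sub = revcomp(sub)
                score = float(pwm.logodds[idx, sub].sum())
                p = pwm.score_pvalue(score)
                key = (p, -score, abs(offset), 0 if strand == "+" else 1)
                if best_key is None or key < best_key:
                    best_key = key
                    best = MotifMatch(
                        site_id=site_id, offset=offset, strand=strand, score=score,
                        pvalue=p, model_id=pwm.model_id, start=start, width=w,
                        core_start=core_start,
                    )
    if n_evaluated == 0:
        raise ValueError(
            f"sequence of length {n} cannot cover centre {center} +/- {radius} "
            f"plus any model width")
    if best is None or best.pvalue >= max_pvalue:
        return None
    return best


def motif_relative_position(match: MotifMatch, snp_pos: int) -> int:
    """Strand-oriented position of a window-coordinate SNP relative to the core.

    Core positions are 0-13 from the core's 5' end on the motif strand;
    5' flank positions are negative, 3' flank positions >= 14.
    """
    if match.strand == "+":
        return snp_pos - match.core_start
    return (match.core_start + match.core_width - 1) - snp_pos


def in_contact_region(pos: int, core_width: int = CORE_WIDTH,
                      upstream: int = CONTACT_5P, downstream: int = CONTACT_3P) -> bool:
    """Whether a motif-relative position lies in the protein-DNA contact region.

    The default 20 bp 5' + 14 bp core + 10 bp 3' split realises the 44 bp
    contact extent; both flank widths are configurable.
    """
    return -upstream <= pos <= core_width - 1 + downstream


def allele_delta(pwm: PWM, match: MotifMatch, snp_pos: int,
                 allele_a: str, allele_b: str):
    """Log-odds difference (bits) between a SNP's alleles at its motif column.

    Returns ``(delta, favored_allele)``.  SNPs outside the matched core give
    ``(0.0, None)``; equal-scoring alleles give favored ``None``.  Alleles are
    given on the + genomic strand and complemented internally for - strand
    matches.
    """
    for a in (allele_a, allele_b):
        if a not in BASES:
            raise ValueError(f"allele {a!r} is not one of A,C,G,T")
    col = motif_relative_position(match, snp_pos)
    if not 0 <= col < match.core_width:
        return 0.0, None
    col_model = col + _model_core_offset(pwm)
    ia, ib = encode_seq(allele_a)[0], encode_seq(allele_b)[0]
    if match.strand == "-":
        ia, ib = 3 - ia, 3 - ib
    la = float(pwm.logodds[col_model, ia])
    lb = float(pwm.logodds[col_model, ib])
    delta = abs(la - lb)
    if la == lb:
        return delta, None
    return delta, (allele_a if la > lb else allele_b)


# -- default (synthetic) CTCF-like models ----------------------------------

#: Synthetic stand-in for the CTCF core motif: a GC-rich 14 bp consensus with
#: per-position confidence chosen to span strong, intermediate and degenerate
#: columns.  Real frequency matrices are inputs; this default only makes the
#: synthetic study self-contained.
_SYNTH_CONSENSUS = "CCGCGAGGTGGCAG"
_SYNTH_CONFIDENCE = (0.95, 0.97, 0.90, 0.85, 0.95, 0.60, 0.90,
                     0.97, 0.40, 0.85, 0.95, 0.97, 0.75, 0.65)


def default_core_freqs() -> np.ndarray:
    f = np.empty((CORE_WIDTH, 4))
    for i, (base, conf) in enumerate(zip(_SYNTH_CONSENSUS, _SYNTH_CONFIDENCE)):
        f[i] = (1.0 - conf) / 3.0
        f[i, BASES.index(base)] = conf
    return f


def default_core_pwm(pseudo: float = DEFAULT_PSEUDO) -> PWM:
    return build_pwm(default_core_freqs(), pseudo=pseudo, model_id="core")


def default_motif_models(pseudo: float = DEFAULT_PSEUDO,
                         spacings: Sequence[int] = (5, 6)) -> list[PWM]:
    """The canonical core model plus two multivalent variants.

    Each variant prepends an 8 bp upstream module at a configurable spacing
    (uniform-frequency spacer columns contribute zero log-odds).  CTCF binds
    multivalently; three models distinguished by the upstream module's
    presence and position emulate that mode structure.
    """
    core = default_core_freqs()
    upstream = "TGCAGTCA"
    up = np.empty((len(upstream), 4))
    for i, base in enumerate(upstream):
        up[i] = 0.1 / 3.0
        up[i, BASES.index(base)] = 0.9
    models = [build_pwm(core, pseudo=pseudo, model_id="core")]
    for k, sp in enumerate(spacings, start=1):
        spacer = np.full((sp, 4), 0.25)
        freqs = np.vstack([up, spacer, core])
        models.append(build_pwm(freqs, pseudo=pseudo, model_id=f"upstream{k}"))
    return models
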