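"""Standard-format input/output and format validation.

Coordinate conventions are centralised here: BED and all internal intervals
are 0-based half-open; VCF-like SNP records are 1-based.  Strand fields are
'+'/'-'.  TSV mirrors carry explicit headers.
"""
from __future__ import annotations

import json
from typing import Dict, Iterable, List, Optional, Sequence

import pandas as pd

from ._util import BASES
from .genotyping import MISSING, SnpCall

FLOAT_FMT = "%.6g"


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_bed(sites, path) -> None:
    """Site catalog as BED6 (0-based half-open; name = site id)."""
    with open(path, "w") as fh:
        for s in sites:
            end = s.genome_start + len(s.seq)
            fh.write(f"{s.chrom}\t{s.genome_start}\t{end}\t{s.site_id}\t0\t{s.strand}\n")


def write_vcf(calls: Sequence[SnpCall], samples: Sequence[str], path,
              chrom_pos: Optional[Dict[str, tuple]] = None) -> None:
    """Minimal VCF v4-style output (1-based POS, GT per sample)."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##INFO=<ID=SQ,Number=1,Type=Float,Description="
                 "\"Synthetic Phred-scaled site quality\">\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for c in calls:
            chrom, pos0 = (chrom_pos or {}).get(c.snp_id, ("chrS", 0))
            flt = "PASS" if c.passed else ";".join(c.filters_failed)
            gts = "\t".join(gt_map[c.genotypes.get(s, MISSING)] for s in samples)
            fh.write(f"{chrom}\t{pos0 + 1}\t{c.snp_id}\t{c.allele_a}\t{c.allele_b}"
                     f"\t{c.quality:.1f}\t{flt}\tSQ={c.quality:.1f}\tGT\t{gts}\n")


def write_genotype_tsv(calls: Sequence[SnpCall], samples: Sequence[str], path,
                       chrom_pos: Optional[Dict[str, tuple]] = None) -> None:
    """Flat genotype table: chrom, start, end, then per-sample allele pairs
    ('00' marks missing data)."""
    rows = []
    for c in calls:
        chrom, pos0 = (chrom_pos or {}).get(c.snp_id, ("chrS", 0))
        row = {"chrom": chrom, "start": pos0, "end": pos0 + 1, "snp_id": c.snp_id}
        for s in samples:
            g = c.genotypes.get(s, MISSING)
            if g == MISSING:
                row[s] = "00"
            else:
                row[s] = {0: c.allele_a * 2, 1: c.allele_a + c.allele_b,
                          2: c.allele_b * 2}[g]
        rows.append(row)
    write_tsv(pd.DataFrame(rows), path)


def write_track_bedgraph(track, chrom: str, path) -> None:
    """Normalized density as bedGraph-style TSV (one row per bin start)."""
    rows = [(chrom, int(s), int(s + track.step), float(v))
            for s, v in zip(track.bin_starts, track.values)]
    write_tsv(pd.DataFrame(rows, columns=["chrom", "start", "end", "value"]), path)


def write_json(obj, path) -> None:
    def default(o):
        try:
            return float(o)
        except Exception:  # pragma: no cover
            return str(o)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")


# -- validation ------------------------------------------------------------

def validate_bed(path) -> List[str]:
    errors = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("track", "#")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                errors.append(f"line {i}: fewer than 3 BED fields")
                continue
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError:
                errors.append(f"line {i}: non-integer coordinates")
                continue
            if end <= start:
                errors.append(f"line {i}: end <= start ({start}, {end})")
            if start < 0:
                errors.append(f"line {i}: negative start")
            if len(f) >= 6 and f[5] not in ("+", "-"):
                errors.append(f"line {i}: strand {f[5]!r} not in +/-")
    return errors


def validate_vcf(path) -> List[str]:
    errors = []
    valid_gt = {"0/0", "0/1", "1/0", "1/1", "./."}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 8:
                errors.append(f"line {i}: fewer than 8 VCF columns")
                continue
            try:
                pos = int(f[1])
                if pos < 1:
                    errors.append(f"line {i}: POS must be 1-based positive")
            except ValueError:
                errors.append(f"line {i}: non-integer POS")
            for col in (3, 4):
                if any(b not in BASES for b in f[col]):
                    errors.append(f"line {i}: non-ACGT allele {f[col]!r}")
            if len(f) > 9 and f[8].startswith("GT"):
                for j, gt in enumerate(f[9:], 10):
                    if gt.split(":")[0] not in valid_gt:
                        errors.append(f"line {i}: column {j}: bad genotype {gt!r}")
    return errors


def validate_tsv(path, required: Iterable[str] = ()) -> List[str]:
    errors = []
    try:
        df = pd.read_csv(path, sep="\t", nrows=5)
    except Exception as e:
        return [f"unreadable TSV: {e}"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        errors.append(f"line 1: missing required columns {missing}")
    return errors


def validate_io(files: Dict[str, str]) -> Dict[str, List[str]]:
    """Format report over a {kind: path} map; kinds: bed, vcf, tsv:<cols>."""
    report = {}
    for kind, path in files.items():
        if kind == "bed" or kind.startswith("bed:"):
            report[path] = validate_bed(path)
        elif kind == "vcf" or kind.startswith("vcf:"):
            report[path] = validate_vcf(path)
        elif kind.startswith("tsv"):
            cols = kind.split(":", 1)[1].split(",") if ":" in kind else ()
            report[path] = validate_tsv(path, cols)
        else:
            report[path] = [f"unknown format kind {kind!r}"]
    return report
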