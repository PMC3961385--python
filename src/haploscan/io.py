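"""Readers and writers for the pipeline's interchange formats.

Formats: pileup TSV (sample_id, pos, ref_count, alt_count, other_count;
positions 1-based on disk, 0-based in memory), a VCF v4.2 subset
(GT:GQ:PL, INFO AF/QD/FS/RPRS; read back through cyvcf2), BED tracks
(0-based half-open; name = source code, optional score), a dbSNP-like
known-variant catalogue, a site-alleles table, and plain YAML config.
All writers are atomic (write to a temp file, then rename).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from cyvcf2 import VCF

from .region import Interval

__all__ = [
    "write_pileups",
    "read_pileups",
    "write_vcf",
    "VcfData",
    "read_vcf",
    "write_bed",
    "read_bed",
    "write_catalogue",
    "read_catalogue",
    "write_sites_table",
    "read_sites_table",
    "load_config",
    "atomic_write_text",
]

PILEUP_COLUMNS = ["sample_id", "pos", "ref_count", "alt_count", "other_count"]


def atomic_write_text(path: str | Path, text: str) -> None:
    path = Path(path)
    tmp = path.with_name(path.name + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


# ---------------------------------------------------------------------------
# pileups
# ---------------------------------------------------------------------------

def write_pileups(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a pileup table (in-memory 0-based pos -> 1-based on disk)."""
    out = frame[PILEUP_COLUMNS].copy()
    out["pos"] = out["pos"] + 1
    path = Path(path)
    tmp = path.with_name(path.name + ".tmp")
    out.to_csv(tmp, sep="\t", index=False)
    os.replace(tmp, path)


def read_pileups(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    missing = set(PILEUP_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"pileup file {path} lacks columns {sorted(missing)}")
    frame["pos"] = frame["pos"] - 1
    return frame


# ---------------------------------------------------------------------------
# VCF subset
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID={chrom},length={length}>
##INFO=<ID=AF,Number=A,Type=Float,Description="Estimated cohort alternate allele frequency">
##INFO=<ID=QD,Number=1,Type=Float,Description="Variant quality by depth of variant-carrying samples">
##INFO=<ID=FS,Number=1,Type=Float,Description="Phred-scaled allele-balance exact-test p">
##INFO=<ID=RPRS,Number=1,Type=Float,Description="Rank-sum z of ref vs alt read counts across het samples">
##FILTER=<ID=LowQD,Description="QD below threshold">
##FILTER=<ID=HighFS,Description="FS above threshold">
##FILTER=<ID=LowRPRS,Description="RPRS below threshold">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##FORMAT=<ID=PL,Number=G,Type=Integer,Description="Phred-scaled genotype likelihoods">
"""


def _fmt(x: float) -> str:
    return f"{x:.4f}".rstrip("0").rstrip(".") if x == x else "."


def write_vcf(
    path: str | Path,
    positions: np.ndarray,
    ref: np.ndarray,
    alt: np.ndarray,
    sample_ids: list[str],
    genotypes: np.ndarray | None = None,
    haplotypes: np.ndarray | None = None,
    gq: np.ndarray | None = None,
    pl: np.ndarray | None = None,
    info: dict[str, np.ndarray] | None = None,
    filters: list[str] | None = None,
    ids: list[str] | None = None,
    qual: np.ndarray | None = None,
    chrom: str = "region1",
    contig_length: int | None = None,
    origin_offset: int = 0,
) -> None:
    """Write the VCF v4.2 subset dialect.

    Provide either ``genotypes`` (S x N alt dosage, -1 missing; unphased
    '/') or ``haplotypes`` (2N x S alleles; phased '|').  ``positions``
    are 0-based and written 1-based plus ``origin_offset``.
    """
    positions = np.asarray(positions)
    S = positions.size
    n = len(sample_ids)
    if (genotypes is None) == (haplotypes is None):
        raise ValueError("provide exactly one of genotypes / haplotypes")
    phased = haplotypes is not None
    length = contig_length if contig_length is not None else (origin_offset + int(positions.max(initial=0)) + 2)
    lines = [_VCF_HEADER.format(chrom=chrom, length=length)]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids) + "\n")
    fmt = "GT:GQ:PL" if (gq is not None or pl is not None) else "GT"
    for j in range(S):
        row_id = ids[j] if ids is not None else "."
        q = _fmt(float(qual[j])) if qual is not None else "."
        flt = filters[j] if filters is not None else "PASS"
        if info:
            pairs = []
            for key in ("AF", "QD", "FS", "RPRS"):
                if key in info and info[key] is not None and info[key][j] == info[key][j]:
                    pairs.append(f"{key}={_fmt(float(info[key][j]))}")
            inf = ";".join(pairs) if pairs else "."
        else:
            inf = "."
        cells = []
        for i in range(n):
            if phased:
                a0, a1 = haplotypes[2 * i, j], haplotypes[2 * i + 1, j]
                gt = ".|." if a0 < 0 or a1 < 0 else f"{a0}|{a1}"
            else:
                g = genotypes[j, i]
                gt = "./." if g < 0 else ("0/0", "0/1", "1/1")[int(g)]
            if fmt == "GT":
                cells.append(gt)
            else:
                gq_s = str(int(gq[j, i])) if gq is not None else "."
                pl_s = ",".join(str(int(x)) for x in pl[j, i]) if pl is not None else "."
                cells.append(f"{gt}:{gq_s}:{pl_s}")
        lines.append(
            f"{chrom}\t{int(positions[j]) + 1 + origin_offset}\t{row_id}\t{ref[j]}\t{alt[j]}\t{q}\t{flt}\t{inf}\t{fmt}\t"
            + "\t".join(cells)
            + "\n"
        )
    atomic_write_text(path, "".join(lines))


@dataclass
class VcfData:
    """In-memory image of the VCF subset dialect."""

    chrom: str
    positions: np.ndarray  # 0-based (origin offset removed by caller if any)
    ids: list[str]
    ref: np.ndarray
    alt: np.ndarray
    sample_ids: list[str]
    genotypes: np.ndarray  # (S, N) alt dosage, -1 missing
    gq: np.ndarray | None = None
    phased: bool = False
    haplotypes: np.ndarray | None = None  # (2N, S) when phased
    filters: list[str] = field(default_factory=list)
    info: dict[str, np.ndarray] = field(default_factory=dict)
    qual: np.ndarray | None = None


def read_vcf(path: str | Path, origin_offset: int = 0) -> VcfData:
    """Read the VCF subset through cyvcf2."""
    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    n = len(sample_ids)
    positions, ids, ref, alt, quals, filters = [], [], [], [], [], []
    geno_rows, gq_rows, hap_rows = [], [], []
    info_rows: dict[str, list[float]] = {k: [] for k in ("AF", "QD", "FS", "RPRS")}
    chrom = ""
    any_phased = True
    for v in vcf:
        chrom = v.CHROM
        positions.append(v.POS - 1 - origin_offset)
        ids.append(v.ID or ".")
        ref.append(v.REF)
        alt.append(v.ALT[0] if v.ALT else ".")
        quals.append(v.QUAL if v.QUAL is not None else np.nan)
        filters.append(v.FILTER or "PASS")
        for k in info_rows:
            val = v.INFO.get(k)
            info_rows[k].append(float(val) if val is not None else np.nan)
        g_row = np.full(n, -1, dtype=np.int8)
        h_row = np.full(2 * n, -1, dtype=np.int8)
        for i, g in enumerate(v.genotypes):
            a = [x for x in g[:-1]]
            if len(a) == 2 and a[0] >= 0 and a[1] >= 0:
                g_row[i] = a[0] + a[1]
                h_row[2 * i], h_row[2 * i + 1] = a[0], a[1]
            if not g[-1]:
                any_phased = False
        geno_rows.append(g_row)
        hap_rows.append(h_row)
        gq = v.format("GQ")
        gq_rows.append(gq[:, 0] if gq is not None else np.full(n, -1))
    S = len(positions)
    genotypes = np.array(geno_rows, dtype=np.int8) if S else np.empty((0, n), dtype=np.int8)
    haps = np.array(hap_rows, dtype=np.int8).T if S else np.empty((2 * n, 0), dtype=np.int8)
    gq_arr = np.array(gq_rows) if gq_rows and not all(np.all(r == -1) for r in gq_rows) else None
    return VcfData(
        chrom=chrom,
        positions=np.array(positions, dtype=np.int64),
        ids=ids,
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        sample_ids=sample_ids,
        genotypes=genotypes,
        gq=gq_arr,
        phased=bool(S) and any_phased,
        haplotypes=haps if S else None,
        filters=filters,
        info={k: np.array(v) for k, v in info_rows.items()},
        qual=np.array(quals),
    )


# ---------------------------------------------------------------------------
# BED tracks
# ---------------------------------------------------------------------------

def write_bed(path: str | Path, intervals: list[Interval], chrom: str = "region1") -> None:
    lines = []
    for iv in intervals:
        cols = [chrom, str(iv.start), str(iv.end), iv.name or "."]
        if iv.value is not None:
            cols.append(f"{iv.value:.2f}")
        lines.append("\t".join(cols) + "\n")
    atomic_write_text(path, "".join(lines))


def read_bed(path: str | Path) -> list[Interval]:
    """Read a BED track; rejects unsorted or malformed input with a line number."""
    out: list[Interval] = []
    last_start = -1
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        cols = line.split("\t")
        if len(cols) < 3:
            raise ValueError(f"{path}:{ln}: fewer than 3 BED columns")
        try:
            start, end = int(cols[1]), int(cols[2])
        except ValueError as exc:
            raise ValueError(f"{path}:{ln}: non-integer coordinates") from exc
        if start < last_start:
            raise ValueError(f"{path}:{ln}: track not sorted by start")
        last_start = start
        name = cols[3] if len(cols) > 3 else ""
        score = float(cols[4]) if len(cols) > 4 and cols[4] not in (".", "") else None
        out.append(Interval(start, end, name, score))
    return out


# ---------------------------------------------------------------------------
# catalogue / site-alleles / config
# ---------------------------------------------------------------------------

def write_catalogue(path: str | Path, positions: np.ndarray, ids: list[str] | None = None) -> None:
    """Known-variant catalogue: 1-based positions with dbSNP-like ids."""
    lines = ["pos\tid\n"]
    for k, p in enumerate(np.asarray(positions)):
        name = ids[k] if ids is not None else f"snv{int(p) + 1}"
        lines.append(f"{int(p) + 1}\t{name}\n")
    atomic_write_text(path, "".join(lines))


def read_catalogue(path: str | Path) -> set[int]:
    """Known positions as a 0-based set."""
    frame = pd.read_csv(path, sep="\t")
    return set(int(p) - 1 for p in frame["pos"])


def write_sites_table(path: str | Path, positions: np.ndarray, ref: np.ndarray, alt: np.ndarray) -> None:
    lines = ["pos\tref\talt\n"]
    for p, r, a in zip(np.asarray(positions), ref, alt):
        lines.append(f"{int(p) + 1}\t{r}\t{a}\n")
    atomic_write_text(path, "".join(lines))


def read_sites_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    frame["pos"] = frame["pos"] - 1
    return frame


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
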