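"""Readers and writers for every on-disk format the pipeline touches.

All tabular output is tab-separated UTF-8 with ``.`` for missing values and
optional ``#``-prefixed header lines carrying a parameter echo (a
reproducibility stamp).  Coordinate conventions are converted exactly once,
at this boundary: gene intervals are BED 0-based half-open on disk and
1-based inclusive in memory; SNP positions are 1-based everywhere.

PLINK bed/bim/fam triplets are supported read-only; writers always emit the
TSV dialects.
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import yaml

MISSING = "."

PHENOTYPE_NUMERIC = [
    "age", "bmi", "vitamin_c", "retinol", "carotene", "iron",
    "alcohol_g_day", "activity_met_day",
]


class FormatError(ValueError):
    """A file violated its declared dialect; message names file/line."""


class GeneSet(NamedTuple):
    name: str
    description: str
    genes: tuple[str, ...]


# ---------------------------------------------------------------------------
# generic TSV with '#' parameter echo
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path, *,
                params: Mapping[str, object] | None = None,
                index: bool = False) -> None:
    """Write a DataFrame as TSV, prefixed by ``# key=value`` echo lines."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in (params or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=index, na_rep=MISSING)


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table`, skipping echo lines."""
    return pd.read_csv(path, sep="\t", comment="#", na_values=[MISSING],
                       **kwargs)


def read_table_params(path: str | Path) -> dict[str, str]:
    """Recover the ``# key=value`` echo header of a TSV."""
    params: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                params[key.strip()] = value.strip()
    return params


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def write_phenotypes(cohort: pd.DataFrame, path: str | Path, *,
                     params: Mapping[str, object] | None = None) -> None:
    if "pid" not in cohort.columns:
        raise FormatError(f"{path}: phenotype table requires a 'pid' column")
    write_table(cohort, path, params=params)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = read_table(path)
    if "pid" not in df.columns:
        raise FormatError(f"{path}: missing required column 'pid'")
    if df["pid"].duplicated().any():
        dup = df.loc[df["pid"].duplicated(), "pid"].iloc[0]
        raise FormatError(f"{path}: duplicated participant id {dup!r}")
    for col in PHENOTYPE_NUMERIC:
        if col in df.columns and not pd.api.types.is_numeric_dtype(df[col]):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()
                           & df[col].notna()]
            line = int(bad[0]) + 2 if len(bad) else "?"
            raise FormatError(
                f"{path}: line {line}: column {col!r} is not numeric")
    return df


# ---------------------------------------------------------------------------
# genotypes — TSV dosage dialect and read-only PLINK triplet
# ---------------------------------------------------------------------------

def write_dosage_tsv(dosage: pd.DataFrame, snp_info: pd.DataFrame,
                     prefix: str | Path, *,
                     params: Mapping[str, object] | None = None) -> None:
    """Write a participants x SNPs dosage matrix plus a SNP map.

    Produces ``<prefix>.dosage.tsv`` (index = participant id, columns = SNP
    ids) and ``<prefix>.snps.tsv`` (snp, chrom, pos, a1, a2).
    """
    prefix = Path(prefix)
    out = dosage.copy()
    out.index.name = "pid"
    write_table(out, prefix.with_suffix(".dosage.tsv"), params=params,
                index=True)
    write_table(snp_info, prefix.with_suffix(".snps.tsv"), params=params)


def read_dosage_tsv(prefix: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    prefix = Path(prefix)
    dosage = read_table(prefix.with_suffix(".dosage.tsv"), index_col="pid")
    snp_info = read_snp_info(prefix.with_suffix(".snps.tsv"))
    missing = set(snp_info["snp"]) - set(dosage.columns)
    if missing:
        raise FormatError(f"{prefix}: SNP map lists ids absent from the "
                          f"dosage matrix: {sorted(missing)[:3]} ...")
    return dosage, snp_info


def read_snp_info(path: str | Path) -> pd.DataFrame:
    info = read_table(path)
    required = {"snp", "chrom", "pos"}
    if not required.issubset(info.columns):
        raise FormatError(f"{path}: SNP map requires columns {sorted(required)}")
    if info["snp"].duplicated().any():
        raise FormatError(f"{path}: duplicated SNP ids")
    return info


def read_plink(prefix: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a PLINK 1 bed/bim/fam triplet into (dosage, snp_info).

    The .bed payload is SNP-major, two bits per genotype:
    00 = hom A1, 10 = het, 11 = hom A2, 01 = missing.  Dosage is the A1
    allele count; missing genotypes become NaN.
    """
    prefix = Path(prefix)
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None,
                      names=["fid", "iid", "pat", "mat", "sex", "pheno"])
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None,
                      names=["chrom", "snp", "cm", "pos", "a1", "a2"])
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != b"\x6c\x1b\x01":
        raise FormatError(f"{prefix}.bed: bad magic or not SNP-major")
    n, m = len(fam), len(bim)
    stride = (n + 3) // 4
    if len(raw) - 3 != stride * m:
        raise FormatError(f"{prefix}.bed: size inconsistent with fam/bim")
    data = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, stride)
    # unpack two-bit codes, little-endian within each byte
    shifts = np.arange(4) * 2
    codes = (data[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(m, stride * 4)[:, :n]
    dose = np.empty(codes.shape, dtype=float)
    dose[codes == 0b00] = 2.0
    dose[codes == 0b10] = 1.0
    dose[codes == 0b11] = 0.0
    dose[codes == 0b01] = np.nan
    dosage = pd.DataFrame(dose.T, index=fam["iid"].astype(str).values,
                          columns=bim["snp"].values)
    dosage.index.name = "pid"
    info = bim[["snp", "chrom", "pos", "a1", "a2"]].copy()
    return dosage, info


# ---------------------------------------------------------------------------
# gene intervals (BED) and gene sets (GMT)
# ---------------------------------------------------------------------------

def write_bed(genes: pd.DataFrame, path: str | Path) -> None:
    """Write gene intervals as BED (0-based half-open) from the in-memory
    1-based inclusive representation (columns gene, chrom, start, end)."""
    out = pd.DataFrame({
        "chrom": genes["chrom"],
        "start": genes["start"].astype(int) - 1,
        "end": genes["end"].astype(int),
        "name": genes["gene"],
    })
    out.to_csv(path, sep="\t", index=False, header=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED gene intervals into 1-based inclusive (gene, chrom, start, end)."""
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: line {lineno}: BED needs >=3 columns")
            chrom, start, end = parts[0], parts[1], parts[2]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer coordinate") from exc
            if end_i < start_i:
                raise FormatError(f"{path}: line {lineno}: end < start")
            name = parts[3] if len(parts) > 3 else f"feature_{lineno}"
            rows.append((name, chrom, start_i + 1, end_i))
    genes = pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])
    if genes["gene"].duplicated().any():
        dup = genes.loc[genes["gene"].duplicated(), "gene"].iloc[0]
        raise FormatError(f"{path}: duplicated gene id {dup!r}")
    return genes


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description, *gs.genes]) + "\n")


def read_gmt(path: str | Path) -> list[GeneSet]:
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: GMT needs id, description, "
                    f">=1 gene")
            name, desc, genes = parts[0], parts[1], tuple(parts[2:])
            if name in seen:
                raise FormatError(f"{path}: line {lineno}: duplicated set id "
                                  f"{name!r}")
            seen.add(name)
            sets.append(GeneSet(name, desc, genes))
    return sets


# ---------------------------------------------------------------------------
# YAML config echo
# ---------------------------------------------------------------------------

def write_config(config: Mapping[str, object], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(dict(config), fh, sort_keys=True)


def read_config(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        loaded = yaml.safe_load(fh)
    if not isinstance(loaded, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return loaded
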