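"""Readers and writers for the package's plain-text table formats.

All writers emit deterministic, byte-stable output (fixed column order,
``\\n`` line endings, repr-stable floats) so that fixture checksums are
reproducible.  Readers are gzip-transparent: any path ending in ``.gz``
is opened through :mod:`gzip`.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import IO

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .datatypes import (SITE_COLUMNS, AlleleCountMatrix, ValidationError,
                        validate_sites)


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode, newline="" if "w" in mode else None)


# ---------------------------------------------------------------- allele TSV

def write_allele_tsv(counts: AlleleCountMatrix, path: str | Path) -> None:
    """Write counts as TSV: site columns then one ``ref,alt`` cell per sample."""
    with _open_text(path, "wt") as fh:
        fh.write("\t".join(SITE_COLUMNS + list(counts.samples)) + "\n")
        for j in range(counts.n_sites):
            site = counts.sites.iloc[j]
            cells = [f"{counts.ref[i, j]},{counts.alt[i, j]}"
                     for i in range(counts.n_samples)]
            fh.write("\t".join([str(site.site_id), str(site.gene_id),
                                str(int(site.pos)), site.ref, site.alt] + cells) + "\n")


def read_allele_tsv(path: str | Path) -> AlleleCountMatrix:
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:5] != SITE_COLUMNS:
            raise ValidationError(
                f"allele table header: expected {SITE_COLUMNS}, got {header[:5]}")
        samples = header[5:]
        if not samples:
            raise ValidationError("allele table header: no sample columns")
        rows, ref_rows, alt_rows = [], [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 5 + len(samples):
                raise ValidationError(
                    f"allele table line {lineno}: {len(parts)} fields, "
                    f"expected {5 + len(samples)}")
            rows.append(parts[:5])
            try:
                pairs = [cell.split(",") for cell in parts[5:]]
                ref_rows.append([int(r) for r, _ in pairs])
                alt_rows.append([int(a) for _, a in pairs])
            except ValueError as exc:
                raise ValidationError(
                    f"allele table line {lineno}: non-integer count ({exc})") from exc
    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    sites["pos"] = sites["pos"].astype(np.int64)
    return AlleleCountMatrix(samples=samples, sites=sites,
                             ref=np.array(ref_rows, dtype=np.int64).T,
                             alt=np.array(alt_rows, dtype=np.int64).T)


# ---------------------------------------------------------------- minimal VCF

_VCF_HEADER = [
    "##fileformat=VCFv4.2",
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">',
]


def write_allele_vcf(counts: AlleleCountMatrix, path: str | Path) -> None:
    """Minimal VCF 4.2: CHROM=gene_id, POS=1-based offset, FORMAT=AD."""
    with _open_text(path, "wt") as fh:
        for line in _VCF_HEADER:
            fh.write(line + "\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(counts.samples) + "\n")
        for j in range(counts.n_sites):
            site = counts.sites.iloc[j]
            cells = [f"{counts.ref[i, j]},{counts.alt[i, j]}"
                     for i in range(counts.n_samples)]
            fh.write("\t".join([str(site.gene_id), str(int(site.pos) + 1),
                                str(site.site_id), site.ref, site.alt,
                                ".", "PASS", ".", "AD"] + cells) + "\n")


def read_allele_vcf(path: str | Path) -> AlleleCountMatrix:
    samples: list[str] = []
    rows, ref_rows, alt_rows = [], [], []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                if len(cols) < 10 or cols[8] != "FORMAT":
                    raise ValidationError(f"VCF line {lineno}: malformed header row")
                samples = cols[9:]
                continue
            if not samples:
                raise ValidationError("VCF: data before #CHROM header")
            parts = line.split("\t")
            if len(parts) != 9 + len(samples):
                raise ValidationError(f"VCF line {lineno}: wrong field count")
            chrom, pos, site_id, ref, alt = parts[0], parts[1], parts[2], parts[3], parts[4]
            fmt = parts[8].split(":")
            try:
                ad_idx = fmt.index("AD")
            except ValueError as exc:
                raise ValidationError(f"VCF line {lineno}: no AD in FORMAT") from exc
            rows.append([site_id, chrom, int(pos) - 1, ref, alt])
            try:
                ads = [p.split(":")[ad_idx].split(",") for p in parts[9:]]
                ref_rows.append([int(a[0]) for a in ads])
                alt_rows.append([int(a[1]) for a in ads])
            except (ValueError, IndexError) as exc:
                raise ValidationError(f"VCF line {lineno}: malformed AD ({exc})") from exc
    if not samples:
        raise ValidationError("VCF: missing #CHROM header")
    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    sites["pos"] = sites["pos"].astype(np.int64)
    return AlleleCountMatrix(samples=samples, sites=validate_sites(sites),
                             ref=np.array(ref_rows, dtype=np.int64).T,
                             alt=np.array(alt_rows, dtype=np.int64).T)


# ------------------------------------------------------------- simple tables

def write_gene_catalogue(catalogue: pd.DataFrame, path: str | Path,
                         sequences: dict[str, str] | None = None,
                         fasta_path: str | Path | None = None) -> None:
    catalogue[["gene_id", "length"]].to_csv(path, sep="\t", index=False,
                                            lineterminator="\n")
    if sequences and fasta_path is not None:
        with _open_text(fasta_path, "wt") as fh:
            for gid in catalogue["gene_id"]:
                fh.write(f">{gid}\n{sequences[str(gid)]}\n")


def read_gene_catalogue(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["gene_id", "length"]:
        raise ValidationError(f"gene catalogue header: got {list(df.columns)}")
    df["length"] = df["length"].astype(np.int64)
    return df


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.reset_index().to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValidationError("metadata: missing sample_id column")
    return df.set_index("sample_id")


def write_coverage(coverage: pd.DataFrame, path: str | Path) -> None:
    coverage.reset_index(names="sample_id").to_csv(path, sep="\t", index=False,
                                                   lineterminator="\n")


def read_coverage(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValidationError("coverage: missing sample_id column")
    return df.set_index("sample_id")


def write_host_genotypes(genotypes: pd.DataFrame, path: str | Path) -> None:
    genotypes.reset_index(names="sample_id").to_csv(
        path, sep="\t", index=False, lineterminator="\n", na_rep="NA")


def read_host_genotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    if "sample_id" not in df.columns:
        raise ValidationError("host genotypes: missing sample_id column")
    df = df.set_index("sample_id")
    vals = df.to_numpy(dtype=float)
    ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
    if not ok.all():
        raise ValidationError("host genotypes: dosages must be 0/1/2 or NA")
    return df.astype("Int64")


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    """Square labelled TSV (Phylip-like with a header row)."""
    df = pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))
    df.to_csv(path, sep="\t", index_label="sample_id", lineterminator="\n")


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.to_numpy(dtype=float), ids=list(df.columns))
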