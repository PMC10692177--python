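"""Readers and writers for the interchange formats.

Formats
-------
- sumstats TSV: header with at least ``SNP`` and ``N`` plus one of ``Z`` or
  ``BETA``/``SE`` (LDSC-style); ``A1``/``A2`` are carried through for the
  caller's allele checks, never used to reorder.
- square LD: whitespace-separated numeric text (as produced by
  ``plink --r square``), optionally gzipped, or a ``.npy`` binary.
- approximation archive: ``.npz`` container plus a JSON sidecar with
  ``{strategy, b, r, p, checksum}``.
- locus definitions: BED-style TSV ``chrom  start  end  [label]`` in 0-based
  half-open coordinates (a flag converts 1-based inclusive input).
- genotype panel: plain-text integer matrix (individuals x markers), or a
  PLINK ``.raw`` additive-coded export.
- phenotype: 2-column TSV (ID, value).
"""

from __future__ import annotations

import gzip
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .core import DenseLD, LDOperator
from .ldapprox import BandedLowRankLD, LDApproximation
from .types import GenotypePanel, SummaryStats

logger = logging.getLogger("heels")

__all__ = [
    "LocusDefinition",
    "read_sumstats",
    "read_ld",
    "save_approximation",
    "load_approximation",
    "read_loci",
    "read_panel_text",
    "write_panel_text",
    "read_plink_raw",
    "read_phenotype",
    "write_phenotype",
    "write_fit_table",
    "file_checksum",
]


@dataclass
class LocusDefinition:
    """One analysis region, 0-based half-open like BED."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"locus {self.label or self.chrom}: start {self.start} >= end {self.end}"
            )


def file_checksum(path: Union[str, Path]) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def read_sumstats(path: Union[str, Path], yty: Optional[float] = None) -> SummaryStats:
    """Read an association-statistics TSV into a SummaryStats.

    With only ``Z`` (or ``BETA``/``SE``, converted to Z) the result is in
    ``z_mode``; supplying the phenotypic sum of squares ``yty`` converts the
    statistics to the exact model scale instead.  Rows with missing values
    are dropped (count logged); per-SNP sample sizes are reduced to their
    median with a warning, since the model assumes a single n.
    """
    df = pd.read_csv(path, sep=r"\s+")
    df.columns = [c.upper() for c in df.columns]
    if "SNP" not in df.columns or "N" not in df.columns:
        raise ValueError(f"{path}: required columns SNP and N are missing")
    if "Z" in df.columns:
        zcol = "Z"
        needed = ["SNP", "N", "Z"]
    elif "BETA" in df.columns and "SE" in df.columns:
        zcol = None
        needed = ["SNP", "N", "BETA", "SE"]
    elif "BETA" in df.columns:
        raise ValueError(f"{path}: BETA without SE requires a Z column or an SE column")
    else:
        raise ValueError(f"{path}: need a Z column or BETA and SE columns")
    for c in needed:
        df[c] = pd.to_numeric(df[c], errors="coerce") if c != "SNP" else df[c]
    n_before = len(df)
    df = df.dropna(subset=[c for c in needed if c != "SNP"])
    dropped = n_before - len(df)
    if dropped:
        logger.warning("%s: dropped %d rows with missing values", path, dropped)
    if df.empty:
        raise ValueError(f"{path}: no usable rows")
    n_vals = df["N"].to_numpy(dtype=float)
    if np.unique(n_vals).size > 1:
        logger.warning(
            "%s: per-SNP N varies (%.0f-%.0f); using the median — the model assumes one n",
            path, n_vals.min(), n_vals.max(),
        )
    n = int(round(float(np.median(n_vals))))
    z = df[zcol].to_numpy(float) if zcol else (df["BETA"] / df["SE"]).to_numpy(float)
    ids = df["SNP"].astype(str).tolist()
    if yty is None:
        return SummaryStats(S=z, n=n, z_mode=True, ids=ids)
    p = len(z)
    S = np.sqrt(n / p) * z * np.sqrt(yty / n)  # model-scale X'y for var(y)=yty/n
    return SummaryStats(S=S, n=n, yty=float(yty), z_mode=False, ids=ids)


def read_ld(path: Union[str, Path], fmt: Optional[str] = None) -> LDOperator:
    """Load an LD matrix or archive into an operator.

    ``fmt`` is inferred from the extension when omitted: ``.npz``/``.json``
    -> approximation archive, ``.npy`` -> binary dense, anything else ->
    square text (transparently gzipped).  Dense inputs are symmetrized as
    (R + R')/2 with the maximum asymmetry logged.
    """
    path = Path(path)
    if fmt is None:
        if path.suffix in (".npz",) or path.name.endswith(".json"):
            fmt = "approx_archive"
        elif path.suffix == ".npy":
            fmt = "binary"
        elif path.name.endswith(".gz"):
            fmt = "square_text_gz"
        else:
            fmt = "square_text"
    if fmt == "approx_archive":
        return load_approximation(path).operator()
    if fmt == "binary":
        R = np.load(path)
    elif fmt in ("square_text", "square_text_gz"):
        opener = gzip.open if fmt == "square_text_gz" else open
        with opener(path, "rt") as fh:
            R = np.loadtxt(fh)
    else:
        raise ValueError(f"unknown LD format {fmt!r}")
    R = np.atleast_2d(np.asarray(R, dtype=float))
    if R.shape[0] != R.shape[1]:
        raise ValueError(f"{path}: LD matrix is not square ({R.shape[0]}x{R.shape[1]})")
    asym = float(np.max(np.abs(R - R.T))) if R.size else 0.0
    if asym > 0:
        logger.info("%s: symmetrized LD (max asymmetry %.3g)", path, asym)
    return DenseLD((R + R.T) / 2.0)


def save_approximation(approx: LDApproximation, prefix: Union[str, Path]) -> Tuple[Path, Path]:
    """Write an approximation archive: ``<prefix>.npz`` + ``<prefix>.json``."""
    prefix = Path(prefix)
    npz_path = prefix.with_suffix(".npz")
    json_path = prefix.with_suffix(".json")
    np.savez(
        npz_path,
        banded_dense=approx.banded_dense,
        factors=approx.factors,
        eigenvalues=approx.eigenvalues,
        banded_factor=(
            approx.banded_factor if approx.banded_factor is not None else np.zeros((0, 0))
        ),
    )
    meta = {
        "strategy": approx.strategy,
        "b": int(approx.b),
        "r": int(approx.r),
        "p": int(approx.p),
        "psd_guaranteed": bool(approx.psd_guaranteed),
        "checksum": file_checksum(npz_path),
    }
    json_path.write_text(json.dumps(meta, indent=1))
    return npz_path, json_path


def load_approximation(path: Union[str, Path]) -> LDApproximation:
    """Read an approximation archive written by :func:`save_approximation`."""
    path = Path(path)
    if path.suffix == ".json":
        prefix = path.with_suffix("")
    elif path.suffix == ".npz":
        prefix = path.with_suffix("")
    else:
        prefix = path
    npz_path, json_path = prefix.with_suffix(".npz"), prefix.with_suffix(".json")
    meta = json.loads(json_path.read_text())
    if meta.get("checksum") and meta["checksum"] != file_checksum(npz_path):
        raise ValueError(f"{npz_path}: checksum mismatch against sidecar")
    data = np.load(npz_path)
    bf = data["banded_factor"]
    return LDApproximation(
        strategy=meta["strategy"],
        p=int(meta["p"]),
        b=int(meta["b"]),
        r=int(meta["r"]),
        banded_dense=data["banded_dense"],
        factors=data["factors"],
        eigenvalues=data["eigenvalues"],
        psd_guaranteed=bool(meta.get("psd_guaranteed", False)),
        banded_factor=bf if bf.size else None,
    )


def read_loci(path: Union[str, Path], one_based: bool = False) -> List[LocusDefinition]:
    """Read locus boundaries; validates non-overlap within each chromosome."""
    loci: List[LocusDefinition] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}: malformed locus line {line!r}")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if one_based:
                start -= 1  # 1-based inclusive -> 0-based half-open
            label = parts[3] if len(parts) > 3 else f"{chrom}:{start}-{end}"
            loci.append(LocusDefinition(chrom, start, end, label))
    by_chrom: dict = {}
    for loc in loci:
        by_chrom.setdefault(loc.chrom, []).append(loc)
    for chrom, group in by_chrom.items():
        group = sorted(group, key=lambda l: l.start)
        for a, b in zip(group, group[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"{path}: overlapping loci {a.label} and {b.label} on {chrom}"
                )
    return loci


def write_panel_text(panel: GenotypePanel, path: Union[str, Path]) -> None:
    header = " ".join(panel.ids) if panel.ids is not None else ""
    np.savetxt(path, panel.G, fmt="%d", header=header)


def read_panel_text(path: Union[str, Path]) -> GenotypePanel:
    ids = None
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        labels = first[1:].split()
        ids = labels or None
    G = np.loadtxt(path, dtype=int)
    G = np.atleast_2d(G)
    maf = G.mean(axis=0) / 2.0
    return GenotypePanel(G=G, maf=maf, ids=ids)


def read_plink_raw(path: Union[str, Path]) -> GenotypePanel:
    """Read a PLINK ``--recode A`` additive-coded .raw file."""
    df = pd.read_csv(path, sep=r"\s+")
    meta_cols = [c for c in ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE") if c in df.columns]
    geno = df.drop(columns=meta_cols)
    G = geno.to_numpy(dtype=float)
    if np.isnan(G).any():
        raise ValueError(f"{path}: missing genotypes are not supported")
    G = G.astype(int)
    maf = G.mean(axis=0) / 2.0
    return GenotypePanel(G=G, maf=maf, ids=list(geno.columns))


def write_phenotype(ids, y, path: Union[str, Path]) -> None:
    pd.DataFrame({"ID": ids, "PHENO": np.asarray(y, float)}).to_csv(
        path, sep="\t", index=False, float_format="%.12g"
    )


def read_phenotype(path: Union[str, Path]) -> Tuple[List[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: phenotype file needs 2 columns (ID, value)")
    return df.iloc[:, 0].astype(str).tolist(), df.iloc[:, 1].to_numpy(dtype=float)


def write_fit_table(rows: List[dict], path: Union[str, Path]) -> None:
    """Per-locus result TSV with fixed column order and %.6g formatting."""
    cols = [
        "locus", "n", "p", "sigma_g2", "sigma_e2", "h2", "se_h2",
        "n_iter", "converged", "boundary", "ld_mode",
    ]
    df = pd.DataFrame(rows)
    for c in cols:
        if c not in df.columns:
            df[c] = np.nan
    df[cols].to_csv(path, sep="\t", index=False, float_format="%.6g")
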