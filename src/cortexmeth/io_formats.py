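"""Readers, writers and validated containers for the external file formats.

Methylation is carried internally as a *proportion* in [0, 1] (the array
"beta value"); effect sizes are only converted to percentage points at the
reporting layer.  Tabular formats are plain TSV; genomic intervals are BED
(0-based, half-open); gene sets are GMT.  Annotation positions follow the
manifest convention (1-based), so a site at position ``p`` overlaps a BED
interval ``[start, end)`` iff ``p - 1`` lies in it.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

MISSING_TOKEN = "NA"

CGI_CLASSES = ("island", "north_shore", "south_shore", "north_shelf", "south_shelf", "open_sea")
GENIC_CLASSES = ("TSS1500", "TSS200", "5'UTR", "body", "3'UTR", "intergenic")

log = logging.getLogger("cortexmeth")


def setup_logging(logfile: str | None = None, level: int = logging.INFO) -> logging.Logger:
    """Configure the package logger to stderr and optionally to a file."""
    log.setLevel(level)
    log.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    sh = logging.StreamHandler(sys.stderr)
    sh.setFormatter(fmt)
    log.addHandler(sh)
    if logfile is not None:
        fh = logging.FileHandler(logfile)
        fh.setFormatter(fmt)
        log.addHandler(fh)
    return log


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass
class BetaMatrix:
    """Sites x samples matrix of methylation proportions in [0, 1].

    Missing values are carried as NaN; all validation is done at
    construction time via :meth:`validate`.
    """

    site_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # float (n_sites, n_samples), NaN = missing

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self) -> None:
        n_sites, n_samples = self.values.shape
        if len(self.site_ids) != n_sites or len(self.sample_ids) != n_samples:
            raise ValueError(
                f"dimension mismatch: {len(self.site_ids)} site ids, "
                f"{len(self.sample_ids)} sample ids, values {self.values.shape}"
            )
        dup = _duplicates(self.site_ids)
        if dup:
            raise ValueError(f"duplicate site ids: {sorted(dup)[:5]}")
        dup = _duplicates(self.sample_ids)
        if dup:
            raise ValueError(f"duplicate sample ids: {sorted(dup)[:5]}")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            bad = np.argwhere(
                np.isfinite(self.values) & ((self.values < 0) | (self.values > 1))
            )
            i, j = bad[0]
            raise ValueError(
                f"beta value out of [0,1] at site {self.site_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}: {self.values[i, j]}"
            )

    @property
    def n_sites(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.site_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BetaMatrix":
        return cls(list(map(str, df.index)), list(map(str, df.columns)), df.to_numpy(float))

    def subset_sites(self, site_ids: list[str]) -> "BetaMatrix":
        idx = {s: i for i, s in enumerate(self.site_ids)}
        rows = [idx[s] for s in site_ids]
        return BetaMatrix(list(site_ids), list(self.sample_ids), self.values[rows])

    def subset_samples(self, sample_ids: list[str]) -> "BetaMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in sample_ids]
        return BetaMatrix(list(self.site_ids), list(sample_ids), self.values[:, cols])


@dataclass
class PeakSet:
    """Open-chromatin peaks of one cell type; intervals 0-based half-open."""

    cell_type_label: str
    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if start >= end:
                raise ValueError(f"empty/inverted interval {chrom}:{start}-{end}")
        self.intervals = sorted(self.intervals, key=lambda iv: (iv[0], iv[1], iv[2]))

    def contains(self, chromosome: str, position: int) -> bool:
        """Membership of a 1-based site position in any interval."""
        p = position - 1
        return any(c == chromosome and s <= p < e for c, s, e in self.intervals)


@dataclass
class GeneSet:
    set_name: str
    gene_symbols: list[str]

    def __post_init__(self) -> None:
        if not self.gene_symbols:
            raise ValueError(f"gene set {self.set_name!r} is empty")
        seen: dict[str, None] = {}
        for g in self.gene_symbols:
            seen.setdefault(g.upper(), None)
        self.gene_symbols = list(seen)


def _duplicates(ids) -> set:
    seen, dup = set(), set()
    for x in ids:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


# ---------------------------------------------------------------------------
# Sample sheet / annotation validation
# ---------------------------------------------------------------------------

SAMPLE_SHEET_COLUMNS = [
    "sample_id", "age_value", "age_unit", "sex", "batch", "donor_id", "fraction", "stage",
]

ANNOTATION_COLUMNS = [
    "site_id", "chromosome", "position", "gene_symbols", "cgi_class", "genic_class", "probe_type",
]


def validate_sample_sheet(sheet: pd.DataFrame, beta: BetaMatrix | None = None) -> pd.DataFrame:
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValueError(f"sample sheet is missing columns: {missing}")
    bad_unit = set(sheet["age_unit"]) - {"pcw", "years"}
    if bad_unit:
        raise ValueError(f"unknown age units: {sorted(bad_unit)}")
    pre = sheet[sheet["stage"] == "prenatal"]
    if len(pre) and not (
        (pre["age_unit"] == "pcw").all()
        and pre["age_value"].between(4, 40).all()
    ):
        raise ValueError("prenatal ages must be in pcw and within [4, 40]")
    if beta is not None:
        absent = set(sheet["sample_id"]) - set(beta.sample_ids)
        if absent:
            raise ValueError(f"sample ids absent from beta matrix: {sorted(absent)[:5]}")
    return sheet


def validate_annotation(annot: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ANNOTATION_COLUMNS if c not in annot.columns]
    if missing:
        raise ValueError(f"annotation is missing columns: {missing}")
    if annot["site_id"].duplicated().any():
        dup = annot.loc[annot["site_id"].duplicated(), "site_id"].tolist()
        raise ValueError(f"duplicate annotation rows for sites: {dup[:5]}")
    if (annot["position"] < 1).any():
        raise ValueError("annotation positions must be >= 1")
    return annot


def split_gene_symbols(symbols) -> list[str]:
    """Split a manifest-style semicolon list into unique uppercase symbols."""
    if symbols is None or (isinstance(symbols, float) and np.isnan(symbols)):
        return []
    out: dict[str, None] = {}
    for g in str(symbols).split(";"):
        g = g.strip().upper()
        if g:
            out.setdefault(g, None)
    return list(out)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_beta_matrix(path) -> BetaMatrix:
    """Read a TSV beta matrix: first column site ids, header row sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[MISSING_TOKEN], keep_default_na=False)
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            raise ValueError(
                f"non-numeric value in column {col!r} at site {bad.index[0]!r}: {bad.iloc[0]!r}"
            ) from None
    return BetaMatrix.from_frame(df)


def write_beta_matrix(beta: BetaMatrix, path) -> None:
    beta.to_frame().to_csv(path, sep="\t", na_rep=MISSING_TOKEN, float_format="%.10g",
                           index_label="site_id")


def read_sample_sheet(path, beta: BetaMatrix | None = None) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "donor_id": str, "batch": str})
    return validate_sample_sheet(sheet, beta)


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, sep="\t", index=False)


def read_annotation(path) -> pd.DataFrame:
    annot = pd.read_csv(path, sep="\t", dtype={"site_id": str, "chromosome": str})
    annot["gene_symbols"] = annot["gene_symbols"].map(split_gene_symbols)
    return validate_annotation(annot)


def write_annotation(annot: pd.DataFrame, path) -> None:
    out = annot.copy()
    out["gene_symbols"] = out["gene_symbols"].map(
        lambda gs: ";".join(gs) if isinstance(gs, (list, tuple)) else gs
    )
    out.to_csv(path, sep="\t", index=False)


def read_bed(path, cell_type_label: str | None = None) -> PeakSet:
    """Read a 3+ column BED file into a :class:`PeakSet` (sorted)."""
    intervals = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {ln}: fewer than 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(f"{path}: line {ln}: start >= end ({start} >= {end})")
            intervals.append((chrom, start, end))
    if cell_type_label is None:
        cell_type_label = str(path)
    return PeakSet(cell_type_label, intervals)


def write_bed(peaks: PeakSet, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in peaks.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_gmt(path) -> list[GeneSet]:
    """Read a GMT file: one set per line (name, description, genes...)."""
    sets = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {ln}: GMT line has fewer than 3 fields")
            sets.append(GeneSet(parts[0], parts[2:]))
    return sets


def write_gmt(sets: list[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.set_name, "na"] + list(gs.gene_symbols)) + "\n")


def read_config(path) -> dict:
    """Flat YAML key-value configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a flat mapping")
    return cfg


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=MISSING_TOKEN, float_format="%.8g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[MISSING_TOKEN], keep_default_na=False)
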