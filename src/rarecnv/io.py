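"""Readers and writers for every external file the pipeline touches.

Internal conventions, applied at the boundary and assumed everywhere else:

* coordinates are 0-based, half-open (BED-native); caller tables are
  declared 1-based inclusive by default (the PennCNV convention) and are
  converted on read,
* chromosome names are normalised to the canonical ``chr``-prefixed form,
  with a configurable alias map for other schemes,
* strand is ignored: CNVs and gene overlap are strand-agnostic here.

Tabular data is handed around as pandas DataFrames with the column schemas
documented below; region tracks as :class:`~rarecnv.intervals.RegionTrack`.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .intervals import RegionTrack

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "ConfigError",
    "ValidationError",
    "CallerDialect",
    "DEFAULT_DIALECT",
    "SkipReport",
    "GeneSetLibrary",
    "CALLERS",
    "CALL_COLUMNS",
    "STRINGENT_COLUMNS",
    "normalize_chrom",
    "read_caller_calls",
    "write_caller_calls",
    "read_regions",
    "write_regions",
    "read_genes",
    "write_genes",
    "read_chrom_lengths",
    "write_chrom_lengths",
    "read_samples",
    "write_samples",
    "read_gmt",
    "write_gmt",
    "read_stringent_cnvs",
    "write_stringent_cnvs",
    "read_association_table",
    "write_association_table",
]


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ConfigError(ValueError):
    """A dialect / threshold configuration is unusable."""


class ValidationError(ValueError):
    """Well-formed input whose content violates a pipeline invariant."""


#: caller identifiers; stand-ins for the three array-CNV HMM callers
CALLERS = ("caller_A", "caller_B", "caller_C")

CALL_COLUMNS = ["sample_id", "chrom", "start", "end", "cnv_type", "n_probes", "quality", "caller"]

STRINGENT_COLUMNS = [
    "sample_id", "chrom", "start", "end", "cnv_type",
    "length", "n_callers", "callers", "max_probes",
]

CNV_TYPES = ("deletion", "duplication")


def normalize_chrom(chrom: str, aliases: Mapping[str, str] | None = None) -> str:
    """Canonical chromosome name: ``chr``-prefixed, alias map applied first."""
    c = str(chrom).strip()
    if aliases and c in aliases:
        c = aliases[c]
    if not c.lower().startswith("chr"):
        c = "chr" + c
    return "chr" + c[3:]


@dataclass(frozen=True)
class CallerDialect:
    """Column mapping and conventions of one caller's output table.

    ``columns`` maps internal field names to the caller's column headers.
    ``one_based`` declares 1-based inclusive coordinates (converted to
    0-based half-open on read). The copy-number state column is mapped to
    deletion/duplication through ``deletion_states`` /
    ``duplication_min_cn``; the diploid state is skipped as copy-neutral.
    """

    columns: Mapping[str, str] = field(default_factory=lambda: {
        "sample_id": "sample_id",
        "chrom": "chrom",
        "start": "start",
        "end": "end",
        "copy_number": "cn",
        "n_probes": "n_probes",
        "quality": "quality",
    })
    one_based: bool = True
    deletion_states: tuple[int, ...] = (0, 1)
    duplication_min_cn: int = 3
    neutral_cn: int = 2
    chrom_aliases: Mapping[str, str] = field(default_factory=dict)

    def cnv_type_of(self, cn: int) -> str | None:
        if cn in self.deletion_states:
            return "deletion"
        if cn >= self.duplication_min_cn:
            return "duplication"
        return None


DEFAULT_DIALECT = CallerDialect()


@dataclass
class SkipReport:
    """Per-row rejections from one caller file."""

    copy_neutral: int = 0
    malformed: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_skipped(self) -> int:
        return self.copy_neutral + len(self.malformed)


def read_caller_calls(
    path,
    caller: str,
    dialect: CallerDialect = DEFAULT_DIALECT,
    chrom_lengths: Mapping[str, int] | None = None,
    strict: bool = True,
) -> tuple[pd.DataFrame, SkipReport]:
    """Parse one caller's tab-separated call table.

    Copy-neutral rows (cn == 2 by default) are always skipped and counted;
    they are not CNVs. Malformed rows (unparseable fields, ``end <=
    start``, unknown chromosome) raise :class:`ValidationError` naming the
    row in strict mode, or are collected in the report otherwise.

    Returns ``(calls, report)`` where ``calls`` has columns
    ``CALL_COLUMNS`` in normalised 0-based half-open coordinates.
    """
    path = Path(path)
    if caller not in CALLERS:
        raise ConfigError(f"unknown caller id {caller!r}; expected one of {CALLERS}")
    raw = pd.read_csv(path, sep="\t", dtype=str)
    missing = [v for v in dialect.columns.values() if v not in raw.columns]
    if missing:
        raise ConfigError(f"{path}: missing required column(s) {missing}")
    col = dialect.columns
    report = SkipReport()
    rows: list[dict] = []
    offset = 1 if dialect.one_based else 0
    for i, rec in enumerate(raw.itertuples(index=False), start=2):  # 1-based incl. header
        rec = dict(zip(raw.columns, rec))
        try:
            cn = int(rec[col["copy_number"]])
            cnv_type = dialect.cnv_type_of(cn)
            if cnv_type is None:
                report.copy_neutral += 1
                continue
            start = int(rec[col["start"]]) - offset
            end = int(rec[col["end"]])
            if end <= start:
                raise ValueError(f"end <= start ({end} <= {start + offset})")
            if start < 0:
                raise ValueError("negative coordinate")
            chrom = normalize_chrom(rec[col["chrom"]], dialect.chrom_aliases)
            if chrom_lengths is not None and chrom not in chrom_lengths:
                raise ValueError(f"chromosome {chrom!r} not in the genome table")
            n_probes = int(rec[col["n_probes"]])
            if n_probes < 1:
                raise ValueError("n_probes < 1")
            rows.append({
                "sample_id": str(rec[col["sample_id"]]),
                "chrom": chrom,
                "start": start,
                "end": end,
                "cnv_type": cnv_type,
                "n_probes": n_probes,
                "quality": float(rec[col["quality"]]),
                "caller": caller,
            })
        except (ValueError, TypeError) as exc:
            if strict:
                raise ValidationError(f"{path}: row {i}: {exc}") from exc
            report.malformed.append((i, str(exc)))
    calls = pd.DataFrame(rows, columns=CALL_COLUMNS)
    if report.n_skipped:
        logger.info("%s: skipped %d copy-neutral and %d malformed rows",
                    path, report.copy_neutral, len(report.malformed))
    return calls, report


def write_caller_calls(calls: pd.DataFrame, path, dialect: CallerDialect = DEFAULT_DIALECT) -> None:
    """Write calls back out in the dialect's coordinate convention."""
    col = dialect.columns
    cn = np.where(calls["cnv_type"].to_numpy() == "deletion",
                  dialect.deletion_states[0], dialect.duplication_min_cn)
    out = pd.DataFrame({
        col["sample_id"]: calls["sample_id"],
        col["chrom"]: calls["chrom"],
        col["start"]: calls["start"] + (1 if dialect.one_based else 0),
        col["end"]: calls["end"],
        col["copy_number"]: cn,
        col["n_probes"]: calls["n_probes"],
        col["quality"]: calls["quality"],
    })
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# region tracks, genes, chromosome table


def read_regions(path, name: str | None = None) -> RegionTrack:
    """Read a BED3+ file into a merged :class:`RegionTrack`.

    Input may be unsorted and overlapping (union taken on load); negative
    coordinates are an error. An empty file yields a valid empty track.
    """
    path = Path(path)
    name = name or path.stem
    records = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: line {ln}: expected >= 3 BED fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}: line {ln}: non-integer coordinate") from exc
            if start < 0:
                raise FormatError(f"{path}: line {ln}: negative coordinate")
            if end <= start:
                raise FormatError(f"{path}: line {ln}: empty interval")
            records.append((normalize_chrom(parts[0]), start, end))
    return RegionTrack.from_records(name, records)


def write_regions(track: RegionTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in track.to_records():
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_genes(path) -> pd.DataFrame:
    """Gene models from BED4 (chrom, start, end, gene_id); unique ids enforced."""
    path = Path(path)
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}: line {ln}: gene BED needs 4 fields (chrom, start, end, gene_id)")
            start, end = int(parts[1]), int(parts[2])
            if end <= start or start < 0:
                raise FormatError(f"{path}: line {ln}: invalid gene interval")
            rows.append((parts[3], normalize_chrom(parts[0]), start, end))
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])
    dup = genes["gene_id"].duplicated()
    if dup.any():
        raise ValidationError(f"{path}: duplicate gene_id(s): "
                              f"{sorted(genes.loc[dup, 'gene_id'].unique())[:5]}")
    return genes


def write_genes(genes: pd.DataFrame, path) -> None:
    out = genes.sort_values(["chrom", "start", "end", "gene_id"], kind="mergesort")
    with open(path, "w") as fh:
        for rec in out.itertuples(index=False):
            fh.write(f"{rec.chrom}\t{rec.start}\t{rec.end}\t{rec.gene_id}\n")


def read_chrom_lengths(path) -> dict[str, int]:
    """Two-column TSV (chrom, length) -> dict keyed by canonical name."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"], comment="#")
    out: dict[str, int] = {}
    for rec in df.itertuples(index=False):
        chrom = normalize_chrom(rec.chrom)
        if chrom in out:
            raise FormatError(f"{path}: duplicate chromosome {chrom}")
        length = int(rec.length)
        if length <= 0:
            raise FormatError(f"{path}: non-positive length for {chrom}")
        out[chrom] = length
    return out


def write_chrom_lengths(lengths: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(lengths):
            fh.write(f"{chrom}\t{lengths[chrom]}\n")


# ---------------------------------------------------------------------------
# sample manifest

SAMPLE_COLUMNS = ["sample_id", "cohort", "subtype", "batch", "call_rate", "lrr_sd", "baf_sd"]


def _parse_rate(value) -> float:
    """Accept both '94.2%' and '0.942' call-rate dialects."""
    s = str(value).strip()
    if s.endswith("%"):
        return round(float(s[:-1]) / 100.0, 12)
    x = float(s)
    return round(x / 100.0, 12) if x > 1.0 else x


def read_samples(path) -> pd.DataFrame:
    """Sample manifest TSV -> DataFrame with ``SAMPLE_COLUMNS``.

    Enforces unique sample ids and the cohort/subtype consistency rule:
    cases carry a CD or UC subtype, controls carry none.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"{path}: manifest missing column(s) {missing}")
    dup = df["sample_id"].duplicated()
    if dup.any():
        raise ValidationError(f"{path}: duplicate sample_id(s): "
                              f"{sorted(df.loc[dup, 'sample_id'].unique())[:5]}")
    cohort = df["cohort"].str.strip().str.lower()
    if not cohort.isin(["case", "control"]).all():
        bad = df.loc[~cohort.isin(["case", "control"]), "cohort"].unique()
        raise ValidationError(f"{path}: unknown cohort value(s) {list(bad)[:5]}")
    subtype = df["subtype"].fillna("none").str.strip().replace({"": "none", "NA": "none"})
    subtype = subtype.where(subtype.isin(["CD", "UC"]), "none")
    raw_subtype = df["subtype"].fillna("none").str.strip()
    bad_case = (cohort == "case") & ~raw_subtype.isin(["CD", "UC"])
    if bad_case.any():
        raise ValidationError(f"{path}: case sample(s) without CD/UC subtype: "
                              f"{df.loc[bad_case, 'sample_id'].tolist()[:5]}")
    bad_ctrl = (cohort == "control") & raw_subtype.isin(["CD", "UC"])
    if bad_ctrl.any():
        raise ValidationError(f"{path}: control sample(s) with a disease subtype: "
                              f"{df.loc[bad_ctrl, 'sample_id'].tolist()[:5]}")
    out = pd.DataFrame({
        "sample_id": df["sample_id"].astype(str),
        "cohort": cohort,
        "subtype": subtype,
        "batch": df["batch"].astype(str),
        "call_rate": df["call_rate"].map(_parse_rate),
        "lrr_sd": df["lrr_sd"].astype(float),
        "baf_sd": df["baf_sd"].astype(float),
    })
    if ((out["call_rate"] < 0) | (out["call_rate"] > 1)).any():
        raise ValidationError(f"{path}: call_rate outside [0, 1]")
    if (out["lrr_sd"] < 0).any() or (out["baf_sd"] < 0).any():
        raise ValidationError(f"{path}: negative intensity SD")
    return out


def write_samples(samples: pd.DataFrame, path) -> None:
    samples[SAMPLE_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene-set libraries (GMT)


@dataclass
class GeneSetLibrary:
    """A named collection of gene sets: set_id -> (description, members)."""

    library_name: str
    sets: dict[str, tuple[str, tuple[str, ...]]]

    def __post_init__(self) -> None:
        for set_id, (_, members) in self.sets.items():
            if len(members) == 0:
                raise ValidationError(f"gene set {set_id!r} has no members")

    def members(self, set_id: str) -> tuple[str, ...]:
        return self.sets[set_id][1]


def read_gmt(path, library_name: str | None = None) -> GeneSetLibrary:
    """GMT: one tab-separated line per set (id, description, members...).

    Duplicate members within a set are dropped (first occurrence kept);
    lines with fewer than three fields are an error with the line number.
    """
    path = Path(path)
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: line {ln}: GMT line needs >= 3 fields")
            set_id, desc = parts[0], parts[1]
            if set_id in sets:
                raise FormatError(f"{path}: line {ln}: duplicate set id {set_id!r}")
            members = tuple(dict.fromkeys(g for g in parts[2:] if g))
            if not members:
                raise FormatError(f"{path}: line {ln}: set {set_id!r} has no members")
            sets[set_id] = (desc, members)
    return GeneSetLibrary(library_name or path.stem, sets)


def write_gmt(library: GeneSetLibrary, path) -> None:
    with open(path, "w") as fh:
        for set_id, (desc, members) in library.sets.items():
            fh.write("\t".join([set_id, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# pipeline products


def _sorted_cnvs(cnvs: pd.DataFrame) -> pd.DataFrame:
    return cnvs.sort_values(["chrom", "start", "end", "sample_id", "cnv_type"],
                            kind="mergesort").reset_index(drop=True)


def write_stringent_cnvs(cnvs: pd.DataFrame, path) -> None:
    """Deterministic TSV of consensus CNVs (stable sort, fixed columns)."""
    out = _sorted_cnvs(cnvs)[STRINGENT_COLUMNS] if len(cnvs) else \
        pd.DataFrame(columns=STRINGENT_COLUMNS)
    out.to_csv(path, sep="\t", index=False)


def read_stringent_cnvs(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "chrom": str,
                                            "callers": str, "cnv_type": str})
    missing = [c for c in STRINGENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: stringent CNV table missing column(s) {missing}")
    for c in ("start", "end", "length", "n_callers", "max_probes"):
        df[c] = df[c].astype(np.int64)
    if len(df) and (df["end"] <= df["start"]).any():
        raise ValidationError(f"{path}: CNV with end <= start")
    return df


ASSOCIATION_COLUMNS = [
    "gene_id", "cnv_type", "case_carriers", "case_cd", "case_uc",
    "control_carriers", "n_cases", "n_controls",
    "or_cmle", "or_sample", "ci_low", "ci_high", "p", "p_adj",
    "m_tests", "is_rare", "significant_rare",
]


def write_association_table(results: pd.DataFrame, path) -> None:
    out = results[ASSOCIATION_COLUMNS] if len(results) else \
        pd.DataFrame(columns=ASSOCIATION_COLUMNS)
    out = out.sort_values(["cnv_type", "p_adj", "p", "gene_id"], kind="mergesort") \
        if len(out) else out
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_association_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ASSOCIATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: association table missing column(s) {missing}")
    return df


def dataclass_to_dict(obj) -> dict:
    return dataclasses.asdict(obj)
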