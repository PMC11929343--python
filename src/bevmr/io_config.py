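"""Reading/writing GWAS summary-statistic tables, pipeline configuration,
and deterministic run metadata.

Summary statistics are plain tab-separated tables with one row per SNP and
the conventional columns (snp_id, chrom, pos, effect_allele, other_allele,
eaf, beta, se, p, n).  Column names in a source file are mapped onto this
schema through an explicit, user-supplied mapping — no fuzzy matching, so a
mis-labelled column is an error rather than a silently wrong analysis.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

VALID_ALLELES = frozenset("ACGT")

#: canonical column order of the summary-statistic schema
SUMMARY_COLUMNS = (
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "p",
    "n",
)

REQUIRED_COLUMNS = ("snp_id", "effect_allele", "other_allele", "beta", "se")


class ConfigurationError(ValueError):
    """A file or configuration does not satisfy the pipeline's contract."""


class ParseError(ValueError):
    """A data row could not be interpreted."""


@dataclass(frozen=True)
class SummaryRecord:
    """One SNP's association with one trait.

    ``beta`` is the additive per-allele effect of ``effect_allele`` on the
    trait (log-odds for binary traits); ``se`` its standard error; ``eaf``
    the effect-allele frequency (may be missing, encoded as NaN).
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    chrom: str = ""
    pos: int = 0
    eaf: float = float("nan")
    p: float = float("nan")
    n: float = float("nan")

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_ALLELES:
            raise ValueError(f"invalid effect allele {self.effect_allele!r}")
        if self.other_allele not in VALID_ALLELES:
            raise ValueError(f"invalid other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele identical")
        if not self.se > 0:
            raise ValueError(f"{self.snp_id}: se must be positive, got {self.se}")


def p_from_beta_se(beta, se):
    """Two-sided normal p-value from an estimate and its standard error."""
    z = np.abs(np.asarray(beta, dtype=float) / np.asarray(se, dtype=float))
    return 2.0 * stats.norm.sf(z)


@dataclass
class SummaryDataset:
    """A block of per-SNP summary statistics for a single trait.

    ``df`` holds one row per SNP with the canonical :data:`SUMMARY_COLUMNS`;
    ``snp_id`` is unique.  ``sample_overlap_tag`` labels the GWAS sample so
    that non-overlap between exposure/mediator/outcome samples can be
    asserted downstream.
    """

    trait_label: str
    df: pd.DataFrame
    sample_overlap_tag: str = ""

    def __post_init__(self) -> None:
        if self.df["snp_id"].duplicated().any():
            dup = self.df.loc[self.df["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise ConfigurationError(
                f"duplicate snp_id {dup!r} in dataset {self.trait_label!r}"
            )
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def snp_ids(self) -> list[str]:
        return self.df["snp_id"].tolist()

    def record(self, snp_id: str) -> SummaryRecord:
        row = self.df.loc[self.df["snp_id"] == snp_id]
        if row.empty:
            raise KeyError(snp_id)
        r = row.iloc[0]
        return SummaryRecord(
            snp_id=r["snp_id"],
            chrom=str(r["chrom"]),
            pos=int(r["pos"]),
            effect_allele=r["effect_allele"],
            other_allele=r["other_allele"],
            eaf=float(r["eaf"]),
            beta=float(r["beta"]),
            se=float(r["se"]),
            p=float(r["p"]),
            n=float(r["n"]),
        )

    def subset(self, snp_ids: Sequence[str]) -> "SummaryDataset":
        keep = self.df[self.df["snp_id"].isin(set(snp_ids))].copy()
        return SummaryDataset(self.trait_label, keep, self.sample_overlap_tag)


@dataclass
class PipelineConfig:
    """Tunable thresholds shared across the MR pipeline.

    Defaults follow standard two-sample MR practice: genome-wide
    significance 5e-8 for instrument selection, LD clumping at r^2 < 0.001
    within a +/-10,000 kb window, palindromic-SNP ambiguity band 0.42-0.58.
    """

    p_threshold: float = 5e-8
    clump_r2: float = 0.001
    clump_window_kb: int = 10_000
    palindromic_eaf_band: tuple[float, float] = (0.42, 0.58)
    n_boot: int = 1000
    n_presso_sim: int = 1000
    seed: int = 0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold <= 1:
            raise ConfigurationError("p_threshold must be in (0, 1]")
        if not 0 <= self.clump_r2 <= 1:
            raise ConfigurationError("clump_r2 must be in [0, 1]")
        if self.clump_window_kb <= 0:
            raise ConfigurationError("clump_window_kb must be positive")
        lo, hi = self.palindromic_eaf_band
        if not 0 <= lo <= hi <= 1:
            raise ConfigurationError("palindromic_eaf_band must be an interval in [0,1]")
        if self.n_boot <= 0 or self.n_presso_sim <= 0:
            raise ConfigurationError("n_boot and n_presso_sim must be positive")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load from a YAML (or JSON, a YAML subset) mapping."""
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{path}: expected a mapping at top level")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "palindromic_eaf_band" in raw:
            raw["palindromic_eaf_band"] = tuple(raw["palindromic_eaf_band"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["palindromic_eaf_band"] = list(self.palindromic_eaf_band)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


DEFAULT_COLUMN_MAP: Mapping[str, str] = {c: c for c in SUMMARY_COLUMNS}


def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_label: str | None = None,
    sample_overlap_tag: str = "",
    sep: str = "\t",
) -> SummaryDataset:
    """Read a delimited summary-statistics table into a :class:`SummaryDataset`.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    column_map
        Maps canonical field names (:data:`SUMMARY_COLUMNS`) to the column
        names used in the file.  Fields absent from the mapping fall back to
        their canonical name; optional fields (eaf, p, n, chrom, pos) that
        the file lacks are filled with missing values.  ``p`` missing is
        recomputed from beta/se as a two-sided normal tail.
    """
    path = Path(path)
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)

    raw = pd.read_csv(path, sep=sep, dtype=str)
    for canonical in REQUIRED_COLUMNS:
        if cmap[canonical] not in raw.columns:
            raise ConfigurationError(
                f"{path.name}: required column {cmap[canonical]!r} "
                f"(for field {canonical!r}) is missing"
            )

    out = pd.DataFrame()
    out["snp_id"] = raw[cmap["snp_id"]].astype(str)
    out["chrom"] = (
        raw[cmap["chrom"]].astype(str) if cmap["chrom"] in raw.columns else ""
    )
    if cmap["pos"] in raw.columns:
        out["pos"] = pd.to_numeric(raw[cmap["pos"]], errors="coerce").fillna(0).astype(int)
    else:
        out["pos"] = 0
    out["effect_allele"] = raw[cmap["effect_allele"]].str.upper()
    out["other_allele"] = raw[cmap["other_allele"]].str.upper()

    for fld in ("beta", "se"):
        col = pd.to_numeric(raw[cmap[fld]], errors="coerce")
        bad = col.isna() & raw[cmap[fld]].notna()
        if bad.any() or col.isna().any():
            row = int(np.flatnonzero(col.isna())[0]) + 2  # header is line 1
            raise ParseError(f"{path.name}: non-numeric {fld} at line {row}")
        out[fld] = col.astype(float)

    for fld in ("eaf", "p", "n"):
        if cmap[fld] in raw.columns:
            out[fld] = pd.to_numeric(raw[cmap[fld]], errors="coerce").astype(float)
        else:
            out[fld] = np.nan

    missing_p = out["p"].isna()
    if missing_p.any():
        out.loc[missing_p, "p"] = p_from_beta_se(
            out.loc[missing_p, "beta"], out.loc[missing_p, "se"]
        )

    if (out["se"] <= 0).any():
        bad = out.loc[out["se"] <= 0, "snp_id"].iloc[0]
        raise ParseError(f"{path.name}: non-positive se for {bad}")
    same = out["effect_allele"] == out["other_allele"]
    if same.any():
        bad = out.loc[same, "snp_id"].iloc[0]
        raise ParseError(f"{path.name}: identical alleles for {bad}")
    bad_allele = ~out["effect_allele"].isin(VALID_ALLELES) | ~out["other_allele"].isin(
        VALID_ALLELES
    )
    if bad_allele.any():
        bad = out.loc[bad_allele, "snp_id"].iloc[0]
        raise ParseError(f"{path.name}: invalid allele code for {bad}")

    label = trait_label if trait_label is not None else path.stem
    return SummaryDataset(label, out[list(SUMMARY_COLUMNS)], sample_overlap_tag)


def write_summary_stats(dataset: SummaryDataset, path: str | Path) -> None:
    """Write a dataset back to the canonical tab-separated format."""
    dataset.df[list(SUMMARY_COLUMNS)].to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def write_report(results: Sequence, path: str | Path) -> None:
    """Serialize a collection of estimates to a tab-separated report table.

    Accepts any mix of objects exposing ``to_row()`` (MREstimate,
    EggerEstimate, PressoResult, MediationEstimate, ...).  Numeric fields
    round-trip through the file to at least 12 significant digits.
    """
    if not results:
        raise ValueError("write_report requires a non-empty results collection")
    rows = []
    for r in results:
        if hasattr(r, "to_row"):
            rows.append(r.to_row())
        elif isinstance(r, Mapping):
            rows.append(dict(r))
        else:
            raise TypeError(f"cannot serialize result of type {type(r).__name__}")
    table = pd.DataFrame(rows)
    table.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_report(path: str | Path) -> pd.DataFrame:
    """Read back a report written by :func:`write_report`."""
    return pd.read_csv(path, sep="\t")


def log_run_metadata(
    out_dir: str | Path,
    config: PipelineConfig,
    extra: Mapping | None = None,
) -> Path:
    """Write a sidecar file with config hash, seed and timestamp.

    Returns the path of the sidecar, ``run_metadata.json`` in ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    if extra:
        meta.update(extra)
    path = out_dir / "run_metadata.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2, default=str)
    return path
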