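"""Selection, LD-pruning and harmonization of genetic instruments.

Instruments are SNPs associated with the exposure below a p-value
threshold, pruned to approximate linkage equilibrium by greedy p-ordered
clumping, and aligned to a common effect allele across the exposure and
outcome GWAS before Wald ratios are formed.  Palindromic variants (A/T or
C/G) whose strand cannot be resolved from allele frequency are dropped
rather than guessed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from bevmr.io_config import SummaryDataset

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _is_palindromic(a1: str, a2: str) -> bool:
    return COMPLEMENT[a1] == a2


@dataclass
class LDMatrix:
    """Squared-correlation (r^2) matrix for a panel of SNPs.

    ``positions`` maps snp_id -> (chrom, pos) so the clumping window can be
    applied on physical distance.
    """

    snp_ids: list[str]
    r2: np.ndarray
    positions: dict[str, tuple[str, int]]

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.snp_ids)
        if self.r2.shape != (k, k):
            raise ValueError("r2 matrix shape does not match snp_ids")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-12):
            raise ValueError("LD matrix diagonal must be 1")
        if not np.allclose(self.r2, self.r2.T, atol=1e-12):
            raise ValueError("LD matrix must be symmetric")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def r2_between(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    @classmethod
    def identity(cls, dataset: SummaryDataset) -> "LDMatrix":
        """All-independent LD (r^2 = 0 off-diagonal) for a dataset's SNPs."""
        ids = dataset.snp_ids
        pos = {
            r.snp_id: (str(r.chrom), int(r.pos))
            for r in dataset.df.itertuples(index=False)
        }
        return cls(ids, np.eye(len(ids)), pos)

    @classmethod
    def from_file(cls, path: str | Path, dataset: SummaryDataset) -> "LDMatrix":
        """Read a square tab-separated r^2 table with SNP-id header/index."""
        tab = pd.read_csv(path, sep="\t", index_col=0)
        ids = [str(c) for c in tab.columns]
        pos = {
            r.snp_id: (str(r.chrom), int(r.pos))
            for r in dataset.df.itertuples(index=False)
            if r.snp_id in set(ids)
        }
        return cls(ids, tab.to_numpy(dtype=float), pos)


@dataclass
class InstrumentStrength:
    """Per-SNP and mean F-statistics; mean_f <= 10 flags weak instruments."""

    per_snp_f: pd.Series
    mean_f: float
    weak: bool

    def to_row(self) -> dict:
        return {"mean_f": self.mean_f, "k_snps": len(self.per_snp_f), "weak": self.weak}


@dataclass
class HarmonizedSet:
    """Exposure/outcome SNP pairs on a common effect-allele orientation.

    ``pairs`` columns: snp_id, beta_exp, se_exp, beta_out, se_out, eaf_exp,
    eaf_out.  ``dropped`` maps snp_id -> reason code ("ambiguous_palindrome"
    or "allele_mismatch").
    """

    pairs: pd.DataFrame
    dropped: dict[str, str] = field(default_factory=dict)
    exposure_label: str = ""
    outcome_label: str = ""
    outcome_binary: bool = True

    def __len__(self) -> int:
        return len(self.pairs)


def select_instruments(dataset: SummaryDataset, p_threshold: float) -> set[str]:
    """SNPs associated with the trait at ``p < p_threshold`` (strict)."""
    if len(dataset) == 0:
        raise ValueError("cannot select instruments from an empty dataset")
    mask = dataset.df["p"] < p_threshold
    selected = set(dataset.df.loc[mask, "snp_id"])
    if not selected:
        import warnings

        warnings.warn(
            f"no SNP passes p < {p_threshold:g} for {dataset.trait_label!r}",
            stacklevel=2,
        )
    return selected


def clump(
    snps: set[str],
    dataset: SummaryDataset,
    ld: LDMatrix,
    r2_threshold: float = 0.001,
    window_kb: int = 10_000,
) -> set[str]:
    """Greedy p-ordered LD clumping.

    Repeatedly keep the remaining SNP with the smallest p-value and discard
    every other remaining SNP on the same chromosome within ``window_kb``
    of it whose r^2 with it is >= ``r2_threshold``.  Ties in p are broken
    by snp_id so the result is independent of input order.
    """
    missing = [s for s in snps if s not in ld]
    if missing:
        raise KeyError(f"SNP {missing[0]!r} missing from LD matrix")
    sub = dataset.df[dataset.df["snp_id"].isin(snps)]
    missing_ds = snps - set(sub["snp_id"])
    if missing_ds:
        raise KeyError(f"SNP {sorted(missing_ds)[0]!r} missing from dataset")

    order = sub.sort_values(["p", "snp_id"], kind="mergesort")
    remaining = list(order["snp_id"])
    info = {
        r.snp_id: (str(r.chrom), int(r.pos)) for r in order.itertuples(index=False)
    }
    kept: set[str] = set()
    window_bp = window_kb * 1000
    while remaining:
        index = remaining.pop(0)
        kept.add(index)
        chrom_i, pos_i = info[index]
        survivors = []
        for s in remaining:
            chrom_s, pos_s = info[s]
            if (
                chrom_s == chrom_i
                and abs(pos_s - pos_i) <= window_bp
                and ld.r2_between(index, s) >= r2_threshold
            ):
                continue
            survivors.append(s)
        remaining = survivors
    return kept


def instrument_strength(dataset: SummaryDataset, snps: set[str]) -> InstrumentStrength:
    """Per-SNP F = (beta/se)^2 and the arithmetic mean across instruments.

    Mean F > 10 is the conventional bar for adequate instrument strength;
    ``weak`` is set when the mean falls at or below it.
    """
    if not snps:
        raise ValueError("instrument_strength requires a non-empty SNP set")
    sub = dataset.df[dataset.df["snp_id"].isin(snps)]
    f = (sub["beta"] / sub["se"]) ** 2
    f.index = sub["snp_id"]
    mean_f = float(f.mean())
    return InstrumentStrength(per_snp_f=f, mean_f=mean_f, weak=mean_f <= 10.0)


def harmonize(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    snps: set[str],
    palindromic_band: tuple[float, float] = (0.42, 0.58),
    outcome_binary: bool = True,
) -> HarmonizedSet:
    """Align outcome effects to the exposure's effect allele per SNP.

    Handles three situations: matching orientation (keep), swapped
    effect/other alleles (negate beta_out, mirror eaf_out), and strand
    flips (complement the outcome alleles, then re-check).  Palindromic
    SNPs are retained only when both allele frequencies fall outside the
    ambiguity band and agree on which allele is minor; a frequency conflict
    is treated as a hidden strand flip and the outcome effect is negated.
    Unresolvable SNPs are dropped with a reason code, never raised.
    """
    exp_df = exposure.df.set_index("snp_id")
    out_df = outcome.df.set_index("snp_id")
    lo, hi = palindromic_band

    rows = []
    dropped: dict[str, str] = {}
    for snp in sorted(snps):
        if snp not in exp_df.index or snp not in out_df.index:
            dropped[snp] = "missing_in_dataset"
            continue
        e = exp_df.loc[snp]
        o = out_df.loc[snp]
        ea_e, oa_e = e["effect_allele"], e["other_allele"]
        ea_o, oa_o = o["effect_allele"], o["other_allele"]
        beta_out, eaf_out = float(o["beta"]), float(o["eaf"])

        def aligned(a1, a2):
            return (a1, a2) == (ea_e, oa_e)

        def swapped(a1, a2):
            return (a1, a2) == (oa_e, ea_e)

        if aligned(ea_o, oa_o):
            pass
        elif swapped(ea_o, oa_o):
            beta_out = -beta_out
            eaf_out = 1.0 - eaf_out if np.isfinite(eaf_out) else eaf_out
        else:
            ca, co = COMPLEMENT[ea_o], COMPLEMENT[oa_o]
            if aligned(ca, co):
                pass
            elif swapped(ca, co):
                beta_out = -beta_out
                eaf_out = 1.0 - eaf_out if np.isfinite(eaf_out) else eaf_out
            else:
                dropped[snp] = "allele_mismatch"
                continue

        eaf_exp = float(e["eaf"])
        if _is_palindromic(ea_e, oa_e):
            freqs_known = np.isfinite(eaf_exp) and np.isfinite(eaf_out)
            in_band = (
                (np.isfinite(eaf_exp) and lo <= eaf_exp <= hi)
                or (np.isfinite(eaf_out) and lo <= eaf_out <= hi)
            )
            if not freqs_known or in_band:
                dropped[snp] = "ambiguous_palindrome"
                continue
            # discordant minor allele across datasets => hidden strand flip
            if (eaf_exp - 0.5) * (eaf_out - 0.5) < 0:
                beta_out = -beta_out
                eaf_out = 1.0 - eaf_out

        rows.append(
            {
                "snp_id": snp,
                "beta_exp": float(e["beta"]),
                "se_exp": float(e["se"]),
                "beta_out": beta_out,
                "se_out": float(o["se"]),
                "eaf_exp": eaf_exp,
                "eaf_out": eaf_out,
            }
        )

    pairs = pd.DataFrame(
        rows,
        columns=[
            "snp_id",
            "beta_exp",
            "se_exp",
            "beta_out",
            "se_out",
            "eaf_exp",
            "eaf_out",
        ],
    )
    return HarmonizedSet(
        pairs=pairs,
        dropped=dropped,
        exposure_label=exposure.trait_label,
        outcome_label=outcome.trait_label,
        outcome_binary=outcome_binary,
    )
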