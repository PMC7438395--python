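"""Genotype, sample-annotation and weight-table I/O plus genotyping QC.

The in-memory genotype container is :class:`GenotypeMatrix` — a samples x
variants matrix of alternate-allele dosages (0/1/2, ``NaN`` = missing) with
variant metadata.  On disk the package speaks minimal VCF v4.2 (GT only,
diploid unphased) and plain TSV tables.  Parsing goes through cyvcf2;
writing the minimal VCF is plain text.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Closed set of cohort group labels.
GROUP_LABELS = ("crhf_case", "chemo_no_hf", "hf_no_chemo", "reference")

VARIANT_COLUMNS = ["variant_id", "chrom", "pos", "ref", "alt", "locus"]

SAMPLE_COLUMNS = [
    "sample_id", "group", "sex", "age", "antihtn",
    "baseline_lvef", "delta_lvef",
]


class VcfParseError(ValueError):
    """Raised for malformed or unsupported VCF content."""


@dataclass
class GenotypeMatrix:
    """Samples x variants alternate-allele dosage matrix.

    Parameters
    ----------
    sample_ids : list of str
        Unique sample identifiers, in matrix row order.
    variants : pandas.DataFrame
        One row per variant with columns ``variant_id, chrom, pos, ref,
        alt, locus`` (``pos`` is 1-based, VCF convention).
    dosages : numpy.ndarray
        Float array of shape ``(n_samples, n_variants)`` with values in
        ``{0, 1, 2}`` or ``NaN`` for missing genotypes.
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample_ids")
        vids = self.variants["variant_id"]
        if vids.duplicated().any():
            dup = vids[vids.duplicated()].iloc[0]
            raise ValueError(f"duplicate variant_id {dup!r}")
        if (self.variants["pos"] < 1).any():
            raise ValueError("variant pos must be >= 1 (1-based)")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be in {0, 1, 2} or NaN")
        self._vindex = {v: i for i, v in enumerate(vids)}
        self._sindex = {s: i for i, s in enumerate(self.sample_ids)}
        miss = np.isnan(self.dosages).mean(axis=0) if len(self.sample_ids) else np.zeros(0)
        for j in np.flatnonzero(miss > 0.10):
            logger.warning(
                "variant %s has %.1f%% missing genotypes",
                vids.iloc[j], 100 * miss[j],
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.variants["variant_id"])

    def variant_index(self, variant_id: str) -> int:
        try:
            return self._vindex[variant_id]
        except KeyError:
            raise KeyError(f"unknown variant_id {variant_id!r}") from None

    def sample_index(self, sample_id: str) -> int:
        try:
            return self._sindex[sample_id]
        except KeyError:
            raise KeyError(f"unknown sample_id {sample_id!r}") from None

    def dosage_vector(self, variant_id: str) -> np.ndarray:
        """Per-sample dosages of one variant (copy)."""
        return self.dosages[:, self.variant_index(variant_id)].copy()

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.sample_index(s) for s in sample_ids]
        return GenotypeMatrix(
            [self.sample_ids[i] for i in idx],
            self.variants.reset_index(drop=True),
            self.dosages[idx, :].copy(),
        )

    def subset_variants(self, variant_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.variant_index(v) for v in variant_ids]
        return GenotypeMatrix(
            list(self.sample_ids),
            self.variants.iloc[idx].reset_index(drop=True),
            self.dosages[:, idx].copy(),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.dosages, index=self.sample_ids, columns=self.variant_ids
        )


@dataclass
class ConcordanceReport:
    """Duplicate-sample genotyping concordance summary."""

    n_pairs: int
    n_snps: int
    n_comparisons: int
    n_skipped_missing: int
    n_discordant: int
    concordance: float

    def summary(self) -> str:
        return (
            f"{self.n_pairs} duplicate pairs x {self.n_snps} SNPs: "
            f"{self.n_comparisons} genotype comparisons "
            f"({self.n_skipped_missing} skipped for missingness), "
            f"{self.n_discordant} discordant, "
            f"concordance {100 * self.concordance:.1f}%"
        )


# ---------------------------------------------------------------------------
# VCF I/O


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal GT-only VCF v4.2 (diploid, unphased).

    Dosage 0/1/2 maps to ``0/0``, ``0/1``, ``1/1``; missing to ``./.``.
    The locus label is carried in an INFO ``LOCUS`` tag so a round trip
    preserves all variant metadata.
    """
    path = Path(path)
    lines = ["##fileformat=VCFv4.2", "##source=chemohf"]
    lines.append(
        '##INFO=<ID=LOCUS,Number=1,Type=String,Description="Locus label">'
    )
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for chrom in pd.unique(matrix.variants["chrom"]):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(matrix.sample_ids)
    )
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    for j, row in matrix.variants.iterrows():
        d = matrix.dosages[:, j]
        gts = ["./." if np.isnan(x) else gt_map[x] for x in d]
        locus = row["locus"] if pd.notna(row["locus"]) else "."
        lines.append(
            "\t".join(
                [
                    str(row["chrom"]), str(int(row["pos"])),
                    str(row["variant_id"]), str(row["ref"]), str(row["alt"]),
                    ".", ".", f"LOCUS={locus}", "GT",
                ]
                + gts
            )
        )
    path.write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Only biallelic diploid records with a GT field are accepted;
    multi-allelic or non-diploid records, and duplicate variant ids, raise
    :class:`VcfParseError` naming the offending record.
    """
    from cyvcf2 import VCF

    path = Path(path)
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError on bad headers
        raise VcfParseError(f"{path}: malformed VCF ({exc})") from exc
    samples = list(vcf.samples)
    rows, dosage_cols, seen = [], [], set()
    for i, var in enumerate(vcf, start=1):
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        if len(var.ALT) != 1:
            raise VcfParseError(
                f"{path}: record {i} ({vid}): multi-allelic records are not supported"
            )
        if vid in seen:
            raise VcfParseError(f"{path}: record {i}: duplicate variant id {vid!r}")
        seen.add(vid)
        col = np.empty(len(samples))
        for s, gt in enumerate(var.genotypes):
            # cyvcf2 genotype entries are [allele_1, ..., allele_k, phased]
            if len(gt) != 3:
                raise VcfParseError(
                    f"{path}: record {i} ({vid}): non-diploid genotype "
                    f"for sample {samples[s]}"
                )
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                col[s] = np.nan
            else:
                col[s] = float((a > 0) + (b > 0))
        locus = var.INFO.get("LOCUS")
        rows.append((vid, var.CHROM, var.POS, var.REF, var.ALT[0], locus))
        dosage_cols.append(col)
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    dosages = (
        np.column_stack(dosage_cols) if dosage_cols else np.zeros((len(samples), 0))
    )
    return GenotypeMatrix(samples, variants, dosages)


# ---------------------------------------------------------------------------
# TSV tables


def write_samples(samples: pd.DataFrame, path: str | Path) -> None:
    """Write the sample annotation table (stable column order)."""
    samples.loc[:, SAMPLE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_samples(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(SAMPLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing sample columns {sorted(missing)}")
    bad = set(df["group"]) - set(GROUP_LABELS)
    if bad:
        raise ValueError(f"{path}: unknown group labels {sorted(bad)}")
    df["antihtn"] = df["antihtn"].astype(bool)
    return df


def write_pairs(pairs: Iterable[tuple[str, str]], path: str | Path) -> None:
    pd.DataFrame(pairs, columns=["sample_id_1", "sample_id_2"]).to_csv(
        path, sep="\t", index=False
    )


def read_pairs(path: str | Path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t")
    return list(df[["sample_id_1", "sample_id_2"]].itertuples(index=False, name=None))


# ---------------------------------------------------------------------------
# Frequencies and QC


def _subset_dosages(
    matrix: GenotypeMatrix,
    variant_id: str,
    sample_subset: Sequence[str] | None,
) -> np.ndarray:
    d = matrix.dosage_vector(variant_id)
    if sample_subset is not None:
        d = d[[matrix.sample_index(s) for s in sample_subset]]
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise ValueError(
            f"no non-missing genotypes for {variant_id} in the requested subset"
        )
    return d


def allele_frequency(
    matrix: GenotypeMatrix,
    variant_id: str,
    sample_subset: Sequence[str] | None = None,
) -> float:
    """Alternate-allele frequency: sum(dosage) / (2 * non-missing samples)."""
    d = _subset_dosages(matrix, variant_id, sample_subset)
    return float(d.sum() / (2 * d.size))


def carrier_frequency(
    matrix: GenotypeMatrix,
    variant_id: str,
    sample_subset: Sequence[str] | None = None,
) -> float:
    """Fraction of non-missing samples carrying >= 1 alternate allele."""
    d = _subset_dosages(matrix, variant_id, sample_subset)
    return float((d >= 1).mean())


def minor_allele_report(
    matrix: GenotypeMatrix, groups: pd.Series | None = None
) -> pd.DataFrame:
    """Per-variant frequency report oriented to the global minor allele.

    The minor allele is defined over all samples combined; the stored
    matrix is never reoriented — flipping happens only in this report so
    effect-direction conventions elsewhere stay fixed to the alt allele.
    """
    recs = []
    for vid in matrix.variant_ids:
        f_all = allele_frequency(matrix, vid)
        flip = f_all > 0.5
        row = matrix.variants.iloc[matrix.variant_index(vid)]
        minor = row["ref"] if flip else row["alt"]
        rec = {
            "variant_id": vid,
            "locus": row["locus"],
            "minor_allele": minor,
            "flipped": flip,
            "maf_overall": 1 - f_all if flip else f_all,
        }
        if groups is not None:
            for g in pd.unique(groups):
                ids = [s for s, gg in zip(matrix.sample_ids, groups) if gg == g]
                f = allele_frequency(matrix, vid, ids)
                rec[f"maf_{g}"] = 1 - f if flip else f
        recs.append(rec)
    return pd.DataFrame(recs)


def duplicate_concordance(
    matrix: GenotypeMatrix, pairs: Sequence[tuple[str, str]]
) -> ConcordanceReport:
    """Genotype concordance across duplicate sample pairs.

    Each pair contributes one comparison per variant; comparisons where
    either member is missing are skipped and counted separately.
    """
    n_skipped = 0
    n_discordant = 0
    n_comparisons = 0
    for s1, s2 in pairs:
        d1 = matrix.dosages[matrix.sample_index(s1), :]
        d2 = matrix.dosages[matrix.sample_index(s2), :]
        ok = ~(np.isnan(d1) | np.isnan(d2))
        n_skipped += int((~ok).sum())
        n_comparisons += int(ok.sum())
        n_discordant += int((d1[ok] != d2[ok]).sum())
    concordance = 1.0 if n_comparisons == 0 else 1 - n_discordant / n_comparisons
    return ConcordanceReport(
        n_pairs=len(pairs),
        n_snps=matrix.n_variants,
        n_comparisons=n_comparisons,
        n_skipped_missing=n_skipped,
        n_discordant=n_discordant,
        concordance=concordance,
    )
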