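"""Genotype and phenotype I/O.

Conventions used throughout the package:

* coordinates are 1-based, as in VCF;
* the effect allele is always ALT, and EAF is the ALT-allele frequency;
* dosages are ALT-allele counts in ``[0, 2]`` (hard calls are 0/1/2);
* phenotype and summary-statistic tables are tab-separated text with a header.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: columns every phenotype table must carry (PCs are optional extras: pc1, pc2, ...)
PHENO_REQUIRED = ("sample_id", "bilirubin", "hypertension", "sex", "age", "bmi", "t2d")

#: summary-statistic column order
SUMSTAT_COLUMNS = ("chrom", "pos", "id", "ea", "oa", "eaf", "beta", "se", "p")


class VcfParseError(ValueError):
    """Raised when a VCF cannot be parsed; carries a line number when known."""


@dataclass
class GenotypeMatrix:
    """Samples x variants effect-allele dosage matrix with variant metadata.

    Attributes
    ----------
    samples : list of str
        Ordered sample identifiers (rows of ``dosage``).
    variants : pandas.DataFrame
        One row per variant with columns ``chrom, pos, id, ref, alt, eaf``
        and optionally ``info`` (imputation info score, NaN when unknown).
    dosage : numpy.ndarray
        ``(n_samples, n_variants)`` float array of ALT-allele dosages in [0, 2].
    """

    samples: list[str]
    variants: pd.DataFrame
    dosage: np.ndarray
    missingness: np.ndarray | None = field(default=None)

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    def eaf_from_dosage(self) -> np.ndarray:
        """Recompute ALT-allele frequency from the dosage matrix."""
        return self.dosage.mean(axis=0) / 2.0

    def validate(self) -> None:
        """Check structural invariants; raises ``ValueError`` on violation."""
        ids = self.variants["id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate variant ID: {dup!r}")
        if len(self.samples) != self.dosage.shape[0]:
            raise ValueError("sample count does not match dosage rows")
        if len(self.variants) != self.dosage.shape[1]:
            raise ValueError("variant count does not match dosage columns")
        stored = np.asarray(self.variants["eaf"], dtype=float)
        recomputed = self.eaf_from_dosage()
        if not np.allclose(stored, recomputed, atol=1e-9, rtol=0.0):
            j = int(np.argmax(np.abs(stored - recomputed)))
            raise ValueError(
                f"stored EAF disagrees with dosage at variant {ids.iloc[j]!r}: "
                f"{stored[j]} vs {recomputed[j]}"
            )

    def subset_variants(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=self.variants.loc[mask].reset_index(drop=True),
            dosage=self.dosage[:, mask],
            missingness=None if self.missingness is None else self.missingness[mask],
        )

    def index_of(self, variant_id: str) -> int:
        idx = np.flatnonzero((self.variants["id"] == variant_id).to_numpy())
        if idx.size == 0:
            raise KeyError(f"variant {variant_id!r} not found")
        return int(idx[0])


@dataclass
class PhenotypeTable:
    """Per-sample phenotypes and covariates.

    Required columns: sample_id, bilirubin (mg/dL), hypertension {0,1},
    sex {0,1; 1 = male}, age (years), bmi (kg/m^2), t2d {0,1}. Principal
    components, when present, are columns named ``pc1, pc2, ...``.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PHENO_REQUIRED if c not in self.df.columns]
        if missing:
            raise ValueError(f"phenotype table missing required column(s): {', '.join(missing)}")
        if self.df["sample_id"].isna().any():
            raise ValueError("phenotype table contains missing sample IDs")
        for col in ("hypertension", "sex", "t2d"):
            vals = self.df[col].dropna()
            if not vals.isin([0, 1]).all():
                raise ValueError(f"column {col!r} must be strictly 0/1")

    @property
    def samples(self) -> list[str]:
        return self.df["sample_id"].astype(str).tolist()

    @property
    def pc_columns(self) -> list[str]:
        return [c for c in self.df.columns if c.startswith("pc") and c[2:].isdigit()]

    def aligned_to(self, samples: list[str]) -> "PhenotypeTable":
        """Reorder rows to match a sample list; all samples must be present."""
        indexed = self.df.set_index(self.df["sample_id"].astype(str))
        missing = [s for s in samples if s not in indexed.index]
        if missing:
            raise ValueError(f"samples absent from phenotype table: {missing[:5]}")
        return PhenotypeTable(indexed.loc[samples].reset_index(drop=True))


def _locate_malformed_line(path: str) -> int | None:
    """Best-effort scan for the first structurally broken data line."""
    try:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if line.startswith("#") or not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 8:
                    return lineno
                try:
                    int(fields[1])
                except ValueError:
                    return lineno
    except OSError:
        return None
    return None


def read_vcf(path: str, dosage_field_preference: str = "DS") -> GenotypeMatrix:
    """Read a VCF 4.x into a :class:`GenotypeMatrix`.

    Uses the DS (dosage) FORMAT field when present and preferred, otherwise
    sums GT alleles. Multiallelic records are rejected with a warning; missing
    genotypes are mean-imputed per variant and the per-variant missingness
    fraction is retained. Variants with all genotypes missing are dropped.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad headers
        lineno = _locate_malformed_line(path)
        where = f" (first malformed line: {lineno})" if lineno else ""
        raise VcfParseError(f"cannot parse VCF {path!r}: {exc}{where}") from exc

    samples = list(vcf.samples)
    n = len(samples)
    rows, cols, miss = [], [], []
    n_multi = 0
    try:
        for rec in vcf:
            if len(rec.ALT) != 1:
                n_multi += 1
                logger.warning("rejecting multiallelic record %s:%s", rec.CHROM, rec.POS)
                continue
            ds = None
            if dosage_field_preference == "DS":
                try:
                    raw = rec.format("DS")
                except KeyError:
                    raw = None
                if raw is not None:
                    ds = np.asarray(raw, dtype=float).reshape(n)
                    ds[ds < 0] = np.nan  # cyvcf2 encodes missing as negative sentinel
            if ds is None:
                gt = rec.gt_types  # 0=hom-ref 1=het 2=unknown 3=hom-alt
                ds = np.choose(gt, [0.0, 1.0, np.nan, 2.0])
            m_frac = float(np.isnan(ds).mean())
            if m_frac == 1.0:
                warnings.warn(
                    f"variant {rec.ID or f'{rec.CHROM}:{rec.POS}'} has no called "
                    "genotypes and was dropped",
                    stacklevel=2,
                )
                continue
            if m_frac > 0:
                ds = np.where(np.isnan(ds), np.nanmean(ds), ds)
            info_score = rec.INFO.get("INFO", rec.INFO.get("R2", None))
            rows.append(
                (
                    rec.CHROM,
                    int(rec.POS),
                    rec.ID or f"{rec.CHROM}:{rec.POS}",
                    rec.REF,
                    rec.ALT[0],
                    float(ds.mean() / 2.0),
                    np.nan if info_score is None else float(info_score),
                )
            )
            cols.append(ds)
            miss.append(m_frac)
    except VcfParseError:
        raise
    except Exception as exc:
        lineno = _locate_malformed_line(path)
        where = f" (first malformed line: {lineno})" if lineno else ""
        raise VcfParseError(f"error while reading VCF {path!r}: {exc}{where}") from exc

    if n_multi:
        logger.info("rejected %d multiallelic record(s)", n_multi)
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt", "eaf", "info"])
    dosage = np.column_stack(cols) if cols else np.empty((n, 0))
    return GenotypeMatrix(samples=samples, variants=variants, dosage=dosage,
                          missingness=np.asarray(miss))


def write_vcf(g: GenotypeMatrix, path: str, dosage: bool = False) -> None:
    """Write a VCF 4.2 file; GT for hard calls, DS for fractional dosages."""
    hard = not dosage and np.allclose(g.dosage, np.round(g.dosage))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if hard:
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        else:
            fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="ALT dosage">\n')
        fh.write('##INFO=<ID=INFO,Number=1,Type=Float,Description="Imputation info score">\n')
        for chrom in pd.unique(g.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(g.samples) + "\n")
        gt_code = {0: "0/0", 1: "0/1", 2: "1/1"}
        has_info = "info" in g.variants.columns
        for j, v in enumerate(g.variants.itertuples(index=False)):
            info = "."
            if has_info and np.isfinite(getattr(v, "info", np.nan)):
                info = f"INFO={v.info:.6g}"
            if hard:
                calls = "\t".join(gt_code[int(round(d))] for d in g.dosage[:, j])
                fmt = "GT"
            else:
                calls = "\t".join(f"{d:.6g}" for d in g.dosage[:, j])
                fmt = "DS"
            fh.write(f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\t.\t{info}\t{fmt}\t{calls}\n")


def filter_variants(g: GenotypeMatrix, maf_min: float = 0.01, info_min: float = 0.3) -> GenotypeMatrix:
    """Keep variants with MAF >= maf_min and (info missing or info >= info_min).

    Both thresholds are inclusive; variant order is preserved.
    """
    if not 0 <= maf_min <= 0.5:
        raise ValueError("maf_min must be in [0, 0.5]")
    if not 0 <= info_min <= 1:
        raise ValueError("info_min must be in [0, 1]")
    eaf = np.asarray(g.variants["eaf"], dtype=float)
    maf = np.minimum(eaf, 1.0 - eaf)
    keep = maf >= maf_min
    if "info" in g.variants.columns:
        info = np.asarray(g.variants["info"], dtype=float)
        keep &= np.isnan(info) | (info >= info_min)
    return g.subset_variants(keep)


def read_phenotypes(path: str) -> PhenotypeTable:
    """Read a tab-separated phenotype table; required columns are validated."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str},
                     float_precision="round_trip")
    return PhenotypeTable(df)


def write_phenotypes(pheno: PhenotypeTable, path: str) -> None:
    pheno.df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_summary_stats(results: pd.DataFrame, path: str) -> None:
    """Write association summary statistics as TSV.

    Expects the canonical columns (:data:`SUMSTAT_COLUMNS`); extra columns
    are carried along after them.
    """
    missing = [c for c in SUMSTAT_COLUMNS if c not in results.columns]
    if missing:
        raise ValueError(f"summary statistics missing column(s): {', '.join(missing)}")
    extras = [c for c in results.columns if c not in SUMSTAT_COLUMNS]
    results[list(SUMSTAT_COLUMNS) + extras].to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_summary_stats(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in SUMSTAT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary statistics missing column(s): {', '.join(missing)}")
    return df
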