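"""VCF and tabular I/O plus variant-quality hard filtering.

Genotypes are held as an alt-allele dosage matrix (samples x loci) with
entries in {0, 1, 2, MISSING}; per-locus metadata (position, alleles, QUAL
and the INFO hard-filter metrics) live in a :class:`VariantTable` aligned
with the matrix columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing diploid genotype in the dosage matrix.
MISSING: int = -1

#: INFO metrics consulted by the hard filter, in canonical order.
INFO_METRICS = ("QD", "FS", "MQ", "SOR", "MQRankSum")


class VcfParseError(ValueError):
    """Raised when a VCF cannot be parsed or violates ploidy assumptions."""


@dataclass
class VariantTable:
    """Per-locus metadata aligned with the columns of a GenotypeMatrix.

    ``df`` columns: chrom, pos (1-based), ref, alt, qual, QD, FS, MQ, SOR,
    MQRankSum, missing_rate.  Absent QUAL/INFO values are NaN.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["chrom", "pos", "ref", "alt", "qual", *INFO_METRICS, "missing_rate"]
        for col in required:
            if col not in self.df.columns:
                raise ValueError(f"VariantTable missing column {col!r}")
        if len(self.df):
            if (self.df["pos"] < 1).any():
                raise ValueError("VariantTable: pos must be >= 1")
            mr = self.df["missing_rate"].to_numpy()
            if ((mr < 0) | (mr > 1)).any():
                raise ValueError("VariantTable: missing_rate must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def locus_keys(self) -> list[str]:
        d = self.df
        return [
            f"{c}:{p}:{r}:{a}"
            for c, p, r, a in zip(d["chrom"], d["pos"], d["ref"], d["alt"])
        ]

    def subset(self, mask_or_index) -> "VariantTable":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            sub = self.df.loc[idx]
        else:
            sub = self.df.iloc[idx]
        return VariantTable(sub.reset_index(drop=True))


@dataclass
class GenotypeMatrix:
    """samples x loci alt-allele dosage matrix with missingness."""

    samples: list[str]
    loci: list[str]
    dosage: np.ndarray  # int8, entries in {0, 1, 2, MISSING}

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.samples), len(self.loci)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.loci)} loci"
            )
        valid = np.isin(self.dosage, (0, 1, 2, MISSING))
        if not valid.all():
            bad = np.unique(self.dosage[~valid])
            raise ValueError(f"dosage entries outside {{0,1,2,MISSING}}: {bad}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def has_missing(self) -> bool:
        return bool((self.dosage == MISSING).any())

    def missing_rate(self) -> np.ndarray:
        """Per-locus fraction of missing genotypes."""
        return (self.dosage == MISSING).mean(axis=0)

    def subset_loci(self, mask_or_index) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            samples=list(self.samples),
            loci=[self.loci[i] for i in idx],
            dosage=self.dosage[:, idx].copy(),
        )

    def subset_samples(self, mask_or_index) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            loci=list(self.loci),
            dosage=self.dosage[idx, :].copy(),
        )


@dataclass
class PhenotypeTable:
    """Sample -> trait value table, optionally keyed by environment.

    ``df`` columns: sample, value and, when environments are present, env.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("sample", "value"):
            if col not in self.df.columns:
                raise ValueError(f"PhenotypeTable missing column {col!r}")
        vals = pd.to_numeric(self.df["value"], errors="coerce")
        if vals.isna().any() or not np.isfinite(vals.to_numpy(dtype=float)).all():
            raise ValueError("PhenotypeTable: non-numeric or non-finite trait value")
        self.df = self.df.copy()
        self.df["value"] = vals.astype(float)
        keys = ["sample", "env"] if self.has_env else ["sample"]
        if self.df.duplicated(subset=keys).any():
            dup = self.df.loc[self.df.duplicated(subset=keys), "sample"].iloc[0]
            raise ValueError(f"duplicate sample id within environment: {dup!r}")

    @property
    def has_env(self) -> bool:
        return "env" in self.df.columns

    def __len__(self) -> int:
        return len(self.df)


@dataclass(frozen=True)
class FilterConfig:
    """Hard-filter bounds; defaults are the standard GATK SNP thresholds.

    A locus is dropped iff any *present* metric violates its bound
    (strict inequalities) or its missing rate reaches ``max_missing_rate``.
    Absent (NaN) metrics never disqualify a locus.
    """

    qd_min: float = 2.0
    qual_min: float = 30.0
    fs_max: float = 60.0
    mq_min: float = 40.0
    sor_max: float = 3.0
    mqranksum_min: float = -12.5
    max_missing_rate: float = 0.95


def read_vcf(path, *, keep_first_alt: bool = False) -> tuple[GenotypeMatrix, VariantTable]:
    """Read a VCF 4.x file into a dosage matrix and variant table.

    Dosage is the alt-allele count from GT (0/0 -> 0, 0/1 or 1/0 -> 1,
    1/1 -> 2, ./. -> MISSING); phased and unphased genotypes are treated
    identically.  Multiallelic records are rejected unless
    ``keep_first_alt`` is set, in which case any non-reference allele is
    counted as the first alternate.

    Raises
    ------
    VcfParseError
        On malformed input, a multiallelic record (without
        ``keep_first_alt``), or a non-diploid genotype.
    """
    from cyvcf2 import VCF

    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises OSError/Exception on bad input
        raise VcfParseError(f"cannot parse VCF {path!r}: {exc}") from exc

    samples = list(vcf.samples)
    n = len(samples)
    rows = []
    dosages = []
    for i, v in enumerate(vcf):
        if len(v.ALT) != 1:
            if not keep_first_alt:
                raise VcfParseError(
                    f"multiallelic record at {v.CHROM}:{v.POS} (record {i + 1}); "
                    "pass keep_first_alt=True to keep the first alternate"
                )
        gts = v.genotypes
        if len(gts) != n:
            raise VcfParseError(f"record {v.CHROM}:{v.POS}: genotype count != sample count")
        col = np.empty(n, dtype=np.int8)
        for j, gt in enumerate(gts):
            alleles = gt[:-1]  # last element is the phase flag
            if len(alleles) != 2:
                raise VcfParseError(
                    f"non-diploid genotype for sample {samples[j]!r} at {v.CHROM}:{v.POS}"
                )
            if alleles[0] < 0 or alleles[1] < 0:
                col[j] = MISSING
            else:
                col[j] = int(alleles[0] > 0) + int(alleles[1] > 0)
        dosages.append(col)
        info = {m: _info_float(v, m) for m in INFO_METRICS}
        rows.append(
            {
                "chrom": v.CHROM,
                "pos": v.POS,
                "ref": v.REF,
                "alt": v.ALT[0] if v.ALT else ".",
                "qual": np.nan if v.QUAL is None else float(v.QUAL),
                **info,
                "missing_rate": float((col == MISSING).mean()) if n else 0.0,
            }
        )
    vcf.close()

    if rows:
        df = pd.DataFrame(rows)
    else:
        df = pd.DataFrame(
            columns=["chrom", "pos", "ref", "alt", "qual", *INFO_METRICS, "missing_rate"]
        )
    vt = VariantTable(df)
    dosage = (
        np.stack(dosages, axis=1) if dosages else np.zeros((n, 0), dtype=np.int8)
    )
    gm = GenotypeMatrix(samples=samples, loci=vt.locus_keys, dosage=dosage)
    return gm, vt


def _info_float(variant, key: str) -> float:
    val = variant.INFO.get(key)
    if val is None:
        return np.nan
    try:
        return float(val)
    except (TypeError, ValueError):
        return np.nan


def write_vcf(path, gm: GenotypeMatrix, vt: VariantTable) -> None:
    """Write a minimal VCF 4.2 text file for the given matrix/table pair.

    QUAL and INFO floats are emitted so that an htslib read-back (which
    stores them as 32-bit floats) reproduces the in-memory values exactly,
    provided those values are float32-representable.
    """
    if gm.n_loci != len(vt):
        raise ValueError("GenotypeMatrix and VariantTable are not aligned")
    d = vt.df
    contigs = list(dict.fromkeys(d["chrom"])) if len(d) else []
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=autogs\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        for m in INFO_METRICS:
            fh.write(f'##INFO=<ID={m},Number=1,Type=Float,Description="{m}">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        for i in range(len(d)):
            row = d.iloc[i]
            qual = "." if pd.isna(row["qual"]) else _fmt_float(row["qual"])
            info_parts = [
                f"{m}={_fmt_float(row[m])}" for m in INFO_METRICS if not pd.isna(row[m])
            ]
            info = ";".join(info_parts) if info_parts else "."
            gts = "\t".join(gt_strings[int(x)] for x in gm.dosage[:, i])
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t.\t{row['ref']}\t{row['alt']}\t"
                f"{qual}\t.\t{info}\tGT\t{gts}\n"
            )


def _fmt_float(x: float) -> str:
    # shortest decimal that round-trips through float32 (htslib's INFO/QUAL type)
    f32 = np.float32(x)
    for prec in range(1, 10):
        s = f"{float(f32):.{prec}f}"
        if np.float32(s) == f32:
            return s
    return repr(float(f32))


def filter_variants(vt: VariantTable, thresholds: FilterConfig | None = None) -> np.ndarray:
    """Return a boolean keep-mask over loci under the hard-filter bounds.

    A locus is dropped iff QD < qd_min, QUAL < qual_min, FS > fs_max,
    MQ < mq_min, SOR > sor_max, MQRankSum < mqranksum_min (each only when
    the metric is present) or missing_rate >= max_missing_rate.
    """
    t = thresholds or FilterConfig()
    d = vt.df
    if not len(d):
        return np.zeros(0, dtype=bool)

    def _viol(col: str, bound: float, low: bool) -> np.ndarray:
        x = d[col].to_numpy(dtype=float)
        present = ~np.isnan(x)
        v = np.zeros(len(d), dtype=bool)
        v[present] = x[present] < bound if low else x[present] > bound
        return v

    drop = (
        _viol("QD", t.qd_min, low=True)
        | _viol("qual", t.qual_min, low=True)
        | _viol("FS", t.fs_max, low=False)
        | _viol("MQ", t.mq_min, low=True)
        | _viol("SOR", t.sor_max, low=False)
        | _viol("MQRankSum", t.mqranksum_min, low=True)
        | (d["missing_rate"].to_numpy(dtype=float) >= t.max_missing_rate)
    )
    keep = ~drop
    if not keep.any():
        logger.warning("filter_variants: no loci pass the hard filter")
    return keep


def impute_missing(gm: GenotypeMatrix, method: str = "mode") -> GenotypeMatrix:
    """Fill MISSING entries; default per-locus most frequent dosage.

    Ties between dosage classes break toward the lower dosage.  A locus with
    every genotype missing cannot be imputed and raises ``ValueError``.
    """
    if method != "mode":
        raise ValueError(f"unknown imputation method {method!r}")
    if not gm.has_missing():
        return gm
    dosage = gm.dosage.copy()
    miss = dosage == MISSING
    all_missing = miss.all(axis=0)
    if all_missing.any():
        bad = [gm.loci[i] for i in np.flatnonzero(all_missing)[:5]]
        raise ValueError(f"cannot impute loci with 100% missing genotypes: {bad}")
    obs = np.where(miss, 127, dosage)  # sentinel outside counted range
    counts = np.stack([(obs == d).sum(axis=0) for d in (0, 1, 2)])
    modes = counts.argmax(axis=0).astype(np.int8)  # argmax takes lowest on ties
    fill = np.broadcast_to(modes, dosage.shape)
    dosage[miss] = fill[miss]
    return GenotypeMatrix(samples=list(gm.samples), loci=list(gm.loci), dosage=dosage)


def read_phenotypes(path) -> PhenotypeTable:
    """Read a phenotype CSV with header columns sample,value[,env]."""
    df = pd.read_csv(path, dtype={0: str})
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    if "sample" not in cols or "value" not in cols:
        raise ValueError(
            f"phenotype CSV {path!r} must have header columns 'sample,value[,env]', got {cols}"
        )
    keep = ["sample", "value"] + (["env"] if "env" in cols else [])
    df = df[keep]
    df["sample"] = df["sample"].astype(str)
    if "env" in keep:
        df["env"] = df["env"].astype(str)
    return PhenotypeTable(df.reset_index(drop=True))


def write_phenotypes(pt: PhenotypeTable, path) -> None:
    pt.df.to_csv(path, index=False)


def write_predictions(table: pd.DataFrame, path) -> None:
    """Write a prediction CSV: sample, predicted[, env]."""
    cols = ["sample", "predicted"] + (["env"] if "env" in table.columns else [])
    table[cols].to_csv(path, index=False)


def intersect_samples(gm: GenotypeMatrix, pt: PhenotypeTable) -> tuple[np.ndarray, np.ndarray]:
    """Match phenotype records to genotype rows case-sensitively.

    Returns (genotype row indices, phenotype row indices), aligned, in
    phenotype order; logs how many phenotype records lacked genotypes.
    """
    pos = {s: i for i, s in enumerate(gm.samples)}
    g_idx, p_idx = [], []
    for j, s in enumerate(pt.df["sample"]):
        if s in pos:
            g_idx.append(pos[s])
            p_idx.append(j)
    dropped = len(pt) - len(p_idx)
    if dropped:
        logger.info("intersect_samples: %d phenotype records without genotypes dropped", dropped)
    return np.asarray(g_idx, dtype=int), np.asarray(p_idx, dtype=int)
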