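"""Genotype and phenotype I/O, quality control, and ranking tables.

Genotypes are held as an N x P minor/alternate-allele dosage matrix with
values 0/1/2 and NaN for missing calls, together with per-SNP metadata
(identifier, chromosome, 1-based position, minor allele frequency).
Supported on-disk formats: VCF 4.x (GT field, biallelic sites), PLINK
``.raw``-style whitespace-separated dosage text, and a plain TSV dosage
matrix.  Phenotypes are two-column TSV (id, value).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix", "Phenotype", "QcReport", "ParseError",
    "read_genotypes", "read_phenotype", "write_phenotype",
    "write_vcf", "write_plink_raw", "qc_filter", "hwe_chisq",
    "flanking_missingness_test", "write_ranking", "read_ranking",
    "mean_impute", "dosage_classes",
]

# Non-genotype leading columns of a PLINK .raw file
_PLINK_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


class ParseError(ValueError):
    """A genotype file did not parse under the named format."""


def _fold_maf(freq: np.ndarray) -> np.ndarray:
    return np.minimum(freq, 1.0 - freq)


@dataclass
class GenotypeMatrix:
    """N x P allele dosages in {0, 1, 2} with NaN for missing calls."""

    dosages: np.ndarray
    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    sample_ids: np.ndarray | None = None
    maf: np.ndarray = field(init=False)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (subjects x SNPs)")
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        n, p = self.dosages.shape
        for name, arr in (("snp_ids", self.snp_ids), ("chrom", self.chrom),
                          ("pos", self.pos)):
            if arr.shape[0] != p:
                raise ValueError(f"{name} length {arr.shape[0]} != {p} SNPs")
        if self.sample_ids is None:
            self.sample_ids = np.array([f"S{i + 1}" for i in range(n)],
                                       dtype=object)
        else:
            self.sample_ids = np.asarray(self.sample_ids, dtype=object)
            if self.sample_ids.shape[0] != n:
                raise ValueError("sample_ids length mismatch")
        ok = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = np.argwhere(~ok)[0]
            raise ValueError(
                f"dosage at (subject {bad[0]}, snp {bad[1]}) not in "
                "{0,1,2,missing}")
        if len(set(self.snp_ids)) != p:
            raise ValueError("snp_ids are not unique")
        # positions nondecreasing within chromosome
        for c in pd.unique(self.chrom):
            pc = self.pos[self.chrom == c]
            if np.any(np.diff(pc) < 0):
                raise ValueError(f"positions not sorted within chromosome {c}")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-missing SNP
            freq = np.nanmean(self.dosages, axis=0) / 2.0
        self.maf = _fold_maf(freq)

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def missingness(self) -> np.ndarray:
        """Per-SNP fraction of missing calls."""
        return np.isnan(self.dosages).mean(axis=0)

    def take_snps(self, index) -> "GenotypeMatrix":
        """New matrix restricted to the given SNP indices (order kept)."""
        index = np.asarray(index)
        return GenotypeMatrix(self.dosages[:, index], self.snp_ids[index],
                              self.chrom[index], self.pos[index],
                              sample_ids=self.sample_ids)


@dataclass
class Phenotype:
    """A continuous univariate phenotype aligned with genotype rows."""

    values: np.ndarray
    ids: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("phenotype values must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("phenotype contains non-finite values")
        if self.ids is None:
            self.ids = np.array([f"S{i + 1}" for i in range(len(self.values))],
                                dtype=object)
        else:
            self.ids = np.asarray(self.ids, dtype=object)
            if len(self.ids) != len(self.values):
                raise ValueError("phenotype ids length mismatch")


@dataclass
class QcReport:
    """Record of removals performed by a QC step, one reason per item."""

    removed_snps: list = field(default_factory=list)
    removed_subjects: list = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)
    n_input_snps: int = 0
    n_output_snps: int = 0
    empty_result: bool = False

    def reasons(self) -> dict:
        out: dict[str, int] = {}
        for _, reason in self.removed_snps:
            out[reason] = out.get(reason, 0) + 1
        return out


# ---------------------------------------------------------------------------
# readers / writers


def _read_vcf(path: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad headers
        raise ParseError(f"cannot open VCF {path}: {exc}") from exc
    samples = np.array(vcf.samples, dtype=object)
    rows, ids, chroms, poss = [], [], [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            logger.warning("skipping multiallelic site %s:%d",
                           rec.CHROM, rec.POS)
            continue
        # gts012: 0/1/2 alt dosage, 3 = missing
        g = rec.gt_types.astype(np.float64)
        g[g == 3] = np.nan
        rows.append(g)
        ids.append(rec.ID if rec.ID not in (None, ".") else
                   f"{rec.CHROM}:{rec.POS}")
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
    if not rows:
        raise ParseError(f"no biallelic sites in {path}")
    return GenotypeMatrix(np.column_stack(rows), ids, chroms, poss,
                          sample_ids=samples)


def _read_plink_raw(path: str) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep=r"\s+")
    except Exception as exc:
        raise ParseError(f"cannot parse PLINK raw file {path}: {exc}") from exc
    meta_cols = [c for c in _PLINK_META if c in df.columns]
    if "IID" not in meta_cols:
        raise ParseError(f"{path}: PLINK raw header must contain IID")
    snp_cols = [c for c in df.columns if c not in meta_cols]
    if not snp_cols:
        raise ParseError(f"{path}: no SNP columns")
    dos = df[snp_cols].to_numpy(dtype=np.float64)
    # strip the _A allele suffix PLINK appends to column names
    ids = [c.rsplit("_", 1)[0] if "_" in c else c for c in snp_cols]
    return GenotypeMatrix(dos, ids, ["0"] * len(ids),
                          np.arange(1, len(ids) + 1),
                          sample_ids=df["IID"].astype(str).to_numpy())


def _read_tsv(path: str) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:
        raise ParseError(f"cannot parse TSV dosage file {path}: {exc}") from exc
    return GenotypeMatrix(df.to_numpy(dtype=np.float64),
                          list(df.columns), ["0"] * df.shape[1],
                          np.arange(1, df.shape[1] + 1),
                          sample_ids=df.index.astype(str).to_numpy())


def read_genotypes(path, format: str = "vcf") -> GenotypeMatrix:
    """Read a genotype matrix from ``vcf``, ``plink_raw`` or ``tsv`` text.

    Missing calls are preserved as NaN; multiallelic VCF sites are skipped
    with a logged warning.  PLINK/TSV formats carry no coordinates, so
    chromosome is set to "0" and positions to the column order.
    """
    readers = {"vcf": _read_vcf, "plink_raw": _read_plink_raw,
               "tsv": _read_tsv}
    if format not in readers:
        raise ValueError(f"unknown genotype format {format!r}")
    return readers[format](str(path))


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write a minimal GT-only VCF 4.2 (REF=A, ALT=C placeholders)."""
    gtmap = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in pd.unique(g.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, g.sample_ids)) + "\n")
        for j in range(g.n_snps):
            gts = "\t".join("./." if np.isnan(d) else gtmap[d]
                            for d in g.dosages[:, j])
            fh.write(f"{g.chrom[j]}\t{g.pos[j]}\t{g.snp_ids[j]}"
                     f"\tA\tC\t.\tPASS\t.\tGT\t{gts}\n")


def write_plink_raw(g: GenotypeMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("FID IID PAT MAT SEX PHENOTYPE "
                 + " ".join(f"{s}_C" for s in g.snp_ids) + "\n")
        for i in range(g.n_subjects):
            row = " ".join("NA" if np.isnan(d) else str(int(d))
                           for d in g.dosages[i])
            fh.write(f"{g.sample_ids[i]} {g.sample_ids[i]} 0 0 0 -9 {row}\n")


def read_phenotype(path) -> Phenotype:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ParseError(f"{path}: phenotype TSV needs (id, value) columns")
    return Phenotype(df.iloc[:, 1].to_numpy(dtype=np.float64),
                     ids=df.iloc[:, 0].astype(str).to_numpy())


def write_phenotype(ph: Phenotype, path) -> None:
    pd.DataFrame({"id": ph.ids, "value": ph.values}).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# quality control


def hwe_chisq(n_ref_hom: int, n_het: int, n_alt_hom: int) -> tuple[float, float]:
    """1-df chi-square goodness-of-fit test for Hardy-Weinberg proportions.

    Expected counts are np^2, 2npq, nq^2 with the allele frequency estimated
    from the same counts.  Returns (statistic, p).  Monomorphic sites give
    statistic 0, p 1.
    """
    n = n_ref_hom + n_het + n_alt_hom
    if n == 0:
        return 0.0, 1.0
    q = (n_het + 2 * n_alt_hom) / (2 * n)
    p = 1.0 - q
    if q == 0.0 or p == 0.0:
        return 0.0, 1.0
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([n_ref_hom, n_het, n_alt_hom], dtype=float)
    stat = float(np.sum((obs - exp) ** 2 / exp))
    return stat, float(stats.chi2.sf(stat, df=1))


def _hwe_pvalues(g: GenotypeMatrix) -> np.ndarray:
    out = np.empty(g.n_snps)
    for j in range(g.n_snps):
        d = g.dosages[:, j]
        d = d[~np.isnan(d)]
        out[j] = hwe_chisq(int(np.sum(d == 0)), int(np.sum(d == 1)),
                           int(np.sum(d == 2)))[1]
    return out


def qc_filter(g: GenotypeMatrix, maf_min: float = 0.01,
              miss_max: float = 0.01,
              hwe_alpha: float = 1e-6) -> tuple[GenotypeMatrix, QcReport]:
    """Remove SNPs with low MAF, high missingness, or HWE deviation.

    A removed SNP is reported once, with the first triggered reason in the
    order maf, missingness, hwe.  Surviving SNPs satisfy MAF >= maf_min,
    missingness <= miss_max and HWE p >= hwe_alpha.
    """
    for name, v in (("maf_min", maf_min), ("miss_max", miss_max),
                    ("hwe_alpha", hwe_alpha)):
        if not 0.0 < v < 1.0:
            raise ValueError(f"{name} must be in (0,1), got {v}")
    report = QcReport(thresholds={"maf_min": maf_min, "miss_max": miss_max,
                                  "hwe_alpha": hwe_alpha},
                      n_input_snps=g.n_snps)
    miss = g.missingness()
    hwe_p = _hwe_pvalues(g)
    keep = np.ones(g.n_snps, dtype=bool)
    for j in range(g.n_snps):
        if g.maf[j] < maf_min:
            report.removed_snps.append((g.snp_ids[j], "maf"))
        elif miss[j] > miss_max:
            report.removed_snps.append((g.snp_ids[j], "missingness"))
        elif hwe_p[j] < hwe_alpha:
            report.removed_snps.append((g.snp_ids[j], "hwe"))
        else:
            continue
        keep[j] = False
    report.n_output_snps = int(keep.sum())
    if report.n_output_snps == 0:
        report.empty_result = True
        warnings.warn("qc_filter removed every SNP", stacklevel=2)
        out = GenotypeMatrix(np.empty((g.n_subjects, 0)), [], [], [],
                             sample_ids=g.sample_ids)
        return out, report
    return g.take_snps(np.flatnonzero(keep)), report


def flanking_missingness_test(g: GenotypeMatrix,
                              alpha: float = 1e-10) -> QcReport:
    """Flag SNPs whose missingness is predicted by flanking genotypes.

    For each SNP with at least one missing call, a logistic regression of the
    missingness indicator on the dosages of up to two flanking SNPs on each
    side (same chromosome; fewer at edges) is compared with the
    intercept-only model by likelihood ratio.  SNPs with model p < alpha are
    flagged; informative missingness of this kind indicates genotyping
    artefacts.  Complete separation is resolved in favour of flagging, with a
    logged note.
    """
    import statsmodels.api as sm

    report = QcReport(thresholds={"alpha": alpha}, n_input_snps=g.n_snps)
    miss = np.isnan(g.dosages)
    any_miss = miss.any(axis=0)
    if not any_miss.any():
        report.n_output_snps = g.n_snps
        return report
    imputed = mean_impute(g.dosages)
    order = np.arange(g.n_snps)
    for j in np.flatnonzero(any_miss):
        same = order[(g.chrom == g.chrom[j])]
        k = int(np.searchsorted(same, j))
        flank = np.concatenate([same[max(0, k - 2):k], same[k + 1:k + 3]])
        if flank.size == 0:
            continue
        ymiss = miss[:, j].astype(float)
        X = sm.add_constant(imputed[:, flank])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(ymiss, X).fit(method="lbfgs", maxiter=200,
                                             disp=0)
                null = sm.Logit(ymiss, np.ones((len(ymiss), 1))).fit(
                    method="lbfgs", maxiter=200, disp=0)
            lr = 2.0 * (fit.llf - null.llf)
            pval = float(stats.chi2.sf(max(lr, 0.0), df=flank.size))
        except Exception:
            logger.warning("separation in missingness regression for %s; "
                           "flagged via likelihood-ratio fallback",
                           g.snp_ids[j])
            pval = 0.0
        if pval < alpha:
            report.removed_snps.append((g.snp_ids[j], "flanking_missingness"))
    report.n_output_snps = g.n_snps - len(report.removed_snps)
    return report


# ---------------------------------------------------------------------------
# rankings and downstream helpers


def write_ranking(table: pd.DataFrame, path) -> None:
    """Write a ranking TSV (snp_id, chrom, pos, score, rank; rank 1 = best).

    ``table`` must carry a ``score`` column oriented so that larger is
    better; tied scores receive their average rank.
    """
    if len(table) == 0:
        raise ValueError("refusing to write an empty ranking table")
    out = table[["snp_id", "chrom", "pos", "score"]].copy()
    out["rank"] = rankdata(-out["score"].to_numpy(), method="average")
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_ranking(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def mean_impute(dosages: np.ndarray) -> np.ndarray:
    """Replace NaN dosages with the per-SNP mean (float output)."""
    out = np.array(dosages, dtype=np.float64, copy=True)
    nan = np.isnan(out)
    if nan.any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            col_mean = np.nanmean(out, axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        out[nan] = np.take(col_mean, np.nonzero(nan)[1])
    return out


def dosage_classes(dosages: np.ndarray) -> np.ndarray:
    """Map (possibly mean-imputed) dosages to int8 classes 0/1/2.

    Class boundaries are the tree split points 0.5 and 1.5, so imputed
    fractional dosages land in the class their value falls in.
    """
    x = mean_impute(dosages)
    return ((x >= 0.5).astype(np.int8) + (x >= 1.5).astype(np.int8))
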