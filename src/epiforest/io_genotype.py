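"""Genotype/phenotype I/O, variant filtering, and tabular output.

Reads PLINK transposed-text (.tped/.tfam) and multi-sample VCF into an
in-memory minor-allele dosage matrix.  Dosages are always oriented on the
*minor* allele as determined from the sample itself, so that the MAF filter
and all downstream statistics share one allele convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

AUTOSOMES = {str(c) for c in range(1, 23)}
VALID_CHROMS = AUTOSOMES | {"X", "Y", "XY", "MT"}

#: tfam/ped phenotype codes: PLINK 1 = control, 2 = case, 0/-9 = missing
_PHENO_MAP = {"1": 0, "2": 1}
_PHENO_MISSING = {"0", "-9"}


class GenotypeParseError(ValueError):
    """Malformed .tped/.tfam/VCF content."""


@dataclass(frozen=True)
class VariantMeta:
    """Per-variant metadata. ``maf`` is recomputed from the dosage data."""

    id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    maf: float

    def __post_init__(self):
        if not (0.0 <= self.maf <= 0.5 + 1e-12):
            raise ValueError(f"maf {self.maf} outside [0, 0.5] for {self.id}")


@dataclass
class GenotypeMatrix:
    """Subjects x variants minor-allele dosage matrix with metadata.

    Every dosage is in {0, 1, 2}; missing genotypes must be rejected or
    imputed at read time, before any modelling stage sees the matrix.
    """

    dosages: np.ndarray
    variants: list[VariantMeta]
    subject_ids: list[str]

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (subjects x variants)")
        n, p = self.dosages.shape
        if p != len(self.variants):
            raise ValueError(
                f"variant metadata length {len(self.variants)} != {p} columns"
            )
        if n != len(self.subject_ids):
            raise ValueError("subject_ids length mismatch")
        if len(set(self.subject_ids)) != n:
            raise ValueError("subject ids are not unique")
        bad = (self.dosages < 0) | (self.dosages > 2)
        if bad.any():
            raise ValueError("dosages outside {0,1,2}; missing data not allowed")

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def compute_mafs(self) -> np.ndarray:
        """Empirical minor-allele frequency per column (always <= 0.5)."""
        f = self.dosages.mean(axis=0) / 2.0
        return np.minimum(f, 1.0 - f)

    def subset_variants(self, mask_or_idx) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            dosages=self.dosages[:, idx],
            variants=[self.variants[i] for i in idx],
            subject_ids=list(self.subject_ids),
        )


@dataclass
class PhenotypeTable:
    """Binary case/control status aligned 1:1 with GenotypeMatrix rows."""

    subject_ids: list[str]
    status: np.ndarray
    sex: np.ndarray | None = None

    def __post_init__(self):
        self.status = np.asarray(self.status, dtype=np.int8)
        if set(np.unique(self.status)) - {0, 1}:
            raise ValueError("status must be binary 0/1")
        if len(np.unique(self.status)) < 2:
            raise ValueError("both classes must be present")
        if len(self.status) != len(self.subject_ids):
            raise ValueError("status length mismatch")
        if self.sex is not None:
            self.sex = np.asarray(self.sex, dtype=np.int8)
            if len(self.sex) != len(self.status):
                raise ValueError("sex length mismatch")

    @property
    def n_cases(self) -> int:
        return int(self.status.sum())

    @property
    def n_controls(self) -> int:
        return int(len(self.status) - self.status.sum())


# ---------------------------------------------------------------------------
# PLINK transposed text
# ---------------------------------------------------------------------------

def _orient_minor(counts_a: np.ndarray, n_subjects: int):
    """Return (dosages_of_minor, flipped) given counts of allele A per subject."""
    freq_a = counts_a.sum() / (2.0 * n_subjects)
    if freq_a > 0.5:
        return (2 - counts_a).astype(np.int8), True
    return counts_a.astype(np.int8), False


def read_tfam(tfam_path) -> PhenotypeTable:
    ids, status, sexes = [], [], []
    with open(tfam_path) as fh:
        for ln, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 6:
                raise GenotypeParseError(f"{tfam_path}:{ln}: expected 6 fields")
            ids.append(fields[1])
            sex_code = fields[4]
            sexes.append(1 if sex_code == "2" else 0)
            ph = fields[5]
            if ph in _PHENO_MAP:
                status.append(_PHENO_MAP[ph])
            elif ph in _PHENO_MISSING:
                raise GenotypeParseError(
                    f"{tfam_path}:{ln}: missing phenotype ({ph}) not supported"
                )
            else:
                raise GenotypeParseError(
                    f"{tfam_path}:{ln}: phenotype {ph!r} not in {{1,2,0,-9}}"
                )
    return PhenotypeTable(subject_ids=ids, status=np.array(status), sex=np.array(sexes))


def read_tped(tped_path, tfam_path, impute_missing: bool = False):
    """Read a .tped/.tfam pair into (GenotypeMatrix, PhenotypeTable).

    Dosages count the minor allele, with minor/major determined per variant
    from the sample allele frequency.  By default a missing genotype ('0')
    is a hard error; with ``impute_missing`` it is filled with the variant's
    modal genotype.
    """
    pheno = read_tfam(tfam_path)
    n = len(pheno.subject_ids)

    rows, metas = [], []
    with open(tped_path) as fh:
        for ln, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 4 + 2 * n:
                raise GenotypeParseError(
                    f"{tped_path}:{ln}: expected {4 + 2 * n} fields for "
                    f"{n} subjects, got {len(fields)}"
                )
            chrom, vid, _cm, pos = fields[:4]
            if chrom not in VALID_CHROMS:
                raise GenotypeParseError(f"{tped_path}:{ln}: bad chromosome {chrom!r}")
            alleles = fields[4:]
            symbols = sorted(set(alleles) - {"0"})
            if any(len(s) != 1 or s not in "ACGT" for s in symbols):
                raise GenotypeParseError(
                    f"{tped_path}:{ln}: unknown allele symbol in {symbols}"
                )
            if len(symbols) > 2:
                raise GenotypeParseError(f"{tped_path}:{ln}: more than 2 alleles")
            a = symbols[0] if symbols else "A"
            arr = np.array(alleles)
            pair = arr.reshape(n, 2)
            missing_mask = (pair == "0").any(axis=1)
            counts_a = (pair == a).sum(axis=1)
            if missing_mask.any():
                if not impute_missing:
                    raise GenotypeParseError(
                        f"{tped_path}:{ln}: missing genotype; "
                        "enable impute_missing or clean the input"
                    )
                vals, cnts = np.unique(counts_a[~missing_mask], return_counts=True)
                counts_a[missing_mask] = vals[np.argmax(cnts)]
            dos, flipped = _orient_minor(counts_a, n)
            b = symbols[1] if len(symbols) == 2 else a
            # dosage counts the minor allele: `a` if not flipped, else `b`
            minor, major = (a, b) if not flipped else (b, a)
            maf = float(dos.mean() / 2.0)
            metas.append(
                VariantMeta(id=vid, chrom=chrom, pos=int(pos),
                            ref_allele=major, alt_allele=minor, maf=maf)
            )
            rows.append(dos)

    dosages = np.stack(rows, axis=1) if rows else np.zeros((n, 0), dtype=np.int8)
    gm = GenotypeMatrix(dosages=dosages, variants=metas,
                        subject_ids=list(pheno.subject_ids))
    return gm, pheno


def write_tped(gm: GenotypeMatrix, pheno: PhenotypeTable, prefix: str) -> None:
    """Write .tped/.tfam; round-trips dosages exactly through read_tped."""
    n = gm.n_subjects
    with open(f"{prefix}.tfam", "w") as fh:
        sex = pheno.sex if pheno.sex is not None else np.zeros(n, dtype=int)
        for sid, s, sx in zip(pheno.subject_ids, pheno.status, sex):
            fh.write(f"FAM {sid} 0 0 {2 if sx else 1} {int(s) + 1}\n")
    with open(f"{prefix}.tped", "w") as fh:
        for j, v in enumerate(gm.variants):
            col = gm.dosages[:, j]
            geno = {
                0: f"{v.ref_allele} {v.ref_allele}",
                1: f"{v.ref_allele} {v.alt_allele}",
                2: f"{v.alt_allele} {v.alt_allele}",
            }
            body = " ".join(geno[int(d)] for d in col)
            fh.write(f"{v.chrom} {v.id} 0 {v.pos} {body}\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(vcf_path, missing: str = "error"):
    """Read a multi-sample VCF into a GenotypeMatrix.

    Biallelic records only; multiallelic records are skipped with a logged
    count.  GT is re-oriented so dosage counts the minor allele.

    Parameters
    ----------
    missing : {'error', 'skip', 'impute'}
        Policy for records with missing GT calls.
    """
    from cyvcf2 import VCF

    if missing not in ("error", "skip", "impute"):
        raise ValueError(f"bad missing policy {missing!r}")

    vcf = VCF(str(vcf_path))
    subject_ids = list(vcf.samples)
    n = len(subject_ids)
    rows, metas = [], []
    n_multi = n_missing_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        gts = np.array(rec.genotypes, dtype=object)
        a1 = np.array([g[0] for g in gts])
        a2 = np.array([g[1] for g in gts])
        miss = (a1 < 0) | (a2 < 0)
        alt_counts = np.where(miss, -1, a1 + a2)
        if miss.any():
            if missing == "error":
                raise GenotypeParseError(
                    f"{vcf_path}: missing GT at {rec.CHROM}:{rec.POS}"
                )
            if missing == "skip":
                n_missing_skipped += 1
                continue
            ok = alt_counts[~miss]
            vals, cnts = np.unique(ok, return_counts=True)
            alt_counts = np.where(miss, vals[np.argmax(cnts)], alt_counts)
        dos, flipped = _orient_minor(alt_counts.astype(np.int64), n)
        chrom = rec.CHROM.removeprefix("chr")
        ref, alt = rec.REF, rec.ALT[0]
        major, minor = (alt, ref) if flipped else (ref, alt)
        # single-character contract for alleles; indels keep first base
        metas.append(
            VariantMeta(id=rec.ID or f"{chrom}:{rec.POS}", chrom=chrom,
                        pos=rec.POS, ref_allele=major[0], alt_allele=minor[0],
                        maf=float(dos.mean() / 2.0))
        )
        rows.append(dos)
    if n_multi:
        logger.info("read_vcf: skipped %d multiallelic records", n_multi)
    if n_missing_skipped:
        logger.info("read_vcf: skipped %d records with missing GT", n_missing_skipped)
    dosages = np.stack(rows, axis=1) if rows else np.zeros((n, 0), dtype=np.int8)
    return GenotypeMatrix(dosages=dosages, variants=metas, subject_ids=subject_ids)


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def filter_variants(gm: GenotypeMatrix, maf_min: float = 0.01,
                    autosomes_only: bool = True) -> GenotypeMatrix:
    """Keep variants with MAF >= maf_min (inclusive) and, optionally,
    autosomal chromosome; column order is preserved."""
    mafs = gm.compute_mafs()
    keep = mafs >= maf_min
    if autosomes_only:
        auto = np.array([v.chrom in AUTOSOMES for v in gm.variants])
        keep &= auto
    if not keep.any():
        raise ValueError("all variants removed by filter")
    out = gm.subset_variants(keep)
    # refresh stored maf so metadata matches the (possibly re-sampled) data
    out.variants = [replace(v, maf=float(m))
                    for v, m in zip(out.variants, out.compute_mafs())]
    return out
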