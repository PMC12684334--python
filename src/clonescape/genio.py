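"""Genotype matrix container, VCF / dosage-TSV I/O and missingness filtering.

The central container is :class:`SNPMatrix`: a diploid individuals x loci
dosage matrix (0/1/2 copies of the ALT allele, ``MISSING`` sentinel for
no-calls) with individual, site (sampling locality) and locus labels.
Filtering follows the reduced-representation SNP workflow for partially
clonal populations: drop loci and individuals with excess missingness,
keep only biallelic polymorphic loci, and diagnose individuals whose
heterozygosity co-varies with their missing-data load.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype call.  Distinct from any valid dosage.
MISSING: int = -9


class EmptyMatrixError(ValueError):
    """Raised when filtering removes every locus or every individual."""


class VCFParseError(ValueError):
    """Raised for a malformed VCF header, naming the offending line."""


@dataclass
class SNPMatrix:
    """Individuals x biallelic loci dosage matrix.

    Parameters
    ----------
    dosages
        Integer array of shape ``(n_individuals, n_loci)`` with values in
        ``{0, 1, 2, MISSING}`` (count of ALT alleles; diploid).
    individual_ids
        One label per row.
    site_of_individual
        Sampling locality per row (sites index all per-locality statistics).
    locus_ids
        One label per column.
    """

    dosages: np.ndarray
    individual_ids: list[str]
    site_of_individual: list[str]
    locus_ids: list[str]
    ploidy: int = 2

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int16)
        n, L = self.dosages.shape
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids length does not match dosage rows")
        if len(self.site_of_individual) != n:
            raise ValueError("site_of_individual length does not match dosage rows")
        if len(self.locus_ids) != L:
            raise ValueError("locus_ids length does not match dosage columns")
        if self.ploidy != 2:
            raise ValueError("only diploid data are supported")
        valid = np.isin(self.dosages, (0, 1, 2, MISSING))
        if not valid.all():
            bad = np.unique(self.dosages[~valid])
            raise ValueError(f"invalid dosage values {bad!r}")

    # -- basic properties -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    @property
    def sites(self) -> list[str]:
        """Unique site labels in order of first appearance."""
        return list(dict.fromkeys(self.site_of_individual))

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def locus_missingness(self) -> np.ndarray:
        return self.missing_mask().mean(axis=0)

    def individual_missingness(self) -> np.ndarray:
        return self.missing_mask().mean(axis=1)

    def is_polymorphic(self) -> np.ndarray:
        """Per-locus flag: more than one allele among non-missing calls."""
        d = np.ma.masked_equal(self.dosages, MISSING)
        if self.n_individuals == 0:
            return np.zeros(self.n_loci, dtype=bool)
        mn = d.min(axis=0)
        mx = d.max(axis=0)
        poly = np.asarray((mx - mn) > 0)
        # also count Aa-only columns (all dosage 1) as polymorphic
        allhet = np.asarray((mn == 1) & (mx == 1))
        out = poly | allhet
        out[np.asarray(d.count(axis=0) == 0)] = False
        return out

    # -- subsetting -------------------------------------------------------
    def take_individuals(self, idx) -> "SNPMatrix":
        idx = np.asarray(idx)
        return SNPMatrix(
            self.dosages[idx],
            [self.individual_ids[i] for i in idx],
            [self.site_of_individual[i] for i in idx],
            list(self.locus_ids),
        )

    def take_loci(self, idx) -> "SNPMatrix":
        idx = np.asarray(idx)
        return SNPMatrix(
            self.dosages[:, idx],
            list(self.individual_ids),
            list(self.site_of_individual),
            [self.locus_ids[i] for i in idx],
        )

    def restrict_to_site(self, site: str) -> "SNPMatrix":
        idx = [i for i, s in enumerate(self.site_of_individual) if s == site]
        if not idx:
            raise KeyError(f"no individuals from site {site!r}")
        return self.take_individuals(idx)

    # -- dosage TSV -------------------------------------------------------
    def to_dosage_tsv(self, path) -> None:
        df = pd.DataFrame(
            np.where(self.dosages == MISSING, np.nan, self.dosages),
            columns=self.locus_ids,
        )
        df.insert(0, "site", self.site_of_individual)
        df.insert(0, "individual_id", self.individual_ids)
        df.to_csv(path, sep="\t", index=False, na_rep="NA")

    @classmethod
    def from_dosage_tsv(cls, path) -> "SNPMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"individual_id": str, "site": str})
        loci = [c for c in df.columns if c not in ("individual_id", "site")]
        dos = df[loci].to_numpy(dtype=float)
        dos = np.where(np.isnan(dos), MISSING, dos).astype(np.int16)
        return cls(dos, df["individual_id"].tolist(), df["site"].tolist(), loci)


# -- VCF ------------------------------------------------------------------

def write_vcf(m: SNPMatrix, path) -> None:
    """Write a minimal VCF v4.2 (GT only, unphased) for ``m``.

    Locus ids of the form ``chrom:pos`` are split back into CHROM/POS;
    anything else goes on a synthetic contig with consecutive positions.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(m.individual_ids)
            + "\n"
        )
        gt_of = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for j, locus in enumerate(m.locus_ids):
            if ":" in locus:
                chrom, pos = locus.split(":", 1)
            else:
                chrom, pos = "1", str(j + 1)
            gts = "\t".join(gt_of[int(d)] for d in m.dosages[:, j])
            fh.write(f"{chrom}\t{pos}\t{locus}\tA\tT\t.\t.\t.\tGT\t{gts}\n")


def _check_vcf_header(path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno == 1 and not line.startswith("##fileformat"):
                raise VCFParseError(
                    f"{path}: line 1: expected '##fileformat', got {line[:40]!r}"
                )
            if line.startswith("#CHROM"):
                cols = line.rstrip("\n").split("\t")
                if cols[:9] != [
                    "#CHROM", "POS", "ID", "REF", "ALT",
                    "QUAL", "FILTER", "INFO", "FORMAT",
                ]:
                    raise VCFParseError(
                        f"{path}: line {lineno}: malformed #CHROM header line"
                    )
                return
            if not line.startswith("#"):
                raise VCFParseError(
                    f"{path}: line {lineno}: data before #CHROM header line"
                )
    raise VCFParseError(f"{path}: no #CHROM header line found")


def read_vcf(path, sites: dict[str, str] | None = None) -> SNPMatrix:
    """Read genotypes (GT) from a VCF into an :class:`SNPMatrix`.

    Multi-allelic and non-SNP records are skipped (count logged).
    ``./.`` becomes :data:`MISSING`; the dosage is the ALT-allele count.

    Parameters
    ----------
    sites
        Optional mapping individual id -> site label.  Individuals absent
        from the mapping (or all of them if ``sites is None``) are labelled
        ``"unknown"``.
    """
    from cyvcf2 import VCF  # deferred: import cost and optional at runtime

    _check_vcf_header(path)
    v = VCF(str(path), gts012=True)
    samples = list(v.samples)
    cols: list[np.ndarray] = []
    loci: list[str] = []
    skipped = 0
    for var in v:
        if len(var.ALT) != 1 or not var.is_snp:
            skipped += 1
            continue
        gt = np.asarray(var.gt_types, dtype=np.int16)  # 0,1,2; 3=unknown
        gt[gt == 3] = MISSING
        cols.append(gt)
        loci.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
    if skipped:
        logger.info("read_vcf: skipped %d multi-allelic/non-SNP records", skipped)
    if not cols:
        raise EmptyMatrixError(f"{path}: no biallelic SNP records")
    dos = np.stack(cols, axis=1)
    sites = sites or {}
    site_labels = [sites.get(s, "unknown") for s in samples]
    return SNPMatrix(dos, samples, site_labels, loci)


# -- filtering ------------------------------------------------------------

@dataclass
class FilterReport:
    """Record of what :func:`filter_matrix` removed and why."""

    loci_removed: list[tuple[str, str]] = field(default_factory=list)
    individuals_removed: list[tuple[str, str]] = field(default_factory=list)
    max_locus_missing: float = 0.05
    max_ind_missing: float = 0.05

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "max_locus_missing": self.max_locus_missing,
                    "max_ind_missing": self.max_ind_missing,
                    "loci_removed": self.loci_removed,
                    "individuals_removed": self.individuals_removed,
                },
                fh,
                indent=1,
            )


def filter_matrix(
    m: SNPMatrix,
    max_locus_missing: float = 0.05,
    max_ind_missing: float = 0.05,
) -> tuple[SNPMatrix, FilterReport]:
    """Missingness / polymorphism filter, iterated to a fixed point.

    Each pass removes, in order: loci with missingness strictly above
    ``max_locus_missing``; individuals strictly above ``max_ind_missing``;
    monomorphic loci.  Passes repeat until nothing changes, which makes
    the operation idempotent.
    """
    report = FilterReport(
        max_locus_missing=max_locus_missing, max_ind_missing=max_ind_missing
    )
    cur = m
    while True:
        changed = False
        lm = cur.locus_missingness()
        drop = lm > max_locus_missing
        if drop.any():
            for i in np.flatnonzero(drop):
                report.loci_removed.append(
                    (cur.locus_ids[i], f"missingness {lm[i]:.4f} > {max_locus_missing}")
                )
            cur = cur.take_loci(np.flatnonzero(~drop))
            changed = True
        if cur.n_loci == 0:
            raise EmptyMatrixError("all loci removed by missingness filter")
        im = cur.individual_missingness()
        drop = im > max_ind_missing
        if drop.any():
            for i in np.flatnonzero(drop):
                report.individuals_removed.append(
                    (
                        cur.individual_ids[i],
                        f"missingness {im[i]:.4f} > {max_ind_missing}",
                    )
                )
            cur = cur.take_individuals(np.flatnonzero(~drop))
            changed = True
        if cur.n_individuals == 0:
            raise EmptyMatrixError("all individuals removed by missingness filter")
        poly = cur.is_polymorphic()
        if (~poly).any():
            for i in np.flatnonzero(~poly):
                report.loci_removed.append((cur.locus_ids[i], "monomorphic"))
            cur = cur.take_loci(np.flatnonzero(poly))
            changed = True
        if cur.n_loci == 0:
            raise EmptyMatrixError("all loci removed (monomorphic)")
        if not changed:
            return cur, report


def het_missing_diag(m: SNPMatrix, k: float = 3.0) -> pd.DataFrame:
    """Per-individual missingness vs heterozygosity diagnostic.

    Heterozygosity is the fraction of non-missing genotypes equal to 1.
    Individuals whose heterozygosity lies beyond ``k`` median absolute
    deviations of the cohort distribution are flagged as outliers —
    candidates for missingness-driven genotyping artefacts.  Individuals
    with no called genotypes get heterozygosity NaN and are not flagged.
    """
    miss = m.individual_missingness()
    called = (~m.missing_mask()).sum(axis=1)
    het_n = (m.dosages == 1).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        het = np.where(called > 0, het_n / np.maximum(called, 1), np.nan)
    finite = het[np.isfinite(het)]
    if finite.size:
        med = float(np.median(finite))
        mad = float(np.median(np.abs(finite - med)))
    else:
        med, mad = np.nan, np.nan
    if mad and np.isfinite(mad) and mad > 0:
        flag = np.abs(het - med) > k * mad
    else:
        flag = np.zeros(m.n_individuals, dtype=bool)
    flag = np.where(np.isfinite(het), flag, False)
    return pd.DataFrame(
        {
            "individual_id": m.individual_ids,
            "site": m.site_of_individual,
            "missingness": miss,
            "heterozygosity": het,
            "outlier": flag.astype(bool),
        }
    )
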