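"""Genotype, phenotype and gene-map input/output.

Internal conventions:

* dosages are counts of the coded allele in {0, 1, 2}; ``numpy.nan`` marks a
  missing genotype until :func:`fold_and_qc` mean-imputes it;
* positions are 1-based (as in VCF); BED intervals are converted at the
  boundary;
* after :func:`fold_and_qc` the coded allele is the minor allele, so every
  per-variant MAF lies in (0, 0.5].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("rplskit")

__all__ = [
    "GenotypeMatrix",
    "PhenotypeTable",
    "GeneMap",
    "VcfParseError",
    "read_vcf",
    "write_vcf",
    "fold_and_qc",
    "read_phenotypes",
    "read_gene_intervals",
    "build_gene_map",
    "align_samples",
]


class VcfParseError(ValueError):
    """Raised when a VCF record cannot be parsed."""


@dataclass
class GenotypeMatrix:
    """n x p matrix of coded-allele dosages with variant metadata.

    ``maf`` is populated by :func:`fold_and_qc` from observed (non-missing)
    entries only and is ``None`` before QC.
    """

    dosages: np.ndarray  # (n, p) float, nan = missing
    sample_ids: list[str]
    variant_ids: list[str]
    chrom: np.ndarray  # (p,) str
    positions: np.ndarray  # (p,) int, 1-based
    ref: np.ndarray | None = None
    alt: np.ndarray | None = None
    maf: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def take_variants(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return replace(
            self,
            dosages=self.dosages[:, idx],
            variant_ids=[self.variant_ids[i] for i in idx],
            chrom=self.chrom[idx],
            positions=self.positions[idx],
            ref=None if self.ref is None else self.ref[idx],
            alt=None if self.alt is None else self.alt[idx],
            maf=None if self.maf is None else self.maf[idx],
        )


@dataclass
class PhenotypeTable:
    """Per-sample trait and covariates, aligned by ``sample_ids``."""

    sample_ids: list[str]
    y: np.ndarray  # (n,)
    covariates: np.ndarray  # (n, q)
    covariate_names: list[str]
    trait_name: str = "y"

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass
class GeneMap:
    """gene name -> ordered (by position) variant indices into a GenotypeMatrix."""

    genes: dict[str, np.ndarray] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.genes.items())

    def __len__(self):
        return len(self.genes)

    def __getitem__(self, gene: str) -> np.ndarray:
        return self.genes[gene]


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read biallelic SNV genotypes from a VCF into ALT-allele dosages.

    Multiallelic records are skipped with a logged warning; missing genotypes
    (``./.``) become ``nan``.  Dosages count the ALT allele; run
    :func:`fold_and_qc` to obtain minor-allele coding.
    """
    from cyvcf2 import VCF

    path = str(path)
    try:
        vcf = VCF(path, gts012=True)
    except Exception as exc:  # cyvcf2 raises bare OSError on bad input
        raise VcfParseError(f"cannot open VCF {path!r}: {exc}") from exc

    samples = list(vcf.samples)
    cols: list[np.ndarray] = []
    vids: list[str] = []
    chroms: list[str] = []
    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    n_skipped = 0
    for rec_no, v in enumerate(vcf, start=1):
        try:
            if len(v.ALT) != 1:
                n_skipped += 1
                logger.warning(
                    "skipping multiallelic record %s:%d (%d ALT alleles)",
                    v.CHROM, v.POS, len(v.ALT),
                )
                continue
            gt = np.asarray(v.gt_types, dtype=float)  # 0/1/2, 3 = unknown
            gt[gt == 3] = np.nan
            cols.append(gt)
            vids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}_{v.POS}")
            chroms.append(str(v.CHROM))
            positions.append(int(v.POS))
            refs.append(v.REF)
            alts.append(v.ALT[0])
        except Exception as exc:
            raise VcfParseError(
                f"malformed VCF record #{rec_no} near {path!r}: {exc}"
            ) from exc
    if n_skipped:
        logger.warning("skipped %d multiallelic records in %s", n_skipped, path)
    if not cols:
        raise VcfParseError(f"no biallelic records found in {path!r}")
    return GenotypeMatrix(
        dosages=np.column_stack(cols),
        sample_ids=samples,
        variant_ids=vids,
        chrom=np.asarray(chroms, dtype=object),
        positions=np.asarray(positions, dtype=int),
        ref=np.asarray(refs, dtype=object),
        alt=np.asarray(alts, dtype=object),
    )


def write_vcf(G: GenotypeMatrix, path: str | Path) -> None:
    """Write integer/missing dosages as a minimal VCF 4.2 file.

    Only exact {0,1,2,nan} dosages are representable; imputed fractional
    values would be silently wrong, so they raise.
    """
    d = G.dosages
    finite = d[np.isfinite(d)]
    if finite.size and not np.allclose(finite, np.round(finite)):
        raise ValueError("cannot write imputed (fractional) dosages to VCF")
    ref = G.ref if G.ref is not None else np.full(G.n_variants, "A", dtype=object)
    alt = G.alt if G.alt is not None else np.full(G.n_variants, "C", dtype=object)
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in pd.unique(G.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.sample_ids)
            + "\n"
        )
        order = np.lexsort((G.positions, G.chrom.astype(str)))
        for j in order:
            gts = [
                "./." if not np.isfinite(d[i, j]) else gt_map[int(round(d[i, j]))]
                for i in range(G.n_samples)
            ]
            fh.write(
                f"{G.chrom[j]}\t{G.positions[j]}\t{G.variant_ids[j]}\t"
                f"{ref[j]}\t{alt[j]}\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def fold_and_qc(G: GenotypeMatrix) -> GenotypeMatrix:
    """Fold to minor-allele coding, drop monomorphic variants, mean-impute.

    Folding recodes ``x -> 2 - x`` wherever the coded-allele frequency among
    observed entries exceeds 0.5; it is idempotent.  MAF is computed from
    observed entries only, before imputation.
    """
    d = G.dosages.astype(float).copy()
    with np.errstate(invalid="ignore"):
        n_obs = np.sum(np.isfinite(d), axis=0)
    keep_obs = n_obs > 0
    freq = np.full(G.n_variants, np.nan)
    freq[keep_obs] = np.nanmean(d[:, keep_obs], axis=0) / 2.0

    flip = freq > 0.5
    d[:, flip] = 2.0 - d[:, flip]
    maf = np.where(flip, 1.0 - freq, freq)

    keep = keep_obs & (maf > 0)
    if not np.any(keep):
        raise ValueError("all variants monomorphic (or fully missing) after folding")
    n_dropped = int(np.sum(~keep))
    if n_dropped:
        logger.info("dropping %d monomorphic/unobserved variants", n_dropped)

    out = G.take_variants(np.flatnonzero(keep))
    d = d[:, keep]
    maf = maf[keep]
    # mean imputation of missing entries, per variant, from observed dosages
    col_mean = np.nanmean(d, axis=0)
    nan_r, nan_c = np.where(~np.isfinite(d))
    d[nan_r, nan_c] = col_mean[nan_c]
    out.dosages = d
    out.maf = maf
    return out


def read_phenotypes(
    path: str | Path,
    trait_name: str,
    covariate_names: list[str] | None = None,
    id_column: str | None = None,
    sep: str | None = None,
) -> PhenotypeTable:
    """Read a delimited phenotype/covariate table (header required).

    The sample-id column is ``id_column`` or, by default, the first column.
    Rows missing the trait or any covariate are dropped with a logged count.
    """
    covariate_names = list(covariate_names or [])
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    if df.empty:
        raise ValueError(f"phenotype file {path!r} has no data rows")
    if id_column is None:
        id_column = df.columns[0]
    for col in [id_column, trait_name, *covariate_names]:
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in {path!r}")
    needed = df[[trait_name, *covariate_names]]
    ok = needed.notna().all(axis=1)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("dropping %d samples with missing trait/covariates", n_dropped)
    df = df.loc[ok]
    if df.empty:
        raise ValueError("no samples left after dropping missing values")
    return PhenotypeTable(
        sample_ids=[str(s) for s in df[id_column]],
        y=df[trait_name].to_numpy(dtype=float),
        covariates=df[covariate_names].to_numpy(dtype=float).reshape(len(df), -1),
        covariate_names=covariate_names,
        trait_name=trait_name,
    )


def read_gene_intervals(path: str | Path, convention: str = "bed"):
    """Read gene intervals from a BED file or a 4-column gene table.

    BED columns: chrom, start, end, name (0-based half-open).  Gene-table
    columns: gene, chrom, start, end (convention per the ``convention`` flag).
    Returns a list of (gene, chrom, start, end) tuples in file order.
    """
    df = pd.read_csv(path, sep=None, engine="python", header=None, comment="#")
    if df.shape[1] < 4:
        raise ValueError(f"gene interval file {path!r} needs at least 4 columns")
    if convention == "bed":
        rows = [(str(r[3]), str(r[0]), int(r[1]), int(r[2])) for r in df.itertuples(index=False)]
    else:
        rows = [(str(r[0]), str(r[1]), int(r[2]), int(r[3])) for r in df.itertuples(index=False)]
    return rows


def build_gene_map(
    intervals,
    G: GenotypeMatrix,
    convention: str = "bed",
) -> GeneMap:
    """Assign variants to genes by interval overlap.

    ``intervals`` is an iterable of ``(gene, chrom, start, end)``.  With
    ``convention="bed"`` intervals are 0-based half-open; with
    ``convention="one_based_closed"`` they are 1-based inclusive.  A variant
    may fall in several (overlapping) genes.  Within each gene, indices are
    ordered by position.
    """
    if convention not in ("bed", "one_based_closed"):
        raise ValueError(f"unknown interval convention {convention!r}")
    genes: dict[str, np.ndarray] = {}
    pos = G.positions
    chrom = G.chrom.astype(str)
    for gene, c, start, end in intervals:
        if convention == "bed":
            lo, hi = start + 1, end  # 1-based closed equivalent
        else:
            lo, hi = start, end
        mask = (chrom == str(c)) & (pos >= lo) & (pos <= hi)
        idx = np.flatnonzero(mask)
        idx = idx[np.argsort(pos[idx], kind="stable")]
        if gene in genes:
            merged = np.union1d(genes[gene], idx)
            idx = merged[np.argsort(pos[merged], kind="stable")]
        genes[gene] = idx
    return GeneMap(genes=genes)


def align_samples(G: GenotypeMatrix, pheno: PhenotypeTable):
    """Join genotypes and phenotypes on sample id.

    The aligned order is the genotype sample order restricted to the common
    ids, so the join is order-independent of the inputs' row orders.
    """
    pheno_index = {s: i for i, s in enumerate(pheno.sample_ids)}
    keep_g = [i for i, s in enumerate(G.sample_ids) if s in pheno_index]
    if not keep_g:
        raise ValueError("no overlapping sample ids between genotypes and phenotypes")
    order_p = [pheno_index[G.sample_ids[i]] for i in keep_g]
    G2 = replace(
        G,
        dosages=G.dosages[keep_g, :],
        sample_ids=[G.sample_ids[i] for i in keep_g],
    )
    P2 = PhenotypeTable(
        sample_ids=[G.sample_ids[i] for i in keep_g],
        y=pheno.y[order_p],
        covariates=pheno.covariates[order_p, :],
        covariate_names=pheno.covariate_names,
        trait_name=pheno.trait_name,
    )
    return G2, P2
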