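"""Reading and writing the pipeline's on-disk formats.

Expression travels as MatrixMarket (cells x genes) plus cell/gene TSVs,
genotypes as VCF (read through cyvcf2; written as plain VCF 4.2 text),
GWAS summary statistics and all result tables as TSV, and fitted models as
a NumPy archive with a JSON header.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix

from .gplvm import CellStateContext

__all__ = [
    "write_expression",
    "read_expression",
    "write_vcf",
    "read_vcf_dosages",
    "save_context",
    "load_context",
]


def write_expression(outdir, Y, cell_meta: pd.DataFrame,
                     gene_meta: pd.DataFrame) -> None:
    """MTX (cells x genes) + cells.tsv + genes.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mmwrite(str(outdir / "matrix.mtx"), csr_matrix(np.asarray(Y)))
    cell_meta.to_csv(outdir / "cells.tsv", sep="\t", index=False)
    gene_meta.to_csv(outdir / "genes.tsv", sep="\t", index=False)


def read_expression(indir):
    indir = Path(indir)
    y = np.asarray(mmread(str(indir / "matrix.mtx")).todense())
    cells = pd.read_csv(indir / "cells.tsv", sep="\t")
    genes = pd.read_csv(indir / "genes.tsv", sep="\t")
    if y.shape != (len(cells), len(genes)):
        raise ValueError(f"matrix shape {y.shape} does not match metadata "
                         f"({len(cells)} cells, {len(genes)} genes)")
    return y, cells, genes


def write_vcf(path, variants: pd.DataFrame,
              genotypes: pd.DataFrame) -> None:
    """Minimal diploid VCF 4.2 with GT fields.

    variants: DataFrame with columns variant, chrom, pos (1-based), and
    optionally ref/alt.  genotypes: DataFrame donors x variants with
    dosages in {0, 1, 2}.
    """
    donors = list(genotypes.index)
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for ch in pd.unique(variants["chrom"]):
            fh.write(f"##contig=<ID={ch}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                 'Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(d) for d in donors) + "\n")
        for row in variants.sort_values(["chrom", "pos"]).itertuples():
            ref = getattr(row, "ref", "A")
            alt = getattr(row, "alt", "G")
            gts = "\t".join(gt_map[int(genotypes.loc[d, row.variant])]
                            for d in donors)
            fh.write(f"{row.chrom}\t{int(row.pos)}\t{row.variant}\t{ref}"
                     f"\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf_dosages(path, region: str | None = None):
    """Donor x variant dosage table with MAFs and positions.

    Dosage comes from the DS format field when present, otherwise from the
    genotype allele sum.  Multi-allelic records are skipped with a warning.

    Returns (dosages DataFrame, variants DataFrame with chrom/pos/maf).
    """
    from cyvcf2 import VCF
    vcf = VCF(str(path))
    donors = list(vcf.samples)
    cols, meta = {}, []
    it = vcf(region) if region else vcf
    for rec in it:
        if len(rec.ALT) != 1:
            warnings.warn(f"skipping multi-allelic record at "
                          f"{rec.CHROM}:{rec.POS}", RuntimeWarning)
            continue
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        try:
            ds = rec.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            dose = np.asarray(ds, dtype=float).ravel()
        else:
            gts = np.asarray(rec.genotype.array())[:, :2]
            dose = np.where((gts < 0).any(axis=1), np.nan,
                            gts.clip(min=0).sum(axis=1)).astype(float)
        if np.any(np.isnan(dose)):
            # mean-impute missing genotypes per variant
            dose = np.where(np.isnan(dose), np.nanmean(dose), dose)
        af = float(np.mean(dose) / 2.0)
        cols[vid] = dose
        meta.append((vid, rec.CHROM, rec.POS, min(af, 1.0 - af)))
    dosages = pd.DataFrame(cols, index=donors)
    variants = pd.DataFrame(meta, columns=["variant", "chrom", "pos",
                                           "maf"])
    return dosages, variants


def save_context(path, context: CellStateContext,
                 extra: dict | None = None) -> None:
    """Persist a fitted cell-state context as an .npz archive."""
    arrays = {k: getattr(context, k) for k in
              ("Z", "zeta", "delta", "omega", "theta", "B", "X")}
    for k in ("theta_u", "B_u", "X_u", "sigma2"):
        v = getattr(context, k)
        if v is not None:
            arrays[k] = v
    header = {"ell_theta": context.ell_theta, "ell_B": context.ell_B,
              "ell_X": context.ell_X, "v_gp": context.v_gp,
              "kernel_mode": context.kernel_mode}
    if extra:
        header.update(extra)
    arrays["_header"] = np.frombuffer(
        json.dumps(header).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_context(path) -> CellStateContext:
    with np.load(path) as data:
        header = json.loads(bytes(data["_header"]).decode())
        kw = {k: data[k] for k in data.files if k != "_header"}
    return CellStateContext(
        Z=kw["Z"], zeta=kw["zeta"], delta=kw["delta"], omega=kw["omega"],
        theta=kw["theta"], B=kw["B"], X=kw["X"],
        theta_u=kw.get("theta_u"), B_u=kw.get("B_u"), X_u=kw.get("X_u"),
        sigma2=kw.get("sigma2"),
        ell_theta=header["ell_theta"], ell_B=header["ell_B"],
        ell_X=header["ell_X"], v_gp=header["v_gp"],
        kernel_mode=header["kernel_mode"])
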