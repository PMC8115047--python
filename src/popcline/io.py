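"""Reading and writing the standard formats the pipeline touches.

VCF input goes through cyvcf2; only biallelic SNP records are converted
(multiallelic or indel records are skipped and counted).  VCF output writes a
minimal v4.2 file with GT-only genotypes, which round-trips losslessly through
:func:`read_vcf`.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import MISSING, GenotypeMatrix, PopulationMap

logger = logging.getLogger(__name__)

_GT_CODE = {(0, 0): 0, (0, 1): 1, (1, 0): 1, (1, 1): 2}


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a diploid VCF into a :class:`GenotypeMatrix`.

    Biallelic SNP records become 0/1/2 alternate-allele dosages; phasing
    ("/" vs "|") is ignored.  Multiallelic records, indels and records with
    symbolic alleles are skipped with a logged count.

    Raises
    ------
    ValueError
        If the file contains no usable biallelic SNP record.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows, ids, chroms, poss, refs, alts = [], [], [], [], [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_skipped += 1
            continue
        # gts012=True: 0/1/2 dosage, 3 = missing
        g = np.asarray(var.gt_types, dtype=np.int8)
        g[g == 3] = MISSING
        rows.append(g)
        ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
    vcf.close()
    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic/non-SNP records", n_skipped)
    if not rows:
        raise ValueError(f"{path}: no usable biallelic SNP records")
    loci = pd.DataFrame(
        {"id": ids, "chrom": chroms, "pos": poss, "ref": refs, "alt": alts}
    )
    return GenotypeMatrix(samples=samples, loci=loci, calls=np.array(rows, dtype=np.int8).T)


def write_vcf(geno: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF v4.2 with GT-only diploid genotypes."""
    loci = geno.loci
    chrom = loci["chrom"] if "chrom" in loci else pd.Series(["1"] * geno.n_loci)
    pos = loci["pos"] if "pos" in loci else pd.Series(np.arange(1, geno.n_loci + 1))
    ref = loci["ref"] if "ref" in loci else pd.Series(["A"] * geno.n_loci)
    alt = loci["alt"] if "alt" in loci else pd.Series(["T"] * geno.n_loci)
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        contigs = pd.unique(np.asarray(chrom, dtype=object))
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(geno.samples) + "\n")
        for j in range(geno.n_loci):
            gts = "\t".join(gt_str[int(g)] for g in geno.calls[:, j])
            fh.write(
                f"{chrom.iloc[j]}\t{pos.iloc[j]}\t{loci['id'].iloc[j]}\t"
                f"{ref.iloc[j]}\t{alt.iloc[j]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_popmap(path: str | Path) -> PopulationMap:
    """Read a tab-separated population map.

    Expected columns: ``sample  population  region  latitude  longitude
    environment`` (header required).
    """
    table = pd.read_csv(path, sep="\t", dtype={"sample": str, "population": str, "region": str})
    for col in ("latitude", "longitude", "environment"):
        if col in table.columns and not pd.api.types.is_numeric_dtype(table[col]):
            raise ValueError(f"{path}: non-numeric values in column {col!r}")
    return PopulationMap(table=table)


def write_popmap(popmap: PopulationMap, path: str | Path) -> None:
    popmap.table.to_csv(path, sep="\t", index=False)


def write_table(result: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    """Write a tabular result as TSV with deterministic column order and
    missing values encoded as ``NA``."""
    result.to_csv(path, sep="\t", index=index, na_rep="NA", float_format="%.10g")


def read_table(path: str | Path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col, na_values=["NA"])
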