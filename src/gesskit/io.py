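"""Genotype format readers/writers (PLINK ped/map text and VCF).

Biallelic, diploid markers only.  Additive codes count the ``a1`` (minor)
allele; missing genotypes are ``-1`` internally, ``0 0`` in PLINK and
``./.`` in VCF.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from gesskit.gwas import GenotypeMatrix, MISSING

__all__ = [
    "write_plink",
    "read_plink",
    "write_vcf",
    "read_vcf",
]


def write_plink(genotypes: GenotypeMatrix, prefix: str) -> None:
    """Write ``prefix + ".ped"`` and ``prefix + ".map"`` text files."""
    snps = genotypes.snps
    with open(f"{prefix}.map", "w") as fh:
        for _, s in snps.iterrows():
            pos = int(s["pos"]) if pd.notna(s["pos"]) else 0
            chrom = s["chrom"] if pd.notna(s["chrom"]) else "0"
            fh.write(f"{chrom}\t{s['snp']}\t0\t{pos}\n")
    a1 = snps["a1"].astype(str).to_numpy()
    a2 = snps["a2"].astype(str).to_numpy()
    with open(f"{prefix}.ped", "w") as fh:
        for i, sample in enumerate(genotypes.samples):
            fields = [str(sample), str(sample), "0", "0", "0", "-9"]
            row = genotypes.codes[i]
            for j, g in enumerate(row):
                if g == MISSING:
                    fields += ["0", "0"]
                elif g == 0:
                    fields += [a2[j], a2[j]]
                elif g == 1:
                    fields += [a1[j], a2[j]]
                else:
                    fields += [a1[j], a1[j]]
            fh.write(" ".join(fields) + "\n")


def read_plink(prefix: str) -> GenotypeMatrix:
    """Read PLINK text files written by :func:`write_plink` (or compatible).

    The minor allele per SNP is taken as ``a1`` = the less frequent allele
    in the file (ties broken alphabetically), so round-trips through
    :func:`write_plink` preserve the codes.
    """
    mp = pd.read_csv(
        f"{prefix}.map",
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "pos"],
        dtype={"chrom": str},
    )
    m = len(mp)
    samples = []
    allele_rows = []
    with open(f"{prefix}.ped") as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            samples.append(parts[1])
            alleles = parts[6:]
            if len(alleles) != 2 * m:
                raise ValueError(
                    f"sample {parts[1]}: expected {2 * m} alleles, got {len(alleles)}"
                )
            allele_rows.append(alleles)
    arr = np.array(allele_rows, dtype=object).reshape(len(samples), m, 2)
    codes = np.zeros((len(samples), m), dtype=np.int8)
    a1_out, a2_out = [], []
    for j in range(m):
        col = arr[:, j, :]
        obs = col[col != "0"]
        uniq, counts = np.unique(obs, return_counts=True)
        if uniq.size == 0:
            a1, a2 = "A", "B"
        elif uniq.size == 1:
            a1, a2 = uniq[0], uniq[0]
        else:
            if uniq.size > 2:
                raise ValueError(f"SNP {mp['snp'][j]}: more than 2 alleles")
            order = np.lexsort((uniq, counts))  # least frequent first
            a1, a2 = uniq[order[0]], uniq[order[1]]
        a1_out.append(a1)
        a2_out.append(a2)
        miss = (col == "0").any(axis=1)
        codes[:, j] = (col == a1).sum(axis=1).astype(np.int8)
        codes[miss, j] = MISSING
    snps = mp[["snp", "chrom", "pos"]].copy()
    snps["a1"] = a1_out
    snps["a2"] = a2_out
    return GenotypeMatrix(codes=codes, snps=snps, samples=samples)


def write_vcf(genotypes: GenotypeMatrix, path: str) -> None:
    """Write a minimal uncompressed VCF (GT only; a1 as ALT allele)."""
    snps = genotypes.snps
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in genotypes.samples)
            + "\n"
        )
        for j, (_, s) in enumerate(snps.iterrows()):
            pos = int(s["pos"]) if pd.notna(s["pos"]) else 0
            chrom = s["chrom"] if pd.notna(s["chrom"]) else "0"
            gts = "\t".join(gt_map[int(g)] for g in genotypes.codes[:, j])
            fh.write(
                f"{chrom}\t{pos}\t{s['snp']}\t{s['a2']}\t{s['a1']}\t.\t.\t.\tGT\t{gts}\n"
            )


def read_vcf(path: str) -> GenotypeMatrix:
    """Read a biallelic diploid VCF; ALT-allele dosage becomes the code."""
    try:
        from cyvcf2 import VCF  # htslib-backed reader

        samples = None
        rows = []
        meta = []
        vcf = VCF(str(path))
        samples = list(vcf.samples)
        for var in vcf:
            gt = np.asarray(var.gt_types)  # 0 hom-ref, 1 het, 3 hom-alt, 2 unknown
            codes = np.select(
                [gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING
            ).astype(np.int8)
            rows.append(codes)
            meta.append(
                (var.ID, str(var.CHROM), int(var.POS), var.ALT[0] if var.ALT else "B", var.REF)
            )
        vcf.close()
    except ImportError:  # plain-text fallback
        samples, rows, meta = _read_vcf_text(path)
    snps = pd.DataFrame(meta, columns=["snp", "chrom", "pos", "a1", "a2"])
    codes = np.vstack(rows).T if rows else np.zeros((len(samples), 0), dtype=np.int8)
    return GenotypeMatrix(codes=codes, snps=snps, samples=samples)


def _read_vcf_text(path):
    samples = []
    rows = []
    meta = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            parts = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                samples = parts[9:]
                continue
            chrom, pos, vid, ref, alt = parts[0], parts[1], parts[2], parts[3], parts[4]
            codes = []
            for g in parts[9:]:
                gt = g.split(":")[0].replace("|", "/")
                if "." in gt:
                    codes.append(MISSING)
                else:
                    codes.append(sum(int(a) for a in gt.split("/")))
            rows.append(np.array(codes, dtype=np.int8))
            meta.append((vid, str(chrom), int(pos), alt, ref))
    return samples, rows, meta
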