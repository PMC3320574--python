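"""Text interchange for genotype panels: PLINK ped/map, VCF, frequency table.

Alleles are written as 'A' (raw allele 0) and 'C' (raw allele 1).  The
{-1, 0, +1} codes are relative to the most frequent allele, so exports
reconstruct raw allele pairs from the code and the stored major-allele
indicator.  Heterozygote phase is not represented (unphased formats).
"""

from __future__ import annotations

import os

import numpy as np

from .popgen import GenomeLayout, GenotypeMatrix

__all__ = [
    "write_ped_map",
    "read_ped_map",
    "write_vcf",
    "read_vcf",
    "write_freq_report",
    "write_phenotypes",
]

_ALLELES = ("A", "C")


def _allele_pairs(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Raw allele indicator pair per genotype (het order arbitrary)."""
    major = gm.major_is_allele1.astype(np.uint8)  # raw index of major allele
    minor = 1 - major
    codes = gm.codes
    a0 = np.where(codes >= 0, major, minor)       # +1/0 -> first allele major
    a1 = np.where(codes == 1, major, minor)       # het -> second allele minor
    return a0.astype(np.uint8), a1.astype(np.uint8)


def locus_names(layout: GenomeLayout) -> list[str]:
    return [
        f"snp{c + 1}_{p}"
        for c, p in zip(layout.chrom, layout.positions_bp)
    ]


def write_ped_map(prefix: str, gm: GenotypeMatrix, layout: GenomeLayout) -> None:
    """Write PLINK text pedigree files ``prefix.ped`` and ``prefix.map``."""
    names = locus_names(layout)
    with open(prefix + ".map", "w") as fh:
        for c, name, cm, bp in zip(
            layout.chrom, names, layout.genetic_map_cm, layout.positions_bp
        ):
            fh.write(f"{c + 1}\t{name}\t{cm:.6f}\t{bp}\n")
    a0, a1 = _allele_pairs(gm)
    with open(prefix + ".ped", "w") as fh:
        for i in range(gm.n_individuals):
            fam = f"pop{gm.subpop_labels[i]}"
            lead = f"{fam}\tind{i}\t0\t0\t0\t-9"
            geno = "\t".join(
                f"{_ALLELES[x]}\t{_ALLELES[y]}" for x, y in zip(a0[i], a1[i])
            )
            fh.write(lead + "\t" + geno + "\n")


def read_ped_map(prefix: str) -> tuple[GenotypeMatrix, GenomeLayout]:
    """Read PLINK text files written by :func:`write_ped_map` (or equivalent)."""
    chroms, cms, bps = [], [], []
    with open(prefix + ".map") as fh:
        for line in fh:
            parts = line.split()
            chroms.append(int(parts[0]) - 1)
            cms.append(float(parts[2]))
            bps.append(int(parts[3]))
    chrom = np.asarray(chroms)
    n_chrom = int(chrom.max()) + 1 if chrom.size else 0
    per = int(np.bincount(chrom).max()) if chrom.size else 0
    layout = GenomeLayout(
        n_chrom, per, chrom, np.asarray(bps, dtype=np.int64), np.asarray(cms)
    )
    rows, labels = [], []
    with open(prefix + ".ped") as fh:
        for line in fh:
            parts = line.split()
            fam = parts[0]
            labels.append(int(fam[3:]) if fam.startswith("pop") else 0)
            alleles = parts[6:]
            a = np.asarray([0 if x == _ALLELES[0] else 1 for x in alleles], dtype=np.uint8)
            rows.append(a.reshape(-1, 2))
    geno = np.stack(rows)                        # (N, L, 2) raw allele indicators
    return _encode_raw(geno, np.asarray(labels)), layout


def _encode_raw(geno: np.ndarray, labels: np.ndarray) -> GenotypeMatrix:
    """Re-encode raw allele pairs against the observed major allele."""
    f1 = geno.mean(axis=(0, 2))
    major_is_allele1 = f1 > 0.5
    major_freq = np.where(major_is_allele1, f1, 1.0 - f1)
    matches = (geno == major_is_allele1[None, :, None].astype(np.uint8)).sum(axis=2)
    codes = (matches - 1).astype(np.int8)
    return GenotypeMatrix(
        codes=codes,
        allele_freqs=major_freq,
        subpop_labels=labels,
        major_is_allele1=major_is_allele1,
        untestable=(f1 == 0.0) | (f1 == 1.0),
    )


def write_vcf(path: str, gm: GenotypeMatrix, layout: GenomeLayout) -> None:
    """Minimal uncompressed biallelic unphased VCF (REF=A, ALT=C)."""
    names = locus_names(layout)
    a0, a1 = _allele_pairs(gm)
    gt = a0.astype(np.int16) + a1                # 0,1,2 copies of raw allele 1
    samples = [f"ind{i}" for i in range(gm.n_individuals)]
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in range(layout.n_chromosomes):
            fh.write(f"##contig=<ID={c + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for j, name in enumerate(names):
            # VCF POS is 1-based
            cols = [
                str(layout.chrom[j] + 1),
                str(int(layout.positions_bp[j]) + 1),
                name,
                _ALLELES[0],
                _ALLELES[1],
                ".",
                "PASS",
                ".",
                "GT",
            ]
            cols.extend(gt_str[int(g)] for g in gt[:, j])
            fh.write("\t".join(cols) + "\n")


def read_vcf(path: str) -> tuple[GenotypeMatrix, GenomeLayout]:
    """Read a biallelic VCF into a genotype matrix (via cyvcf2)."""
    from cyvcf2 import VCF

    vcf = VCF(path)
    n = len(vcf.samples)
    chroms, bps, rows = [], [], []
    for var in vcf:
        chroms.append(int(var.CHROM) - 1)
        bps.append(var.POS - 1)
        # gt_types: 0=hom-ref, 1=het, 3=hom-alt (2 is unknown)
        gt = np.asarray(var.genotype.array())[:, :2].sum(axis=1)
        rows.append(gt)
    vcf.close()
    chrom = np.asarray(chroms)
    n_chrom = int(chrom.max()) + 1 if chrom.size else 0
    per = int(np.bincount(chrom).max()) if chrom.size else 0
    cm = np.asarray(bps, dtype=float) * 1e-6  # 1 cM/Mb fallback map
    layout = GenomeLayout(n_chrom, per, chrom, np.asarray(bps, dtype=np.int64), cm)
    alt_counts = np.stack(rows).T.astype(np.int16)  # (N, L) copies of allele 1
    geno = np.stack(
        [(alt_counts >= 1).astype(np.uint8), (alt_counts == 2).astype(np.uint8)],
        axis=2,
    )
    return _encode_raw(geno, np.zeros(n, dtype=int)), layout


def write_freq_report(path: str, gm: GenotypeMatrix, layout: GenomeLayout) -> None:
    """TSV of per-locus major-allele frequency and testability."""
    names = locus_names(layout)
    with open(path, "w") as fh:
        fh.write("chrom\tsnp\tpos_bp\tmajor_allele\tmajor_freq\tuntestable\n")
        for j, name in enumerate(names):
            major = _ALLELES[int(gm.major_is_allele1[j])]
            fh.write(
                f"{layout.chrom[j] + 1}\t{name}\t{layout.positions_bp[j]}\t"
                f"{major}\t{gm.allele_freqs[j]:.6f}\t{int(gm.untestable[j])}\n"
            )


def write_phenotypes(path: str, ids: np.ndarray, values: np.ndarray, names: list[str]) -> None:
    """PLINK-style phenotype table: FID IID then one column per trait."""
    values = np.atleast_2d(values)
    if values.shape[0] != len(ids):
        values = values.T
    with open(path, "w") as fh:
        fh.write("FID\tIID\t" + "\t".join(names) + "\n")
        for i, ind in enumerate(ids):
            row = "\t".join(f"{v:.10g}" for v in values[i])
            fh.write(f"pop0\tind{ind}\t{row}\n")
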