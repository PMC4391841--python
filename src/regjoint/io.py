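"""File I/O: PLINK bed/bim/fam, phased VCF, and tabular outputs.

The PLINK codec implements the SNP-major binary layout directly: magic bytes
0x6c 0x1b, mode byte 0x01, then ceil(n/4) bytes per SNP with 2-bit codes
00 = homozygous A1, 10 = heterozygous, 11 = homozygous A2, 01 = missing.
Genotypes are returned as counts of the A1 (alternate) allele; missing calls
keep the sentinel and are imputed only downstream, never at I/O.

Phased VCF reading goes through cyvcf2; multi-allelic and unphased records
are skipped and counted.  Fixture panels are written as plain-text VCF.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .hapcore import MISSING, GenotypeDataset

__all__ = [
    "read_plink",
    "write_plink",
    "read_phased_vcf",
    "write_phased_vcf",
]

_BED_MAGIC = bytes([0x6C, 0x1B])
# 2-bit code -> A1 allele count (01 = missing)
_CODE_TO_COUNT = np.array([2, MISSING, 1, 0], dtype=np.int16)
_COUNT_TO_CODE = {2: 0b00, 1: 0b10, 0: 0b11, MISSING: 0b01}


def read_plink(prefix: str | Path) -> GenotypeDataset:
    """Read a bed/bim/fam triplet as alternate(A1)-allele counts."""
    prefix = Path(prefix)
    bed, bim, fam = (prefix.with_suffix(s) for s in (".bed", ".bim", ".fam"))
    for f in (bed, bim, fam):
        if not f.exists():
            raise FileNotFoundError(f)
    fam_df = pd.read_csv(
        fam, sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"], dtype={"iid": str},
    )
    bim_df = pd.read_csv(
        bim, sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "snp_id": str},
    )
    n, m = len(fam_df), len(bim_df)
    raw = np.fromfile(bed, dtype=np.uint8)
    if raw[:2].tobytes() != _BED_MAGIC:
        raise ValueError(f"{bed}: not a PLINK bed file (bad magic)")
    if raw[2] != 0x01:
        raise ValueError(f"{bed}: only SNP-major mode (0x01) is supported")
    bpv = (n + 3) // 4  # bytes per variant
    body = raw[3:]
    if body.size != bpv * m:
        raise ValueError(f"{bed}: size inconsistent with bim/fam ({n} x {m})")
    blocks = body.reshape(m, bpv)
    # unpack 2-bit codes, little-endian within each byte
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (blocks[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(m, bpv * 4)[:, :n]
    G = _CODE_TO_COUNT[codes].T.copy()  # n x m
    meta = pd.DataFrame(
        {
            "chrom": bim_df["chrom"],
            "pos": bim_df["pos"].astype(int),
            "snp_id": bim_df["snp_id"],
            "ref": bim_df["a2"],
            "alt": bim_df["a1"],
        }
    )
    return GenotypeDataset(G, meta, list(fam_df["iid"]))


def write_plink(G: GenotypeDataset, prefix: str | Path) -> None:
    """Write bed/bim/fam (SNP-major) for a GenotypeDataset."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = G.n, G.m
    fam = pd.DataFrame(
        {
            "fid": G.sample_ids,
            "iid": G.sample_ids,
            "father": 0,
            "mother": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)
    bim = pd.DataFrame(
        {
            "chrom": G.snp_meta["chrom"],
            "snp_id": G.snp_meta["snp_id"],
            "cm": 0,
            "pos": G.snp_meta["pos"],
            "a1": G.snp_meta["alt"],
            "a2": G.snp_meta["ref"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    bpv = (n + 3) // 4
    codes = np.empty((m, bpv * 4), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.uint8)
    for cnt, code in _COUNT_TO_CODE.items():
        lut[np.int16(cnt) & 0xFF] = code
    codes[:, :n] = lut[(G.G.T.astype(np.int16) & 0xFF)]
    codes[:, n:] = 0b00
    codes = codes.reshape(m, bpv, 4)
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    packed = (
        (codes.astype(np.uint16) << shifts[None, None, :]).sum(axis=2).astype(np.uint8)
    )
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC + bytes([0x01]))
        fh.write(packed.tobytes())


def write_phased_vcf(panel, path: str | Path) -> None:
    """Write a PhasedPanel (even row count: haplotype pairs) as plain VCF."""
    hap = panel.haplotypes
    if hap.shape[0] % 2 != 0:
        raise ValueError("panel must have an even number of haplotypes")
    n = hap.shape[0] // 2
    meta = panel.snp_meta
    samples = [f"S{i + 1}" for i in range(n)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(meta["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for j in range(panel.m):
            gts = "\t".join(
                f"{hap[2 * i, j]}|{hap[2 * i + 1, j]}" for i in range(n)
            )
            fh.write(
                f"{meta['chrom'][j]}\t{meta['pos'][j]}\t{meta['snp_id'][j]}\t"
                f"{meta['ref'][j]}\t{meta['alt'][j]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_phased_vcf(path: str | Path):
    """Read phased biallelic records into a PhasedPanel.

    Multi-allelic and not-fully-phased records are skipped; the number of
    skipped records is attached as ``panel.snp_meta.attrs['skipped']``.
    """
    from cyvcf2 import VCF

    from .simkit import PhasedPanel

    cols = []
    rows = {"chrom": [], "pos": [], "snp_id": [], "ref": [], "alt": []}
    skipped = 0
    vcf = VCF(str(path))
    for variant in vcf:
        if len(variant.ALT) != 1:
            skipped += 1
            continue
        gts = variant.genotypes  # [allele0, allele1, phased]
        if any((len(g) < 3 or not g[2] or g[0] < 0 or g[1] < 0) for g in gts):
            skipped += 1
            continue
        col = np.empty(2 * len(gts), dtype=np.int8)
        for i, g in enumerate(gts):
            col[2 * i] = g[0]
            col[2 * i + 1] = g[1]
        cols.append(col)
        rows["chrom"].append(str(variant.CHROM))
        rows["pos"].append(int(variant.POS))
        rows["snp_id"].append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        rows["ref"].append(variant.REF)
        rows["alt"].append(variant.ALT[0])
    vcf.close()
    if not cols:
        raise ValueError(f"{path}: no usable phased biallelic records")
    meta = pd.DataFrame(rows)
    meta.attrs["skipped"] = skipped
    return PhasedPanel(np.column_stack(cols), meta)
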