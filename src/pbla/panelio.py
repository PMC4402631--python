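"""Reading and writing genotype panels: PLINK-style .ped/.map text and VCF.

Genotypes are written with alleles A (major) / B (minor) in .ped files so
minor-allele dose round-trips exactly; missing calls are ``0 0``.
VCF reading uses cyvcf2; VCF writing emits minimal uncompressed text.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import CASE, CONTROL, MISSING, UNKNOWN, GenotypePanel

__all__ = [
    "read_ped_map",
    "write_ped_map",
    "read_map",
    "write_map",
    "read_vcf",
    "write_vcf",
    "read_phenotypes",
    "write_phenotypes",
]

# PLINK phenotype codes: 2=case, 1=control, 0/-9=missing
_PED_PHENO = {CASE: "2", CONTROL: "1", UNKNOWN: "-9"}
_PED_PHENO_INV = {"2": CASE, "1": CONTROL, "0": UNKNOWN, "-9": UNKNOWN}


def read_map(path) -> pd.DataFrame:
    """Read a PLINK .map file (chrom, id, cM, bp)."""
    df = pd.read_csv(
        path, sep=r"\s+", header=None, names=["chrom", "id", "cm", "bp"],
        dtype={"chrom": str, "id": str, "cm": float, "bp": np.int64},
    )
    return df[["id", "chrom", "bp", "cm"]]


def write_map(markers: pd.DataFrame, path) -> None:
    cm = markers["cm"] if "cm" in markers.columns else pd.Series(0.0, index=markers.index)
    out = pd.DataFrame(
        {"chrom": markers["chrom"], "id": markers["id"], "cm": cm, "bp": markers["bp"]}
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def write_ped_map(panel: GenotypePanel, prefix) -> tuple[Path, Path]:
    """Write ``<prefix>.ped`` and ``<prefix>.map``; returns both paths."""
    prefix = Path(prefix)
    ped_path, map_path = prefix.with_suffix(".ped"), prefix.with_suffix(".map")
    write_map(panel.markers, map_path)
    allele = {0: "A A", 1: "A B", 2: "B B", MISSING: "0 0"}
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(panel.sample_ids):
            pheno = _PED_PHENO[int(panel.phenotype[i])]
            geno = " ".join(allele[int(g)] for g in panel.calls[i])
            fh.write(f"{sid} {sid} 0 0 0 {pheno} {geno}\n")
    return ped_path, map_path


def read_ped_map(prefix) -> GenotypePanel:
    """Read a ``.ped``/``.map`` pair written by :func:`write_ped_map`.

    Minor-allele dose is taken as the count of ``B`` alleles (any non-``A``
    allele character counts as the minor allele).
    """
    prefix = Path(prefix)
    markers = read_map(prefix.with_suffix(".map"))
    sample_ids, phenos, rows = [], [], []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            sample_ids.append(parts[1])
            phenos.append(_PED_PHENO_INV.get(parts[5], UNKNOWN))
            alleles = parts[6:]
            if len(alleles) != 2 * len(markers):
                raise ValueError(
                    f"sample {parts[1]}: {len(alleles)} alleles for {len(markers)} markers"
                )
            a1, a2 = alleles[0::2], alleles[1::2]
            dose = np.empty(len(markers), dtype=np.int8)
            for j, (x, y) in enumerate(zip(a1, a2)):
                if x == "0" or y == "0":
                    dose[j] = MISSING
                else:
                    dose[j] = (x != "A") + (y != "A")
            rows.append(dose)
    return GenotypePanel(
        sample_ids=sample_ids,
        phenotype=np.array(phenos, dtype=np.int8),
        calls=np.vstack(rows) if rows else np.empty((0, len(markers)), dtype=np.int8),
        markers=markers,
    )


def write_vcf(panel: GenotypePanel, path, sites_only: bool = False) -> None:
    """Write a minimal uncompressed VCF (GT-only; A=REF major, B=ALT minor)."""
    gt = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in panel.markers["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
        if not sites_only:
            cols += ["FORMAT"] + list(panel.sample_ids)
        fh.write("\t".join(cols) + "\n")
        for j, row in enumerate(panel.markers.itertuples(index=False)):
            fields = [str(row.chrom), str(row.bp), str(row.id), "A", "B", ".", "PASS", "."]
            if not sites_only:
                fields += ["GT"] + [gt[int(g)] for g in panel.calls[:, j]]
            fh.write("\t".join(fields) + "\n")


def read_vcf(path, phenotypes=None) -> GenotypePanel:
    """Read a VCF into a panel via cyvcf2 (biallelic sites only).

    ``phenotypes`` is an optional Series/dict of case/control per sample;
    absent samples get phenotype UNKNOWN.
    """
    from cyvcf2 import VCF

    from .core import phenotype_codes

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    recs, doses = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        recs.append({"id": var.ID or f"{var.CHROM}_{var.POS}", "chrom": var.CHROM, "bp": var.POS})
        types = var.gt_types  # 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        dose = np.select([types == 0, types == 1, types == 3], [0, 1, 2], default=MISSING)
        doses.append(dose.astype(np.int8))
    vcf.close()
    markers = pd.DataFrame(recs, columns=["id", "chrom", "bp"])
    calls = np.column_stack(doses) if doses else np.empty((len(sample_ids), 0), dtype=np.int8)
    pheno = np.full(len(sample_ids), UNKNOWN, dtype=np.int8)
    if phenotypes is not None:
        coded = phenotype_codes(phenotypes)
        for i, sid in enumerate(sample_ids):
            if sid in coded.index:
                pheno[i] = coded[sid]
    return GenotypePanel(sample_ids=sample_ids, phenotype=pheno, calls=calls, markers=markers)


def read_phenotypes(path) -> pd.Series:
    """Read a two-column (sample_id, case/control) tab-separated file."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "status"], comment="#")
    from .core import phenotype_codes

    return phenotype_codes(pd.Series(df["status"].to_numpy(), index=df["sample_id"].to_numpy()))


def write_phenotypes(labels: pd.Series, path) -> None:
    inv = {CASE: "case", CONTROL: "control", UNKNOWN: "unknown"}
    with open(path, "w") as fh:
        for sid, code in labels.items():
            fh.write(f"{sid}\t{inv[int(code)]}\n")
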