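"""Readers and writers: phased VCF, local-ancestry tables, result tables.

Real-data mode ingests phased biallelic VCFs (via cyvcf2) and local
ancestry either as RFMix-style ``msp.tsv`` window tables or as per-variant
long tables. Synthetic cohorts can be exported to the same formats, and
every output directory carries a JSON run manifest sufficient to re-run the
computation bit-identically.

Coordinate conventions: VCF positions are 1-based; internal variant
indexing is 0-based; msp windows are treated as closed position intervals.
Ancestry coding is fixed at 1 = African, 0 = European.
"""

from __future__ import annotations

import datetime
import json
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import GlobalAncestryVector, HaplotypePanel, LocalAncestryPanel

__all__ = [
    "RunManifest",
    "read_phased_haplotypes",
    "read_local_ancestry",
    "write_phased_vcf",
    "write_local_ancestry_table",
    "write_results",
    "write_manifest",
]

ARTIFACT_VERSION = "0.1.0"


@dataclass
class RunManifest:
    parameters: dict
    master_seed: int
    timestamp: str = field(
        default_factory=lambda: datetime.datetime.now(datetime.UTC).isoformat()
    )
    artifact_version: str = ARTIFACT_VERSION

    def to_json(self) -> str:
        return json.dumps(
            {
                "parameters": self.parameters,
                "master_seed": self.master_seed,
                "timestamp": self.timestamp,
                "artifact_version": self.artifact_version,
            },
            indent=2,
            sort_keys=True,
        )


def read_phased_haplotypes(path: str, role: str = "causal") -> HaplotypePanel:
    """Read a phased biallelic VCF into an (n, p, 2) binary panel.

    Multi-allelic or unphased records are rejected with the offending
    record named.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    rows = []
    ids = []
    for variant in vcf:
        label = variant.ID or f"{variant.CHROM}:{variant.POS}"
        if len(variant.ALT) != 1:
            raise ValueError(f"multi-allelic record not supported: {label}")
        gts = variant.genotypes  # [allele1, allele2, phased]
        calls = np.empty((len(gts), 2), dtype=np.int8)
        for i, (a1, a2, phased) in enumerate(gts):
            if not phased:
                raise ValueError(f"unphased genotype at record {label}, sample {i}")
            if a1 < 0 or a2 < 0:
                raise ValueError(f"missing genotype at record {label}, sample {i}")
            calls[i] = (a1, a2)
        rows.append(calls)
        ids.append(label)
    if not rows:
        raise ValueError(f"no variants found in {path}")
    alleles = np.stack(rows, axis=1)  # (n, p, 2)
    return HaplotypePanel(alleles, variant_ids=ids, role=role)


def read_local_ancestry(
    path: str,
    dialect: str = "long_table",
    variant_positions: Optional[np.ndarray] = None,
    n_individuals: Optional[int] = None,
    n_variants: Optional[int] = None,
) -> LocalAncestryPanel:
    """Read binary local-ancestry calls aligned to a haplotype panel.

    ``long_table``: tab-separated columns individual, variant, hap1_anc,
    hap2_anc (0-based indices, 1 = African). ``msp``: RFMix msp.tsv with
    windows (spos/epos, closed intervals) expanded to the supplied variant
    positions; ancestry code 1 is taken as African.
    """
    if dialect == "long_table":
        df = pd.read_csv(path, sep="\t")
        need = {"individual", "variant", "hap1_anc", "hap2_anc"}
        if not need.issubset(df.columns):
            raise ValueError(f"long table must have columns {sorted(need)}")
        n = n_individuals or int(df["individual"].max()) + 1
        p = n_variants or int(df["variant"].max()) + 1
        calls = np.zeros((n, p, 2), dtype=np.int8)
        calls[df["individual"], df["variant"], 0] = df["hap1_anc"]
        calls[df["individual"], df["variant"], 1] = df["hap2_anc"]
        return LocalAncestryPanel(calls)

    if dialect != "msp":
        raise ValueError("dialect must be 'msp' or 'long_table'")
    if variant_positions is None:
        raise ValueError("msp dialect requires variant_positions")
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#Subpopulation"):
            raise ValueError("not an msp file: missing #Subpopulation header")
        header = fh.readline().lstrip("#").strip().split("\t")
        df = pd.read_csv(fh, sep="\t", names=header)
    hap_cols = header[6:]
    n = len(hap_cols) // 2
    pos = np.asarray(variant_positions)
    p = pos.shape[0]
    calls = np.full((n, p, 2), -1, dtype=np.int8)
    for row in df.itertuples(index=False):
        in_window = (pos >= row.spos) & (pos <= row.epos)
        if not in_window.any():
            continue
        vals = np.asarray(row[6:], dtype=np.int8)
        calls[:, in_window, 0] = vals[0::2][:, None]
        calls[:, in_window, 1] = vals[1::2][:, None]
    uncovered = np.flatnonzero((calls == -1).any(axis=(0, 2)))
    if uncovered.size:
        raise ValueError(
            f"variants outside all msp windows: {uncovered[:10].tolist()}"
        )
    return LocalAncestryPanel(calls)


def write_phased_vcf(
    panel: HaplotypePanel, path: str, chrom: str = "1", positions=None
) -> None:
    """Write an (n, p, 2) binary panel as a minimal phased VCF."""
    n, p = panel.n, panel.p
    if positions is None:
        positions = np.arange(1, p + 1)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        samples = "\t".join(f"ind{i}" for i in range(n))
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        for j in range(p):
            gts = "\t".join(
                f"{panel.alleles[i, j, 0]}|{panel.alleles[i, j, 1]}" for i in range(n)
            )
            fh.write(
                f"{chrom}\t{positions[j]}\t{panel.variant_ids[j]}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_local_ancestry_table(la: LocalAncestryPanel, path: str) -> None:
    """Write calls as a long table: individual, variant, hap1_anc, hap2_anc."""
    n, p = la.n, la.p
    idx = np.indices((n, p)).reshape(2, -1)
    pd.DataFrame(
        {
            "individual": idx[0],
            "variant": idx[1],
            "hap1_anc": la.calls[:, :, 0].ravel(),
            "hap2_anc": la.calls[:, :, 1].ravel(),
        }
    ).to_csv(path, sep="\t", index=False)


def write_results(table: pd.DataFrame, outdir: str, name: str, manifest=None) -> str:
    """Write a results table as TSV (plus a JSON manifest when given)."""
    os.makedirs(outdir, exist_ok=True)
    path = os.path.join(outdir, f"{name}.tsv")
    table.to_csv(path, sep="\t", index=False)
    if manifest is not None:
        write_manifest(manifest, outdir)
    return path


def write_manifest(manifest: RunManifest, outdir: str) -> str:
    os.makedirs(outdir, exist_ok=True)
    path = os.path.join(outdir, "run_manifest.json")
    with open(path, "w") as fh:
        fh.write(manifest.to_json() + "\n")
    return path
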