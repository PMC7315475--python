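"""Readers and writers for the pipeline's file dialects.

Genotypes travel as VCF 4.x (parsed with cyvcf2; the optional ``AA`` INFO
tag carries the ancestral allele, 1000 Genomes convention).  Association
tables, ancestry fractions and all outputs are header-carrying
tab-separated text.

Only biallelic SNPs are supported: indels and multi-allelic records are
skipped with a logged count.  Allele matching everywhere is exact-string on
A/C/G/T; no strand flipping is attempted (silent flipping of palindromic
SNPs is a classic scoring error), so unmatched SNPs are excluded and
reported instead.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .containers import (
    MISSING,
    AncestryProfile,
    COHORT_ANCESTRY_LABELS,
    GenotypeMatrix,
    SnpAssociation,
    VariantRecord,
)

logger = logging.getLogger("admixprs")

_BASES = {"A", "C", "G", "T"}


def _is_biallelic_snp(ref: str, alts: Sequence[str]) -> bool:
    return len(alts) == 1 and ref in _BASES and alts[0] in _BASES


def read_vcf(path: str | Path) -> tuple[list[VariantRecord], list[str]]:
    """Read biallelic SNPs from a VCF into variant records.

    Genotypes are decoded to alternate-allele counts (0/1/2, missing for
    ``./.``).  The ``AA`` INFO value becomes the ancestral allele when it
    matches REF or ALT (case-insensitive); otherwise the ancestral state is
    unknown and a warning is logged.  Multi-allelic records and indels are
    skipped with a logged count.
    """
    vcf = VCF(str(path), gts012=True)
    individuals = list(vcf.samples)
    records: list[VariantRecord] = []
    n_skipped = 0
    n_aa_mismatch = 0
    for v in vcf:
        if not _is_biallelic_snp(v.REF, v.ALT):
            n_skipped += 1
            continue
        # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        g = np.asarray(v.gt_types, dtype=np.int16)
        g[g == 3] = MISSING
        aa = v.INFO.get("AA")
        ancestral = None
        if aa is not None:
            aa = str(aa).split("|")[0].strip().upper()
            if aa == v.REF:
                ancestral = v.REF
            elif aa == v.ALT[0]:
                ancestral = v.ALT[0]
            else:
                n_aa_mismatch += 1
        vid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}"
        records.append(
            VariantRecord(
                chrom=v.CHROM,
                pos=v.POS,
                id=vid,
                ref=v.REF,
                alt=v.ALT[0],
                ancestral=ancestral,
                genotypes=g,
            )
        )
    if n_skipped:
        logger.info("read_vcf(%s): skipped %d non-biallelic-SNP records", path, n_skipped)
    if n_aa_mismatch:
        logger.warning(
            "read_vcf(%s): %d AA values matched neither REF nor ALT; "
            "ancestral state set to unknown",
            path,
            n_aa_mismatch,
        )
    return records, individuals


def read_genotype_matrix(path: str | Path) -> GenotypeMatrix:
    """Read a VCF straight into a :class:`GenotypeMatrix`."""
    records, individuals = read_vcf(path)
    return GenotypeMatrix.from_variant_records(records, individuals)


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a genotype matrix as uncompressed VCF 4.2 with AA annotation."""
    path = Path(path)
    chroms = list(dict.fromkeys(matrix.snps["chrom"].astype(str)))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            '##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral Allele">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.individuals)
            + "\n"
        )
        gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for j in range(matrix.n_snps):
            row = matrix.snps.iloc[j]
            anc = row["ancestral"]
            info = f"AA={anc}" if anc is not None and pd.notna(anc) else "."
            calls = "\t".join(gt_strings[int(g)] for g in matrix.dosages[:, j])
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{row['id']}\t{row['ref']}\t"
                f"{row['alt']}\t.\t.\t{info}\tGT\t{calls}\n"
            )


# ---------------------------------------------------------------------------
# association tables
# ---------------------------------------------------------------------------

_REQUIRED_ASSOC_COLS = ["id", "chrom", "pos", "effect_allele", "other_allele"]


def read_association_table(path: str | Path) -> list[SnpAssociation]:
    """Read a tab-separated trait-association table.

    Required columns: id, chrom, pos, effect_allele, other_allele.
    Optional: cohort_ancestry (comma-separated labels), effect_polarity,
    weight.  Rows with identical effect and other allele are rejected with
    a warning; duplicate ids collapse to a single association carrying the
    union of their ancestry labels.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "id": str})
    missing = [c for c in _REQUIRED_ASSOC_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"association table {path} missing column(s) {missing}")
    out: dict[str, SnpAssociation] = {}
    n_rejected = 0
    n_dup = 0
    for _, row in df.iterrows():
        if row["effect_allele"] == row["other_allele"]:
            n_rejected += 1
            logger.warning(
                "association %s: effect allele equals other allele; row rejected",
                row["id"],
            )
            continue
        labels: frozenset[str] = frozenset()
        if "cohort_ancestry" in df.columns and pd.notna(row.get("cohort_ancestry")):
            labels = frozenset(
                s.strip() for s in str(row["cohort_ancestry"]).split(",") if s.strip()
            )
            bad = labels - COHORT_ANCESTRY_LABELS
            if bad:
                raise ValueError(
                    f"association {row['id']}: unknown ancestry label(s) {sorted(bad)}"
                )
        polarity = "unknown"
        if "effect_polarity" in df.columns and pd.notna(row.get("effect_polarity")):
            polarity = str(row["effect_polarity"])
        weight = None
        if "weight" in df.columns and pd.notna(row.get("weight")):
            weight = float(row["weight"])
        assoc = SnpAssociation(
            id=str(row["id"]),
            chrom=str(row["chrom"]),
            pos=int(row["pos"]),
            effect_allele=str(row["effect_allele"]),
            other_allele=str(row["other_allele"]),
            cohort_ancestry=labels,
            effect_polarity=polarity,
            weight=weight,
        )
        if assoc.id in out:
            n_dup += 1
            prev = out[assoc.id]
            out[assoc.id] = SnpAssociation(
                id=prev.id,
                chrom=prev.chrom,
                pos=prev.pos,
                effect_allele=prev.effect_allele,
                other_allele=prev.other_allele,
                cohort_ancestry=prev.cohort_ancestry | assoc.cohort_ancestry,
                effect_polarity=prev.effect_polarity,
                weight=prev.weight,
            )
        else:
            out[assoc.id] = assoc
    if n_dup:
        logger.info("read_association_table(%s): merged %d duplicate ids", path, n_dup)
    if n_rejected:
        logger.info(
            "read_association_table(%s): rejected %d malformed rows", path, n_rejected
        )
    return list(out.values())


def write_association_table(
    associations: Sequence[SnpAssociation], path: str | Path
) -> None:
    rows = [
        {
            "id": a.id,
            "chrom": a.chrom,
            "pos": a.pos,
            "effect_allele": a.effect_allele,
            "other_allele": a.other_allele,
            "cohort_ancestry": ",".join(sorted(a.cohort_ancestry)),
            "effect_polarity": a.effect_polarity,
        }
        for a in associations
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ancestry fractions
# ---------------------------------------------------------------------------

_FRACTION_COLS = ["f_African", "f_European", "f_NativeAmerican"]


def read_ancestry_fractions(path: str | Path) -> list[AncestryProfile]:
    """Read per-individual three-way ancestry fractions (TSV).

    Rows whose fractions do not sum to 1 within 1e-3 are excluded entirely
    with a warning (never renormalized).
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ["individual_id"] + _FRACTION_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"ancestry table {path} missing column(s) {missing}")
    profiles = []
    n_rejected = 0
    for _, row in df.iterrows():
        total = sum(float(row[c]) for c in _FRACTION_COLS)
        if not (1.0 - 1e-3 <= total <= 1.0 + 1e-3):
            n_rejected += 1
            logger.warning(
                "ancestry row %s: fractions sum to %.6f; row rejected",
                row["individual_id"],
                total,
            )
            continue
        vals = np.array([float(row[c]) for c in _FRACTION_COLS])
        vals = vals / vals.sum()  # absorb sub-1e-3 rounding before validation
        profiles.append(AncestryProfile(str(row["individual_id"]), *vals))
    if n_rejected:
        logger.info(
            "read_ancestry_fractions(%s): rejected %d rows", path, n_rejected
        )
    return profiles


def write_ancestry_fractions(
    profiles: Sequence[AncestryProfile], path: str | Path
) -> None:
    pd.DataFrame(
        {
            "individual_id": [p.individual_id for p in profiles],
            "f_African": [p.f_African for p in profiles],
            "f_European": [p.f_European for p in profiles],
            "f_NativeAmerican": [p.f_NativeAmerican for p in profiles],
        }
    ).to_csv(path, sep="\t", index=False)


def ancestry_frame(profiles: Sequence[AncestryProfile]) -> pd.DataFrame:
    """Profiles as a DataFrame indexed by individual id."""
    return pd.DataFrame(
        [
            {
                "individual_id": p.individual_id,
                "f_African": p.f_African,
                "f_European": p.f_European,
                "f_NativeAmerican": p.f_NativeAmerican,
            }
            for p in profiles
        ]
    ).set_index("individual_id")
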