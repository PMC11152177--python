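"""Readers and writers for the pipeline's on-disk formats.

Conventions: VCF and GFF3 positions are 1-based, BED is 0-based half-open;
everything is converted to 1-based at the boundary. Genotypes are stored as
alternate-allele dosages. All tabular formats are TSV with a header row.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import MISSING, AbundanceTable, GenotypeMatrix, RelationshipMatrix


class FormatError(ValueError):
    pass


class SchemaError(ValueError):
    pass


# ---------------------------------------------------------------- genotypes

def read_vcf(path: str | Path, skip_multiallelic: bool = True) -> GenotypeMatrix:
    """Read GT fields from a VCF into an alternate-allele dosage matrix.

    Half-calls and missing genotypes map to the missing marker; multi-allelic
    records are skipped with a warning by default (split upstream if needed).
    """
    from cyvcf2 import VCF  # deferred: import cost and optional at runtime

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, meta = [], []
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            if skip_multiallelic:
                continue
            raise FormatError(f"multi-allelic record at {rec.CHROM}:{rec.POS}")
        gts = rec.genotype.array()[:, :2]
        dos = np.where((gts < 0).any(axis=1), MISSING, (gts > 0).sum(axis=1))
        rows.append(dos.astype(np.int16))
        meta.append((rec.CHROM, rec.POS, rec.ID or f"{rec.CHROM}:{rec.POS}",
                     rec.REF, rec.ALT[0]))
    if n_multi:
        import warnings

        warnings.warn(f"skipped {n_multi} multi-allelic records")
    if not meta:
        raise FormatError(f"no biallelic records in {path}")
    variant_meta = pd.DataFrame(meta, columns=["chrom", "pos", "id", "ref", "alt"])
    return GenotypeMatrix(
        dosages=np.column_stack(rows), variant_meta=variant_meta, sample_ids=samples
    )


_DOSAGE_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(G: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal GT-only VCF (v4.2, 1-based positions)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(G.variant_meta["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(G.sample_ids) + "\n")
        for j, rec in G.variant_meta.iterrows():
            gts = "\t".join(_DOSAGE_CODE[int(d)] for d in G.dosages[:, j])
            fh.write(f"{rec.chrom}\t{rec.pos}\t{rec.id}\t{rec.ref}\t{rec.alt}"
                     f"\t.\t.\t.\tGT\t{gts}\n")


def write_dosage_tsv(G: GenotypeMatrix, path: str | Path) -> None:
    """Samples x SNPs dosage TSV; missing written as NA."""
    df = pd.DataFrame(
        np.where(G.dosages == MISSING, np.nan, G.dosages),
        index=pd.Index(G.sample_ids, name="sample_id"),
        columns=G.variant_meta["id"],
    )
    df.to_csv(path, sep="\t", na_rep="NA")


def read_dosage_tsv(
    path: str | Path, variant_meta: pd.DataFrame | None = None
) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    dos = df.to_numpy(dtype=float)
    bad = ~(np.isnan(dos) | np.isin(dos, (0.0, 1.0, 2.0)))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise FormatError(f"non-dosage value at row {i + 1}, column {j + 1}")
    dosages = np.where(np.isnan(dos), MISSING, dos).astype(np.int16)
    if variant_meta is None:
        m = dosages.shape[1]
        variant_meta = pd.DataFrame(
            {"chrom": ["1"] * m, "pos": np.arange(1, m + 1), "id": list(df.columns),
             "ref": ["A"] * m, "alt": ["G"] * m}
        )
    return GenotypeMatrix(
        dosages=dosages, variant_meta=variant_meta, sample_ids=[str(s) for s in df.index]
    )


def read_genotypes(path: str | Path, format: str = "vcf") -> GenotypeMatrix:
    """Dispatch on format: "vcf" or "dosage-tsv"."""
    if format == "vcf":
        return read_vcf(path)
    if format == "dosage-tsv":
        return read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format: {format}")


# -------------------------------------------------------------- flat tables

def read_table(
    path: str | Path,
    required: tuple[str, ...] = ("sample_id",),
    numeric: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Validated TSV reader: required columns, typed numerics, unique IDs."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"missing required column '{col}' in {path}")
    if "sample_id" in df.columns and df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
        raise SchemaError(f"duplicate sample ID '{dup}' in {path}")
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            r = int(bad.idxmax())
            raise SchemaError(
                f"non-numeric value in column '{col}' row {r + 2} of {path}"
            )
        df[col] = coerced
    return df


def write_abundance_tsv(A: AbundanceTable, path: str | Path) -> None:
    pd.DataFrame(
        A.rel_abundance,
        index=pd.Index(A.sample_ids, name="sample_id"),
        columns=A.taxon_meta["taxon_id"],
    ).to_csv(path, sep="\t")


def read_abundance_tsv(path: str | Path, level: str = "ASV") -> AbundanceTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    rel = df.to_numpy(dtype=float)
    meta = pd.DataFrame(
        {"taxon_id": list(df.columns), "level": [level] * df.shape[1],
         "detection_rate": (rel > 0).mean(axis=0)}
    )
    return AbundanceTable(
        rel_abundance=rel, taxon_meta=meta, sample_ids=[str(s) for s in df.index]
    )


def write_relationship_tsv(K: RelationshipMatrix, path: str | Path) -> None:
    """Full n x n matrix with sample IDs as header and index."""
    pd.DataFrame(K.values, index=K.sample_ids, columns=K.sample_ids).to_csv(
        path, sep="\t", index_label="sample_id"
    )


def read_relationship_tsv(path: str | Path, kind: str = "GRM") -> RelationshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    v = df.to_numpy(dtype=float)
    v = (v + v.T) / 2.0  # text round-trip may perturb symmetry in the last ulp
    return RelationshipMatrix(values=v, sample_ids=[str(s) for s in df.columns], kind=kind)


def write_sparse_triplets(K: RelationshipMatrix, path: str | Path) -> None:
    """id1, id2, value triplets of the nonzero lower triangle incl. diagonal
    (GCTA .grm.sp flavor)."""
    ids = K.sample_ids
    with open(path, "w") as fh:
        fh.write("id1\tid2\tvalue\n")
        for i in range(K.n):
            for j in range(i + 1):
                if K.values[i, j] != 0.0:
                    fh.write(f"{ids[i]}\t{ids[j]}\t{K.values[i, j]:.10g}\n")


# ----------------------------------------------------------- TSS annotation

def read_tss(path: str | Path, format: str = "gff3") -> pd.DataFrame:
    """Gene TSS table (gene_id, chrom, tss 1-based) from GFF3 or BED.

    GFF3: `gene` features, strand-aware (TSS = start on +, end on −).
    BED: 0-based half-open; TSS = start+1 on +, end on −; name column is the
    gene ID.
    """
    rows = []
    if format == "gff3":
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                if line.startswith("#") or not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 9:
                    raise FormatError(f"malformed GFF3 line {ln}")
                if f[2] != "gene":
                    continue
                attrs = dict(
                    kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
                )
                gid = attrs.get("ID") or attrs.get("gene_id")
                if gid is None:
                    raise FormatError(f"gene without ID at GFF3 line {ln}")
                start, end, strand = int(f[3]), int(f[4]), f[6]
                rows.append((gid, f[0], start if strand != "-" else end))
    elif format == "bed":
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 4:
                    raise FormatError(f"BED needs >= 4 columns at line {ln}")
                start, end = int(f[1]), int(f[2])
                strand = f[5] if len(f) > 5 else "+"
                rows.append((f[3], f[0], start + 1 if strand != "-" else end))
    else:
        raise ValueError(f"unknown annotation format: {format}")
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "tss"])


def write_expression_tsv(
    counts: pd.DataFrame, lengths: pd.Series, path: str | Path
) -> None:
    """Genes x samples counts with a leading `length` column."""
    out = counts.copy()
    out.insert(0, "length", lengths.reindex(counts.index))
    out.to_csv(path, sep="\t", index_label="gene_id")


def read_expression_tsv(path: str | Path) -> tuple[pd.DataFrame, pd.Series]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "length" not in df.columns:
        raise SchemaError(f"missing required column 'length' in {path}")
    lengths = df.pop("length").astype(float)
    return df.astype(np.int64), lengths
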