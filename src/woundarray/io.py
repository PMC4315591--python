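"""Readers and writers for the pipeline's plain-text formats.

Expression matrices and design tables travel as TSV, gene annotations as
BED6 or refGene-style TSV, ontologies as OBO 1.2 and annotations as
GAF-style TSV (see :mod:`woundarray.ontology` for the latter two).
"""

from __future__ import annotations

import pandas as pd

from .core import DesignTable, ExpressionMatrix, ValidationError


def write_expression(m: ExpressionMatrix, path) -> None:
    df = m.values.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t")


def read_expression(path, scale: str = "linear") -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        row = df.index[df.isna().any(axis=1)][0]
        raise ValidationError(f"missing value in row {row!r} of {path}")
    return ExpressionMatrix(df, scale=scale)


def write_design(design: DesignTable, path) -> None:
    design.table.to_csv(path, sep="\t", index=False)


def read_design(path, conditions=None) -> DesignTable:
    df = pd.read_csv(path, sep="\t")
    kwargs = {} if conditions is None else {"conditions": tuple(conditions)}
    return DesignTable(df, **kwargs)


def read_expression_table(
    matrix_path, design_path, scale: str = "linear", conditions=None
) -> tuple[ExpressionMatrix, DesignTable]:
    """Load and cross-validate an expression matrix and its design."""
    m = read_expression(matrix_path, scale=scale)
    d = read_design(design_path, conditions=conditions)
    d.validate_against(m)
    return m, d


def write_bed(annotation: pd.DataFrame, path) -> None:
    """Write loci as BED6 (chrom, start, end, name, score, strand)."""
    bed = pd.DataFrame(
        {
            "chrom": annotation["arm"],
            "start": annotation["start"],
            "end": annotation["end"],
            "name": annotation["gene"],
            "score": 0,
            "strand": annotation["strand"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValidationError(f"{path}:{lineno}: expected ≥6 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ValidationError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from None
            rows.append((parts[3], parts[0], start, end, parts[5]))
    return pd.DataFrame(rows, columns=["gene", "arm", "start", "end", "strand"])


REFGENE_COLUMNS = [
    "bin", "name", "chrom", "strand", "txStart", "txEnd", "cdsStart",
    "cdsEnd", "exonCount", "exonStarts", "exonEnds", "score", "name2",
]


def write_refgene(annotation: pd.DataFrame, path) -> None:
    """Write loci in refGene-style TSV; gene symbol goes into name2."""
    df = pd.DataFrame(
        {
            "bin": 0,
            "name": ["NM_" + g for g in annotation["gene"]],
            "chrom": ["chr" + a for a in annotation["arm"]],
            "strand": annotation["strand"],
            "txStart": annotation["start"],
            "txEnd": annotation["end"],
            "cdsStart": annotation["start"],
            "cdsEnd": annotation["end"],
            "exonCount": 1,
            "exonStarts": annotation["start"].astype(str) + ",",
            "exonEnds": annotation["end"].astype(str) + ",",
            "score": 0,
            "name2": annotation["gene"],
        }
    )
    df.to_csv(path, sep="\t", header=False, index=False)


def read_refgene(path) -> pd.DataFrame:
    """Read refGene-style TSV; first transcript per name2 symbol is kept."""
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < len(REFGENE_COLUMNS):
                raise ValidationError(
                    f"{path}:{lineno}: expected ≥{len(REFGENE_COLUMNS)} columns"
                )
            chrom = parts[2]
            arm = chrom[3:] if chrom.startswith("chr") else chrom
            try:
                start, end = int(parts[4]), int(parts[5])
            except ValueError:
                raise ValidationError(
                    f"{path}:{lineno}: non-integer txStart/txEnd"
                ) from None
            rows.append((parts[12], arm, start, end, parts[3]))
    df = pd.DataFrame(rows, columns=["gene", "arm", "start", "end", "strand"])
    return df.drop_duplicates(subset="gene", keep="first").reset_index(drop=True)


def read_gene_annotation(path, format: str = "bed") -> pd.DataFrame:
    if format == "bed":
        return read_bed(path)
    if format == "refgene":
        return read_refgene(path)
    raise ValidationError(f"unrecognized annotation format {format!r}")
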