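"""Containers and on-disk formats for the three data layers.

Genotypes are stored as alternate-allele counts (0/1/2); the minor allele
frequency is folded downstream, so allele labeling never changes results.
Coordinates are 1-based as in VCF; chromosome labels are opaque strings
compared literally.  In TSV dialects "NA" (any case) and the empty cell
both mean missing.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "ExpressionMatrix",
    "PhenotypeTable",
    "GeneSetCollection",
    "PpiEdgeList",
    "read_genotypes",
    "write_genotypes",
    "read_expression",
    "write_expression",
    "read_phenotypes",
    "write_phenotypes",
    "read_gene_sets",
    "write_gene_sets",
    "read_ppi",
    "write_ppi",
    "align_cohort",
]

_NA_STRINGS = {"", "na", "nan", "."}


class DataValidationError(ValueError):
    """Raised when an input file or container violates its contract."""


def _is_missing_token(cell: str) -> bool:
    return cell.strip().lower() in _NA_STRINGS


@dataclass
class GenotypeMatrix:
    """Samples x SNPs allele-count calls plus per-SNP metadata.

    ``calls`` is a float DataFrame (samples as rows, SNPs as columns) with
    values in {0, 1, 2} or NaN for missing.  ``snp_meta`` is indexed by
    snp_id with columns chrom, pos, ref, alt, gene (any may be empty).
    """

    calls: pd.DataFrame
    snp_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.snp_meta is None:
            self.snp_meta = pd.DataFrame(
                {"chrom": "", "pos": 1, "ref": "A", "alt": "B", "gene": ""},
                index=self.calls.columns,
            )
        self.validate()

    def validate(self) -> None:
        if self.calls.index.duplicated().any():
            raise DataValidationError("duplicate sample ids in genotype matrix")
        if self.calls.columns.duplicated().any():
            raise DataValidationError("duplicate snp ids in genotype matrix")
        vals = self.calls.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise DataValidationError(
                f"genotype call {vals[i, j]!r} at sample "
                f"{self.calls.index[i]!r}, snp {self.calls.columns[j]!r} "
                "not in {0,1,2,NA}"
            )
        if not self.snp_meta.index.equals(self.calls.columns):
            raise DataValidationError("snp_meta index does not match call columns")
        if (pd.to_numeric(self.snp_meta["pos"], errors="coerce") < 1).any():
            raise DataValidationError("SNP positions must be >= 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.calls.columns)

    def subset_samples(self, sample_ids) -> "GenotypeMatrix":
        return GenotypeMatrix(self.calls.loc[list(sample_ids)], self.snp_meta.copy())

    def subset_snps(self, snp_ids) -> "GenotypeMatrix":
        ids = list(snp_ids)
        return GenotypeMatrix(self.calls[ids], self.snp_meta.loc[ids])


@dataclass
class ExpressionMatrix:
    """Probes x samples log2 intensities plus optional probe annotations.

    ``probe_meta`` is indexed by probe_id with columns gene and chrom;
    missing annotations are empty strings.
    """

    values: pd.DataFrame
    probe_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.probe_meta is None:
            self.probe_meta = pd.DataFrame(
                {"gene": "", "chrom": ""}, index=self.values.index
            )
        self.validate()

    def validate(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise DataValidationError(f"duplicate probe id {dup!r}")
        if self.values.columns.duplicated().any():
            raise DataValidationError("duplicate sample ids in expression matrix")
        if not self.probe_meta.index.equals(self.values.index):
            raise DataValidationError("probe_meta index does not match probe rows")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def has_missing(self) -> bool:
        return bool(self.values.isna().any().any())

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(sample_ids)], self.probe_meta.copy())

    def subset_probes(self, probe_ids) -> "ExpressionMatrix":
        ids = list(probe_ids)
        return ExpressionMatrix(self.values.loc[ids], self.probe_meta.loc[ids])


_OPTIONAL_TRAITS = (
    "age_decade",
    "gender",
    "recurrence_frequency",
    "recurrence_code",
    "recurrence_after_sample",
    "ki67_step",
    "chrom_arm_losses",
    "chr22_deletion",
)


@dataclass
class PhenotypeTable:
    """Per-sample WHO grade (1-3), derived binary stage, optional traits.

    Stage is 0 for grade I and 1 for grades II/III (lowly malignant vs
    malignant).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        tab = self.table
        if tab.index.duplicated().any():
            raise DataValidationError("duplicate sample ids in phenotype table")
        grades = tab["who_grade"]
        if not grades.isin([1, 2, 3]).all():
            bad = grades[~grades.isin([1, 2, 3])]
            raise DataValidationError(
                f"who_grade outside {{1,2,3}} for sample(s) {list(bad.index)}"
            )
        stage = derive_stage(grades)
        if "stage_binary" in tab.columns:
            if not (tab["stage_binary"] == stage).all():
                raise DataValidationError("stage_binary inconsistent with who_grade")
        else:
            tab = tab.copy()
            tab["stage_binary"] = stage
            self.table = tab

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def who_grade(self) -> pd.Series:
        return self.table["who_grade"]

    @property
    def stage_binary(self) -> pd.Series:
        return self.table["stage_binary"]

    def traits(self) -> pd.DataFrame:
        cols = [c for c in self.table.columns if c != "stage_binary"]
        return self.table[cols]

    def subset_samples(self, sample_ids) -> "PhenotypeTable":
        return PhenotypeTable(self.table.loc[list(sample_ids)])


def derive_stage(who_grade: pd.Series) -> pd.Series:
    """Binary malignancy stage: 0 for WHO grade I, 1 for grades II/III."""
    return (who_grade.astype(int) > 1).astype(int)


@dataclass
class GeneSetCollection:
    """term_id -> (description, frozenset of gene symbols)."""

    sets: dict

    def __post_init__(self) -> None:
        for term, (_desc, genes) in self.sets.items():
            if not genes:
                raise DataValidationError(f"gene set {term!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def genes(self, term: str) -> frozenset:
        return self.sets[term][1]

    def items(self):
        return self.sets.items()


@dataclass
class PpiEdgeList:
    """Undirected, deduplicated protein-protein edges without self-loops."""

    edges: frozenset  # of 2-element frozensets

    @classmethod
    def from_pairs(cls, pairs) -> "PpiEdgeList":
        edges = set()
        for a, b in pairs:
            if a == b:
                continue
            edges.add(frozenset((a, b)))
        return cls(frozenset(edges))

    @property
    def nodes(self) -> frozenset:
        out: set = set()
        for e in self.edges:
            out |= e
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.edges)

    def has_edge(self, a, b) -> bool:
        return frozenset((a, b)) in self.edges


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_tsv_matrix(path, index_name: str) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        index_col=0,
        dtype=str,
        keep_default_na=False,
        comment=None,
    )
    df.index.name = index_name
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def _to_float(df: pd.DataFrame, what: str) -> pd.DataFrame:
    out = pd.DataFrame(np.nan, index=df.index, columns=df.columns, dtype=float)
    for j, col in enumerate(df.columns):
        cells = df[col]
        mask = cells.map(_is_missing_token)
        try:
            out[col] = pd.to_numeric(cells.where(~mask), errors="raise").astype(float)
        except (ValueError, TypeError):
            bad = cells[~mask & pd.to_numeric(cells, errors="coerce").isna()]
            row = bad.index[0] if len(bad) else df.index[0]
            raise DataValidationError(
                f"non-numeric {what} cell {bad.iloc[0]!r} at row {row!r}, "
                f"column {col!r}"
            ) from None
    return out


def read_genotypes(path, format: str = "tsv_dosage") -> GenotypeMatrix:
    """Read genotypes from a TSV dosage table or a minimal VCF.

    TSV dosage: header row of snp_ids, first column sample_id, cells in
    {0,1,2,NA}.  VCF: v4.x with GT calls; only biallelic records are
    accepted ("0/0"->0, "0/1"/"1/0"->1, "1/1"->2, "./."->missing).
    """
    if format == "tsv_dosage":
        raw = _read_tsv_matrix(path, "sample_id")
        calls = _to_float(raw, "genotype")
        return GenotypeMatrix(calls)
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path) -> GenotypeMatrix:
    sample_ids: list[str] = []
    snp_ids: list[str] = []
    meta_rows: list[dict] = []
    columns: list[np.ndarray] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                fields = line.split("\t")
                sample_ids = fields[9:]
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise DataValidationError(f"truncated VCF record: {line[:60]!r}")
            chrom, pos, vid, ref, alt = fields[0], fields[1], fields[2], fields[3], fields[4]
            if "," in alt:
                raise DataValidationError(
                    f"multi-allelic VCF record at {chrom}:{pos} ({vid})"
                )
            fmt_keys = fields[8].split(":")
            if "GT" not in fmt_keys:
                raise DataValidationError(f"no GT field at {chrom}:{pos}")
            gt_idx = fmt_keys.index("GT")
            dosages = np.empty(len(sample_ids), dtype=float)
            for s, cell in enumerate(fields[9:]):
                gt = cell.split(":")[gt_idx].replace("|", "/")
                alleles = gt.split("/")
                if any(a == "." for a in alleles):
                    dosages[s] = np.nan
                    continue
                try:
                    counts = [int(a) for a in alleles]
                except ValueError:
                    raise DataValidationError(
                        f"malformed GT {gt!r} at {chrom}:{pos}, sample "
                        f"{sample_ids[s]!r}"
                    ) from None
                if any(a not in (0, 1) for a in counts):
                    raise DataValidationError(
                        f"multi-allelic GT {gt!r} at {chrom}:{pos}"
                    )
                dosages[s] = sum(counts)
            snp_id = vid if vid not in (".", "") else f"{chrom}:{pos}"
            snp_ids.append(snp_id)
            meta_rows.append(
                {"chrom": chrom, "pos": int(pos), "ref": ref, "alt": alt, "gene": ""}
            )
            columns.append(dosages)
    if not sample_ids:
        raise DataValidationError("VCF has no #CHROM header line")
    calls = pd.DataFrame(
        np.column_stack(columns) if columns else np.empty((len(sample_ids), 0)),
        index=pd.Index(sample_ids, name="sample_id"),
        columns=snp_ids,
    )
    meta = pd.DataFrame(meta_rows, index=snp_ids)
    return GenotypeMatrix(calls, meta)


def write_genotypes(geno: GenotypeMatrix, path, format: str = "tsv_dosage") -> None:
    """Write genotypes; the TSV writer uses integer cells and NA for missing."""
    if format == "tsv_dosage":
        out = geno.calls.map(lambda v: "NA" if pd.isna(v) else str(int(v)))
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")
        return
    if format == "vcf":
        _write_vcf(geno, path)
        return
    raise ValueError(f"unknown genotype format {format!r}")


def _write_vcf(geno: GenotypeMatrix, path) -> None:
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.sample_ids)
            + "\n"
        )
        for snp in geno.snp_ids:
            m = geno.snp_meta.loc[snp]
            cells = [
                gt_map.get(v, "./.") if not pd.isna(v) else "./."
                for v in geno.calls[snp]
            ]
            fh.write(
                f"{m['chrom'] or '1'}\t{int(m['pos'])}\t{snp}\t{m['ref'] or 'A'}\t"
                f"{m['alt'] or 'C'}\t.\t.\t.\tGT\t" + "\t".join(cells) + "\n"
            )


def read_expression(path, meta_path=None) -> ExpressionMatrix:
    """Read a probes x samples TSV; optionally merge a probe-annotation TSV.

    The sidecar must have a probe_id first column and may carry ``gene`` and
    ``chrom`` columns; probes without a sidecar row keep empty annotations.
    """
    raw = _read_tsv_matrix(path, "probe_id")
    values = _to_float(raw, "expression")
    meta = None
    if meta_path is not None:
        side = pd.read_csv(
            meta_path, sep="\t", index_col=0, dtype=str, keep_default_na=False
        )
        meta = pd.DataFrame({"gene": "", "chrom": ""}, index=values.index)
        for col in ("gene", "chrom"):
            if col in side.columns:
                shared = side.index.intersection(values.index)
                meta.loc[shared, col] = side.loc[shared, col]
    return ExpressionMatrix(values, meta)


def write_expression(expr: ExpressionMatrix, path, meta_path=None) -> None:
    out = expr.values.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t", na_rep="NA", float_format="%.10g")
    if meta_path is not None:
        meta = expr.probe_meta.copy()
        meta.index.name = "probe_id"
        meta.to_csv(meta_path, sep="\t")


def read_phenotypes(path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False, dtype=str)
    df.index = df.index.astype(str)
    out = pd.DataFrame(index=df.index)
    out["who_grade"] = pd.to_numeric(df["who_grade"], errors="raise").astype(int)
    for col in df.columns:
        if col in ("who_grade",):
            continue
        cells = df[col]
        mask = cells.map(_is_missing_token)
        out[col] = pd.to_numeric(cells.where(~mask), errors="coerce")
    return PhenotypeTable(out)


def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    out = pheno.table.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", na_rep="NA", float_format="%.10g")


def read_gene_sets(path) -> GeneSetCollection:
    """Read a GMT file (term, description, tab-separated gene symbols)."""
    sets: dict = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3 or not any(g.strip() for g in parts[2:]):
                raise DataValidationError(f"GMT line {ln}: term with no genes")
            term, desc = parts[0], parts[1]
            if term in sets:
                raise DataValidationError(f"GMT line {ln}: duplicate term {term!r}")
            genes = frozenset(g.strip() for g in parts[2:] if g.strip())
            sets[term] = (desc, genes)
    return GeneSetCollection(sets)


def write_gene_sets(collection: GeneSetCollection, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for term, (desc, genes) in collection.items():
            fh.write("\t".join([term, desc, *sorted(genes)]) + "\n")


def read_ppi(path) -> PpiEdgeList:
    """Read a two-column TSV edge list; duplicates and self-loops dropped."""
    pairs = []
    with open(path, "rt", encoding="utf-8") as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise DataValidationError(f"PPI line {ln}: expected two columns")
            pairs.append((parts[0].strip(), parts[1].strip()))
    return PpiEdgeList.from_pairs(pairs)


def write_ppi(ppi: PpiEdgeList, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for edge in sorted(tuple(sorted(e)) for e in ppi.edges):
            fh.write(f"{edge[0]}\t{edge[1]}\n")


def align_cohort(geno: GenotypeMatrix, expr: ExpressionMatrix, pheno: PhenotypeTable):
    """Restrict all three layers to their shared samples, in a common order.

    The shared order is the genotype matrix's sample order restricted to the
    intersection, so the operation is idempotent.
    """
    shared = [
        s
        for s in geno.sample_ids
        if s in set(expr.sample_ids) and s in set(pheno.sample_ids)
    ]
    if not shared:
        raise DataValidationError("no samples shared across genotype/expression/phenotype")
    return (
        geno.subset_samples(shared),
        expr.subset_samples(shared),
        pheno.subset_samples(shared),
    )
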