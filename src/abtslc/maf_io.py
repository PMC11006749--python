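"""Reading, validating and filtering MAF-format somatic mutation calls.

A MAF (Mutation Annotation Format) file is a tab-separated table with one
somatic variant call per row.  This module reads the GDC open-access dialect
('#'-prefixed comment lines, ``Hugo_Symbol`` / ``Variant_Classification`` /
``Tumor_Sample_Barcode`` mandatory columns), normalises the handful of columns
the downstream analyses need into a compact :class:`MutationTable`, and builds
the :class:`SampleRegistry` that provides every denominator used elsewhere.

Only gene-symbol-level analysis is supported: strand and genomic coordinates
are intentionally ignored.  Protein positions are 1-based residue indices.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, MafFormatError

logger = logging.getLogger(__name__)

#: Variant_Classification labels counted as protein-altering ("qualifying")
#: throughout the pipeline; this is the maftools non-synonymous convention.
NONSYNONYMOUS_CLASSES = frozenset({
    "Missense_Mutation",
    "Nonsense_Mutation",
    "Nonstop_Mutation",
    "Frame_Shift_Del",
    "Frame_Shift_Ins",
    "In_Frame_Del",
    "In_Frame_Ins",
    "Splice_Site",
    "Translation_Start_Site",
})

#: Closed Variant_Classification vocabulary accepted by default (GDC MAF).
DEFAULT_VOCABULARY = frozenset(NONSYNONYMOUS_CLASSES | {
    "Silent",
    "Splice_Region",
    "3'UTR",
    "5'UTR",
    "3'Flank",
    "5'Flank",
    "Intron",
    "RNA",
    "IGR",
    "Targeted_Region",
})

SIFT_CATEGORIES = frozenset({
    "deleterious",
    "deleterious_low_confidence",
    "tolerated",
    "tolerated_low_confidence",
})

POLYPHEN_CATEGORIES = frozenset({
    "benign",
    "possibly_damaging",
    "probably_damaging",
    "unknown",
})

#: Canonical internal column order of MutationTable.df.
CANONICAL_COLUMNS = (
    "gene", "sample", "cohort", "classification",
    "protein_pos", "sift", "polyphen",
)

_MANDATORY = ("Hugo_Symbol", "Variant_Classification", "Tumor_Sample_Barcode")

_POSITION_RE = re.compile(r"\d+")
_ANNOTATION_PAREN_RE = re.compile(r"\s*\(.*\)\s*$")


@dataclass(frozen=True)
class MafDialect:
    """Column mapping and parsing rules for a MAF flavour.

    The defaults match the GDC "simple nucleotide variation" download.
    ``cohort_column`` is non-standard; when absent from the file every record
    is assigned ``default_cohort`` (a sample manifest can refine this later).
    """

    gene_column: str = "Hugo_Symbol"
    sample_column: str = "Tumor_Sample_Barcode"
    classification_column: str = "Variant_Classification"
    protein_position_column: str = "Protein_position"
    sift_column: str = "SIFT"
    polyphen_column: str = "PolyPhen"
    cohort_column: str = "Cohort"
    default_cohort: str = "NA"
    comment_char: str = "#"
    vocabulary: frozenset = DEFAULT_VOCABULARY
    strict: bool = True


@dataclass
class MutationTable:
    """Ordered collection of somatic mutation records with provenance.

    ``df`` holds one record per row with the canonical columns
    ``gene, sample, cohort, classification, protein_pos, sift, polyphen``.
    ``protein_pos`` is a nullable integer (1-based residue index);
    ``sift``/``polyphen`` are categorical strings or missing (``pd.NA``).
    """

    df: pd.DataFrame
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in CANONICAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"MutationTable missing columns: {missing}")
        self.df = self.df.loc[:, list(CANONICAL_COLUMNS)].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_records(self) -> int:
        return len(self.df)

    def with_provenance(self, note: str) -> "MutationTable":
        return MutationTable(self.df, [*self.provenance, note])

    def restrict_to_genes(self, genes) -> "MutationTable":
        sub = self.df[self.df["gene"].isin(set(genes))]
        return MutationTable(sub, [*self.provenance,
                                   f"restricted to {len(set(genes))} genes"])


@dataclass
class SampleRegistry:
    """Mapping of tumour sample barcodes to cohorts.

    Provides the per-cohort and overall sample counts used as incidence
    denominators.  Samples with zero mutations cannot appear in a MAF, so
    registries may be built from an external manifest whose total exceeds the
    barcodes present in the mutation table.
    """

    cohorts: pd.Series  # index: sample barcode, value: cohort label

    def __post_init__(self) -> None:
        if self.cohorts.index.duplicated().any():
            dups = self.cohorts.index[self.cohorts.index.duplicated()][:3]
            raise ValueError(f"duplicate sample barcodes in registry: {list(dups)}")
        self.cohorts = self.cohorts.astype(str)
        self.cohorts.index = self.cohorts.index.astype(str)

    @property
    def n_total(self) -> int:
        return int(len(self.cohorts))

    @property
    def cohort_sizes(self) -> pd.Series:
        return self.cohorts.value_counts().sort_index()

    @property
    def samples(self) -> pd.Index:
        return self.cohorts.index

    def cohort_of(self, barcode: str) -> str:
        return str(self.cohorts.loc[barcode])

    @classmethod
    def from_table(cls, table: MutationTable) -> "SampleRegistry":
        """Registry of the distinct barcodes present in a mutation table."""
        first = table.df.drop_duplicates("sample").set_index("sample")["cohort"]
        return cls(first.sort_index())

    @classmethod
    def from_manifest(cls, path) -> "SampleRegistry":
        """Read a two-column (sample, cohort) TSV manifest (header required)."""
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
        cols = {c.lower(): c for c in df.columns}
        s_col = cols.get("sample", cols.get("tumor_sample_barcode"))
        c_col = cols.get("cohort", cols.get("project"))
        if s_col is None or c_col is None:
            raise MafFormatError(
                "sample manifest needs 'sample' and 'cohort' columns, "
                f"found {list(df.columns)}")
        return cls(df.set_index(s_col)[c_col])

    def to_manifest(self, path) -> None:
        out = self.cohorts.rename("cohort").rename_axis("sample").reset_index()
        out.to_csv(path, sep="\t", index=False)


def parse_protein_position(raw) -> "int | None":
    """Extract the first residue index from a MAF-style protein position field.

    Handles plain indices (``"123"``), position/length pairs (``"123/456"``)
    and HGVS-like protein change strings (``"p.R328Q"`` -> 328).  Empty,
    ``"-"``, ``"."`` or unparseable values yield ``None`` — missingness is a
    value here, never an error.
    """
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    text = str(raw).strip()
    if text in ("", "-", ".", "NA", "nan", "<NA>"):
        return None
    m = _POSITION_RE.search(text)
    if m is None:
        return None
    pos = int(m.group(0))
    return pos if pos >= 1 else None


def _normalise_annotation(raw, allowed: frozenset) -> "str | None":
    """Map 'deleterious(0.01)'-style MAF annotation values to bare categories."""
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    text = _ANNOTATION_PAREN_RE.sub("", str(raw).strip()).strip().lower()
    return text if text in allowed else None


def read_maf(path, dialect: MafDialect = MafDialect()) -> MutationTable:
    """Read a MAF file into a :class:`MutationTable`.

    Comment lines (``dialect.comment_char`` prefix) are skipped.  Missing
    optional columns (protein position, SIFT, PolyPhen, cohort) yield missing
    fields rather than errors.  In strict mode a record with an empty sample
    barcode, an unknown classification, or an empty gene symbol raises
    :class:`MafFormatError` with its line number; in lenient mode such rows
    are dropped with a logged warning.
    """
    try:
        raw = pd.read_csv(path, sep="\t", comment=dialect.comment_char,
                          dtype=str, keep_default_na=False, na_values=[""])
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed TSV
        raise MafFormatError(f"cannot parse {path}: {exc}") from exc

    for col in _MANDATORY:
        if col not in raw.columns:
            raise MafFormatError(f"{path}: missing mandatory MAF column '{col}'")

    df = pd.DataFrame({
        "gene": raw[dialect.gene_column].astype("string").str.strip(),
        "sample": raw[dialect.sample_column].astype("string").str.strip(),
        "classification":
            raw[dialect.classification_column].astype("string").str.strip(),
    })
    if dialect.cohort_column in raw.columns:
        df["cohort"] = (raw[dialect.cohort_column].astype("string")
                        .fillna(dialect.default_cohort))
    else:
        df["cohort"] = dialect.default_cohort

    if dialect.protein_position_column in raw.columns:
        df["protein_pos"] = raw[dialect.protein_position_column].map(
            parse_protein_position)
    else:
        df["protein_pos"] = None
    df["protein_pos"] = df["protein_pos"].astype("Int64")

    for key, col, allowed in (
            ("sift", dialect.sift_column, SIFT_CATEGORIES),
            ("polyphen", dialect.polyphen_column, POLYPHEN_CATEGORIES)):
        if col in raw.columns:
            df[key] = raw[col].map(lambda v: _normalise_annotation(v, allowed))
        else:
            df[key] = None
        df[key] = df[key].astype("string")

    bad = (df["sample"].isna() | (df["sample"] == "")
           | df["gene"].isna() | (df["gene"] == "")
           | ~df["classification"].isin(dialect.vocabulary))
    if bad.any():
        lines = (np.flatnonzero(bad.to_numpy()) + 2).tolist()  # +header +1-based
        if dialect.strict:
            raise MafFormatError(
                f"{path}: {bad.sum()} unparseable/invalid rows "
                f"(first data-file lines: {lines[:5]})")
        logger.warning("%s: skipping %d invalid rows (lines %s...)",
                       path, int(bad.sum()), lines[:5])
        df = df[~bad]

    return MutationTable(df, provenance=[f"read_maf({path})"])


def write_maf(table: MutationTable, path) -> None:
    """Write a MutationTable back out as a GDC-dialect MAF.

    Field values round-trip exactly through :func:`read_maf` (missing protein
    positions become ``"-"``, missing annotations empty strings).
    """
    d = MafDialect()
    out = pd.DataFrame({
        d.gene_column: table.df["gene"],
        d.sample_column: table.df["sample"],
        d.cohort_column: table.df["cohort"],
        d.classification_column: table.df["classification"],
        d.protein_position_column:
            table.df["protein_pos"].map(lambda v: "-" if pd.isna(v) else str(v)),
        d.sift_column: table.df["sift"].fillna(""),
        d.polyphen_column: table.df["polyphen"].fillna(""),
    })
    with open(path, "w") as fh:
        fh.write("#version gdc-1.0\n")
        out.to_csv(fh, sep="\t", index=False)


def filter_qualifying(table: MutationTable,
                      classes=NONSYNONYMOUS_CLASSES,
                      vocabulary: frozenset = DEFAULT_VOCABULARY) -> MutationTable:
    """Keep only records whose classification is in ``classes``.

    ``classes`` must be a non-empty subset of the configured vocabulary;
    anything else is a configuration error, not a silent no-op.
    """
    classes = frozenset(classes)
    if not classes:
        raise ConfigurationError("qualifying class set is empty")
    unknown = classes - vocabulary
    if unknown:
        raise ConfigurationError(
            f"unknown Variant_Classification labels: {sorted(unknown)}")
    sub = table.df[table.df["classification"].isin(classes)]
    return MutationTable(
        sub, [*table.provenance,
              f"filter_qualifying({len(classes)} classes, kept {len(sub)})"])


def deduplicate(table: MutationTable) -> MutationTable:
    """Drop duplicated (gene, sample, classification, protein_pos) rows.

    Off by default in the pipeline; the GDC MAF may legitimately contain
    recurrent identical calls in multi-allelic contexts.
    """
    sub = table.df.drop_duplicates(
        ["gene", "sample", "classification", "protein_pos"])
    return MutationTable(sub, [*table.provenance,
                               f"deduplicate(kept {len(sub)})"])


def patient_of(barcode: str, n_chars: int = 12) -> str:
    """Patient identity = first ``n_chars`` characters of a TCGA-style barcode."""
    return str(barcode)[:n_chars]
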