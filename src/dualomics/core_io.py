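"""Shared domain types and text readers/writers.

All coordinates are 1-based inclusive (GFF convention) throughout the
package; conversion to 0-based half-open happens only in BED writers.
Tabular I/O is UTF-8, tab-delimited, with "." or an empty field for
missing values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA = "rna"
PROTEIN = "protein"
OMICS = (RNA, PROTEIN)

#: marker used for missing values in tab-separated output
MISSING = "."

_FLOAT_FMT = "%.6f"


def _is_hypothetical(description: str) -> bool:
    return "hypothetical" in description.lower()


@dataclass(frozen=True)
class GeneAnnotation:
    """One annotated gene feature.

    ``start``/``end`` are 1-based inclusive coordinates on ``contig_id``;
    ``cog_class`` is a single uppercase COG letter or ``None``.  When
    ``is_hypothetical`` is not given it is derived from the description
    (case-insensitive substring "hypothetical").
    """

    locus_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    description: str = ""
    cog_class: str | None = None
    is_hypothetical: bool | None = None

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"gene {self.locus_id}: start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"gene {self.locus_id}: end ({self.end}) < start ({self.start})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.locus_id}: strand must be '+' or '-', got {self.strand!r}")
        if self.cog_class is not None and (
            len(self.cog_class) != 1 or not self.cog_class.isalpha()
        ):
            raise ValueError(
                f"gene {self.locus_id}: cog_class must be a single letter, got {self.cog_class!r}"
            )
        if self.is_hypothetical is None:
            object.__setattr__(self, "is_hypothetical", _is_hypothetical(self.description))

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, start: int, end: int) -> bool:
        """True if the 1-based inclusive interval [start, end] intersects the gene."""
        return start <= self.end and end >= self.start


@dataclass(frozen=True)
class ExperimentDesign:
    """Conditions, reference condition and replicate labels of one experiment.

    Contrasts are indexed by the order of non-reference conditions and
    labelled R0/R1/... (RNA) or P0/P1/... (protein), each meaning
    "condition minus reference".
    """

    conditions: tuple[str, ...]
    reference: str
    replicates: tuple[str, ...] = ("A", "B")

    def __post_init__(self) -> None:
        object.__setattr__(self, "conditions", tuple(self.conditions))
        object.__setattr__(self, "replicates", tuple(self.replicates))
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("condition labels must be unique")
        if self.reference not in self.conditions:
            raise ValueError(f"reference {self.reference!r} not among conditions")
        if len(self.conditions) < 2:
            raise ValueError("need at least one non-reference condition")
        if not 1 <= len(self.replicates) <= 2:
            raise ValueError("1 or 2 replicate labels required")
        if len(set(self.replicates)) != len(self.replicates):
            raise ValueError("replicate labels must be unique")

    @property
    def non_reference(self) -> tuple[str, ...]:
        return tuple(c for c in self.conditions if c != self.reference)

    def contrast_label(self, omic: str, condition: str) -> str:
        if omic not in OMICS:
            raise ValueError(f"unknown omic {omic!r}")
        if condition not in self.non_reference:
            raise ValueError(f"{condition!r} is not a non-reference condition")
        prefix = "R" if omic == RNA else "P"
        return f"{prefix}{self.non_reference.index(condition)}"

    def columns(self) -> list[tuple[str, str]]:
        return [(c, r) for c in self.conditions for r in self.replicates]


@dataclass
class ExpressionMatrix:
    """log2 expression values, loci x (condition, replicate).

    ``data`` carries loci on the index and a two-level column index
    (condition, replicate); missing values are NaN.  ``filter_log`` maps
    locus -> list of human-readable reasons for removed values.
    """

    omic: str
    data: pd.DataFrame
    filter_log: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.omic not in OMICS:
            raise ValueError(f"omic must be one of {OMICS}, got {self.omic!r}")
        if self.data.columns.nlevels != 2:
            raise ValueError("data columns must be a (condition, replicate) MultiIndex")

    @property
    def loci(self) -> pd.Index:
        return self.data.index

    def log_filter(self, locus: str, reason: str) -> None:
        self.filter_log.setdefault(locus, []).append(reason)

    def values_for(self, condition: str, replicate: str) -> pd.Series:
        return self.data[(condition, replicate)]


@dataclass(frozen=True)
class PeptideEvidence:
    """One identified peptide with its reporter-channel intensities.

    ``log_e`` is the base-10 log of the identification expectation value
    (more negative is more confident).  ``reporter_intensities`` maps
    channel label -> non-negative intensity.
    """

    protein_id: str
    peptide: str
    log_e: float
    reporter_intensities: Mapping[str, float]

    def __post_init__(self) -> None:
        if not np.isfinite(self.log_e):
            raise ValueError(f"peptide {self.peptide!r}: log_e must be finite")
        for channel, value in self.reporter_intensities.items():
            if value < 0:
                raise ValueError(
                    f"peptide {self.peptide!r}: negative intensity in channel {channel!r}"
                )
        object.__setattr__(self, "reporter_intensities", dict(self.reporter_intensities))


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: uppercase sequence} mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str] | Iterable[tuple[str, str]], path: str | Path) -> None:
    items = sequences.items() if isinstance(sequences, Mapping) else sequences
    records = (SeqRecord(Seq(seq), id=name, description="") for name, seq in items)
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Annotations

_GFF_FEATURE_TYPES = ("gene",)
_TSV_REQUIRED = ("locus", "contig", "start", "end", "strand")


def _clean_cog(raw: str | None, locus: str) -> str | None:
    if raw is None or raw == "" or raw == MISSING:
        return None
    raw = raw.strip().upper()
    if len(raw) > 1:
        warnings.warn(
            f"gene {locus}: multi-letter COG assignment {raw!r}; keeping first letter",
            stacklevel=3,
        )
    return raw[0]


def _parse_gff_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition("=")
        attrs[key.strip()] = value.strip()
    return attrs


def _infer_annotation_format(path: Path) -> str:
    if path.suffix.lower() in (".gff", ".gff3"):
        return "gff3"
    return "tsv"


def read_annotations(
    path: str | Path,
    fmt: str | None = None,
    feature_types: Sequence[str] = _GFF_FEATURE_TYPES,
) -> list[GeneAnnotation]:
    """Read gene annotations from GFF3 or a tab-separated table.

    GFF3 rows whose type is not in ``feature_types`` are ignored.  The COG
    letter comes from the ``cog_class`` attribute (GFF3) or the ``COG``
    column (TSV); a ``hypothetical`` attribute/column overrides the
    description-based detection.  Raises ``ValueError`` naming the line on
    malformed input or duplicate locus ids.
    """
    path = Path(path)
    fmt = fmt or _infer_annotation_format(path)
    if fmt == "gff3":
        annotations = _read_gff3(path, feature_types)
    elif fmt == "tsv":
        annotations = _read_annotation_tsv(path)
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")
    seen: set[str] = set()
    for ann in annotations:
        if ann.locus_id in seen:
            raise ValueError(f"{path}: duplicate locus_id {ann.locus_id!r}")
        seen.add(ann.locus_id)
    return annotations


def _read_gff3(path: Path, feature_types: Sequence[str]) -> list[GeneAnnotation]:
    annotations: list[GeneAnnotation] = []
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if line.startswith("##FASTA"):
                break
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}: line {lineno}: expected 9 GFF3 columns, got {len(fields)}")
            contig, _source, ftype, start, end, _score, strand, _phase, attr_text = fields
            if ftype not in feature_types:
                continue
            attrs = _parse_gff_attributes(attr_text)
            locus = attrs.get("locus_tag") or attrs.get("ID")
            if not locus:
                raise ValueError(f"{path}: line {lineno}: feature has no locus_tag/ID")
            try:
                hypo = attrs.get("hypothetical")
                annotations.append(
                    GeneAnnotation(
                        locus_id=locus,
                        contig_id=contig,
                        start=int(start),
                        end=int(end),
                        strand=strand,
                        description=attrs.get("product", attrs.get("description", "")),
                        cog_class=_clean_cog(attrs.get("cog_class"), locus),
                        is_hypothetical=None if hypo is None else hypo.lower() in ("true", "1", "yes"),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return annotations


def _read_annotation_tsv(path: Path) -> list[GeneAnnotation]:
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _TSV_REQUIRED if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing annotation columns: {', '.join(missing)}")
    annotations: list[GeneAnnotation] = []
    for row_idx, row in table.iterrows():
        lineno = int(row_idx) + 2  # header is line 1
        locus = row["locus"]
        try:
            hypo_raw = row.get("hypothetical", "")
            annotations.append(
                GeneAnnotation(
                    locus_id=locus,
                    contig_id=row["contig"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    strand=row["strand"],
                    description=row.get("description", ""),
                    cog_class=_clean_cog(row.get("COG"), locus),
                    is_hypothetical=None if hypo_raw == "" else hypo_raw.lower() in ("true", "1", "yes"),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return annotations


def write_annotations(
    annotations: Iterable[GeneAnnotation], path: str | Path, fmt: str | None = None
) -> None:
    """Serialize annotations to GFF3 or TSV, coordinate-faithfully."""
    path = Path(path)
    fmt = fmt or _infer_annotation_format(path)
    if fmt == "gff3":
        with open(path, "w", encoding="utf-8") as handle:
            handle.write("##gff-version 3\n")
            for ann in annotations:
                attrs = [f"ID={ann.locus_id}", f"locus_tag={ann.locus_id}"]
                if ann.description:
                    attrs.append(f"product={ann.description}")
                if ann.cog_class:
                    attrs.append(f"cog_class={ann.cog_class}")
                attrs.append(f"hypothetical={'true' if ann.is_hypothetical else 'false'}")
                handle.write(
                    "\t".join(
                        [
                            ann.contig_id,
                            "dualomics",
                            "gene",
                            str(ann.start),
                            str(ann.end),
                            MISSING,
                            ann.strand,
                            MISSING,
                            ";".join(attrs),
                        ]
                    )
                    + "\n"
                )
    elif fmt == "tsv":
        rows = [
            {
                "locus": ann.locus_id,
                "contig": ann.contig_id,
                "start": ann.start,
                "end": ann.end,
                "strand": ann.strand,
                "description": ann.description,
                "COG": ann.cog_class or "",
                "hypothetical": "true" if ann.is_hypothetical else "false",
            }
            for ann in annotations
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")


def validate_against_genome(
    annotations: Iterable[GeneAnnotation], genome: Mapping[str, str]
) -> None:
    """Check that every annotation fits inside its contig."""
    for ann in annotations:
        if ann.contig_id not in genome:
            raise ValueError(f"gene {ann.locus_id}: unknown contig {ann.contig_id!r}")
        if ann.end > len(genome[ann.contig_id]):
            raise ValueError(
                f"gene {ann.locus_id}: end {ann.end} beyond contig "
                f"{ann.contig_id} length {len(genome[ann.contig_id])}"
            )


def extract_gene_sequences(
    genome: Mapping[str, str], annotations: Iterable[GeneAnnotation]
) -> dict[str, str]:
    """Gene-strand-oriented sequences for each annotated gene."""
    out: dict[str, str] = {}
    for ann in annotations:
        seq = genome[ann.contig_id][ann.start - 1 : ann.end]
        if ann.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        out[ann.locus_id] = seq
    return out


# ---------------------------------------------------------------------------
# Expression tables


def _expected_columns(design: ExperimentDesign) -> list[str]:
    return [f"{c}:{r}" for c, r in design.columns()]


def read_expression_table(
    path: str | Path, design: ExperimentDesign, omic: str
) -> ExpressionMatrix:
    """Read a loci x (condition:replicate) log2 expression TSV.

    The header must contain a ``locus`` column plus one ``condition:replicate``
    column per design cell; missing cells are "." or empty.
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t", index_col="locus", na_values=[MISSING, ""])
    expected = _expected_columns(design)
    missing = [c for c in expected if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing expression columns: {', '.join(missing)}")
    data = table[expected].astype(float)
    data.columns = pd.MultiIndex.from_tuples(
        design.columns(), names=["condition", "replicate"]
    )
    return ExpressionMatrix(omic=omic, data=data)


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    flat = matrix.data.copy()
    flat.columns = [f"{c}:{r}" for c, r in flat.columns]
    flat.index.name = "locus"
    flat.to_csv(path, sep="\t", float_format=_FLOAT_FMT, na_rep=MISSING)


# ---------------------------------------------------------------------------
# Peptide evidence tables

_PEPTIDE_FIXED = ("protein", "peptide", "log_e")


def read_peptide_table(path: str | Path) -> list[PeptideEvidence]:
    """Read peptide evidence: protein, peptide, log_e, then one column per channel."""
    path = Path(path)
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in _PEPTIDE_FIXED if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing peptide columns: {', '.join(missing)}")
    channels = [c for c in table.columns if c not in _PEPTIDE_FIXED]
    if not channels:
        raise ValueError(f"{path}: no reporter channel columns found")
    return [
        PeptideEvidence(
            protein_id=row["protein"],
            peptide=row["peptide"],
            log_e=float(row["log_e"]),
            reporter_intensities={ch: float(row[ch]) for ch in channels},
        )
        for _, row in table.iterrows()
    ]


def write_peptide_table(evidence: Iterable[PeptideEvidence], path: str | Path) -> None:
    evidence = list(evidence)
    channels: list[str] = []
    for ev in evidence:
        for ch in ev.reporter_intensities:
            if ch not in channels:
                channels.append(ch)
    rows = [
        {
            "protein": ev.protein_id,
            "peptide": ev.peptide,
            "log_e": ev.log_e,
            **{ch: ev.reporter_intensities.get(ch, 0.0) for ch in channels},
        }
        for ev in evidence
    ]
    pd.DataFrame(rows, columns=[*_PEPTIDE_FIXED, *channels]).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT
    )


# ---------------------------------------------------------------------------
# Contrast tables

CONTRAST_COLUMNS = [
    "locus",
    "contrast",
    "z0_raw",
    "z1_raw",
    "z2_raw",
    "z3_raw",
    "z0",
    "z1",
    "z2",
    "z3",
    "znet",
    "regulation",
    "snr",
    "fdr",
]

_CONTRAST_FLOAT = [c for c in CONTRAST_COLUMNS if c not in ("locus", "contrast", "regulation")]


def _format_float(value: float) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return MISSING
    if np.isinf(value):
        return "inf" if value > 0 else "-inf"
    return _FLOAT_FMT % value


def write_contrast_table(results: Iterable, path: str | Path) -> None:
    """Write per-gene contrast results (``ContrastResult``-shaped records) as TSV.

    Numeric fields are written to 6 decimals and round-trip through
    :func:`read_contrast_table` without loss at that precision.
    """
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("\t".join(CONTRAST_COLUMNS) + "\n")
        for res in results:
            row = [getattr(res, "locus_id"), getattr(res, "contrast")]
            for col in CONTRAST_COLUMNS[2:]:
                if col == "regulation":
                    row.append(getattr(res, col))
                else:
                    row.append(_format_float(getattr(res, col)))
            handle.write("\t".join(row) + "\n")


def read_contrast_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", na_values=[MISSING])
    missing = [c for c in CONTRAST_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing contrast columns: {', '.join(missing)}")
    for col in _CONTRAST_FLOAT:
        table[col] = pd.to_numeric(table[col])
    return table
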