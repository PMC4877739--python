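"""Expression quantitation: exact read-length alignment counting, log2-sum
matrices for RNA and protein, and validation correlations."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from dualomics.core_io import (
    PROTEIN,
    RNA,
    ExperimentDesign,
    ExpressionMatrix,
    PeptideEvidence,
)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class AlignmentCounts:
    """Integer exact-alignment counts, loci x sample.

    ``counts`` carries loci on the index and (condition, replicate) tuples
    on the columns.  ``skipped_reads`` records, per sample, reads dropped
    for non-ACGT characters.
    """

    counts: pd.DataFrame
    skipped_reads: dict[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("alignment counts must be non-negative")


def _read_sequences(reads: Iterable) -> list[str]:
    out = []
    for read in reads:
        if isinstance(read, str):
            out.append(read.upper())
        elif isinstance(read, (tuple, list)) and len(read) == 2:
            out.append(str(read[1]).upper())
        else:  # SeqRecord-like
            out.append(str(read.seq).upper())
    return out


def count_exact_readmers(
    reads: Iterable,
    gene_sequences: Mapping[str, str],
    both_strands: bool = True,
    mode: str = "reads",
) -> tuple[dict[str, int], int]:
    """Count exact full-length read alignments against gene sequences.

    A read counts toward a gene when it occurs verbatim in the gene
    sequence (or, with ``both_strands``, in its reverse complement).  In
    ``"reads"`` mode a read increments each matching gene once regardless
    of how many times it occurs; ``"occurrences"`` mode adds every
    occurrence.  Returns (per-gene counts, number of skipped reads).
    Raises on mixed read lengths; reads with non-ACGT characters are
    skipped and counted.
    """
    if mode not in ("reads", "occurrences"):
        raise ValueError(f"mode must be 'reads' or 'occurrences', got {mode!r}")
    sequences = _read_sequences(reads)
    counts = {gene: 0 for gene in gene_sequences}
    if not sequences:
        return counts, 0
    lengths = {len(s) for s in sequences}
    if len(lengths) > 1:
        raise ValueError(f"mixed read lengths: {sorted(lengths)}")
    (read_len,) = lengths

    # index every read-length window of every gene (both strands if asked)
    index: dict[str, dict[str, int]] = {}
    for gene, seq in gene_sequences.items():
        seq = seq.upper()
        targets = [seq]
        if both_strands:
            targets.append(reverse_complement(seq))
        for target in targets:
            for i in range(len(target) - read_len + 1):
                kmer = target[i : i + read_len]
                per_gene = index.setdefault(kmer, {})
                per_gene[gene] = per_gene.get(gene, 0) + 1

    skipped = 0
    valid = set("ACGT")
    for seq in sequences:
        if not valid.issuperset(seq):
            skipped += 1
            continue
        hit = index.get(seq)
        if hit is None:
            continue
        for gene, occurrences in hit.items():
            counts[gene] += occurrences if mode == "occurrences" else 1
    return counts, skipped


def count_samples(
    reads_by_sample: Mapping[tuple[str, str], Iterable],
    gene_sequences: Mapping[str, str],
    both_strands: bool = True,
    mode: str = "reads",
) -> AlignmentCounts:
    """Count reads for several (condition, replicate) samples."""
    columns = list(reads_by_sample)
    data = {}
    skipped = {}
    for sample, reads in reads_by_sample.items():
        counts, n_skipped = count_exact_readmers(
            reads, gene_sequences, both_strands=both_strands, mode=mode
        )
        data[sample] = counts
        skipped[sample] = n_skipped
    frame = pd.DataFrame(data, columns=pd.MultiIndex.from_tuples(columns)).fillna(0).astype(int)
    frame.index.name = "locus"
    return AlignmentCounts(counts=frame, skipped_reads=skipped)


def build_rna_matrix(
    counts: AlignmentCounts, design: ExperimentDesign, min_counts: int = 2
) -> ExpressionMatrix:
    """RNA expression = log2 of the per-gene alignment count per sample.

    Cells with fewer than ``min_counts`` alignments are left missing and
    recorded in the filter log (never written as log2 of zero).
    """
    expected = design.columns()
    missing = [c for c in expected if c not in counts.counts.columns]
    if missing:
        raise ValueError(f"count table lacks design samples: {missing}")
    raw = counts.counts[expected].astype(float)
    values = raw.where(raw >= min_counts)
    matrix = ExpressionMatrix(
        omic=RNA,
        data=np.log2(values),
    )
    matrix.data.columns = pd.MultiIndex.from_tuples(
        expected, names=["condition", "replicate"]
    )
    below = raw < min_counts
    for locus in raw.index[below.any(axis=1)]:
        for cond, rep in raw.columns[below.loc[locus]]:
            matrix.log_filter(locus, f"min_counts[{cond}:{rep}]")
    return matrix


def build_protein_matrix(
    evidence: Iterable[PeptideEvidence],
    design: ExperimentDesign,
    min_peptides: int = 2,
    peptide_log_e_max: float = -1.5,
    protein_log_e_max: float = -10.0,
    channel_map: Mapping[str, str] | None = None,
    replicate_label: str = "1",
) -> ExpressionMatrix:
    """Protein expression = log2 of summed reporter intensities per channel.

    A protein is kept only with at least ``min_peptides`` peptides at
    ``log_e < peptide_log_e_max`` (strict) and a summed peptide log(e)
    below ``protein_log_e_max``; non-qualifying peptides contribute no
    intensity.  ``channel_map`` maps reporter channel labels onto design
    conditions (identity by default).  The resulting matrix has a single
    replicate level (4-plex channels are one replicate set).
    """
    evidence = list(evidence)
    channel_map = dict(channel_map) if channel_map else None
    filter_log: dict[str, list[str]] = {}

    by_protein: dict[str, list[PeptideEvidence]] = {}
    for ev in evidence:
        by_protein.setdefault(ev.protein_id, []).append(ev)

    conditions = list(design.conditions)
    rows: dict[str, dict[str, float]] = {}
    for protein, peptides in sorted(by_protein.items()):
        qualifying = [p for p in peptides if p.log_e < peptide_log_e_max]
        if len(qualifying) < min_peptides:
            filter_log.setdefault(protein, []).append(
                f"min_peptides[{len(qualifying)}<{min_peptides}]"
            )
            continue
        protein_log_e = sum(p.log_e for p in qualifying)
        if not protein_log_e < protein_log_e_max:
            filter_log.setdefault(protein, []).append(
                f"protein_log_e[{protein_log_e:.2f}>={protein_log_e_max}]"
            )
            continue
        sums = dict.fromkeys(conditions, 0.0)
        for pep in qualifying:
            for channel, intensity in pep.reporter_intensities.items():
                condition = channel_map.get(channel, channel) if channel_map else channel
                if condition not in sums:
                    raise ValueError(
                        f"protein {protein}: reporter channel {channel!r} maps to no design condition"
                    )
                sums[condition] += intensity
        rows[protein] = {
            cond: (math.log2(total) if total > 0 else float("nan"))
            for cond, total in sums.items()
        }

    frame = pd.DataFrame.from_dict(rows, orient="index")
    if frame.empty:
        frame = pd.DataFrame(index=pd.Index([], name="locus"), columns=conditions, dtype=float)
    frame = frame[conditions]
    frame.columns = pd.MultiIndex.from_tuples(
        [(c, replicate_label) for c in conditions], names=["condition", "replicate"]
    )
    frame.index.name = "locus"
    return ExpressionMatrix(omic=PROTEIN, data=frame, filter_log=filter_log)


def correlation_r2(x, y) -> float:
    """R^2 of the ordinary least-squares fit of y on x.

    Pairs with a missing value on either side are dropped; at least 3
    complete pairs and nonzero variance in x are required.
    """
    if isinstance(x, pd.Series) and isinstance(y, pd.Series):
        x, y = x.align(y, join="inner")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    fit = stats.linregress(x, y)
    return float(fit.rvalue**2)
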