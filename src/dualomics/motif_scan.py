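"""Degenerate IUPAC consensus scanning and gene-association of hits.

Positions are 1-based inclusive on the forward strand; a minus-strand hit
means the window's reverse complement matches the consensus.  A window
matching on both strands with the same mismatch count is reported once on
"+" with ``palindromic=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np

from dualomics.core_io import GeneAnnotation

IUPAC_CODES: dict[str, str] = {
    "A": "A",
    "C": "C",
    "G": "G",
    "T": "T",
    "R": "AG",
    "Y": "CT",
    "S": "CG",
    "W": "AT",
    "K": "GT",
    "M": "AC",
    "B": "CGT",
    "D": "AGT",
    "H": "ACT",
    "V": "ACG",
    "N": "ACGT",
}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def complement_consensus(consensus: str) -> str:
    """Reverse complement of a degenerate IUPAC pattern."""
    return consensus.translate(_IUPAC_COMPLEMENT)[::-1]


def matches_code(base: str, code: str) -> bool:
    """True if a concrete base satisfies one IUPAC code (N matches anything)."""
    if code == "N":
        return True
    return base in IUPAC_CODES[code]


@dataclass(frozen=True)
class MotifHit:
    """One consensus match on a genome."""

    contig_id: str
    start: int  # 1-based, leftmost base on the forward strand
    strand: str
    matched_sequence: str  # forward-strand slice
    mismatches: int
    palindromic: bool = False
    association: str = "unassociated"
    associated_locus: str | None = None

    @property
    def end(self) -> int:
        return self.start + len(self.matched_sequence) - 1


def _validate_consensus(consensus: str) -> str:
    consensus = consensus.upper()
    for ch in consensus:
        if ch not in IUPAC_CODES:
            raise ValueError(f"invalid IUPAC character {ch!r} in consensus")
    if len(consensus) < 4:
        raise ValueError("consensus must be at least 4 bases long")
    return consensus


def _mismatch_profile(seq_codes: np.ndarray, consensus: str) -> np.ndarray:
    """Mismatch count of every window of ``len(consensus)`` against it."""
    n = len(seq_codes)
    length = len(consensus)
    if n < length:
        return np.zeros(0, dtype=np.int32)
    n_windows = n - length + 1
    mismatches = np.zeros(n_windows, dtype=np.int32)
    for j, code in enumerate(consensus):
        if code == "N":
            continue
        allowed = np.frombuffer(IUPAC_CODES[code].encode(), dtype=np.uint8)
        ok = np.isin(seq_codes[j : j + n_windows], allowed)
        mismatches += ~ok
    return mismatches


def scan_consensus(
    genome: Mapping[str, str] | str,
    consensus: str,
    max_mismatches: int = 0,
    strands: str = "both",
) -> list[MotifHit]:
    """Find all windows matching a degenerate consensus.

    ``genome`` is a {contig: sequence} mapping (a bare string is treated
    as a single contig "seq").  With ``strands="both"`` the reverse
    complement of the consensus is also matched against the forward
    sequence, reported as minus-strand hits at the same leftmost forward
    coordinate.  Consensus "N" positions match any character and never
    count as a mismatch.
    """
    consensus = _validate_consensus(consensus)
    if strands not in ("forward", "both"):
        raise ValueError(f"strands must be 'forward' or 'both', got {strands!r}")
    if isinstance(genome, str):
        genome = {"seq": genome}
    length = len(consensus)
    rc_consensus = complement_consensus(consensus)
    hits: list[MotifHit] = []
    for contig, seq in genome.items():
        seq = seq.upper()
        codes = np.frombuffer(seq.encode(), dtype=np.uint8)
        fwd = _mismatch_profile(codes, consensus)
        fwd_positions = {
            int(i): int(fwd[i]) for i in np.nonzero(fwd <= max_mismatches)[0]
        }
        rev_positions: dict[int, int] = {}
        if strands == "both":
            rev = _mismatch_profile(codes, rc_consensus)
            rev_positions = {
                int(i): int(rev[i]) for i in np.nonzero(rev <= max_mismatches)[0]
            }
        for i in sorted(set(fwd_positions) | set(rev_positions)):
            window = seq[i : i + length]
            in_fwd = i in fwd_positions
            in_rev = i in rev_positions
            if in_fwd and in_rev and fwd_positions[i] == rev_positions[i]:
                hits.append(
                    MotifHit(contig, i + 1, "+", window, fwd_positions[i], palindromic=True)
                )
                continue
            if in_fwd:
                hits.append(MotifHit(contig, i + 1, "+", window, fwd_positions[i]))
            if in_rev:
                hits.append(MotifHit(contig, i + 1, "-", window, rev_positions[i]))
    return hits


def associate_hits(
    hits: Iterable[MotifHit],
    annotations: Iterable[GeneAnnotation],
    upstream_window: int = 200,
    downstream: bool = False,
) -> list[MotifHit]:
    """Classify hits as overlapping, adjacent or unassociated.

    A hit overlaps a gene when any of its bases lies within the gene body.
    Otherwise it is adjacent when it lies within ``upstream_window`` bp on
    the gene's 5' side (strand-aware; ``downstream=True`` also accepts the
    3' side).  The nearest qualifying gene wins.
    """
    by_contig: dict[str, list[GeneAnnotation]] = {}
    for ann in annotations:
        by_contig.setdefault(ann.contig_id, []).append(ann)

    out: list[MotifHit] = []
    for hit in hits:
        genes = by_contig.get(hit.contig_id, [])
        best: tuple[int, int, str] | None = None  # (rank, distance, locus)
        for gene in genes:
            if gene.overlaps(hit.start, hit.end):
                candidate = (0, 0, gene.locus_id)
            else:
                gaps = []
                if gene.strand == "+":
                    upstream_gap = gene.start - hit.end
                    downstream_gap = hit.start - gene.end
                else:
                    upstream_gap = hit.start - gene.end
                    downstream_gap = gene.start - hit.end
                if 1 <= upstream_gap <= upstream_window:
                    gaps.append(upstream_gap)
                if downstream and 1 <= downstream_gap <= upstream_window:
                    gaps.append(downstream_gap)
                if not gaps:
                    continue
                candidate = (1, min(gaps), gene.locus_id)
            if best is None or candidate < best:
                best = candidate
        if best is None:
            out.append(replace(hit, association="unassociated", associated_locus=None))
        elif best[0] == 0:
            out.append(replace(hit, association="overlapping", associated_locus=best[2]))
        else:
            out.append(replace(hit, association="adjacent", associated_locus=best[2]))
    return out


HIT_COLUMNS = [
    "contig",
    "start",
    "end",
    "strand",
    "matched_sequence",
    "mismatches",
    "palindromic",
    "association",
    "locus",
]


def write_hits(hits: Iterable[MotifHit], path) -> None:
    """Write hits as a TSV (1-based inclusive coordinates)."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("\t".join(HIT_COLUMNS) + "\n")
        for hit in hits:
            handle.write(
                "\t".join(
                    [
                        hit.contig_id,
                        str(hit.start),
                        str(hit.end),
                        hit.strand,
                        hit.matched_sequence,
                        str(hit.mismatches),
                        "true" if hit.palindromic else "false",
                        hit.association,
                        hit.associated_locus or ".",
                    ]
                )
                + "\n"
            )


def write_hits_bed(hits: Iterable[MotifHit], path) -> None:
    """Write hits as BED (0-based half-open conversion at this boundary)."""
    with open(path, "w", encoding="utf-8") as handle:
        for hit in hits:
            name = hit.associated_locus or "."
            handle.write(
                f"{hit.contig_id}\t{hit.start - 1}\t{hit.end}\t{name}\t{hit.mismatches}\t{hit.strand}\n"
            )
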