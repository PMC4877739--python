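"""Synthetic data generators with ground truth.

Everything is driven by a ``numpy.random.default_rng`` seed and is
byte-reproducible: genomes with annotated non-overlapping genes and
optionally planted consensus motif sites, exact-substring read sets,
dual-omic expression experiments (replicated RNA matrices plus 4-plex
peptide evidence sharing the same underlying signal), and
exponential-then-plateau fermentation time courses that satisfy their
input stoichiometry exactly before noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from dualomics.core_io import (
    RNA,
    ExperimentDesign,
    ExpressionMatrix,
    GeneAnnotation,
    PeptideEvidence,
)
from dualomics.fermentation import FermentationSeries
from dualomics.motif_scan import IUPAC_CODES
from dualomics.quantitation import reverse_complement

_BASES = np.array(list("ACGT"))
_AMINO_ACIDS = list("ACDEFGHIKLMNPQRSTVWY")

_DESCRIPTIONS = (
    "ABC transporter permease",
    "glycoside hydrolase family protein",
    "transcriptional regulator",
    "sugar kinase",
    "alcohol dehydrogenase",
    "two-component sensor histidine kinase",
    "ferredoxin oxidoreductase",
)

DEFAULT_COG_ALPHABET = "CEFGHIJKLMNOPQRSTUV"


@dataclass
class MotifPlan:
    """Request/record of exact consensus sites planted in a genome."""

    consensus: str
    n_planted: int
    planted_positions: list[tuple[str, int, str]] = field(default_factory=list)


@dataclass
class SyntheticTruth:
    """Per-gene ground truth emitted by :func:`simulate_omics`."""

    baseline: pd.Series
    noise_sd: float
    effects: pd.DataFrame  # loci x non-reference conditions, signed log2
    is_differential: pd.DataFrame  # same shape, boolean

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        silent = ~self.is_differential.to_numpy()
        if not np.allclose(self.effects.to_numpy()[silent], 0.0):
            raise ValueError("non-differential genes must have zero effect")

    @property
    def differential_loci(self) -> pd.Index:
        return self.is_differential.index[self.is_differential.any(axis=1)]

    def to_tsv(self, path: str | Path) -> None:
        out = pd.DataFrame({"baseline": self.baseline, "noise_sd": self.noise_sd})
        for cond in self.effects.columns:
            out[f"effect:{cond}"] = self.effects[cond]
            out[f"differential:{cond}"] = self.is_differential[cond]
        out.index.name = "locus"
        out.to_csv(path, sep="\t", float_format="%.6f")


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _realize_consensus(rng: np.random.Generator, consensus: str) -> str:
    return "".join(rng.choice(list(IUPAC_CODES[code])) for code in consensus.upper())


def generate_annotated_genome(
    n_genes: int,
    gene_length_range: tuple[int, int] = (300, 900),
    intergenic_length_range: tuple[int, int] = (50, 200),
    cog_alphabet: str = DEFAULT_COG_ALPHABET,
    motif_plan: MotifPlan | None = None,
    seed: int = 0,
    contig_id: str = "ctg1",
    hypothetical_frac: float = 0.15,
) -> tuple[dict[str, str], list[GeneAnnotation], MotifPlan | None]:
    """One random contig with non-overlapping annotated genes.

    Genes get random strands, COG letters drawn uniformly from
    ``cog_alphabet`` and a ``hypothetical_frac`` share of "hypothetical
    protein" descriptions.  If ``motif_plan`` requests sites, exact
    realizations of the consensus are written over the sequence at random
    non-overlapping positions (random strand) and recorded in the returned
    plan.  Identical seeds give byte-identical output.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    for lo, hi in (gene_length_range, intergenic_length_range):
        if lo < 1 or hi < lo:
            raise ValueError("length ranges must be positive with lo <= hi")
    rng = np.random.default_rng(seed)
    parts: list[str] = []
    annotations: list[GeneAnnotation] = []
    cursor = 0

    def emit_intergenic() -> None:
        nonlocal cursor
        length = int(rng.integers(intergenic_length_range[0], intergenic_length_range[1] + 1))
        parts.append(_random_dna(rng, length))
        cursor += length

    emit_intergenic()
    width = max(4, len(str(n_genes)))
    for i in range(n_genes):
        length = int(rng.integers(gene_length_range[0], gene_length_range[1] + 1))
        start = cursor + 1
        parts.append(_random_dna(rng, length))
        cursor += length
        strand = "+" if rng.random() < 0.5 else "-"
        hypothetical = bool(rng.random() < hypothetical_frac)
        description = (
            "hypothetical protein"
            if hypothetical
            else str(rng.choice(_DESCRIPTIONS))
        )
        annotations.append(
            GeneAnnotation(
                locus_id=f"g{i + 1:0{width}d}",
                contig_id=contig_id,
                start=start,
                end=cursor,
                strand=strand,
                description=description,
                cog_class=str(rng.choice(list(cog_alphabet))),
            )
        )
        emit_intergenic()

    sequence = list("".join(parts))
    plan_out: MotifPlan | None = None
    if motif_plan is not None and motif_plan.n_planted > 0:
        length = len(motif_plan.consensus)
        if length > len(sequence):
            raise ValueError("requested motifs cannot fit in the genome")
        occupied: list[tuple[int, int]] = []
        positions: list[tuple[str, int, str]] = []
        attempts = 0
        while len(positions) < motif_plan.n_planted:
            attempts += 1
            if attempts > 1000 * motif_plan.n_planted:
                raise ValueError("requested motifs cannot fit without overlapping")
            start0 = int(rng.integers(0, len(sequence) - length + 1))
            if any(start0 < e and start0 + length > s for s, e in occupied):
                continue
            site = _realize_consensus(rng, motif_plan.consensus)
            strand = "+" if rng.random() < 0.5 else "-"
            placed = site if strand == "+" else reverse_complement(site)
            sequence[start0 : start0 + length] = placed
            occupied.append((start0, start0 + length))
            positions.append((contig_id, start0 + 1, strand))
        plan_out = MotifPlan(
            consensus=motif_plan.consensus,
            n_planted=motif_plan.n_planted,
            planted_positions=positions,
        )
    genome = {contig_id: "".join(sequence)}
    return genome, annotations, plan_out


def simulate_reads(
    genome: Mapping[str, str],
    annotations: Sequence[GeneAnnotation],
    abundances: Mapping[str, float],
    read_length: int = 100,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Exact-substring reads from gene-strand-oriented gene sequences.

    Per-gene read counts are Poisson with the given means; start positions
    are uniform.  Every emitted read occurs verbatim in its source gene.
    """
    rng = np.random.default_rng(seed)
    by_locus = {a.locus_id: a for a in annotations}
    reads: list[tuple[str, str]] = []
    for locus in abundances:
        if locus not in by_locus:
            raise ValueError(f"abundance given for unknown gene {locus!r}")
    for ann in annotations:
        mean = float(abundances.get(ann.locus_id, 0.0))
        if mean < 0:
            raise ValueError(f"gene {ann.locus_id}: negative abundance")
        if mean == 0:
            continue
        if ann.length < read_length:
            raise ValueError(
                f"gene {ann.locus_id} is shorter ({ann.length} bp) than the read length"
            )
        seq = genome[ann.contig_id][ann.start - 1 : ann.end]
        if ann.strand == "-":
            seq = reverse_complement(seq)
        n_reads = int(rng.poisson(mean))
        if n_reads == 0:
            continue
        starts = rng.integers(0, ann.length - read_length + 1, size=n_reads)
        for k, s in enumerate(starts):
            reads.append((f"{ann.locus_id}_r{k}", seq[s : s + read_length]))
    return reads


def simulate_omics(
    design: ExperimentDesign,
    n_genes: int,
    frac_de: float = 0.1,
    effect_magnitude: float = 2.0,
    noise_sd: float = 0.25,
    protein_detect_frac: float = 0.5,
    peptides_per_protein: tuple[int, int] = (2, 6),
    seed: int = 0,
    baseline_mean: float = 10.0,
    baseline_sd: float = 2.0,
    protein_noise_sd: float | None = None,
) -> tuple[ExpressionMatrix, list[PeptideEvidence], SyntheticTruth]:
    """A replicated RNA experiment plus matching 4-plex peptide evidence.

    Gene g under condition c, replicate r gets log2 value
    ``baseline_g + effect_{g,c} + Normal(0, noise_sd)``.  A
    ``protein_detect_frac`` subset of genes also yields peptide evidence
    whose per-channel summed reporter intensities equal ``2**signal`` for
    the same deterministic signal plus independent protein noise
    (``protein_noise_sd``, defaulting to ``noise_sd``), so the RNA-protein
    correlation is tunable through the two noise levels.
    """
    if not 0 <= frac_de <= 1:
        raise ValueError("frac_de must be within [0, 1]")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if not design.non_reference:
        raise ValueError("design has no non-reference condition")
    rng = np.random.default_rng(seed)
    protein_noise_sd = noise_sd if protein_noise_sd is None else protein_noise_sd

    width = max(4, len(str(n_genes)))
    loci = pd.Index([f"g{i + 1:0{width}d}" for i in range(n_genes)], name="locus")
    baseline = pd.Series(rng.normal(baseline_mean, baseline_sd, n_genes), index=loci)

    n_de = int(round(frac_de * n_genes))
    de_loci = rng.choice(n_genes, size=n_de, replace=False)
    conditions = design.non_reference
    is_diff = pd.DataFrame(False, index=loci, columns=list(conditions))
    effects = pd.DataFrame(0.0, index=loci, columns=list(conditions))
    for cond in conditions:
        signs = rng.choice([-1.0, 1.0], size=n_de)
        effects.iloc[de_loci, effects.columns.get_loc(cond)] = signs * float(effect_magnitude)
        is_diff.iloc[de_loci, is_diff.columns.get_loc(cond)] = True

    signal = pd.DataFrame(
        {cond: baseline + (effects[cond] if cond in effects else 0.0) for cond in design.conditions}
    )
    signal[design.reference] = baseline

    columns = pd.MultiIndex.from_tuples(design.columns(), names=["condition", "replicate"])
    rna = pd.DataFrame(index=loci, columns=columns, dtype=float)
    for cond, rep in design.columns():
        rna[(cond, rep)] = signal[cond] + rng.normal(0.0, noise_sd, n_genes)
    rna_matrix = ExpressionMatrix(omic=RNA, data=rna)

    n_detect = int(round(protein_detect_frac * n_genes))
    detected = np.sort(rng.choice(n_genes, size=n_detect, replace=False))
    kmin, kmax = peptides_per_protein
    evidence: list[PeptideEvidence] = []
    for gi in detected:
        locus = loci[gi]
        channel_values = {
            cond: float(signal.loc[locus, cond] + rng.normal(0.0, protein_noise_sd))
            for cond in design.conditions
        }
        n_peptides = int(rng.integers(kmin, kmax + 1))
        weights = rng.dirichlet(np.ones(n_peptides))
        for j in range(n_peptides):
            peptide = "".join(rng.choice(_AMINO_ACIDS, size=int(rng.integers(8, 21))))
            log_e = float(-rng.uniform(6.0, 12.0))
            intensities = {
                cond: weights[j] * float(2.0 ** channel_values[cond])
                for cond in design.conditions
            }
            evidence.append(
                PeptideEvidence(
                    protein_id=locus,
                    peptide=peptide,
                    log_e=log_e,
                    reporter_intensities=intensities,
                )
            )

    truth = SyntheticTruth(
        baseline=baseline,
        noise_sd=noise_sd,
        effects=effects,
        is_differential=is_diff,
    )
    return rna_matrix, evidence, truth


def simulate_fermentation(
    stoichiometry: Mapping[str, float],
    mu: float,
    timepoints: Sequence[float],
    seed: int = 0,
    substrate: str = "glucose",
    substrate_mm: float = 10.0,
    od0: float = 0.05,
    od_per_mm: float = 0.04,
    noise_sd: float = 0.0,
) -> FermentationSeries:
    """Exponential-then-plateau growth with exact stoichiometric closure.

    Substrate consumption is proportional to biomass gain (``od_per_mm``
    OD units per mM consumed) and each product accumulates as
    ``yield x consumed``; growth plateaus when the substrate runs out.
    Optional multiplicative log-normal measurement noise is applied after
    the closed stoichiometry is laid down.
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    times = np.asarray(list(timepoints), dtype=float)
    if (times < 0).any():
        raise ValueError("timepoints must be non-negative")
    if (np.diff(times) <= 0).any():
        raise ValueError("timepoints must be strictly increasing")
    if any(y < 0 for y in stoichiometry.values()):
        raise ValueError("yields must be non-negative")
    rng = np.random.default_rng(seed)

    od_max = od0 + od_per_mm * substrate_mm
    od = np.minimum(od0 * np.exp(mu * times), od_max)
    consumed = (od - od0) / od_per_mm
    data = {"time": times, "od600": od, substrate: substrate_mm - consumed}
    # sorted product order keeps the output canonical across config dialects
    for product in sorted(stoichiometry):
        data[product] = stoichiometry[product] * consumed
    frame = pd.DataFrame(data)
    if noise_sd > 0:
        for col in frame.columns:
            if col == "time":
                continue
            frame[col] *= np.exp(rng.normal(0.0, noise_sd, len(frame)))
    return FermentationSeries(frame, substrate=substrate, biomass_col="od600")
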