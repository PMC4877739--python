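"""Per-gene difference scores, population normalization, Znet merging and
COG tabulation.

For a contrast of condition X against reference Y with replicates A and B,
four raw log2 differences are computed per gene:

* intra-replicate: ``z0 = B_X - A_X`` and ``z1 = B_Y - A_Y``
* cross-state:     ``z2 = A_X - A_Y`` and ``z3 = B_X - B_Y``

Each difference population is normalized to mean 0 / SD 1 (population SD),
and the two normalized cross-state scores are merged into a single
normalized contrast score per gene (Znet).  A positive Znet means higher
expression under the contrast condition; a negative one means higher
expression under the reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd

from dualomics.core_io import ExperimentDesign, ExpressionMatrix, GeneAnnotation

RAW_COLUMNS = ["z0_raw", "z1_raw", "z2_raw", "z3_raw"]
NORM_COLUMNS = ["z0", "z1", "z2", "z3"]

#: default |Znet| threshold: outermost ~10 % of a Gaussian population
DEFAULT_THRESHOLD = 1.65


@dataclass
class ContrastResult:
    """All scores for one gene in one contrast."""

    locus_id: str
    contrast: str
    z0_raw: float
    z1_raw: float
    z2_raw: float
    z3_raw: float
    z0: float
    z1: float
    z2: float
    z3: float
    znet: float
    regulation: str
    snr: float = float("nan")
    fdr: float = float("nan")


def raw_differences(
    expr: ExpressionMatrix, design: ExperimentDesign, condition: str
) -> pd.DataFrame:
    """Raw z0..z3 log2 differences for the contrast ``condition - reference``.

    Genes missing any of the four required values are dropped from the
    contrast and recorded in the matrix's ``filter_log``.
    """
    if len(design.replicates) != 2:
        raise ValueError(
            "two replicates are required for intra-replicate differences; "
            "use cross_state_only() for a single replicate set"
        )
    if condition not in design.non_reference:
        raise ValueError(f"{condition!r} is not a non-reference condition of the design")
    rep_a, rep_b = design.replicates
    x, y = condition, design.reference
    frame = pd.DataFrame(
        {
            "z0_raw": expr.data[(x, rep_b)] - expr.data[(x, rep_a)],
            "z1_raw": expr.data[(y, rep_b)] - expr.data[(y, rep_a)],
            "z2_raw": expr.data[(x, rep_a)] - expr.data[(y, rep_a)],
            "z3_raw": expr.data[(x, rep_b)] - expr.data[(y, rep_b)],
        }
    )
    complete = frame.dropna()
    for locus in frame.index.difference(complete.index):
        expr.log_filter(locus, f"incomplete[{condition}]")
    return complete


def normalize_population(values) -> np.ndarray | pd.Series:
    """Affine-map a difference population to mean 0 and SD 1 (population SD).

    Order-preserving; raises on fewer than 2 finite values or zero spread.
    """
    arr = np.asarray(values, dtype=float)
    finite = np.isfinite(arr)
    if finite.sum() < 2:
        raise ValueError("need at least 2 finite values to normalize")
    mean = arr[finite].mean()
    sd = arr[finite].std(ddof=0)
    if sd == 0:
        raise ValueError("degenerate population: zero spread")
    out = (arr - mean) / sd
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name)
    return out


def mean_merge(z2, z3):
    """Default merge rule: average of the two normalized cross-state scores."""
    return (np.asarray(z2, dtype=float) + np.asarray(z3, dtype=float)) / 2.0


def merge_znet(
    z2: pd.Series,
    z3: pd.Series,
    merge_rule: Callable = mean_merge,
) -> pd.Series:
    """Merge two normalized cross-state score populations into Znet.

    The merged values are renormalized so the Znet population again has
    mean 0 and SD 1.  ``merge_rule`` is pluggable; the default is the
    per-gene average.
    """
    if not z2.index.equals(z3.index):
        raise ValueError("z2 and z3 must cover the same genes in the same order")
    merged = pd.Series(merge_rule(z2, z3), index=z2.index, name="znet")
    return normalize_population(merged)


def cross_state_only(
    expr: ExpressionMatrix,
    design: ExperimentDesign,
    condition: str,
    replicate: str | None = None,
) -> pd.Series:
    """Single-replicate-set contrast: Znet from cross-state differences only.

    Used for the proteomic mode where only one replicate set is analysed;
    ``replicate`` defaults to the matrix's only replicate level.
    """
    if condition not in design.non_reference:
        raise ValueError(f"{condition!r} is not a non-reference condition of the design")
    levels = expr.data.columns.get_level_values(1).unique()
    if replicate is None:
        if len(levels) != 1:
            raise ValueError("replicate must be named when the matrix has several")
        replicate = levels[0]
    if replicate not in levels:
        raise ValueError(f"designated replicate {replicate!r} absent from matrix")
    diff = (expr.data[(condition, replicate)] - expr.data[(design.reference, replicate)]).dropna()
    for locus in expr.data.index.difference(diff.index):
        expr.log_filter(locus, f"incomplete[{condition}]")
    return normalize_population(diff.rename("znet"))


def classify(znet: pd.Series, threshold: float = DEFAULT_THRESHOLD) -> pd.Series:
    """up / down / ns per gene; ties at the threshold count as regulated."""
    out = pd.Series("ns", index=znet.index, name="regulation")
    out[znet >= threshold] = "up"
    out[znet <= -threshold] = "down"
    return out


def compute_contrast(
    expr: ExpressionMatrix,
    design: ExperimentDesign,
    condition: str,
    threshold: float = DEFAULT_THRESHOLD,
    merge_rule: Callable = mean_merge,
) -> pd.DataFrame:
    """Full two-replicate contrast: raw differences -> normalized -> Znet.

    Returns a frame indexed by locus with raw scores, normalized scores,
    ``znet`` and ``regulation`` columns.
    """
    raw = raw_differences(expr, design, condition)
    frame = raw.copy()
    for raw_col, norm_col in zip(RAW_COLUMNS, NORM_COLUMNS):
        frame[norm_col] = normalize_population(raw[raw_col])
    frame["znet"] = merge_znet(frame["z2"], frame["z3"], merge_rule=merge_rule)
    frame["regulation"] = classify(frame["znet"], threshold)
    return frame


def contrast_results(
    frame: pd.DataFrame, contrast_label: str
) -> list[ContrastResult]:
    """Convert a contrast frame into ContrastResult records."""
    records = []
    for locus, row in frame.iterrows():
        records.append(
            ContrastResult(
                locus_id=locus,
                contrast=contrast_label,
                z0_raw=row.get("z0_raw", float("nan")),
                z1_raw=row.get("z1_raw", float("nan")),
                z2_raw=row.get("z2_raw", float("nan")),
                z3_raw=row.get("z3_raw", float("nan")),
                z0=row.get("z0", float("nan")),
                z1=row.get("z1", float("nan")),
                z2=row.get("z2", float("nan")),
                z3=row.get("z3", float("nan")),
                znet=row["znet"],
                regulation=row["regulation"],
                snr=row.get("snr", float("nan")),
                fdr=row.get("fdr", float("nan")),
            )
        )
    return records


UNANNOTATED_CLASS = "?"


def classify_and_tabulate(
    rna: Mapping[str, pd.Series],
    protein: Mapping[str, pd.Series],
    annotations: Iterable[GeneAnnotation],
    threshold: float = DEFAULT_THRESHOLD,
    exclude_classes: frozenset[str] | set[str] = frozenset({"S"}),
    exclude_hypotheticals: bool = True,
) -> pd.DataFrame:
    """Count up/down regulated genes per COG class, per contrast, per omic.

    ``rna`` and ``protein`` map condition label -> Znet series.  Output rows
    are COG letters (``?`` for loci without an annotation or COG letter);
    columns are a (condition, source, direction) MultiIndex where source is
    ``rna``, ``protein`` or ``overlap``.  Overlap counts genes past the
    threshold in the same direction in both omics, excluding the configured
    COG classes and (optionally) hypothetical genes; the exclusions apply
    to the overlap counts only.
    """
    ann_by_locus = {a.locus_id: a for a in annotations}

    def cog_of(locus: str) -> str:
        ann = ann_by_locus.get(locus)
        if ann is None or ann.cog_class is None:
            return UNANNOTATED_CLASS
        return ann.cog_class

    def excluded(locus: str) -> bool:
        ann = ann_by_locus.get(locus)
        cog = cog_of(locus)
        if cog in exclude_classes:
            return True
        return bool(exclude_hypotheticals and ann is not None and ann.is_hypothetical)

    conditions = sorted(set(rna) | set(protein))
    counts: dict[tuple[str, str, str], dict[str, int]] = {}

    def bump(cog: str, condition: str, source: str, direction: str) -> None:
        col = (condition, source, direction)
        counts.setdefault(col, {})
        counts[col][cog] = counts[col].get(cog, 0) + 1

    for condition in conditions:
        per_omic_sets: dict[str, dict[str, set[str]]] = {}
        for source, mapping in (("rna", rna), ("protein", protein)):
            znet = mapping.get(condition)
            if znet is None:
                continue
            up = set(znet.index[znet >= threshold])
            down = set(znet.index[znet <= -threshold])
            per_omic_sets[source] = {"up": up, "down": down}
            for direction, loci in (("up", up), ("down", down)):
                for locus in loci:
                    bump(cog_of(locus), condition, source, direction)
        if "rna" in per_omic_sets and "protein" in per_omic_sets:
            for direction in ("up", "down"):
                overlap = (
                    per_omic_sets["rna"][direction] & per_omic_sets["protein"][direction]
                )
                for locus in overlap:
                    if not excluded(locus):
                        bump(cog_of(locus), condition, "overlap", direction)

    all_cogs = sorted({cog for col in counts.values() for cog in col})
    columns = pd.MultiIndex.from_tuples(
        [
            (condition, source, direction)
            for condition in conditions
            for source in ("rna", "protein", "overlap")
            for direction in ("down", "up")
        ],
        names=["condition", "source", "direction"],
    )
    table = pd.DataFrame(0, index=pd.Index(all_cogs, name="cog"), columns=columns)
    for col, per_cog in counts.items():
        for cog, n in per_cog.items():
            table.loc[cog, col] = n
    return table


def write_cog_table(table: pd.DataFrame, path) -> None:
    flat = table.copy()
    flat.columns = ["|".join(col) for col in flat.columns]
    flat.to_csv(path, sep="\t")
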