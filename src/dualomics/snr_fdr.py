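"""Signal-to-noise statistic and Monte-Carlo false discovery rate.

The system-level S/N is the ratio of the mean cross-state population SD to
the mean intra-replicate population SD, computed on the raw log2
differences.  The gene-level S/N is the ratio of the cross-state to
intra-replicate 2-vector magnitudes of the *normalized* scores, scaled by
the system S/N; with the default multiplicative scaling the gene statistic
reduces to the raw-scale magnitude ratio, so a pure-noise gene (all four
differences drawn from the same distribution) has the closed-form null law
``P(S/N > c) = 1 / (1 + c^2)``.

The FDR of an S/N cutoff is calibrated by synthesizing null genes from the
observed intra-replicate noise and pushing them through the identical
normalization and S/N computation (a conservative plug-in estimate with
the null fraction fixed at 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from dualomics.differential import NORM_COLUMNS, RAW_COLUMNS

#: S/N cutoff conventionally used to flag reliable differential calls
DEFAULT_SNR_CUTOFF = 2.8
DEFAULT_CUTOFFS = (1.0, 2.0, DEFAULT_SNR_CUTOFF, 4.0)


@dataclass(frozen=True)
class SnrModel:
    """Dataset-level noise model for one contrast."""

    system_snr: float
    intra_noise_sd: float
    cross_sd: float
    n_genes: int
    mc_replicates: int = 0
    seed: int | None = None


def system_snr(raw_diffs: pd.DataFrame) -> SnrModel:
    """Fit the system S/N from a raw-difference frame (z0_raw..z3_raw).

    system S/N = mean(SD(z2_raw), SD(z3_raw)) / mean(SD(z0_raw), SD(z1_raw)),
    with SDs taken over genes (population convention).
    """
    missing = [c for c in RAW_COLUMNS if c not in raw_diffs.columns]
    if missing:
        raise ValueError(f"raw difference frame lacks columns: {', '.join(missing)}")
    if len(raw_diffs) < 2:
        raise ValueError("need at least 2 genes to estimate the system S/N")
    sds = raw_diffs[RAW_COLUMNS].std(ddof=0)
    intra = float((sds["z0_raw"] + sds["z1_raw"]) / 2.0)
    cross = float((sds["z2_raw"] + sds["z3_raw"]) / 2.0)
    if intra == 0:
        raise ValueError("zero intra-replicate standard deviation")
    return SnrModel(
        system_snr=cross / intra,
        intra_noise_sd=intra,
        cross_sd=cross,
        n_genes=len(raw_diffs),
    )


def _snr_from_components(
    z0: np.ndarray,
    z1: np.ndarray,
    z2: np.ndarray,
    z3: np.ndarray,
    system: float,
    scale_mode: str,
) -> np.ndarray:
    cross = np.hypot(z2, z3)
    intra = np.hypot(z0, z1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = cross / intra
    # a zero intra-replicate magnitude yields +inf, ranked above all finite
    ratio = np.where(intra == 0, np.inf, ratio)
    if scale_mode == "multiply":
        return ratio * system
    if scale_mode == "divide":
        return ratio / system
    raise ValueError(f"scale_mode must be 'multiply' or 'divide', got {scale_mode!r}")


def gene_snr(
    z: pd.DataFrame, model: SnrModel, scale_mode: str = "multiply"
) -> pd.Series:
    """Per-gene S/N from normalized z0..z3 columns."""
    missing = [c for c in NORM_COLUMNS if c not in z.columns]
    if missing:
        raise ValueError(f"normalized score frame lacks columns: {', '.join(missing)}")
    values = _snr_from_components(
        z["z0"].to_numpy(float),
        z["z1"].to_numpy(float),
        z["z2"].to_numpy(float),
        z["z3"].to_numpy(float),
        model.system_snr,
        scale_mode,
    )
    return pd.Series(values, index=z.index, name="snr")


@dataclass
class FdrResult:
    """Monte-Carlo FDR calibration output.

    ``cutoff_table`` has one row per cutoff with observed and mean null
    exceedance counts, the raw capped FDR estimate and the monotonized
    estimate (non-increasing in the cutoff).  ``gene_fdr`` gives each
    gene's estimated FDR at its own S/N, monotonized to be non-increasing
    in S/N.
    """

    cutoff_table: pd.DataFrame
    gene_fdr: pd.Series
    model: SnrModel


def monte_carlo_fdr(
    observed_snr: pd.Series,
    model: SnrModel,
    cutoffs=DEFAULT_CUTOFFS,
    mc_replicates: int = 100,
    seed: int = 0,
    scale_mode: str = "multiply",
) -> FdrResult:
    """Estimate the FDR of S/N cutoffs by simulating pure-noise genes.

    Per Monte-Carlo replicate, ``model.n_genes`` null genes get all four
    raw differences drawn Normal(0, intra_noise_sd); these are normalized
    with the observed model's population scales and scored with the
    observed system S/N.  FDR(c) = min(1, mean null exceedance / observed
    exceedance); cutoffs with no observed gene above them report NaN.
    """
    cutoffs = sorted(float(c) for c in cutoffs)
    if any(c <= 0 for c in cutoffs):
        raise ValueError("cutoffs must be positive")
    if mc_replicates < 1:
        raise ValueError("mc_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    obs = observed_snr.to_numpy(float)

    null_counts = np.zeros((mc_replicates, len(cutoffs)))
    pooled: list[np.ndarray] = []
    for rep in range(mc_replicates):
        draws = rng.normal(0.0, model.intra_noise_sd, size=(model.n_genes, 4))
        # identical normalization: divide by the observed population scales
        z0 = draws[:, 0] / model.intra_noise_sd
        z1 = draws[:, 1] / model.intra_noise_sd
        z2 = draws[:, 2] / model.cross_sd
        z3 = draws[:, 3] / model.cross_sd
        snr_null = _snr_from_components(z0, z1, z2, z3, model.system_snr, scale_mode)
        for j, c in enumerate(cutoffs):
            null_counts[rep, j] = np.count_nonzero(snr_null > c)
        pooled.append(snr_null)

    obs_counts = np.array([np.count_nonzero(obs > c) for c in cutoffs], dtype=float)
    mean_null = null_counts.mean(axis=0)
    se_null = (
        null_counts.std(axis=0, ddof=1) / np.sqrt(mc_replicates)
        if mc_replicates > 1
        else np.zeros(len(cutoffs))
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        raw_fdr = np.where(obs_counts > 0, np.minimum(1.0, mean_null / obs_counts), np.nan)
        fdr_se = np.where(obs_counts > 0, se_null / obs_counts, np.nan)
    mono = np.minimum.accumulate(np.where(np.isnan(raw_fdr), np.inf, raw_fdr))
    mono_fdr = np.where(np.isnan(raw_fdr), np.nan, np.minimum(mono, 1.0))

    cutoff_table = pd.DataFrame(
        {
            "cutoff": cutoffs,
            "n_observed": obs_counts.astype(int),
            "mean_null": mean_null,
            "fdr_raw": raw_fdr,
            "fdr_se": fdr_se,
            "fdr": mono_fdr,
        }
    )

    # per-gene FDR at each gene's own S/N (>= so the gene counts itself)
    pooled_sorted = np.sort(np.concatenate(pooled))
    finite_obs = np.where(np.isfinite(obs), obs, np.finfo(float).max)
    null_ge = len(pooled_sorted) - np.searchsorted(pooled_sorted, finite_obs, side="left")
    obs_sorted = np.sort(finite_obs)
    obs_ge = len(obs_sorted) - np.searchsorted(obs_sorted, finite_obs, side="left")
    gene_raw = np.minimum(1.0, (null_ge / mc_replicates) / obs_ge)
    # monotonize: traverse S/N ascending, carry the running minimum upward
    order = np.argsort(finite_obs)
    mono_vals = np.minimum.accumulate(gene_raw[order])
    gene_fdr = np.empty_like(gene_raw)
    gene_fdr[order] = mono_vals
    gene_fdr_series = pd.Series(gene_fdr, index=observed_snr.index, name="fdr")

    fitted = SnrModel(
        system_snr=model.system_snr,
        intra_noise_sd=model.intra_noise_sd,
        cross_sd=model.cross_sd,
        n_genes=model.n_genes,
        mc_replicates=mc_replicates,
        seed=seed,
    )
    return FdrResult(cutoff_table=cutoff_table, gene_fdr=gene_fdr_series, model=fitted)


def attach_snr_fdr(
    contrast_frame: pd.DataFrame,
    cutoffs=DEFAULT_CUTOFFS,
    mc_replicates: int = 100,
    seed: int = 0,
    scale_mode: str = "multiply",
) -> tuple[pd.DataFrame, FdrResult]:
    """Add ``snr`` and ``fdr`` columns to a two-replicate contrast frame."""
    model = system_snr(contrast_frame)
    snr = gene_snr(contrast_frame, model, scale_mode=scale_mode)
    result = monte_carlo_fdr(
        snr,
        model,
        cutoffs=cutoffs,
        mc_replicates=mc_replicates,
        seed=seed,
        scale_mode=scale_mode,
    )
    out = contrast_frame.copy()
    out["snr"] = snr
    out["fdr"] = result.gene_fdr
    return out, result
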