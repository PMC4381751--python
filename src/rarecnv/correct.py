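"""Principal-component correction of the LRR matrix.

Batch structure (plate, cohort, reagent, scanner drift) appears as a few
large linear components of the samples x SNPs LRR matrix.  Scores are fitted
on a masked, thinned marker subset — immunoglobulin, telomeric, centromeric
and MHC regions are excluded and markers thinned to ~15% — so that genuinely
rare CNV signal (carried by <1% of samples at any locus) cannot dominate a
component.  Every manifest SNP is then regressed on the leading k scores and
replaced by its residual; the intercept is removed with the components, so
corrected columns have (approximately) zero mean.  Common copy-number
polymorphisms are expected to be distorted by this step: the pipeline
targets rare CNVs only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import RegionSet, SnpManifest


@dataclass
class PcModel:
    """Fitted correction model, persisted for audit."""

    marker_indices: np.ndarray   # manifest indices of the thinned fitting subset
    k: int
    scores: np.ndarray           # samples x k left singular directions
    singular_values: np.ndarray


def select_correction_markers(manifest: SnpManifest,
                              exclusion_regions: list[RegionSet] | None,
                              thin_fraction: float = 0.15,
                              seed: int = 0) -> np.ndarray:
    """Manifest indices of masked + uniformly thinned markers (sorted).

    The subset size is ``floor(thin_fraction * n_eligible)``; thinning is
    without replacement from the seeded generator.
    """
    eligible = np.ones(len(manifest), dtype=bool)
    for rs in exclusion_regions or []:
        eligible &= ~rs.mask_snps(manifest)
    idx = np.flatnonzero(eligible)
    n_keep = int(np.floor(thin_fraction * len(idx)))
    if n_keep < 1:
        raise ValueError("no markers left after masking/thinning")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(idx, size=n_keep, replace=False)
    return np.sort(chosen)


def fit_pc_model(lrr: np.ndarray, marker_indices: np.ndarray, k: int = 24) -> PcModel:
    """Sample scores = leading k left singular directions of the
    column-centred samples x subset matrix (missing values mean-imputed)."""
    X = lrr[:, marker_indices].copy()
    col_mean = np.nanmean(X, axis=0)
    nan_mask = ~np.isfinite(X)
    if nan_mask.any():
        X[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    X -= X.mean(axis=0)
    if k > min(X.shape):
        raise ValueError(f"k={k} exceeds the rank bound {min(X.shape)}")
    if k == 0:
        return PcModel(marker_indices, 0, np.zeros((X.shape[0], 0)), np.zeros(0))
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    return PcModel(marker_indices, k, U[:, :k], s[:k])


def remove_components(lrr: np.ndarray, model: PcModel) -> np.ndarray:
    """Residual of each SNP's LRR regressed on the k scores plus intercept.

    ``k = 0`` returns the input unchanged.  Missing entries stay missing;
    columns containing missing values are fitted on their observed entries.
    """
    if model.k == 0:
        return lrr.copy()
    n, _ = lrr.shape
    A = np.column_stack([np.ones(n), model.scores])       # n x (k+1)
    out = np.array(lrr, dtype=float, copy=True)

    complete = np.all(np.isfinite(lrr), axis=0)
    if complete.any():
        Y = lrr[:, complete]
        beta, *_ = np.linalg.lstsq(A, Y, rcond=None)
        out[:, complete] = Y - A @ beta
    for j in np.flatnonzero(~complete):
        obs = np.isfinite(lrr[:, j])
        if obs.sum() <= model.k + 1:
            continue  # too few observations to fit; leave column untouched
        beta, *_ = np.linalg.lstsq(A[obs], lrr[obs, j], rcond=None)
        out[obs, j] = lrr[obs, j] - A[obs] @ beta
    return out


def fit_and_remove_components(lrr: np.ndarray, marker_indices: np.ndarray,
                              k: int = 24) -> tuple[np.ndarray, PcModel]:
    """Convenience: fit scores on the subset and correct every SNP."""
    model = fit_pc_model(lrr, marker_indices, k=k)
    return remove_components(lrr, model), model
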