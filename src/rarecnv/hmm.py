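"""Hidden-Markov-model segmentation of LRR/BAF into copy-number calls.

Five hidden states (copy numbers 0, 1, 2, 3, 4; no copy-neutral LOH state).
The emission model couples a Gaussian LRR term with a BAF genotype-band
mixture whose band weights follow a binomial in the population B-allele
frequency (PFB); BAF values at exactly 0 or 1 are treated as censored point
masses.  Transitions decay with inter-marker distance,
``a_ij(d) = pi_j * (1 - exp(-d/D))`` for ``i != j``, so distant markers
revert towards the stationary, diploid-dominant prior.

Decoding is per chromosome and vectorised across samples.  Ties in the
Viterbi recursion resolve to the lower copy-number state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from typing import Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

from .model import CnvCall, IntensityPanel, SnpManifest

N_STATES = 5
DIPLOID = 2
STATE_CN = np.array([0, 1, 2, 3, 4])

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class HmmParams:
    """Emission and transition parameters; defaults follow the PennCNV convention."""

    lrr_mean: np.ndarray = field(default_factory=lambda: np.array([-3.5, -0.67, 0.0, 0.40, 0.68]))
    lrr_sd: np.ndarray = field(default_factory=lambda: np.array([1.3, 0.28, 0.16, 0.21, 0.24]))
    baf_sd: float = 0.04            # SD of each BAF genotype band
    eps_out: float = 0.01           # uniform outlier weight mixed into BAF densities
    boundary_eps: float = 1e-3      # floor mass at BAF exactly 0/1 (keeps CN0 comparable)
    pi: np.ndarray = field(default_factory=lambda: np.array([1e-4, 9e-4, 0.998, 9e-4, 1e-4]))
    transition_scale_bp: float = 100_000.0  # D: distance scale of state persistence

    def __post_init__(self):
        self.lrr_mean = np.asarray(self.lrr_mean, float)
        self.lrr_sd = np.asarray(self.lrr_sd, float)
        self.pi = np.asarray(self.pi, float)
        if np.any(self.lrr_sd <= 0) or self.baf_sd <= 0:
            raise ValueError("emission SDs must be positive")
        if abs(self.pi.sum() - 1.0) > 1e-9 or np.any(self.pi <= 0):
            raise ValueError("pi must be a positive distribution")


def log_transition_matrices(pos_bp: np.ndarray, params: HmmParams) -> np.ndarray:
    """(n-1, 5, 5) log transition matrices for consecutive marker distances."""
    d = np.diff(pos_bp.astype(float))
    leave = 1.0 - np.exp(-d / params.transition_scale_bp)  # (n-1,)
    A = leave[:, None, None] * params.pi[None, None, :] * np.ones((1, N_STATES, 1))
    idx = np.arange(N_STATES)
    A[:, idx, idx] = 0.0
    A[:, idx, idx] = 1.0 - A.sum(axis=2)[:, idx]
    return np.log(A)


def _baf_bands(pfb: np.ndarray, cn: int) -> tuple[np.ndarray, np.ndarray]:
    """Band means (k/cn) and per-SNP binomial weights for a copy-number state."""
    k = np.arange(cn + 1)
    means = k / cn
    p = pfb[None, :]
    weights = np.array([comb(cn, ki) for ki in k])[:, None] * \
        p ** k[:, None] * (1.0 - p) ** (cn - k)[:, None]
    return means, weights  # (cn+1,), (cn+1, n_snps)


def log_emissions(lrr: np.ndarray, baf: np.ndarray, pfb: np.ndarray,
                  params: HmmParams) -> np.ndarray:
    """Per-SNP log emission likelihoods, shape (n_samples, n_snps, 5).

    Missing LRR or BAF contributes only the non-missing term; a SNP missing
    both contributes 0 to every state.
    """
    lrr = np.atleast_2d(lrr)
    baf = np.atleast_2d(baf)
    n_s, n_m = lrr.shape
    out = np.zeros((n_s, n_m, N_STATES))

    lrr_ok = np.isfinite(lrr)
    z = (lrr[:, :, None] - params.lrr_mean[None, None, :]) / params.lrr_sd[None, None, :]
    loglrr = -0.5 * z ** 2 - np.log(params.lrr_sd)[None, None, :] - 0.5 * _LOG2PI
    out += np.where(lrr_ok[:, :, None], loglrr, 0.0)

    baf_ok = np.isfinite(baf)
    b = np.where(baf_ok, baf, 0.5)
    at0 = baf_ok & (b <= 0.0)
    at1 = baf_ok & (b >= 1.0)
    interior = baf_ok & ~at0 & ~at1
    sd = params.baf_sd
    eps = params.eps_out

    baf_ll = np.zeros((n_s, n_m, N_STATES))
    # CN0: no genotype structure — uniform density, boundary mass at the floor
    dens0 = np.where(interior, 1.0, 0.0) + np.where(at0 | at1, params.boundary_eps, 0.0)
    baf_ll[:, :, 0] = np.log(np.where(baf_ok, dens0, 1.0))

    for s, cn in ((1, 1), (2, 2), (3, 3), (4, 4)):
        means, w = _baf_bands(pfb, cn)  # (k,), (k, n_m)
        dens = np.zeros((n_s, n_m))
        mass0 = (w * norm.cdf((0.0 - means[:, None]) / sd)).sum(axis=0)   # (n_m,)
        mass1 = (w * norm.sf((1.0 - means[:, None]) / sd)).sum(axis=0)
        for mu, wk in zip(means, w):
            dens += wk[None, :] * np.exp(-0.5 * ((b - mu) / sd) ** 2) / (sd * np.sqrt(2 * np.pi))
        mixed = np.where(interior, (1 - eps) * dens + eps, 0.0)
        mixed += np.where(at0, np.maximum((1 - eps) * mass0[None, :], params.boundary_eps), 0.0)
        mixed += np.where(at1, np.maximum((1 - eps) * mass1[None, :], params.boundary_eps), 0.0)
        baf_ll[:, :, s] = np.log(np.where(baf_ok, mixed, 1.0))

    out += baf_ll
    return out


def _viterbi_paths(logE: np.ndarray, logA: np.ndarray, logpi: np.ndarray) -> np.ndarray:
    """Batched Viterbi decode; ties resolve to the lowest state index (lowest CN)."""
    n_s, n_m, _ = logE.shape
    back = np.empty((n_s, n_m, N_STATES), dtype=np.int8)
    delta = logpi[None, :] + logE[:, 0, :]
    back[:, 0, :] = 0
    for t in range(1, n_m):
        cand = delta[:, :, None] + logA[t - 1][None, :, :]   # (n_s, prev, next)
        best = np.argmax(cand, axis=1)                       # first max -> lowest CN
        back[:, t, :] = best
        delta = np.take_along_axis(cand, best[:, None, :], axis=1)[:, 0, :] + logE[:, t, :]
    paths = np.empty((n_s, n_m), dtype=np.int8)
    paths[:, -1] = np.argmax(delta, axis=1)
    for t in range(n_m - 1, 0, -1):
        paths[:, t - 1] = np.take_along_axis(
            back[:, t, :], paths[:, t][:, None].astype(np.intp), axis=1)[:, 0]
    return paths


def _forward_backward(logE: np.ndarray, logA: np.ndarray, logpi: np.ndarray) -> np.ndarray:
    """Batched forward-backward; returns posteriors (n_samples, n_snps, 5)."""
    n_s, n_m, _ = logE.shape
    alpha = np.empty_like(logE)
    beta = np.empty_like(logE)
    alpha[:, 0, :] = logpi[None, :] + logE[:, 0, :]
    for t in range(1, n_m):
        alpha[:, t, :] = logE[:, t, :] + logsumexp(
            alpha[:, t - 1, :, None] + logA[t - 1][None, :, :], axis=1)
    beta[:, -1, :] = 0.0
    for t in range(n_m - 2, -1, -1):
        beta[:, t, :] = logsumexp(
            logA[t][None, :, :] + (logE[:, t + 1, :] + beta[:, t + 1, :])[:, None, :], axis=2)
    logpost = alpha + beta
    logpost -= logsumexp(logpost, axis=2, keepdims=True)
    return np.exp(logpost)


def _segments_from_path(path: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal runs of non-diploid states as (start_idx, end_idx, state)."""
    segs = []
    n = len(path)
    i = 0
    while i < n:
        if path[i] != DIPLOID:
            j = i
            while j + 1 < n and path[j + 1] == path[i]:
                j += 1
            segs.append((i, j, int(path[i])))
            i = j + 1
        else:
            i += 1
    return segs


def call_cnvs(panel: IntensityPanel, params: HmmParams | None = None,
              with_quality: bool = True) -> list[CnvCall]:
    """Segment every sample of a panel into CNV calls, per chromosome.

    Quality is the mean forward-backward posterior of the called state over
    the call's supporting SNPs.
    """
    params = params or HmmParams()
    man = panel.manifest
    logpi = np.log(params.pi)
    calls: list[CnvCall] = []
    for chrom, sl in man.chrom_slices().items():
        pos = man.pos_bp[sl]
        if np.any(np.diff(pos) < 0):
            raise ValueError("manifest not sorted by position")
        pfb = man.pfb[sl]
        logE = log_emissions(panel.lrr[:, sl], panel.baf[:, sl], pfb, params)
        logA = log_transition_matrices(pos, params)
        paths = _viterbi_paths(logE, logA, logpi)
        post = _forward_backward(logE, logA, logpi) if with_quality else None
        for i, sample in enumerate(panel.samples):
            for a, b_, st in _segments_from_path(paths[i]):
                q = float(post[i, a:b_ + 1, st].mean()) if with_quality else 1.0
                calls.append(CnvCall(sample_id=sample, chrom=chrom,
                                     start_bp=int(pos[a]), end_bp=int(pos[b_]),
                                     copy_number=int(STATE_CN[st]),
                                     n_snps=b_ - a + 1, quality=min(q, 1.0)))
    calls.sort(key=lambda c: (c.sample_id, c.chrom, c.start_bp))
    return calls


def viterbi_segments(lrr: np.ndarray, baf: np.ndarray, manifest: SnpManifest,
                     params: HmmParams | None = None,
                     sample_id: str = "sample") -> list[CnvCall]:
    """Single-sample convenience wrapper around the batched decoder.

    PFB is taken from the manifest, which also fixes marker order.
    """
    panel = IntensityPanel([sample_id], manifest,
                           np.atleast_2d(np.asarray(lrr, float)),
                           np.atleast_2d(np.asarray(baf, float)),
                           np.full((1, len(manifest)), -1, dtype=np.int8))
    return call_cnvs(panel, params or HmmParams())


def state_posteriors(lrr: np.ndarray, baf: np.ndarray, pos_bp: np.ndarray,
                     pfb: np.ndarray, params: HmmParams | None = None) -> np.ndarray:
    """Forward-backward posteriors for one sample window; rows sum to 1."""
    params = params or HmmParams()
    logE = log_emissions(np.atleast_2d(lrr), np.atleast_2d(baf), pfb, params)
    logA = log_transition_matrices(np.asarray(pos_bp), params)
    return _forward_backward(logE, logA, np.log(params.pi))[0]


def merge_fragments(calls: Sequence[CnvCall], manifest: SnpManifest,
                    rho: float = 0.2) -> list[CnvCall]:
    """Merge same-copy-number fragments split by short gaps.

    Consecutive calls (one sample, one chromosome) merge when
    ``gap / (len_left + gap + len_right) < rho``; applied left-to-right and
    iterated to a fixed point.  ``n_snps`` is recounted from the manifest and
    quality is the SNP-weighted mean of the merged members.
    """
    out: list[CnvCall] = []
    by_key: dict[tuple[str, str, int], list[CnvCall]] = {}
    for c in calls:
        by_key.setdefault((c.sample_id, c.chrom, c.copy_number), []).append(c)
    for (sample, chrom, cn), group in by_key.items():
        group = sorted(group, key=lambda c: c.start_bp)
        for a, b in zip(group, group[1:]):
            if b.start_bp <= a.end_bp:
                raise ValueError(f"overlapping calls for {sample} on {chrom}")
        changed = True
        while changed:
            changed = False
            merged: list[CnvCall] = []
            for c in group:
                if merged:
                    left = merged[-1]
                    gap = c.start_bp - left.end_bp - 1
                    total = left.length_bp + gap + c.length_bp
                    if gap / total < rho:
                        n = manifest.n_snps_in(chrom, left.start_bp, c.end_bp)
                        q = (left.quality * left.n_snps + c.quality * c.n_snps) / \
                            (left.n_snps + c.n_snps)
                        merged[-1] = CnvCall(sample, chrom, left.start_bp, c.end_bp,
                                             cn, n, q)
                        changed = True
                        continue
                merged.append(c)
            group = merged
        out.extend(group)
    out.sort(key=lambda c: (c.sample_id, c.chrom, c.start_bp))
    return out


def score_quality(call: CnvCall, posteriors: np.ndarray, snp_offsets: np.ndarray) -> float:
    """Mean posterior of the called state over the call's supporting SNPs."""
    if len(snp_offsets) == 0:
        raise ValueError("call has no supporting SNPs in the posterior window")
    state = int(np.searchsorted(STATE_CN, call.copy_number))
    return float(posteriors[snp_offsets, state].mean())


def parent_state_evidence(call: CnvCall, parent_lrr: np.ndarray, parent_baf: np.ndarray,
                          pfb: np.ndarray, params: HmmParams | None = None,
                          llr_threshold: float = 0.0) -> str:
    """Relaxed re-test of a child call against one parent's intensities.

    Sums the per-SNP log-likelihood ratio of the called state versus diploid
    over the call's SNPs on the parent's data.  Returns ``"supported"`` when
    the LLR exceeds the threshold, ``"unsupported"`` otherwise, and
    ``"unknown"`` when the parent has no usable data at any of the SNPs.
    """
    params = params or HmmParams()
    lrr = np.atleast_2d(np.asarray(parent_lrr, float))
    baf = np.atleast_2d(np.asarray(parent_baf, float))
    usable = np.isfinite(lrr) | np.isfinite(baf)
    if not usable.any():
        return "unknown"
    logE = log_emissions(lrr, baf, np.asarray(pfb, float), params)[0]
    state = int(np.searchsorted(STATE_CN, call.copy_number))
    llr = float((logE[:, state] - logE[:, DIPLOID]).sum())
    return "supported" if llr > llr_threshold else "unsupported"
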