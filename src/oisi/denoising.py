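"""Stimulus-locked pattern extraction and spatial smoothing.

The indicator-function decomposition finds spatial patterns v maximizing the
ratio of stimulus-locked variance to residual (noise) variance, i.e. the
generalized eigenproblem

    C_S v = λ (C_N + εI) v

with C_S the pixel covariance of the condition-mean maps, C_N the covariance
of per-trial residual maps (trial map minus its condition mean), and a small
ridge ε for invertibility.  Components with λ > 1 carry more stimulus-locked
than residual variance and are retained; filtering projects a map (about the
ensemble mean) onto the retained patterns under the noise metric.

When both ensembles have fewer samples than pixels the problem is solved
exactly in snapshot (sample) space: the noise metric M = C_N + εI is
whitened through the SVD of the residual ensemble (Woodbury form of
M^{-1/2}), and the whitened signal covariance — whose rank is bounded by the
number of signal snapshots — is diagonalized in that small space.  A direct
dense pixel-space solve is available for cross-checking on small problems.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence, Tuple

import h5py
import numpy as np
import scipy.linalg
from scipy import ndimage as ndi

from .preprocessing import (
    STAGE_DENOISED,
    STAGE_SMOOTHED,
    ResponseMap,
)

__all__ = [
    "GIFBasis",
    "gif_fit",
    "gif_filter",
    "gaussian_smooth",
    "permutation_null_lambda",
    "save_gif_basis",
    "load_gif_basis",
]

#: relative rank cutoff: eigenvalues below RANK_RTOL * λ_max are numerical zeros
RANK_RTOL = 1e-10


@dataclass
class GIFBasis:
    """Result of an indicator-function fit.

    ``patterns`` are the generalized eigenvectors, M-orthonormal
    (v_i^T (C_N+εI) v_j = δ_ij); they act as spatial *filters* extracting
    component amplitudes.  The corresponding ``metric_patterns``
    a_i = (C_N+εI) v_i are the activation patterns — they live in the range
    of the signal covariance and are what a retained component looks like in
    the image; the pair is biorthogonal (v_i^T a_j = δ_ij).  ``eigenvalues``
    holds the full descending spectrum of the solved problem; only the
    ``n_retained`` leading pairs are stored.
    """

    eigenvalues: np.ndarray            # descending, >= 0
    patterns: np.ndarray               # (n_retained, h, w)
    metric_patterns: np.ndarray        # (n_retained, h, w)
    mean_map: np.ndarray               # (h, w) signal-ensemble mean
    eps: float
    retain_threshold: float
    residuals: np.ndarray              # relative eigen-residual per retained pair

    @property
    def n_retained(self) -> int:
        return self.patterns.shape[0]

    @property
    def shape_yx(self) -> Tuple[int, int]:
        return self.mean_map.shape


def _as_matrix(maps: Sequence[ResponseMap]) -> np.ndarray:
    if len(maps) < 2:
        raise ValueError("need at least 2 maps in each ensemble")
    shape = maps[0].values.shape
    for m in maps[1:]:
        if m.values.shape != shape:
            raise ValueError("maps have mismatched dimensions")
    X = np.stack([m.values.ravel() for m in maps])
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in ensemble")
    return X


def gif_fit(
    signal_maps: Sequence[ResponseMap],
    noise_maps: Sequence[ResponseMap],
    retain_threshold: float = 1.0,
    eps_scale: float = 1.0,
    method: str = "auto",
) -> GIFBasis:
    """Fit the indicator-function basis from signal and noise ensembles.

    ``retain_threshold``: keep components with λ above it (default 1: more
    stimulus-locked than residual variance).  ``eps_scale`` sets the ridge
    ε = eps_scale · trace(C_N)/n_pixels (with a tiny absolute floor when the
    residual ensemble is exactly zero, e.g. noiseless simulations).  The
    default ridge equals the mean per-pixel residual variance: when the
    residual ensemble spans fewer dimensions than there are pixels, the
    sample noise covariance is singular off that span, and a much smaller
    ridge lets the eigensolver manufacture spuriously large eigenvalues in
    the unsampled directions (where the Rayleigh quotient divides by ~ε
    alone), defeating the λ > 1 retain rule.  With the noise-floor ridge,
    directions the residuals never sampled are charged the average noise
    variance instead of ~0.
    ``method``: "snapshot", "dense", or "auto" (snapshot when both ensembles
    are smaller than the pixel count).
    """
    S = _as_matrix(signal_maps)
    N = _as_matrix(noise_maps)
    if S.shape[1] != N.shape[1]:
        raise ValueError("signal and noise maps have mismatched dimensions")
    ns, p = S.shape
    nn = N.shape[0]
    shape = signal_maps[0].values.shape

    mean_map = S.mean(axis=0)
    Sc = S - mean_map
    Nc = N - N.mean(axis=0)

    trace_cn = float((Nc ** 2).sum()) / (nn - 1)
    eps = eps_scale * trace_cn / p
    if eps <= 0.0:
        eps = 1e-12  # exactly-zero residuals (noiseless data): keep M invertible

    if method == "auto":
        method = "snapshot" if max(ns, nn) < p else "dense"
    if method not in ("snapshot", "dense"):
        raise ValueError(f"unknown method {method!r}")

    if method == "dense":
        C_S = Sc.T @ Sc / (ns - 1)
        M = Nc.T @ Nc / (nn - 1) + eps * np.eye(p)
        w, V = scipy.linalg.eigh(C_S, M)
        order = np.argsort(w)[::-1]
        eigvals = np.clip(w[order], 0.0, None)
        vecs = V[:, order]  # already M-orthonormal (eigh type 1)
    else:
        # snapshot space: whiten with M^{-1/2} via SVD of the residual ensemble
        _, s_n, VnT = np.linalg.svd(Nc, full_matrices=False)
        Vn = VnT.T                      # (p, r)
        d = s_n ** 2 / (nn - 1)         # noise covariance eigenvalues in span(Vn)

        def msqrt_inv(X: np.ndarray) -> np.ndarray:
            """Apply M^{-1/2} to the columns of X."""
            proj = Vn.T @ X
            return Vn @ (proj / np.sqrt(d + eps)[:, None]) + (X - Vn @ proj) / np.sqrt(eps)

        Y = msqrt_inv(Sc.T) / np.sqrt(ns - 1)   # (p, ns)
        G = Y.T @ Y
        w, U = np.linalg.eigh(G)
        order = np.argsort(w)[::-1]
        eigvals = np.clip(w[order], 0.0, None)
        U = U[:, order]
        lam_max = eigvals[0] if eigvals.size else 0.0
        nz = eigvals > max(lam_max * RANK_RTOL, 0.0)
        W = Y @ U[:, nz]
        W /= np.sqrt(eigvals[nz])[None, :]       # whitened patterns, unit norm
        vecs = np.full((p, eigvals.size), np.nan)
        vecs[:, : nz.sum()] = msqrt_inv(W)       # v = M^{-1/2} w, so v^T M v = 1
        eigvals = eigvals.copy()

    lam_max = eigvals[0] if eigvals.size else 0.0
    retain = (eigvals > retain_threshold) & (eigvals > lam_max * RANK_RTOL)
    k = int(retain.sum())
    patterns = vecs[:, :k].T if k else np.empty((0, p))

    # metric images and eigen-residuals of the retained pairs
    metric = np.empty_like(patterns)
    residuals = np.empty(k)
    for i in range(k):
        v = patterns[i]
        mv = Nc.T @ (Nc @ v) / (nn - 1) + eps * v
        metric[i] = mv
        csv = Sc.T @ (Sc @ v) / (ns - 1)
        denom = np.linalg.norm(csv)
        residuals[i] = np.linalg.norm(csv - eigvals[i] * mv) / denom if denom > 0 else 0.0

    return GIFBasis(
        eigenvalues=eigvals,
        patterns=patterns.reshape(k, *shape),
        metric_patterns=metric.reshape(k, *shape),
        mean_map=mean_map.reshape(shape),
        eps=float(eps),
        retain_threshold=float(retain_threshold),
        residuals=residuals,
    )


def permutation_null_lambda(
    trial_maps: Sequence[ResponseMap],
    n_groups: int,
    rng: np.random.Generator,
    n_permutations: int = 3,
    eps_scale: float = 1.0,
) -> float:
    """Null level for the leading indicator eigenvalue by trial permutation.

    Randomly reassigns the per-trial maps to ``n_groups`` pseudo-conditions
    of equal size, rebuilds pseudo condition means and residuals, and refits
    the generalized eigenproblem.  Shuffling destroys stimulus locking but
    preserves the noise covariance, so the largest pseudo eigenvalue
    estimates how far sampling error alone can push λ — the small-sample
    inflation of snapshot covariances that a fixed λ > 1 rule cannot see.
    Returns the maximum over ``n_permutations`` shuffles; retention
    thresholds should take max(1, this).
    """
    n = len(trial_maps)
    if n % n_groups:
        raise ValueError("trial count must divide evenly into pseudo-conditions")
    size = n // n_groups
    lam = 0.0
    for _ in range(n_permutations):
        order = rng.permutation(n)
        means, residuals = [], []
        for g in range(n_groups):
            members = [trial_maps[i] for i in order[g * size : (g + 1) * size]]
            mean = np.mean([m.values for m in members], axis=0)
            means.append(members[0].with_values(mean))
            residuals.extend(m.with_values(m.values - mean) for m in members)
        basis = gif_fit(means, residuals, retain_threshold=np.inf, eps_scale=eps_scale)
        if basis.eigenvalues.size:
            lam = max(lam, float(basis.eigenvalues[0]))
    return lam


def gif_filter(rmap: ResponseMap, basis: GIFBasis) -> ResponseMap:
    """Project a map onto the retained activation patterns.

    Returns ensemble_mean + Σ_i a_i · v_i^T (map − ensemble_mean), with
    filters v_i and activation patterns a_i = (C_N+εI) v_i: the biorthogonal
    (oblique, noise-metric) projection onto the span of the retained
    patterns.  Component amplitudes are read out by the filters; the map is
    rebuilt from the patterns, so stimulus-locked content — which lives in
    the range of the signal covariance, the patterns' home — is preserved
    while directions no filter responds to are discarded.  Idempotent
    because v_i^T a_j = δ_ij.
    """
    if rmap.values.shape != basis.shape_yx:
        raise ValueError("map dimensions do not match the fitted basis")
    x = rmap.values.ravel() - basis.mean_map.ravel()
    if basis.n_retained:
        V = basis.patterns.reshape(basis.n_retained, -1)
        A = basis.metric_patterns.reshape(basis.n_retained, -1)
        out = basis.mean_map.ravel() + A.T @ (V @ x)
    else:
        out = basis.mean_map.ravel().copy()
    return rmap.with_values(out.reshape(basis.shape_yx), stage=STAGE_DENOISED)


def gaussian_smooth(rmap: ResponseMap, sd_px: float = 3.0) -> ResponseMap:
    """Low-pass filter with a normalized 2-D Gaussian kernel (reflect boundary)."""
    if sd_px <= 0:
        raise ValueError("sd_px must be > 0")
    smoothed = ndi.gaussian_filter(rmap.values, sigma=sd_px, mode="reflect")
    return rmap.with_values(smoothed, stage=STAGE_SMOOTHED)


def save_gif_basis(basis: GIFBasis, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("eigenvalues", data=basis.eigenvalues)
        f.create_dataset("patterns", data=basis.patterns)
        f.create_dataset("metric_patterns", data=basis.metric_patterns)
        f.create_dataset("mean_map", data=basis.mean_map)
        f.create_dataset("residuals", data=basis.residuals)
        f.attrs["eps"] = basis.eps
        f.attrs["retain_threshold"] = basis.retain_threshold


def load_gif_basis(path: str | Path) -> GIFBasis:
    with h5py.File(path, "r") as f:
        return GIFBasis(
            eigenvalues=f["eigenvalues"][()],
            patterns=f["patterns"][()],
            metric_patterns=f["metric_patterns"][()],
            mean_map=f["mean_map"][()],
            residuals=f["residuals"][()],
            eps=float(f.attrs["eps"]),
            retain_threshold=float(f.attrs["retain_threshold"]),
        )
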