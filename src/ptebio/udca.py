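"""Unsupervised Diffusion Component Analysis (UDCA) for epileptiform-window
detection in multichannel EEG.

The recording is cut into 50%-overlapping windows. Each window is summarized
by its per-channel means and its channel covariance matrix; a symmetrized
local-Mahalanobis quadratic form (SVD pseudo-inverse covariances) measures
dissimilarity between windows. A Gaussian affinity kernel over these distances
is normalized and squared in two stages, eigendecomposed, and the resulting
point-cloud coordinates form candidate 3-D embeddings (all eigenvector triples
excluding the trivial leading one). The triple with the largest spread — mean
Euclidean distance of embedded points to their center of mass — is selected,
and windows far from the center of mass are flagged as outliers; on EEG with
epileptiform transients these outliers line up with the spike-bearing windows.

Out-of-sample windows are embedded with a Nystrom extension: their raw
affinity rows are pushed through the same two normalization stages and
projected on the retained eigenvectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Literal, Sequence

import numpy as np

from .errors import ArgumentError, StageError
from .io import EEGRecording

logger = logging.getLogger(__name__)


@dataclass
class UDCAConfig:
    """Pipeline parameters.

    window_size : samples per segment (even; default 400 = 2 s at 200 Hz).
    k_e : Gaussian kernel scale; the affinity is exp(-d / (4 k_e)). The
        numeric default is 10; pass the string "median" to calibrate the
        scale to the spread of the data so that the median off-diagonal
        pairwise distance maps to affinity exp(-1) (k_e = median d / 4),
        the standard bandwidth heuristic for diffusion kernels.
    svd_tol : relative singular-value cutoff for covariance pseudo-inverses.
    n_eigenvectors : retained eigenpairs (>= embed_dim + 1; the leading,
        constant eigenvector never enters an embedding).
    outlier_rule : "mad" flags scores above median + param * MAD;
        "quantile" flags the top ``param`` fraction of scores.
    """

    window_size: int = 400
    k_e: float | Literal["median"] = 10.0
    svd_tol: float = 1e-6
    n_eigenvectors: int = 8
    outlier_rule: Literal["mad", "quantile"] = "quantile"
    outlier_param: float = 0.05
    overlap_frac: float = field(default=0.5, init=False)  # fixed by the method
    embed_dim: int = field(default=3, init=False)         # fixed by the method

    def __post_init__(self) -> None:
        if isinstance(self.k_e, str):
            if self.k_e != "median":
                raise ArgumentError("k_e must be a positive number or 'median'")
        elif self.k_e <= 0:
            raise ArgumentError("k_e must be positive")
        if not (0 < self.svd_tol < 1):
            raise ArgumentError("svd_tol must be in (0, 1)")
        if self.n_eigenvectors < self.embed_dim + 1:
            raise ArgumentError("n_eigenvectors must be >= embed_dim + 1")
        if self.outlier_param <= 0:
            raise ArgumentError("outlier_param must be positive")
        if self.outlier_rule not in ("mad", "quantile"):
            raise ArgumentError(f"unknown outlier rule {self.outlier_rule!r}")


@dataclass
class SegmentSet:
    """Ordered 50%-overlapping windows with per-window summary statistics."""

    segments: np.ndarray          # (n_segments, n_channels, window_size)
    features: np.ndarray          # (n_segments, n_channels * window_size)
    covariances: np.ndarray       # (n_segments, n_channels, n_channels)
    inv_covariances: np.ndarray   # SVD pseudo-inverses of the above
    channel_means: np.ndarray     # (n_segments, n_channels)
    start_samples: np.ndarray     # first sample index of each segment
    fs: float
    t0: float
    channel_labels: list[str]

    @property
    def n_segments(self) -> int:
        return self.segments.shape[0]

    @property
    def window_size(self) -> int:
        return self.segments.shape[2]

    def start_times_s(self) -> np.ndarray:
        return self.t0 + self.start_samples / self.fs


def _pinv_svd(mat: np.ndarray, svd_tol: float) -> np.ndarray:
    """Pseudo-inverse via SVD with relative cutoff; zero matrix maps to zero."""
    u, s, vt = np.linalg.svd(mat, hermitian=True)
    if s.size == 0 or s[0] == 0:
        return np.zeros_like(mat)
    keep = s > svd_tol * s[0]
    inv_s = np.where(keep, 1.0 / np.where(keep, s, 1.0), 0.0)
    return (vt.T * inv_s) @ u.T


def segment(rec: EEGRecording, window_size: int,
            svd_tol: float = 1e-6) -> SegmentSet:
    """Cut a recording into 50%-overlapping windows of ``window_size`` samples.

    The number of segments is ``(n_samples - window_size) // (window_size/2)
    + 1``; any trailing remainder is dropped. Each segment's channel
    covariance and its SVD pseudo-inverse are precomputed.
    """
    if window_size % 2 != 0:
        raise ArgumentError("window_size must be even (half-overlap step)")
    if window_size < 2:
        raise ArgumentError("window_size must be >= 2")
    if window_size > rec.n_samples:
        raise ArgumentError(
            f"window_size {window_size} exceeds recording length {rec.n_samples}"
        )
    hop = window_size // 2
    n_seg = (rec.n_samples - window_size) // hop + 1
    starts = np.arange(n_seg) * hop
    segs = np.stack([rec.data[:, s:s + window_size] for s in starts])
    feats = segs.reshape(n_seg, -1)  # channel-major flattening
    means = segs.mean(axis=2)
    covs = np.empty((n_seg, rec.n_channels, rec.n_channels))
    invs = np.empty_like(covs)
    for i in range(n_seg):
        c = np.cov(segs[i]) if rec.n_channels > 1 else np.atleast_2d(np.var(segs[i], ddof=1))
        c = np.atleast_2d(c)
        covs[i] = c
        if not c.any():
            logger.warning("segment %d is flat; pseudo-inverse set to zero", i)
        invs[i] = _pinv_svd(c, svd_tol)
    return SegmentSet(segments=segs, features=feats, covariances=covs,
                      inv_covariances=invs, channel_means=means,
                      start_samples=starts, fs=rec.fs, t0=rec.t0,
                      channel_labels=list(rec.channel_labels))


def qc_cross_correlation(seg: SegmentSet, max_lag: int,
                         floor: float = 0.1) -> dict[tuple[str, str], float]:
    """Per-channel-pair QC: median (across segments) of the maximal
    normalized cross-correlation magnitude over lags within ``max_lag``.

    Report-only: pairs whose summary falls below ``floor`` are logged as
    warnings, never dropped. Zero-variance segments are excluded from the
    median.
    """
    if max_lag >= seg.window_size:
        raise ArgumentError("max_lag must be smaller than the window size")
    if max_lag < 0:
        raise ArgumentError("max_lag must be >= 0")
    n_seg, n_ch, w = seg.segments.shape
    center = w - 1
    sl = slice(center - max_lag, center + max_lag + 1)
    out: dict[tuple[str, str], float] = {}
    for a, b in combinations(range(n_ch), 2):
        vals = np.full(n_seg, np.nan)
        for i in range(n_seg):
            xa = seg.segments[i, a] - seg.segments[i, a].mean()
            xb = seg.segments[i, b] - seg.segments[i, b].mean()
            sa, sb = xa.std(), xb.std()
            if sa == 0 or sb == 0:
                continue  # undefined for flat traces
            cc = np.correlate(xa, xb, mode="full")[sl] / (w * sa * sb)
            vals[i] = np.abs(cc).max()
        finite = vals[np.isfinite(vals)]
        key = (seg.channel_labels[a], seg.channel_labels[b])
        out[key] = float(np.median(finite)) if finite.size else float("nan")
        if np.isfinite(out[key]) and out[key] < floor:
            logger.warning("QC: channels %s-%s show weak cross-correlation "
                           "(median max |rho| = %.3f)", key[0], key[1], out[key])
    return out


def mahalanobis_metric(seg: SegmentSet) -> np.ndarray:
    """Squared Mahalanobis quadratic form between consecutive segments.

    The difference vector is the per-channel mean difference; the metric is
    the average of the two segments' pseudo-inverse covariances. Returns a
    vector of length ``n_segments - 1``; entries are >= 0.
    """
    m = seg.channel_means
    d = np.empty(seg.n_segments - 1)
    for i in range(seg.n_segments - 1):
        diff = m[i + 1] - m[i]
        p = 0.5 * (seg.inv_covariances[i] + seg.inv_covariances[i + 1])
        d[i] = float(diff @ p @ diff)
    return np.maximum(d, 0.0)


def pairwise_mahalanobis(seg: SegmentSet) -> np.ndarray:
    """Full symmetric matrix of the quadratic form between all segment pairs.

    d(i, j) = 0.5 * [dm' P_i dm + dm' P_j dm] with dm the per-channel mean
    difference — the symmetrized local-covariance Mahalanobis metric.
    """
    m = seg.channel_means
    n = seg.n_segments
    q = np.empty((n, n))
    for i in range(n):
        diffs = m - m[i]                       # (n, c)
        q[i] = np.einsum("nc,cd,nd->n", diffs, seg.inv_covariances[i], diffs)
    d = 0.5 * (q + q.T)
    np.fill_diagonal(d, 0.0)
    return np.maximum(d, 0.0)


def affinity_kernel(d: np.ndarray, k_e: float = 10.0) -> np.ndarray:
    """Gaussian affinity A = exp(-d / (4 k_e)) applied elementwise."""
    d = np.asarray(d, dtype=float)
    if k_e <= 0:
        raise ArgumentError("k_e must be positive")
    if (d < 0).any():
        raise ArgumentError("distances must be non-negative (metric violation)")
    return np.exp(-d / (4.0 * k_e))


@dataclass
class DiffusionDecomposition:
    """Spectral objects from the two-stage normalized kernel."""

    eigenvalues: np.ndarray       # descending, length n_eigenvectors
    eigenvectors: np.ndarray      # (n, n_eigenvectors), orthonormal (W2 basis)
    point_clouds: np.ndarray      # (n, n_eigenvectors), embedding coordinates
    row_sums_j1: np.ndarray
    row_sums_j2: np.ndarray
    stage1_normalized: np.ndarray  # A1
    stage2_normalized: np.ndarray  # A2
    kernel: np.ndarray             # A


def diffusion_decomposition(a: np.ndarray,
                            n_eigenvectors: int = 8) -> DiffusionDecomposition:
    """Two-stage normalization and eigendecomposition of an affinity kernel.

    Stage s normalizes the current matrix symmetrically by the square root of
    its row sums and squares it; after two stages the operator W2 is
    symmetric positive semidefinite with leading eigenvalue 1. Point-cloud
    coordinates are the eigenvectors rescaled by 1/sqrt(row sums), so the
    leading coordinate is constant and each remaining column is a diffusion
    coordinate.
    """
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ArgumentError("kernel must be square")
    n = a.shape[0]
    if not np.allclose(a, a.T, atol=1e-10):
        raise ArgumentError("kernel must be symmetric within 1e-10")
    a = 0.5 * (a + a.T)
    if (a < 0).any() or (a > 1 + 1e-12).any():
        raise ArgumentError("kernel entries must lie in [0, 1]")
    n_eigenvectors = min(n_eigenvectors, n)

    j1 = a.sum(axis=1)
    if (j1 <= 0).any():
        raise ArgumentError("kernel has a zero row sum (isolated segment)")
    s1 = np.sqrt(j1)
    a1 = a / np.outer(s1, s1)
    w1 = a1 @ a1
    j2 = w1.sum(axis=1)
    s2 = np.sqrt(j2)
    a2 = w1 / np.outer(s2, s2)
    w2 = a2 @ a2
    w2 = 0.5 * (w2 + w2.T)

    try:
        evals, evecs = np.linalg.eigh(w2)
    except np.linalg.LinAlgError as exc:
        raise StageError("diffusion_decomposition",
                         f"eigensolver failed: {exc}") from exc
    order = np.argsort(evals)[::-1]
    evals = evals[order][:n_eigenvectors]
    evecs = evecs[:, order][:, :n_eigenvectors]
    # deterministic sign: largest-magnitude entry of each eigenvector positive
    for k in range(evecs.shape[1]):
        pivot = np.argmax(np.abs(evecs[:, k]))
        if evecs[pivot, k] < 0:
            evecs[:, k] = -evecs[:, k]
    clds = evecs / s2[:, None]
    return DiffusionDecomposition(eigenvalues=evals, eigenvectors=evecs,
                                  point_clouds=clds, row_sums_j1=j1,
                                  row_sums_j2=j2, stage1_normalized=a1,
                                  stage2_normalized=a2, kernel=a)


def nystrom_extension(affinity_rows: np.ndarray,
                      decomp: DiffusionDecomposition,
                      n_coords: int | None = None) -> np.ndarray:
    """Embed held-out points from their raw affinity rows to the training set.

    Each row is pushed through the same two normalization stages as the
    training kernel and projected on the retained eigenvectors; extending a
    training point reproduces its in-sample point-cloud coordinates. Returns
    psi with one column per retained eigenpair (column 0 is the trivial
    constant; columns 1 and 2 are the first and second diffusion coordinates).
    """
    b = np.atleast_2d(np.asarray(affinity_rows, dtype=float))
    n = decomp.kernel.shape[0]
    if b.shape[1] != n:
        raise ArgumentError(
            f"affinity rows have {b.shape[1]} columns, training set has {n}"
        )
    k_avail = decomp.eigenvalues.size
    if n_coords is None:
        n_coords = k_avail
    if n_coords > k_avail:
        raise ArgumentError(
            f"requested {n_coords} coordinates but only {k_avail} eigenpairs retained"
        )
    j1_new = b.sum(axis=1)
    dead = np.flatnonzero(j1_new <= 0)
    if dead.size:
        raise ArgumentError(
            f"held-out segment(s) {dead.tolist()} have zero affinity to the "
            "training set (infinitely far)"
        )
    b1 = b / np.sqrt(np.outer(j1_new, decomp.row_sums_j1))
    w1_rows = b1 @ decomp.stage1_normalized
    j2_new = w1_rows.sum(axis=1)
    if (j2_new <= 0).any():
        raise ArgumentError("held-out segment lost all affinity after stage 1")
    evals = decomp.eigenvalues[:n_coords]
    if (evals <= 0).any():
        raise ArgumentError(
            "cannot extend on eigenpairs with non-positive eigenvalues; "
            "request fewer coordinates"
        )
    # push through stage 2 and project on the orthonormal eigenvectors of W2;
    # for a training row this reproduces its point-cloud coordinates exactly
    s2 = np.sqrt(decomp.row_sums_j2)
    r = w1_rows / (j2_new[:, None] * s2[None, :])
    w2_rows = r @ decomp.stage2_normalized
    return (w2_rows @ decomp.eigenvectors[:, :n_coords]) / evals[None, :]


def select_embedding(point_clouds: np.ndarray
                     ) -> tuple[tuple[int, int, int], np.ndarray, float,
                                dict[tuple[int, int, int], float]]:
    """Choose the 3-D embedding with maximal spread.

    Candidates are all triples of point-cloud columns excluding the trivial
    leading column (0-based index 0). Spread is the mean Euclidean distance of
    embedded points to their center of mass; ties break to the
    lexicographically smallest triple. Returns (triple, coordinates, spread,
    spread per candidate).
    """
    n_eig = point_clouds.shape[1]
    if n_eig < 4:
        raise ArgumentError("need at least 4 retained eigenvectors")
    spreads: dict[tuple[int, int, int], float] = {}
    best: tuple[int, int, int] | None = None
    best_spread = -1.0
    for triple in combinations(range(1, n_eig), 3):
        coords = point_clouds[:, triple]
        spread = embedding_spread(coords)
        spreads[triple] = spread
        if spread > best_spread:
            best, best_spread = triple, spread
    assert best is not None
    return best, point_clouds[:, best], best_spread, spreads


def embedding_spread(coords: np.ndarray) -> float:
    """Mean Euclidean distance of points to their center of mass."""
    center = coords.mean(axis=0)
    return float(np.linalg.norm(coords - center, axis=1).mean())


def outlier_scores(coords: np.ndarray,
                   rule: Literal["mad", "quantile"] = "quantile",
                   param: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Distance-from-center outlier scores and boolean flags.

    mad rule: flag scores above median + param * MAD (median absolute
    deviation). quantile rule: flag the top ``round(param * n)`` scores.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < 3:
        raise ArgumentError("need at least 3 embedded points")
    if param <= 0:
        raise ArgumentError("param must be positive")
    center = coords.mean(axis=0)
    scores = np.linalg.norm(coords - center, axis=1)
    flags = np.zeros(scores.size, dtype=bool)
    if rule == "mad":
        med = np.median(scores)
        mad = np.median(np.abs(scores - med))
        flags = scores > med + param * mad
    elif rule == "quantile":
        k = int(round(param * scores.size))
        if k > 0:
            top = np.argsort(-scores, kind="stable")[:k]
            flags[top] = True
    else:
        raise ArgumentError(f"unknown outlier rule {rule!r}")
    return scores, flags


@dataclass
class UDCAResult:
    """Everything the pipeline computes, window-aligned to the recording."""

    config: UDCAConfig
    segment_set: SegmentSet
    distances: np.ndarray                 # consecutive-segment quadratic forms
    pairwise_distances: np.ndarray
    kernel: np.ndarray
    decomposition: DiffusionDecomposition
    psi: np.ndarray                       # Nystrom self-extension of training rows
    embeddings: dict[tuple[int, int, int], float]   # triple -> spread
    selected_embedding: tuple[int, int, int]
    selected_coords: np.ndarray
    selected_spread: float
    outlier_scores: np.ndarray
    outlier_flags: np.ndarray
    qc: dict[tuple[str, str], float]
    window_start_s: np.ndarray
    k_e_used: float = 10.0

    @property
    def eigenvalues(self) -> np.ndarray:
        return self.decomposition.eigenvalues

    def flagged_times_s(self) -> np.ndarray:
        return self.window_start_s[self.outlier_flags]


def run_udca(rec: EEGRecording, cfg: UDCAConfig | None = None) -> UDCAResult:
    """Run the full pipeline: segment, QC, metric, kernel, decomposition,
    embedding selection, and outlier flagging. Deterministic given inputs."""
    cfg = cfg or UDCAConfig()

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except ArgumentError:
            raise
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError(name, str(exc)) from exc

    seg = stage("segment", segment, rec, cfg.window_size, cfg.svd_tol)
    min_seg = cfg.embed_dim + 2
    if seg.n_segments < min_seg:
        raise ArgumentError(
            f"recording yields {seg.n_segments} segments; need >= {min_seg}"
        )
    qc = stage("qc_cross_correlation", qc_cross_correlation, seg,
               max_lag=min(cfg.window_size // 4, seg.window_size - 1))
    consec = stage("mahalanobis_metric", mahalanobis_metric, seg)
    pair_d = stage("pairwise_mahalanobis", pairwise_mahalanobis, seg)
    if cfg.k_e == "median":
        off_diag = pair_d[~np.eye(pair_d.shape[0], dtype=bool)]
        pos = off_diag[off_diag > 0]
        k_e = float(np.median(pos)) / 4.0 if pos.size else 1.0
        logger.info("kernel scale calibrated to median pairwise distance: "
                    "k_e = %.4g", k_e)
    else:
        k_e = float(cfg.k_e)
    kernel = stage("affinity_kernel", affinity_kernel, pair_d, k_e)
    decomp = stage("diffusion_decomposition", diffusion_decomposition,
                   kernel, cfg.n_eigenvectors)
    psi = stage("nystrom_extension", nystrom_extension, kernel, decomp)
    triple, coords, spread, spreads = stage("select_embedding",
                                            select_embedding,
                                            decomp.point_clouds)
    scores, flags = stage("outlier_scores", outlier_scores, coords,
                          cfg.outlier_rule, cfg.outlier_param)
    times = seg.start_times_s()
    logger.info("UDCA: %d segments, selected eigenvector triple %s "
                "(spread %.4g), %d window(s) flagged at %s",
                seg.n_segments, triple, spread, int(flags.sum()),
                ", ".join(f"{t:.1f}s" for t in times[flags]) or "none")
    return UDCAResult(config=cfg, segment_set=seg, distances=consec,
                      pairwise_distances=pair_d, kernel=kernel,
                      decomposition=decomp, psi=psi, embeddings=spreads,
                      selected_embedding=triple, selected_coords=coords,
                      selected_spread=spread, outlier_scores=scores,
                      outlier_flags=flags, qc=qc, window_start_s=times,
                      k_e_used=k_e)
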