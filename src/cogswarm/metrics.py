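"""Quantification of emergent structure: phase order, reward-centered phase
rings, capture statistics, spatial coverage and cluster decomposition.

The source phenomena are visual (phase-sorted rings, line segments, locked
subgroups); here they are operationalized as scalar statistics with stated
ranges so structure claims become testable: the Kuramoto order parameter for
global synchrony, a Fisher-Lee circular-circular correlation between bearing
and phase for rings, connected components of the visibility graph for
clusters, and the dispersion of per-agent phase velocities for frequency
locking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .geometry import Arena

__all__ = [
    "kuramoto_order",
    "ring_phase_score",
    "ring_phase_test",
    "CaptureStats",
    "capture_statistics",
    "coverage",
    "cluster_decomposition",
    "frequency_locking",
    "collinearity",
    "structure_report",
]


def kuramoto_order(theta) -> float:
    """Magnitude of the mean unit phasor: 1 for identical phases, ~0 for
    incoherent phases."""
    theta = np.asarray(theta, dtype=np.float64)
    if theta.size == 0:
        raise ValueError("kuramoto_order needs at least one phase")
    return float(np.abs(np.exp(1j * theta).mean()))


def _fisher_lee(a: np.ndarray, b: np.ndarray) -> float:
    """Fisher-Lee circular-circular correlation between angle samples."""
    da = a[:, None] - a[None, :]
    db = b[:, None] - b[None, :]
    iu = np.triu_indices(len(a), k=1)
    sa = np.sin(da[iu])
    sb = np.sin(db[iu])
    den = np.sqrt((sa**2).sum() * (sb**2).sum())
    if den == 0.0:
        return 0.0
    return float((sa * sb).sum() / den)


def ring_phase_score(x, theta, center, r_min: float, r_max: float):
    """Circular correlation between bearing from ``center`` and phase over
    agents inside the annulus [r_min, r_max]; 1 for a perfectly phase-sorted
    ring, -1 for reverse sorting. Returns None for fewer than 4 members."""
    x = np.asarray(x, dtype=np.float64)
    theta = np.asarray(theta, dtype=np.float64)
    center = np.asarray(center, dtype=np.float64)
    d = np.linalg.norm(x - center, axis=1)
    sel = (d >= r_min) & (d <= r_max)
    if int(sel.sum()) < 4:
        return None
    phi = np.arctan2(x[sel, 1] - center[1], x[sel, 0] - center[0])
    return _fisher_lee(phi, theta[sel])


def ring_phase_test(
    x, theta, center, r_min: float, r_max: float, n_perm: int = 999, seed: int = 0
):
    """Ring score plus a permutation p-value for |score| under phase
    shuffling within the annulus. Returns (score, p) or (None, None)."""
    x = np.asarray(x, dtype=np.float64)
    theta = np.asarray(theta, dtype=np.float64)
    center = np.asarray(center, dtype=np.float64)
    d = np.linalg.norm(x - center, axis=1)
    sel = (d >= r_min) & (d <= r_max)
    if int(sel.sum()) < 4:
        return None, None
    phi = np.arctan2(x[sel, 1] - center[1], x[sel, 0] - center[0])
    th = theta[sel]
    score = _fisher_lee(phi, th)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if abs(_fisher_lee(phi, rng.permutation(th))) >= abs(score):
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return score, p


@dataclass(frozen=True)
class CaptureStats:
    """Per-reward first-contact times (None if never captured) and the
    all-rewards success flag."""

    times: dict
    success: bool


def capture_statistics(record) -> CaptureStats:
    """First capture time per reward from a run record's capture events."""
    times: dict = {rid: None for rid in record.reward_ids}
    for _, ev in record.captures.iterrows():
        rid = record.reward_ids[int(ev["reward"])]
        t = float(ev["time"])
        if times[rid] is None or t < times[rid]:
            times[rid] = t
    success = bool(times) and all(v is not None for v in times.values())
    return CaptureStats(times=times, success=success)


def _allowable_cells(arena: Arena, cell_size: float):
    xmin, ymin, xmax, ymax = arena.bounds
    nx = max(1, int(np.ceil((xmax - xmin) / cell_size)))
    ny = max(1, int(np.ceil((ymax - ymin) / cell_size)))
    cx = xmin + (np.arange(nx) + 0.5) * cell_size
    cy = ymin + (np.arange(ny) + 0.5) * cell_size
    XX, YY = np.meshgrid(cx, cy, indexing="ij")
    centers = np.column_stack([XX.ravel(), YY.ravel()])
    ok = arena.points_allowable(centers).reshape(nx, ny)
    return (xmin, ymin, nx, ny), ok


def coverage(record, arena: Arena, cell_size: float = 25.0) -> float:
    """Fraction of allowable grid cells visited by any recorded agent
    position."""
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    (xmin, ymin, nx, ny), ok = _allowable_cells(arena, cell_size)
    pts = record.x.reshape(-1, 2)
    ix = np.clip(((pts[:, 0] - xmin) / cell_size).astype(int), 0, nx - 1)
    iy = np.clip(((pts[:, 1] - ymin) / cell_size).astype(int), 0, ny - 1)
    visited = np.zeros((nx, ny), dtype=bool)
    visited[ix, iy] = True
    n_allow = int(ok.sum())
    if n_allow == 0:
        return 0.0
    return float((visited & ok).sum() / n_allow)


def cluster_decomposition(x, V) -> np.ndarray:
    """Connected components of the visibility graph as cluster labels."""
    V = np.asarray(V)
    _, labels = connected_components(csr_matrix(V > 0), directed=False)
    return labels


def frequency_locking(theta_history, labels, dt: float) -> dict:
    """Std of per-agent mean phase velocity within each cluster (rad/s);
    0 means a perfect frequency lock."""
    th = np.asarray(theta_history, dtype=np.float64)
    if th.shape[0] < 2:
        raise ValueError("need at least two recorded frames")
    dth = np.angle(np.exp(1j * np.diff(th, axis=0)))  # wrapped to (-pi, pi]
    omega = dth.mean(axis=0) / dt
    return {
        int(lab): float(np.std(omega[labels == lab]))
        for lab in np.unique(labels)
    }


def collinearity(x) -> float:
    """Line-formation statistic: 1 - lambda2/lambda1 of the positional
    covariance eigenvalues (1 for perfectly collinear points). Reported for
    inspection; not an acceptance statistic."""
    x = np.asarray(x, dtype=np.float64)
    if len(x) < 3:
        return 0.0
    ev = np.linalg.eigvalsh(np.cov(x.T))
    if ev[-1] <= 0:
        return 0.0
    return float(1.0 - ev[0] / ev[-1])


def structure_report(
    record,
    arena: Arena,
    annulus: tuple[float, float] = (0.0, 0.15),
    cell_size: float = 25.0,
) -> pd.DataFrame:
    """Per-frame structure time series: Kuramoto order, per-reward ring
    scores over the annulus (fractions of the notional radius), cumulative
    coverage and visibility-cluster count."""
    R = arena.notional_radius
    r_min, r_max = annulus[0] * R, annulus[1] * R
    (xmin, ymin, nx, ny), ok = _allowable_cells(arena, cell_size)
    visited = np.zeros((nx, ny), dtype=bool)
    n_allow = max(1, int(ok.sum()))
    rows = []
    for f, t in enumerate(record.times):
        pos = record.x_s[f] if record.mode == "single" else record.x[f]
        row = {"time": float(t), "kuramoto_r": kuramoto_order(record.theta[f])}
        for k, rid in enumerate(record.reward_ids):
            row[f"ring_{rid}"] = ring_phase_score(
                pos, record.theta[f], arena.reward_xy[k], r_min, r_max
            )
        pts = record.x[f]
        ix = np.clip(((pts[:, 0] - xmin) / cell_size).astype(int), 0, nx - 1)
        iy = np.clip(((pts[:, 1] - ymin) / cell_size).astype(int), 0, ny - 1)
        visited[ix, iy] = True
        row["coverage"] = float((visited & ok).sum() / n_allow)
        row["collinearity"] = collinearity(pos)
        rows.append(row)
    return pd.DataFrame(rows)
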