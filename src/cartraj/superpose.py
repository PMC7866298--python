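"""Rigid-body superposition and fluctuation statistics.

Implements least-squares (Kabsch) superposition via SVD, with a batched
variant used for the all-pairs RMS2D matrix, plus the derived statistics:
RMSD time series against a first-frame or trajectory-average reference, the
iterated average structure, per-residue RMSF about the average structure and
the pooled pairwise 2D-RMSD matrix.

Superposition is unweighted by default (every selected atom weight 1);
mass-weighting is available through the ``weights`` arguments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_model import Trajectory, Topology
from .selections import AtomSelection, selection_for_rule


@dataclass(frozen=True)
class FitResult:
    rotation: np.ndarray      # (3, 3), proper: det = +1
    translation: np.ndarray   # (3,): x -> x @ R.T + t maps mobile onto reference
    rmsd: float               # Å, at the optimum


def _as_weights(weights, n: int) -> np.ndarray:
    if weights is None:
        return np.ones(n)
    w = np.asarray(weights, dtype=float)
    if w.shape != (n,):
        raise ValueError("weights must be one value per atom")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    return w


def kabsch_fit(mobile: np.ndarray, reference: np.ndarray,
               weights=None) -> FitResult:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns the proper rotation (det = +1), translation and the minimal
    weighted RMSD over all rigid motions.  Requires at least three
    non-collinear reference atoms.
    """
    a = np.asarray(mobile, dtype=float)
    b = np.asarray(reference, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("mobile and reference must both be (n_atoms, 3)")
    n = a.shape[0]
    if n < 3:
        raise ValueError("superposition requires at least 3 atoms")
    w = _as_weights(weights, n)
    wsum = w.sum()
    ac = a - (w[:, None] * a).sum(0) / wsum
    bc = b - (w[:, None] * b).sum(0) / wsum
    # collinearity check on the reference: rank of centered coordinates
    if np.linalg.matrix_rank(bc, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) reference geometry")
    cov = (w[:, None] * ac).T @ bc
    u, s, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(u @ vt))
    rot = (u * np.array([1.0, 1.0, d])) @ vt  # maps mobile -> reference frame
    rot = rot.T  # convention: x @ rot.T rotates mobile coordinates
    b_cent = (w[:, None] * b).sum(0) / wsum
    a_cent = (w[:, None] * a).sum(0) / wsum
    trans = b_cent - a_cent @ rot.T
    # direct evaluation avoids the cancellation of the E0 - 2*trace formula
    msd = (w * ((a @ rot.T + trans - b) ** 2).sum(-1)).sum() / wsum
    return FitResult(rot, trans, float(np.sqrt(msd)))


def rmsd_plain(a: np.ndarray, b: np.ndarray, weights=None) -> float:
    """RMSD without superposition: sqrt of the weighted mean squared
    deviation between two coordinate sets as given."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("coordinate sets must have identical shapes")
    w = _as_weights(weights, a.shape[0])
    return float(np.sqrt((w * ((a - b) ** 2).sum(-1)).sum() / w.sum()))


def apply_fit(coords: np.ndarray, fit: FitResult) -> np.ndarray:
    return np.asarray(coords, dtype=float) @ fit.rotation.T + fit.translation


def superpose_frames(coords: np.ndarray, reference: np.ndarray,
                     fit_indices: np.ndarray, weights=None) -> np.ndarray:
    """Superpose every frame onto ``reference`` using the fit atoms; the
    returned array has all atoms transformed."""
    out = np.empty_like(coords, dtype=float)
    for f in range(coords.shape[0]):
        fit = kabsch_fit(coords[f, fit_indices], reference, weights)
        out[f] = apply_fit(coords[f], fit)
    return out


def pairwise_rmsd_matrix(frames: np.ndarray, weights=None) -> np.ndarray:
    """Best-fit RMSD between all frame pairs of a (n_frames, n_atoms, 3)
    stack, via batched 3x3 SVDs."""
    x = np.asarray(frames, dtype=float)
    n_frames, n_atoms = x.shape[0], x.shape[1]
    if n_frames < 2:
        raise ValueError("pairwise RMSD needs at least 2 frames")
    if n_atoms < 3:
        raise ValueError("superposition requires at least 3 atoms")
    w = _as_weights(weights, n_atoms)
    wsum = w.sum()
    xc = x - (w[None, :, None] * x).sum(1, keepdims=True) / wsum
    xw = w[None, :, None] * xc
    norms = (xw * xc).sum((1, 2))  # weighted squared norms per frame
    mat = np.zeros((n_frames, n_frames))
    for i in range(n_frames - 1):
        cov = np.einsum("aj,nak->njk", xw[i], xc[i + 1:])
        s = np.linalg.svd(cov, compute_uv=False)
        det = np.linalg.det(cov)
        traces = s[:, 0] + s[:, 1] + np.where(det < 0, -s[:, 2], s[:, 2])
        msd = np.maximum(norms[i] + norms[i + 1:] - 2.0 * traces, 0.0) / wsum
        mat[i, i + 1:] = np.sqrt(msd)
    return mat + mat.T


def average_structure(traj: Trajectory, sel: AtomSelection,
                      weights=None, tol: float = 1e-6,
                      max_iter: int = 50) -> np.ndarray:
    """Iterated average structure over the selection.

    Frames are superposed onto the first frame and averaged; superposition is
    then iterated onto the running average until it moves by less than
    ``tol`` Å (max atom displacement).
    """
    if traj.n_frames < 2:
        raise ValueError("average structure needs at least 2 frames")
    idx = sel.indices
    frames = traj.coords[:, idx]
    ref = frames[0]
    avg = None
    for _ in range(max_iter):
        fitted = np.empty_like(frames)
        for f in range(frames.shape[0]):
            fitted[f] = apply_fit(frames[f], kabsch_fit(frames[f], ref, weights))
        new_avg = fitted.mean(0)
        if avg is not None and np.abs(new_avg - avg).max() < tol:
            avg = new_avg
            break
        avg = new_avg
        ref = avg
    return avg


def rmsd_series(traj: Trajectory, sel: AtomSelection,
                reference: str = "first", weights=None) -> pd.DataFrame:
    """Per-frame best-fit RMSD on the selection.

    ``reference`` is ``"first"`` (the first production frame) or
    ``"average"`` (the iterated trajectory-average structure).
    """
    idx = sel.indices
    if reference == "first":
        ref = traj.coords[0, idx]
    elif reference == "average":
        ref = average_structure(traj, sel, weights)
    else:
        raise ValueError("reference must be 'first' or 'average'")
    values = np.array([
        kabsch_fit(traj.coords[f, idx], ref, weights).rmsd
        for f in range(traj.n_frames)
    ])
    return pd.DataFrame({"time_ns": traj.times, "rmsd_A": values,
                         "reference": reference, "rule": sel.rule})


def rmsf(traj: Trajectory, topology: Topology, residues, rule: str = "core",
         fit_selection: AtomSelection | None = None,
         methylarginine_aliases=None, weights=None) -> pd.DataFrame:
    """Per-residue RMSF about the average structure.

    All frames are superposed onto the iterated average structure over the
    union selection (default: the given residues under ``rule``); the atomic
    RMSF is sqrt(mean_t |r_a(t) - mean r_a|^2) and the residue value is the
    unweighted mean of its selected atoms' RMSFs (cpptraj ``byres``
    convention).

    ``residues`` maps labels to residue keys (dict) or is a list of residue
    keys (labelled by chain/number).
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    if isinstance(residues, dict):
        labels, keys = list(residues), list(residues.values())
    else:
        keys = [(str(c), int(n)) for c, n in
                (r.key if hasattr(r, "key") else r for r in residues)]
        labels = [f"{c}/{n}" for c, n in keys]
    per_res_sel = [
        selection_for_rule(topology, [k], rule, methylarginine_aliases)
        for k in keys
    ]
    if fit_selection is None:
        all_idx = np.unique(np.concatenate([s.indices for s in per_res_sel]))
        fit_selection = AtomSelection(all_idx, rule, tuple(keys))
    avg = average_structure(traj, fit_selection, weights)
    fitted = superpose_frames(traj.coords, avg, fit_selection.indices, weights)
    mean_pos = fitted.mean(0)
    atomic = np.sqrt(((fitted - mean_pos) ** 2).sum(-1).mean(0))
    rows = []
    for label, key, s in zip(labels, keys, per_res_sel):
        rows.append({"role": label, "chain": key[0], "res_number": key[1],
                     "rule": rule, "rmsf_A": float(atomic[s.indices].mean())})
    return pd.DataFrame(rows)


@dataclass
class Rms2dMatrix:
    """Pairwise best-fit RMSD over pooled frames, with frame provenance."""

    values: np.ndarray                    # (n, n), symmetric, zero diagonal
    trajectory_ids: np.ndarray            # (n,) pooled-frame provenance
    times: np.ndarray                     # (n,) frame times within replicate
    rule: str = "custom"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("RMS2D matrix must be square")
        if np.any(v < 0) or not np.allclose(v, v.T, atol=1e-9) or \
                np.any(np.abs(np.diag(v)) > 1e-9):
            raise ValueError("RMS2D matrix must be symmetric, non-negative, "
                             "with zero diagonal")


def rms2d(trajectories: list[Trajectory], sel: AtomSelection,
          weights=None, rule: str | None = None) -> Rms2dMatrix:
    """Pool frames across replicates and compute all-pairs best-fit RMSD."""
    if not trajectories:
        raise ValueError("rms2d needs at least one trajectory")
    frames = np.concatenate([t.coords[:, sel.indices] for t in trajectories])
    if frames.shape[0] < 2:
        raise ValueError("rms2d needs at least 2 pooled frames")
    ids = np.concatenate([np.full(t.n_frames, i)
                          for i, t in enumerate(trajectories)])
    times = np.concatenate([t.times for t in trajectories])
    mat = pairwise_rmsd_matrix(frames, weights)
    return Rms2dMatrix(mat, ids, times, rule or sel.rule)


def equilibration_time(series: pd.DataFrame, window_ns: float = 10.0,
                       tol: float = 0.2) -> float:
    """Earliest time t such that the running mean of the RMSD over
    ``[t, t+window]`` changes by less than ``tol`` Å for all later windows;
    ``inf`` if the series never settles.

    A diagnostic only — the analysis applies the configured cutoff (default
    20 ns) regardless.
    """
    times = np.asarray(series["time_ns"], dtype=float)
    values = np.asarray(series["rmsd_A"], dtype=float)
    if times[-1] - times[0] <= window_ns:
        raise ValueError("series must be longer than the window")
    starts = times[times <= times[-1] - window_ns]
    means = np.array([
        values[(times >= t0) & (times <= t0 + window_ns)].mean()
        for t0 in starts
    ])
    # A settled verdict needs at least one full window of later window-starts;
    # otherwise the tail window alone would trivially qualify on any series.
    for k, t0 in enumerate(starts):
        if t0 > times[-1] - 2.0 * window_ns:
            break
        if np.all(np.abs(means[k:] - means[k]) < tol):
            return float(t0)
    return float("inf")
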