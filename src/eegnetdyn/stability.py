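"""Quasi-stable network detection via inter-epoch matrix distances.

The change between the functional networks of consecutive epochs is
summarized by the entrywise L1 distance ("edit distance")

    dist(S1, S2) = sum_ij |S1_ij - S2_ij|,

optionally by the L2 (Frobenius) distance or by one minus the normalized
cosine similarity of the flattened matrices.  A transition is *stable* when
its distance falls more than two standard deviations below the mean of a
null distribution built from one of two surrogate constructions:

* ``matrix_randomization`` — every connectivity matrix is randomized by a
  degree- and strength-preserving weighted rewiring (sign classes handled
  separately), and distances between consecutive randomized matrices are
  pooled.
* ``temporal_shift`` — surrogate recordings are made by deleting a random
  prefix (0–5 s) independently from every channel and trimming to a fixed
  30 s, destroying cross-channel alignment while preserving each channel's
  autostructure; the whole connectivity stage is re-run on the surrogates.

Maximal runs of stable transitions become :class:`StablePeriod` objects:
a run of ``k`` stable transitions spans ``k + 1`` epochs and its averaged
network is the entrywise mean of the spanned epochs' matrices.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .datatypes import (
    ConnectivityMatrix,
    DistanceVector,
    MultichannelRecording,
    NullDistribution,
    StablePeriod,
    as_weights,
)

__all__ = [
    "edit_distance",
    "alt_distance",
    "matrix_distance",
    "distance_vector",
    "randomize_network",
    "temporal_shift_null",
    "build_null_distribution",
    "stability_threshold",
    "detect_stable_periods",
]


def _pair(S1, S2) -> tuple[np.ndarray, np.ndarray]:
    A, B = as_weights(S1), as_weights(S2)
    if A.shape != B.shape:
        raise ValueError(f"matrix shapes differ: {A.shape} vs {B.shape}")
    return A, B


def edit_distance(S1, S2) -> float:
    """Entrywise L1 distance between two equally sized matrices."""
    A, B = _pair(S1, S2)
    return float(np.abs(A - B).sum())


def alt_distance(S1, S2, metric: str) -> float:
    """Alternative inter-matrix distances: ``l2`` or ``cosine``.

    ``l2`` is the Frobenius distance; ``cosine`` is one minus the normalized
    inner product of the flattened matrices (range [0, 2]), undefined for a
    zero matrix.
    """
    A, B = _pair(S1, S2)
    if metric == "l2":
        return float(np.sqrt(((A - B) ** 2).sum()))
    if metric == "cosine":
        na = np.linalg.norm(A)
        nb = np.linalg.norm(B)
        if na == 0 or nb == 0:
            raise ValueError("cosine distance undefined for a zero matrix")
        return float(1.0 - (A * B).sum() / (na * nb))
    raise ValueError(f"unknown metric {metric!r}")


def matrix_distance(S1, S2, metric: str = "l1") -> float:
    if metric == "l1":
        return edit_distance(S1, S2)
    return alt_distance(S1, S2, metric)


def distance_vector(matrices: Sequence, metric: str = "l1") -> DistanceVector:
    """Distances between consecutive matrices of one epoch sequence."""
    if len(matrices) < 2:
        raise ValueError("need at least 2 matrices")
    vals = [matrix_distance(matrices[k], matrices[k + 1], metric) for k in range(len(matrices) - 1)]
    return DistanceVector(np.asarray(vals), metric=metric)


# ---------------------------------------------------------------------------
# Null model 1: degree/strength-preserving matrix randomization
# ---------------------------------------------------------------------------

def _rewire(W: np.ndarray, n_sweeps: int, rng: np.random.Generator) -> np.ndarray:
    """Degree-preserving double-edge swaps on the (signed) weighted graph.

    Weights travel with their edges, so the weight multiset and every node's
    binary degree are conserved exactly.  ``n_sweeps`` × E swap attempts.
    """
    W = W.copy()
    iu, ju = np.where(np.triu(W, 1) != 0)
    E = len(iu)
    if E < 2:
        return W
    edges = list(zip(iu.tolist(), ju.tolist()))
    for _ in range(n_sweeps * E):
        e1, e2 = rng.choice(E, size=2, replace=False)
        a, b = edges[e1]
        c, d = edges[e2]
        if rng.random() < 0.5:
            c, d = d, c
        if len({a, b, c, d}) < 4:
            continue
        if W[a, d] != 0 or W[c, b] != 0:
            continue
        wab, wcd = W[a, b], W[c, d]
        W[a, b] = W[b, a] = 0.0
        W[c, d] = W[d, c] = 0.0
        W[a, d] = W[d, a] = wab
        W[c, b] = W[b, c] = wcd
        edges[e1] = (min(a, d), max(a, d))
        edges[e2] = (min(c, b), max(c, b))
    return W


def _assign_weights(
    W0: np.ndarray,
    magnitudes: np.ndarray,
    iu: np.ndarray,
    ju: np.ndarray,
    strengths: np.ndarray,
    sign: float,
    rng: np.random.Generator,
) -> None:
    """Strength-matched rank reassignment of one sign class's weights.

    Repeatedly picks a random unassigned edge, ranks its expected weight
    (product of the endpoints' residual strengths) among the remaining
    edges, and gives it the remaining weight magnitude of the same rank;
    residual strengths are decremented after every assignment.  This
    conserves the weight multiset exactly and tracks each node's strength
    closely.
    """
    weights = np.sort(magnitudes)  # ascending
    alive_w = np.ones(len(weights), dtype=bool)
    alive_e = np.ones(len(iu), dtype=bool)
    S = strengths.astype(float).copy()
    for _ in range(len(iu)):
        e_idx = np.where(alive_e)[0]
        pick = e_idx[rng.integers(len(e_idx))]
        P = S[iu[e_idx]] * S[ju[e_idx]]
        rank = int(np.sum(P < P[e_idx == pick][0]))  # rank among remaining
        w_idx = np.where(alive_w)[0]
        rank = min(rank, len(w_idx) - 1)
        w = weights[w_idx[rank]]
        i, j = int(iu[pick]), int(ju[pick])
        W0[i, j] = W0[j, i] = sign * w
        S[i] -= w
        S[j] -= w
        alive_e[pick] = False
        alive_w[w_idx[rank]] = False


def randomize_network(
    S: "ConnectivityMatrix | np.ndarray",
    seed: "int | np.random.Generator" = 0,
    n_sweeps: int = 5,
) -> ConnectivityMatrix:
    """Randomize a signed weighted undirected network, preserving the weight
    multiset and binary degree sequence exactly and per-node strengths
    approximately.

    Positive and negative edges form separate sign classes.  The binary
    topology is first randomized by degree-preserving double-edge swaps
    (skipped when the graph is complete, where no rewiring is possible);
    each sign class's weight magnitudes are then reassigned to its edges by
    the rank-based strength-matching procedure of
    :func:`_assign_weights`.
    """
    W = as_weights(S).copy()
    n = W.shape[0]
    if not np.allclose(W, W.T):
        raise ValueError("input must be symmetric")
    np.fill_diagonal(W, 0.0)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n_offdiag = n * (n - 1)
    if np.count_nonzero(W) < n_offdiag:
        W_r = _rewire(W, n_sweeps, rng)
    else:
        W_r = W  # complete graph: topology is fixed
    W0 = np.zeros_like(W)
    for sign in (1.0, -1.0):
        A = (W * sign) > 0
        A_r = (W_r * sign) > 0
        if not A.any():
            continue
        iu_o, ju_o = np.where(np.triu(A, 1))
        strengths = (np.abs(W) * A).sum(axis=1)
        iu, ju = np.where(np.triu(A_r, 1))
        _assign_weights(W0, np.abs(W[iu_o, ju_o]), iu, ju, strengths, sign, rng)
    epoch_index = S.epoch_index if isinstance(S, ConnectivityMatrix) else 0
    return ConnectivityMatrix(W0, epoch_index=epoch_index)


# ---------------------------------------------------------------------------
# Null model 2: per-channel temporal shifts
# ---------------------------------------------------------------------------

def temporal_shift_null(
    recording: MultichannelRecording,
    seed: "int | np.random.Generator" = 0,
    max_delete: float = 5.0,
    final_length: float = 30.0,
) -> MultichannelRecording:
    """Surrogate recording with randomized per-channel start times.

    For every channel independently, a start coordinate ``n`` is drawn
    uniformly from ``1 .. max_delete*fs`` (1-based; 2560 at 512 Hz with the
    default 5 s) and the channel is taken to begin there; all channels are
    then trimmed to exactly ``final_length`` seconds.  Shifts are applied
    per channel (a common shift would leave the network structure intact,
    defeating the purpose of the surrogate).
    """
    fs = recording.fs
    n_final = int(round(final_length * fs))
    n_max = int(round(max_delete * fs))
    if recording.n_samples < n_max + n_final:
        raise ValueError(
            f"recording of {recording.n_samples} samples too short for "
            f"max_delete={max_delete}s + final_length={final_length}s at {fs} Hz"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = np.empty((recording.n_channels, n_final))
    for ch in range(recording.n_channels):
        start_1based = int(rng.integers(1, n_max + 1)) if n_max > 0 else 1
        s0 = start_1based - 1
        out[ch] = recording.samples[ch, s0 : s0 + n_final]
    return MultichannelRecording(
        out,
        fs=fs,
        channel_labels=list(recording.channel_labels),
        condition=recording.condition,
    )


# ---------------------------------------------------------------------------
# Null distribution, threshold, stable periods
# ---------------------------------------------------------------------------

def build_null_distribution(
    inputs: Sequence,
    model: str,
    metric: str = "l1",
    n_replicates: int = 100,
    seed: int = 0,
    condition: Optional[str] = None,
    epoch_length: Optional[float] = None,
    max_lag: Optional[int] = None,
    max_delete: float = 5.0,
    final_length: float = 30.0,
) -> NullDistribution:
    """Pool surrogate inter-matrix distances across subjects of one condition.

    For ``matrix_randomization``, ``inputs`` is a list of per-subject
    connectivity-matrix sequences; every replicate randomizes each sequence's
    matrices and collects consecutive distances.  For ``temporal_shift``,
    ``inputs`` is a list of per-subject recordings; every replicate re-runs
    epoching (consecutive, ``epoch_length``) and the connectivity stage on
    freshly shifted surrogates.  The pooled sample list defines the null
    mean and SD from which the stability threshold is derived.
    """
    if not inputs:
        raise ValueError("no inputs")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    dists: list[float] = []
    if model == "matrix_randomization":
        for seq in inputs:
            if len(seq) < 2:
                raise ValueError("each matrix sequence needs at least 2 matrices")
        for _ in range(n_replicates):
            for seq in inputs:
                randomized = [randomize_network(m, seed=rng) for m in seq]
                dists.extend(distance_vector(randomized, metric).values)
    elif model == "temporal_shift":
        from .connectivity import connectivity_matrix
        from .preprocess import epoch_recording

        if epoch_length is None:
            raise ValueError("temporal_shift null requires epoch_length")
        for _ in range(n_replicates):
            for rec in inputs:
                surrogate = temporal_shift_null(
                    rec, seed=rng, max_delete=max_delete, final_length=final_length
                )
                epochs = epoch_recording(surrogate, epoch_length=epoch_length)
                if len(epochs) < 2:
                    raise ValueError("surrogate yields fewer than 2 epochs")
                mats = [
                    connectivity_matrix(ep, max_lag=max_lag, epoch_index=k)[0]
                    for k, ep in enumerate(epochs)
                ]
                dists.extend(distance_vector(mats, metric).values)
    else:
        raise ValueError(f"unknown null model {model!r}")
    return NullDistribution(np.asarray(dists), model=model, metric=metric, condition=condition)


def stability_threshold(null: NullDistribution) -> float:
    """Stability cutoff: two standard deviations below the null mean.

    May be negative for L1/L2 distances, in which case no transition can be
    stable.
    """
    if len(null.samples) < 2:
        raise ValueError("null distribution needs at least 2 samples")
    return null.mean - 2.0 * null.sd


def detect_stable_periods(
    distances: "DistanceVector | np.ndarray",
    threshold: float,
    epoch_length: float,
    matrices: Sequence,
) -> list[StablePeriod]:
    """Segment maximal runs of stable transitions into quasi-stable periods.

    Transition ``t`` (between epochs ``t`` and ``t+1``) is stable iff
    ``distances[t] < threshold`` (strict).  A maximal run of ``k`` stable
    transitions spans ``k + 1`` epochs, has duration ``(k+1) * epoch_length``
    seconds, and its averaged network is the entrywise mean of the spanned
    epochs' matrices.
    """
    vals = distances.values if isinstance(distances, DistanceVector) else np.asarray(distances)
    if len(vals) != len(matrices) - 1:
        raise ValueError("distance count must be one less than matrix count")
    stable = vals < threshold
    periods: list[StablePeriod] = []
    t = 0
    while t < len(stable):
        if not stable[t]:
            t += 1
            continue
        run_start = t
        while t < len(stable) and stable[t]:
            t += 1
        start_epoch, end_epoch = run_start, t  # t == last stable transition + 1
        member = [as_weights(matrices[k]) for k in range(start_epoch, end_epoch + 1)]
        avg = ConnectivityMatrix(np.mean(member, axis=0), epoch_index=start_epoch)
        periods.append(
            StablePeriod(
                start_epoch=start_epoch,
                end_epoch=end_epoch,
                duration=(end_epoch - start_epoch + 1) * epoch_length,
                averaged_network=avg,
            )
        )
    return periods
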