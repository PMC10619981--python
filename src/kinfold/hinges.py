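"""Coiled-coil break ("hinge") detection on CA traces.

A folded stalk reverses direction at a short break in the coiled-coil.  The
detector slides a window along each chain's CA trace, takes the dominant
direction (first principal component, oriented N-to-C) of each window, and
calls a hinge wherever the angle between the axes of the windows flanking a
position exceeds a kink threshold, with non-maximum suppression so one
physical break yields one call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import KinfoldError
from .structmodel import StructureModel


@dataclass(frozen=True)
class HingeCall:
    """One detected coiled-coil break."""

    chain_id: str
    residue_position: int
    kink_angle: float  # degrees, between flanking window axes
    window: int


def _ca_trace(model: StructureModel, chain_id: str) -> tuple[np.ndarray, list[int]]:
    resnums = model.residue_numbers(chain_id)
    pts = []
    kept = []
    for r in resnums:
        site = (chain_id, r, "CA")
        if model.has_site(site):
            pts.append(model.position(site))
            kept.append(r)
    return np.array(pts), kept


def local_axes(trace: np.ndarray, window: int = 9) -> np.ndarray:
    """Per-position unit axis of the CA trace, oriented N-to-C.

    For each window of ``window`` consecutive CA positions, the axis is the
    first principal direction of the coordinates, sign-fixed to point along
    the chain (positive projection on the window's end-to-start chord).
    Returns an (n - window + 1, 3) array; row i is the axis of the window
    starting at position i.
    """
    trace = np.asarray(trace, dtype=float)
    n = len(trace)
    if n < window:
        raise KinfoldError(f"chain has {n} CA positions, window is {window}")
    if window < 3:
        raise ValueError("window must be >= 3")
    axes = np.empty((n - window + 1, 3))
    for i in range(n - window + 1):
        seg = trace[i : i + window]
        centered = seg - seg.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        axis = vt[0]
        chord = seg[-1] - seg[0]
        if np.dot(axis, chord) < 0:
            axis = -axis
        axes[i] = axis / np.linalg.norm(axis)
    return axes


def detect_breaks(
    trace: np.ndarray,
    kink_threshold: float = 45.0,
    window: int = 9,
    min_separation: int = 10,
    resnums: list[int] | None = None,
    chain_id: str = "",
) -> list[HingeCall]:
    """Find positions where the chain direction kinks by more than threshold.

    At each interior position the axes of the windows ending at and starting
    from it are compared; angles above ``kink_threshold`` (degrees) are
    candidate breaks, reduced by non-maximum suppression within
    ``min_separation`` residues.  Calls are sorted by position.
    """
    trace = np.asarray(trace, dtype=float)
    n = len(trace)
    if n < 2 * window:
        raise KinfoldError(
            f"chain has {n} CA positions; need >= {2 * window} for flanking "
            f"windows of {window}"
        )
    axes = local_axes(trace, window=window)
    # angle at position p (0-based) between window ending at p and starting at p
    angles = np.full(n, np.nan)
    for p in range(window - 1, n - window + 1):
        before = axes[p - window + 1]
        after = axes[p]
        cosang = np.clip(np.dot(before, after), -1.0, 1.0)
        angles[p] = np.degrees(np.arccos(cosang))

    candidates = [
        p for p in range(n) if np.isfinite(angles[p]) and angles[p] > kink_threshold
    ]
    # a sharp break produces a plateau of above-threshold positions about one
    # window wide; cluster nearby candidates and report each cluster's
    # angle-weighted centre (the argmax jitters between the plateau edges)
    clusters: list[list[int]] = []
    for p in sorted(candidates):
        if clusters and p - clusters[-1][-1] < min_separation:
            clusters[-1].append(p)
        else:
            clusters.append([p])
    if resnums is None:
        resnums = list(range(1, n + 1))
    calls = []
    for cluster in clusters:
        weights = np.array([angles[p] - kink_threshold for p in cluster])
        center = int(round(np.average(cluster, weights=weights)))
        calls.append(
            HingeCall(
                chain_id=chain_id,
                residue_position=resnums[center],
                kink_angle=float(max(angles[p] for p in cluster)),
                window=window,
            )
        )
    return sorted(calls, key=lambda c: c.residue_position)


def detect_breaks_in_model(
    model: StructureModel,
    kink_threshold: float = 45.0,
    window: int = 9,
    min_separation: int = 10,
    merge_within: int = 3,
) -> list[HingeCall]:
    """Run break detection on every chain; merge per-chain calls.

    Calls on different chains within ``merge_within`` residues of each other
    are reported once (the stronger kink), reflecting that a hinge in a
    dimer involves both chains.
    """
    calls: list[HingeCall] = []
    for chain in model.chain_ids():
        trace, resnums = _ca_trace(model, chain)
        calls.extend(
            detect_breaks(
                trace,
                kink_threshold=kink_threshold,
                window=window,
                min_separation=min_separation,
                resnums=resnums,
                chain_id=chain,
            )
        )
    merged: list[HingeCall] = []
    for call in sorted(calls, key=lambda c: (-c.kink_angle, c.chain_id)):
        if all(
            abs(call.residue_position - m.residue_position) > merge_within
            for m in merged
        ):
            merged.append(call)
    return sorted(merged, key=lambda c: c.residue_position)
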