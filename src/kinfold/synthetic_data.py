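"""Ground-truth generators for structures, crosslink tables and motility events.

The toy structure emulates a two-chain coiled-coil motor protein: a motor
stub, four stalk segments and a tail stub laid out as ideal helices with a
1.5 A/residue rise, in either an extended conformation or a folded one in
which the chain reverses direction at a planted hinge (the coiled-coil break
between the third and fourth stalk segments).  Folding brings designated
site pairs on the two arms of the fold within crosslinking range while the
same pairs are far apart in the extended conformer, mirroring the compact
(~half-length) versus extended (~80 nm for a 533-residue contour) dichotomy
seen for autoinhibited motors.

Crosslink simulation draws true positives from site pairs whose ground-truth
minimum inter-anchor distance is within the crosslinker limit and false
positives uniformly from the remaining pairs; motility simulation draws
Poisson landings, exponential dwells (frame-quantized and censored at movie
end) and Gaussian velocities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import KinfoldError
from .structmodel import AtomRecord, RigidTransform, StructureModel
from .xlmap import CrosslinkRecord

HELIX_RISE = 1.5  # A per residue along the coiled-coil axis
HELIX_RADIUS = 2.3  # A, CA helix radius
HELIX_TWIST = np.deg2rad(100.0)  # per residue
CHAIN_OFFSET = 10.0  # A between the two helix axes of the dimer
FOLD_OFFSET = 12.0  # A lateral offset of the folded-back arm

# Default segment layout (residues), 963 total like a full-length heavy chain:
# motor stub 1-400 (motor+neck), cc2 401-540, cc3a 541-690, cc3b 691-820,
# cc4 821-907, tail stub 908-963.  The hinge sits at the cc3a/cc3b junction.
DEFAULT_SEGMENTS = {
    "motor": 400,
    "cc2": 140,
    "cc3a": 150,
    "cc3b": 130,
    "cc4": 87,
    "tail": 56,
}


def _default_sites(hinge: int, total: int, stalk_start: int) -> list[int]:
    """Crosslinkable sites paired across the hinge, plus motor-stub sites.

    Cross-hinge pairs (hinge - d, hinge + d + e) come within crosslinking
    range when the chain folds back; the offsets e vary from pair to pair so
    the resulting restraint targets are irregular and pin a unique placement
    (a perfectly regular layout leaves mirror-like degeneracies).  Spacing is
    kept above 16 residues on each helix so that no same-strand pair, and no
    cross-hinge pair in the extended conformer, is within 24 A.
    """
    sites: list[int] = list(range(50, max(stalk_start - 9, 51), 100))[:4]
    offsets = (0, 3, 6, 9)
    d, k = 18, 0
    while hinge - d > stalk_start and hinge + d + offsets[k % 4] <= total:
        sites.extend([hinge - d, hinge + d + offsets[k % 4]])
        d += 26
        k += 1
    return sorted(set(s for s in sites if 1 <= s <= total))


@dataclass
class ToyDimerSpec:
    """Parameters of the synthetic two-chain coiled-coil model."""

    segments: dict = field(default_factory=lambda: dict(DEFAULT_SEGMENTS))
    conformation: str = "folded"  # or "extended"
    contact_distance: float = 24.0
    sites: list[int] | None = None
    noise_sd: float = 0.0  # per-coordinate Gaussian jitter, A
    seed: int = 0

    @property
    def total_residues(self) -> int:
        return sum(self.segments.values())

    @property
    def hinge_position(self) -> int:
        """Residue index of the planted break (end of the third stalk segment)."""
        n = 0
        for name, length in self.segments.items():
            n += length
            if name == "cc3a":
                return n
        raise KinfoldError("segment layout must contain a 'cc3a' segment")

    @property
    def stalk_start(self) -> int:
        """Last residue of the first (motor-stub) segment."""
        return next(iter(self.segments.values()))

    def site_positions(self) -> list[int]:
        if self.sites is not None:
            return sorted(set(self.sites))
        return _default_sites(
            self.hinge_position, self.total_residues, self.stalk_start
        )

    def validate(self) -> None:
        if self.conformation not in ("extended", "folded"):
            raise KinfoldError(f"unknown conformation {self.conformation!r}")
        if any(v < 1 for v in self.segments.values()):
            raise KinfoldError("segment lengths must be positive")
        names = list(self.segments)
        if "cc3a" not in names:
            raise KinfoldError("segment layout must contain a 'cc3a' segment")
        h = self.hinge_position
        if not 0 < h < self.total_residues:
            raise KinfoldError("hinge must be interior to the chain")


def build_toy_dimer(spec: ToyDimerSpec) -> StructureModel:
    """Build the CA-only two-chain toy model described by ``spec``.

    Extended mode runs both helices along +z; folded mode reverses direction
    at the hinge and offsets the returning arm laterally, so residues i and
    2*hinge - i on the two arms face each other roughly ``FOLD_OFFSET`` apart.
    """
    spec.validate()
    n = spec.total_residues
    h = spec.hinge_position
    folded = spec.conformation == "folded"
    rng = np.random.default_rng(spec.seed)

    site_set = set(spec.site_positions())
    atoms: list[AtomRecord] = []
    for chain_idx, chain_id in enumerate("AB"):
        y0 = chain_idx * CHAIN_OFFSET
        for i in range(1, n + 1):
            phase = HELIX_TWIST * i + (np.pi if chain_idx else 0.0)
            wob_x = HELIX_RADIUS * np.cos(phase)
            wob_y = HELIX_RADIUS * np.sin(phase)
            if folded and i > h:
                # returning arm: direction reversed, laterally offset
                z = (2 * h - i) * HELIX_RISE
                x = FOLD_OFFSET + wob_x
            else:
                z = i * HELIX_RISE
                x = wob_x
            pos = np.array([x, y0 + wob_y, z])
            if spec.noise_sd > 0:
                pos = pos + rng.normal(scale=spec.noise_sd, size=3)
            resname = "LYS" if i in site_set else "ALA"
            atoms.append(AtomRecord(chain_id, i, resname, "CA", pos))
    model = StructureModel(
        atoms,
        metadata={
            "conformation": spec.conformation,
            "hinge": h,
            "sites": spec.site_positions(),
        },
    )
    if folded:
        _check_contacts(model, spec)
    return model


def contact_pairs(spec: ToyDimerSpec) -> list[tuple[int, int]]:
    """Designated cross-hinge site pairs guaranteed close when folded.

    A pair (i, j) with i <= hinge < j faces itself across the fold when the
    axial mismatch |i + j - 2*hinge| is small enough that the inter-arm
    offset plus helix wobble stays within the contact distance.
    """
    h = spec.hinge_position
    lateral = FOLD_OFFSET + 2 * HELIX_RADIUS  # worst-case with wobble
    if spec.contact_distance <= lateral:
        return []
    max_dz = np.sqrt(spec.contact_distance**2 - lateral**2)
    max_mismatch = int(max_dz / HELIX_RISE)
    sites = spec.site_positions()
    return sorted(
        (i, j)
        for i in sites
        for j in sites
        if i <= h < j and abs(i + j - 2 * h) <= max_mismatch
    )


def _check_contacts(model: StructureModel, spec: ToyDimerSpec) -> None:
    for i, j in contact_pairs(spec):
        d = np.linalg.norm(
            model.position(("A", i, "CA")) - model.position(("A", j, "CA"))
        )
        if d > spec.contact_distance:
            raise KinfoldError(
                f"folded conformer violates contact pair ({i}, {j}): {d:.1f} A"
            )


# ---------------------------------------------------------------------------
# Crosslink simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedCrosslinkSet:
    """Crosslink records plus per-record truth labels and parameters."""

    records: list[CrosslinkRecord]
    labels: list[str]  # "true_positive" | "false_positive"
    params: dict

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "Protein1": [r.protein_a for r in self.records],
                "Site1": [r.site_a for r in self.records],
                "Protein2": [r.protein_b for r in self.records],
                "Site2": [r.site_b for r in self.records],
                "E-value": [r.evalue for r in self.records],
                "label": self.labels,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().drop(columns="label").to_csv(path, index=False)


def _min_pair_distance(
    model: StructureModel, site_i: int, site_j: int, anchor: str, chains: Sequence[str]
) -> float:
    best = np.inf
    for ca in chains:
        if not model.has_site((ca, site_i, anchor)):
            continue
        pi = model.position((ca, site_i, anchor))
        for cb in chains:
            if (ca, site_i) == (cb, site_j):
                continue
            if not model.has_site((cb, site_j, anchor)):
                continue
            d = float(np.linalg.norm(pi - model.position((cb, site_j, anchor))))
            best = min(best, d)
    return best


def simulate_crosslinks(
    model: StructureModel,
    sites: Sequence[int] | None = None,
    threshold: float = 24.0,
    detection_prob: float = 1.0,
    fp_rate: float = 0.0,
    seed: int = 0,
    protein: str = "KIF5B",
    n_links: int | None = None,
    include_self_links: bool = False,
    decoy_fraction: float = 0.0,
) -> SimulatedCrosslinkSet:
    """Simulate a crosslink identification table from a ground-truth model.

    Every unordered site pair whose minimum inter-anchor (CA) distance over
    all chain combinations is <= ``threshold`` is detected with probability
    ``detection_prob`` as a true positive.  False positives are drawn
    uniformly without replacement from the remaining (distant) pairs so the
    expected false-positive fraction of the table equals ``fp_rate``.
    E-values are log-uniform in [1e-8, 1e-2); if ``decoy_fraction`` > 0 extra
    rows with E-values in [0.01, 0.05) are appended to exercise the parser
    filter.  Same-position inter-chain pairs (homodimer self-links) are
    excluded unless ``include_self_links``.  Deterministic for a given seed.
    """
    if not (0 <= detection_prob <= 1 and 0 <= fp_rate < 1):
        raise ValueError("detection_prob in [0,1] and fp_rate in [0,1) required")
    rng = np.random.default_rng(seed)
    if sites is None:
        sites = model.metadata.get("sites")
        if sites is None:
            raise ValueError("no sites given and none recorded in model metadata")
    sites = sorted(set(sites))
    chains = model.chain_ids()

    near: list[tuple[int, int, float]] = []
    far: list[tuple[int, int, float]] = []
    for a_idx in range(len(sites)):
        for b_idx in range(a_idx, len(sites)):
            i, j = sites[a_idx], sites[b_idx]
            if i == j and not include_self_links:
                continue
            d = _min_pair_distance(model, i, j, "CA", chains)
            if not np.isfinite(d):
                continue
            (near if d <= threshold else far).append((i, j, d))

    if not near:
        import warnings

        warnings.warn("no site pairs within the crosslinker limit", stacklevel=2)

    detected = [p for p in near if rng.random() < detection_prob]
    if n_links is not None:
        n_tp = int(round(n_links * (1 - fp_rate)))
        n_fp = n_links - n_tp
        if n_tp > len(detected):
            raise KinfoldError(
                f"requested {n_tp} true positives but only {len(detected)} "
                "detectable pairs exist"
            )
        tp_idx = rng.choice(len(detected), size=n_tp, replace=False)
        detected = [detected[k] for k in sorted(tp_idx)]
    else:
        n_fp = (
            int(round(len(detected) * fp_rate / (1 - fp_rate))) if fp_rate > 0 else 0
        )
    n_fp = min(n_fp, len(far))
    fp_idx = rng.choice(len(far), size=n_fp, replace=False) if n_fp else []
    fps = [far[k] for k in sorted(fp_idx)]

    records: list[CrosslinkRecord] = []
    labels: list[str] = []
    row = 2
    for (i, j, d), label in [(p, "true_positive") for p in detected] + [
        (p, "false_positive") for p in fps
    ]:
        ev = 10 ** rng.uniform(-8, np.log10(0.01))
        records.append(
            CrosslinkRecord(protein, i, protein, j, ev, source_row=row,
                            target_distance=d)
        )
        labels.append(label)
        row += 1
    # shuffle rows so labels are not positionally encoded
    order = rng.permutation(len(records))
    records = [records[k] for k in order]
    labels = [labels[k] for k in order]
    for k, r in enumerate(records):
        records[k] = CrosslinkRecord(
            r.protein_a, r.site_a, r.protein_b, r.site_b, r.evalue,
            source_row=2 + k, target_distance=r.target_distance,
        )

    n_decoy = int(round(decoy_fraction * len(records)))
    for k in range(n_decoy):
        i, j = rng.choice(sites, size=2, replace=False)
        ev = rng.uniform(0.01, 0.05)
        records.append(
            CrosslinkRecord(protein, int(i), protein, int(j), ev,
                            source_row=2 + len(records))
        )
        labels.append("decoy")

    return SimulatedCrosslinkSet(
        records=records,
        labels=labels,
        params={
            "threshold": threshold,
            "detection_prob": detection_prob,
            "fp_rate": fp_rate,
            "seed": seed,
            "n_near_pairs": len(near),
            "n_far_pairs": len(far),
        },
    )


# ---------------------------------------------------------------------------
# Fragmentation
# ---------------------------------------------------------------------------

def make_fragments(
    model: StructureModel,
    boundaries: Sequence[tuple[int, int]],
    scramble: bool = False,
    seed: int = 0,
    noise_sd: float = 0.0,
):
    """Cut a model into fragments at the given inclusive residue intervals.

    Consecutive intervals must overlap or abut.  With ``scramble`` every
    non-first fragment is displaced by a random rigid transform, recorded in
    the returned specs as ground truth (``true_transform`` inverts the
    scrambling).  ``noise_sd`` adds independent per-coordinate Gaussian
    jitter to every fragment, emulating independently predicted fragments
    whose shared residues do not agree exactly.  Returns a list of
    :class:`kinfold.assembly.FragmentSpec`.
    """
    from .assembly import FragmentSpec  # local import to avoid a cycle
    from scipy.spatial.transform import Rotation

    boundaries = [tuple(b) for b in boundaries]
    for (s1, e1), (s2, e2) in zip(boundaries, boundaries[1:]):
        if s2 > e1 + 1:
            raise KinfoldError(
                f"gap between fragment intervals ({s1},{e1}) and ({s2},{e2})"
            )
    rng = np.random.default_rng(seed)
    fragments = []
    prev_name: str | None = None
    prev_interval: tuple[int, int] | None = None
    for idx, (start, end) in enumerate(boundaries):
        sub = model.select(residue_range=(start, end))
        if noise_sd > 0:
            jitter = rng.normal(scale=noise_sd, size=(len(sub), 3))
            sub = StructureModel(
                [
                    AtomRecord(
                        a.chain_id, a.residue_number, a.residue_name,
                        a.atom_name, a.position + dx,
                    )
                    for a, dx in zip(sub, jitter)
                ],
                sub.metadata,
            )
        name = f"frag_{start}_{end}"
        overlap_with = None
        if prev_interval is not None:
            lo, hi = max(start, prev_interval[0]), min(end, prev_interval[1])
            if hi >= lo:
                overlap_with = (prev_name, (lo, hi))
        transform = RigidTransform.identity()
        if scramble and idx > 0:
            R = Rotation.random(random_state=int(rng.integers(2**31 - 1))).as_matrix()
            t = rng.uniform(-50, 50, size=3)
            transform = RigidTransform(R, t)
            sub = sub.transformed(transform)
        fragments.append(
            FragmentSpec(
                name=name,
                model=sub,
                residue_interval=(start, end),
                overlap_with=overlap_with,
                true_transform=transform.inverse(),
            )
        )
        prev_name, prev_interval = name, (start, end)
    return fragments


# ---------------------------------------------------------------------------
# Motility simulation
# ---------------------------------------------------------------------------

def simulate_motility(
    true_rate: float = 5.0,  # events / um / s / uM
    dwell_mean: float = 2.0,  # s
    velocity_mean: float = 0.8,  # um/s
    velocity_sd: float = 0.1,
    n_mts: int = 25,
    mt_length: float | tuple[float, float] = 10.0,  # um, or (mean, sd)
    duration: float = 60.0,  # s
    frame_interval: float = 0.2,  # s
    concentration: float = 0.0015,  # uM
    seed: int = 0,
    group: str = "WT",
) -> tuple[pd.DataFrame, dict]:
    """Simulate a single-molecule event table.

    Per microtubule the landing count is Poisson(rate x length x duration x
    concentration); dwells are exponential, quantized to frames and censored
    at the movie end; displacement is velocity x observed dwell with Gaussian
    velocity.  Start positions are drawn so events stay on the microtubule,
    leaving dwell and velocity distributions undistorted.  Returns the event
    table and the generating truth.
    """
    for name, v in [
        ("true_rate", true_rate), ("dwell_mean", dwell_mean),
        ("velocity_mean", velocity_mean), ("duration", duration),
        ("frame_interval", frame_interval), ("concentration", concentration),
    ]:
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration / frame_interval))
    rows = []
    for mt in range(n_mts):
        if isinstance(mt_length, tuple):
            length = max(1.0, rng.normal(*mt_length))
        else:
            length = float(mt_length)
        n_events = rng.poisson(true_rate * length * duration * concentration)
        for _ in range(n_events):
            start_frame = int(rng.integers(0, n_frames))
            dwell = rng.exponential(dwell_mean)
            n_int = max(1, int(round(dwell / frame_interval)))
            end_frame = start_frame + n_int
            censored = end_frame > n_frames
            end_frame = min(end_frame, n_frames)
            obs_dwell = (end_frame - start_frame) * frame_interval
            v = rng.normal(velocity_mean, velocity_sd)
            disp = abs(v) * obs_dwell
            if disp >= length:
                disp = length
            start_pos = rng.uniform(0, length - disp)
            rows.append(
                {
                    "mt_id": f"{group}_mt{mt}",
                    "mt_length_um": length,
                    "start_frame": start_frame,
                    "end_frame": end_frame,
                    "start_pos_um": start_pos,
                    "end_pos_um": start_pos + disp,
                    "group": group,
                    "censored": censored,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "mt_id", "mt_length_um", "start_frame", "end_frame",
            "start_pos_um", "end_pos_um", "group", "censored",
        ],
    )
    truth = {
        "true_rate": true_rate,
        "dwell_mean": dwell_mean,
        "velocity_mean": velocity_mean,
        "velocity_sd": velocity_sd,
        "duration": duration,
        "frame_interval": frame_interval,
        "concentration": concentration,
        "n_mts": n_mts,
        "seed": seed,
    }
    return df, truth
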