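"""Synthetic conformational ensembles with prescribed basin populations.

Stands in for MD trajectories: each frame assigns every residue a
Ramachandran basin by an i.i.d. categorical draw with configurable weights,
samples a (Φ, Ψ) pair inside that basin's box (uniformly by default, or
von-Mises-concentrated around the ideal conformer center), and builds the
Cartesian conformation by internal-coordinate construction.  By design the
emitted basin label of every pair agrees with re-classification of the
dihedrals measured on the built structure.

Frames are independent by default — the analysis stages consume only
per-frame (Φ, Ψ) statistics, so trajectory autocorrelation is irrelevant to
them — but a first-order label-persistence knob is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .basins import IDEAL_CENTERS, BasinPartition, default_partition
from .geometry import (Conformation, PeptideSpec, build_ensemble_coordinates,
                       extract_phi_psi_batch)

__all__ = [
    "EnsembleConfig",
    "sample_basin_sequence",
    "sample_angles_in_basin",
    "generate_ensemble",
]

# Crude proline ring-closure realism: Φ restricted to this window when it
# intersects the requested basin box.
PROLINE_PHI_WINDOW = (-110.0, -50.0)


@dataclass
class EnsembleConfig:
    """Recipe for a synthetic ensemble.

    ``basin_weights`` maps basin names to fractions summing to 1 (order
    follows the partition for array input).  ``jitter`` is ``"uniform"``
    (uniform over each basin box) or a von Mises concentration κ
    (dimensionless; larger is tighter around the ideal conformer center).
    ``autocorrelation`` is the per-residue probability of repeating the
    previous frame's basin label (0 = i.i.d. frames).
    """

    spec: PeptideSpec
    n_frames: int
    basin_weights: dict[str, float] | tuple[float, ...]
    seed: int = 0
    jitter: str | float = "uniform"
    omega: float = 180.0
    per_residue_independent: bool = True
    autocorrelation: float = 0.0
    partition: BasinPartition = field(default_factory=default_partition)

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        names = self.partition.names
        if isinstance(self.basin_weights, dict):
            unknown = set(self.basin_weights) - set(names)
            if unknown:
                raise ValueError(f"unknown basins in weights: {sorted(unknown)}")
            w = np.array([self.basin_weights.get(n, 0.0) for n in names])
        else:
            w = np.asarray(self.basin_weights, dtype=float)
            if w.shape != (len(names),):
                raise ValueError(
                    f"need {len(names)} weights in partition order, got {w.shape}"
                )
        if np.any(w < 0):
            raise ValueError("basin weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"basin weights must sum to 1 (got {w.sum():.12f})")
        self._weights = w / w.sum()
        if not (0.0 <= self.autocorrelation < 1.0):
            raise ValueError("autocorrelation must be in [0, 1)")

    @property
    def weights(self) -> np.ndarray:
        return self._weights


def sample_basin_sequence(config: EnsembleConfig, rng=None) -> np.ndarray:
    """Basin codes of shape (n_frames, n_residues), categorical draws with
    the configured weights (optionally with first-order persistence)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    f, r = config.n_frames, config.spec.n_residues
    codes = rng.choice(len(config.weights), size=(f, r), p=config.weights)
    if config.autocorrelation > 0 and f > 1:
        keep = rng.random(size=(f, r)) < config.autocorrelation
        for i in range(1, f):
            codes[i] = np.where(keep[i], codes[i - 1], codes[i])
    return codes


def _basin_center(basin):
    """Ideal conformer center, or the box midpoint when the tabulated ideal
    point falls outside the basin's own box."""
    center = IDEAL_CENTERS.get(basin.name)
    if center is None or not bool(basin.contains(*center)):
        return basin.center
    return center


def sample_angles_in_basin(name: str, partition: BasinPartition,
                           jitter, rng, size: int = 1,
                           phi_window=None) -> tuple[np.ndarray, np.ndarray]:
    """Draw (Φ, Ψ) pairs guaranteed to lie inside the named basin's box.

    ``jitter="uniform"`` draws uniformly over the box; a numeric κ draws
    angular noise around the basin's ideal center with rejection until
    inside the box (κ = ∞ returns the center exactly).  ``phi_window``
    optionally restricts Φ to an interval intersected with the box.
    """
    k = partition.names.index(name)
    basin = partition.basins[k]
    phi_lo, phi_hi = basin.phi_lo, basin.phi_hi
    if phi_window is not None:
        lo = max(phi_lo, phi_window[0])
        hi = min(phi_hi, phi_window[1])
        if lo < hi:
            phi_lo, phi_hi = lo, hi

    if jitter == "uniform":
        return (rng.uniform(phi_lo, phi_hi, size),
                rng.uniform(basin.psi_lo, basin.psi_hi, size))

    kappa = float(jitter)
    c_phi, c_psi = _basin_center(basin)
    if np.isinf(kappa):
        return np.full(size, c_phi), np.full(size, c_psi)
    phi = np.empty(size)
    psi = np.empty(size)
    pending = np.arange(size)
    while pending.size:
        p = c_phi + np.degrees(rng.vonmises(0.0, kappa, pending.size))
        s = c_psi + np.degrees(rng.vonmises(0.0, kappa, pending.size))
        ok = ((p >= phi_lo) & (p < phi_hi)
              & (s >= basin.psi_lo)
              & ((s <= basin.psi_hi) if basin.psi_hi_closed else (s < basin.psi_hi)))
        phi[pending[ok]] = p[ok]
        psi[pending[ok]] = s[ok]
        pending = pending[~ok]
    return phi, psi


def _sample_angles(config: EnsembleConfig, codes: np.ndarray, rng):
    """Fill (Φ, Ψ) arrays for a code matrix, honouring proline windows."""
    f, r = codes.shape
    phi = np.empty((f, r))
    psi = np.empty((f, r))
    is_pro = np.array([res == "PRO" for res in config.spec.sequence])
    for k, basin in enumerate(config.partition.basins):
        for pro in (False, True):
            mask = (codes == k) & (is_pro[None, :] == pro)
            n = int(mask.sum())
            if n == 0:
                continue
            window = PROLINE_PHI_WINDOW if pro else None
            p, s = sample_angles_in_basin(
                basin.name, config.partition, config.jitter, rng, size=n,
                phi_window=window,
            )
            phi[mask] = p
            psi[mask] = s
    return phi, psi


def generate_ensemble(config: EnsembleConfig):
    """Generate a synthetic ensemble.

    Returns ``(conformations, table)``: a list of built conformations (one
    per frame) and a tidy DataFrame with columns frame, residue, phi, psi,
    label giving the sampled torsions and their basin labels.
    """
    rng = np.random.default_rng(config.seed)
    codes = sample_basin_sequence(config, rng)
    phi, psi = _sample_angles(config, codes, rng)
    atoms, coords = build_ensemble_coordinates(
        config.spec, phi, psi, omega=config.omega
    )
    confs = [
        Conformation(atoms=atoms, coordinates=coords[i], frame_id=i)
        for i in range(config.n_frames)
    ]
    f, r = codes.shape
    names = np.array(config.partition.names)
    table = pd.DataFrame({
        "frame": np.repeat(np.arange(f), r),
        "residue": np.tile(np.arange(1, r + 1), f),
        "phi": phi.ravel(),
        "psi": psi.ravel(),
        "label": names[codes.ravel()],
    })
    return confs, table


def verify_labels(config: EnsembleConfig, confs, table) -> bool:
    """Check that measured dihedrals of every built frame re-classify to the
    emitted labels (over residues whose (Φ, Ψ) pair is defined)."""
    coords = np.stack([c.coordinates for c in confs])
    res_ids, phi, psi = extract_phi_psi_batch(confs[0].atoms, coords)
    codes = config.partition.classify_many(phi, psi)
    names = np.array(config.partition.names)
    pivot = table.pivot(index="frame", columns="residue", values="label")
    expected = pivot.loc[:, res_ids].to_numpy()
    return bool(np.all(names[codes] == expected))
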