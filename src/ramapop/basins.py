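"""Six-basin Ramachandran classification and population thermodynamics.

(Φ, Ψ) pairs are assigned to six rectangular basins that tile torsion
space — PII, β, αR, 3₁₀, C7eq on the left (Φ < 0) half-plane, split by Ψ,
and αL covering the whole right half-plane.  Basin populations are turned
into relative free energies by Boltzmann inversion,

    F_b = −k_B T ln(N_b / N_ref),

with the reference basin the most populated one, so F_ref = 0 and all other
free energies are ≥ 0.  k_B = 0.0019872 kcal mol⁻¹ K⁻¹; the default
temperature is 300 K.

Angles are canonicalised to (−180, 180] with Φ = +180° identified with
−180° (assigned to the left half-plane), making classification a total
function on finite inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

KB_KCAL = 0.0019872  # Boltzmann constant, kcal mol^-1 K^-1
DEFAULT_TEMPERATURE = 300.0

__all__ = [
    "KB_KCAL",
    "DEFAULT_TEMPERATURE",
    "Basin",
    "BasinPartition",
    "PopulationTable",
    "default_partition",
    "classify_pair",
    "tally_populations",
    "free_energy_difference",
    "psi_cutoff_scan",
    "split_half_convergence",
    "read_dihedral_table",
    "write_dihedral_table",
]


def canonicalize_phi(phi):
    """Wrap Φ to [−180, 180): +180 is identified with −180."""
    return (np.asarray(phi, dtype=float) + 180.0) % 360.0 - 180.0


def canonicalize_psi(psi):
    """Wrap Ψ to (−180, 180]."""
    a = (np.asarray(psi, dtype=float) + 180.0) % 360.0 - 180.0
    return np.where(a == -180.0, 180.0, a)


@dataclass(frozen=True)
class Basin:
    """A rectangular (Φ, Ψ) box.  Bounds are half-open [lo, hi) except that
    ``psi_hi_closed`` marks a closed upper Ψ edge (needed for Ψ = 180°)."""

    name: str
    phi_lo: float
    phi_hi: float
    psi_lo: float
    psi_hi: float
    psi_hi_closed: bool = False

    def contains(self, phi, psi):
        phi = np.asarray(phi)
        psi = np.asarray(psi)
        in_phi = (phi >= self.phi_lo) & (phi < self.phi_hi)
        if self.psi_hi_closed:
            in_psi = (psi >= self.psi_lo) & (psi <= self.psi_hi)
        else:
            in_psi = (psi >= self.psi_lo) & (psi < self.psi_hi)
        return in_phi & in_psi

    @property
    def center(self):
        return (0.5 * (self.phi_lo + self.phi_hi),
                0.5 * (self.psi_lo + self.psi_hi))


# Ideal conformer centers used for concentrated within-basin sampling.
IDEAL_CENTERS = {
    "PII": (-60.0, 140.0),
    "beta": (-120.0, 130.0),
    "alphaR": (-65.0, -40.0),
    "three10": (-60.0, -30.0),
    "C7eq": (-120.0, 50.0),
    "alphaL": (65.0, 40.0),
}


@dataclass(frozen=True)
class BasinPartition:
    """An ordered set of basins tiling (Φ, Ψ) space.

    The default six-basin partition places the PII/β boundary at
    Ψ = ``psi_pii_beta_cutoff`` (135° by default).
    """

    basins: tuple[Basin, ...]
    psi_pii_beta_cutoff: float = 135.0

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(b.name for b in self.basins)

    def classify(self, phi: float, psi: float) -> str:
        """Basin name for one (Φ, Ψ) pair in degrees."""
        return self.names[int(self.classify_many([phi], [psi])[0])]

    def classify_many(self, phi, psi) -> np.ndarray:
        """Integer basin codes (indices into ``names``) for angle arrays."""
        phi = canonicalize_phi(phi)
        psi = canonicalize_psi(psi)
        if not (np.all(np.isfinite(phi)) and np.all(np.isfinite(psi))):
            raise ValueError("non-finite dihedral angles")
        codes = np.full(phi.shape, -1, dtype=int)
        for k, basin in enumerate(self.basins):
            mask = basin.contains(phi, psi) & (codes == -1)
            codes[mask] = k
        if np.any(codes == -1):
            bad = np.argwhere(codes == -1)[0]
            raise ValueError(
                f"partition does not cover (phi={phi[tuple(bad)]}, "
                f"psi={psi[tuple(bad)]})"
            )
        return codes

    def with_psi_cutoff(self, cutoff: float) -> "BasinPartition":
        """Move the PII/β boundary to ``cutoff`` (degrees).

        The union PII ∪ β and every other basin are unchanged.  A cutoff at
        or below the β floor (50°) or at/above 180° is rejected.
        """
        if not 50.0 < cutoff < 180.0:
            raise ValueError(
                f"psi cutoff must lie strictly between 50 and 180 deg, got {cutoff}"
            )
        new = []
        for b in self.basins:
            if b.name == "PII":
                new.append(replace(b, psi_lo=cutoff))
            elif b.name == "beta":
                new.append(replace(b, psi_hi=cutoff))
            else:
                new.append(b)
        return BasinPartition(tuple(new), psi_pii_beta_cutoff=cutoff)

    def is_total(self, step: float = 1.0) -> bool:
        """Grid-verify that every (Φ, Ψ) gets exactly one basin."""
        phi = np.arange(-180.0 + step, 180.0 + step / 2, step)
        psi = np.arange(-180.0 + step, 180.0 + step / 2, step)
        pp, ss = np.meshgrid(phi, psi)
        cphi = canonicalize_phi(pp)
        cpsi = canonicalize_psi(ss)
        hits = np.zeros(pp.shape, dtype=int)
        for basin in self.basins:
            hits += basin.contains(cphi, cpsi).astype(int)
        return bool(np.all(hits == 1))


def default_partition(psi_pii_beta_cutoff: float = 135.0) -> BasinPartition:
    """The six-basin partition: PII, β, αR, 3₁₀, C7eq (left half-plane,
    split by Ψ) and αL (right half-plane)."""
    basins = (
        Basin("PII", -180.0, 0.0, psi_pii_beta_cutoff, 180.0, psi_hi_closed=True),
        Basin("beta", -180.0, 0.0, 50.0, psi_pii_beta_cutoff),
        Basin("alphaR", -180.0, 0.0, -180.0, -25.0),
        Basin("three10", -180.0, 0.0, -25.0, 0.0),
        Basin("C7eq", -180.0, 0.0, 0.0, 50.0),
        Basin("alphaL", 0.0, 180.0, -180.0, 180.0, psi_hi_closed=True),
    )
    return BasinPartition(basins, psi_pii_beta_cutoff=psi_pii_beta_cutoff)


def classify_pair(phi: float, psi: float,
                  partition: BasinPartition | None = None) -> str:
    """Assign one (Φ, Ψ) pair (degrees) to its Ramachandran basin."""
    if partition is None:
        partition = default_partition()
    return partition.classify(phi, psi)


def free_energy_difference(nb, nref, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Boltzmann inversion F = −k_B T ln(N_b/N_ref), kcal/mol.

    Accepts counts or fractions (invariant to common rescaling).  Zero or
    negative occupancies have no defined free energy and raise.
    """
    if nb <= 0 or nref <= 0:
        raise ValueError("free energy undefined for empty basins")
    return float(-KB_KCAL * temperature * np.log(nb / nref)) + 0.0


@dataclass(frozen=True)
class PopulationTable:
    """Per-basin counts, fractions and relative free energies."""

    names: tuple[str, ...]
    counts: tuple[int, ...]
    temperature: float
    reference: str

    @property
    def total(self) -> int:
        return int(sum(self.counts))

    @property
    def fractions(self) -> dict[str, float]:
        t = self.total
        return {n: c / t for n, c in zip(self.names, self.counts)}

    @property
    def free_energies(self) -> dict[str, float | None]:
        """kcal/mol relative to the reference basin; None where empty."""
        ref = self.counts[self.names.index(self.reference)]
        return {
            n: (free_energy_difference(c, ref, self.temperature) if c > 0 else None)
            for n, c in zip(self.names, self.counts)
        }

    def fraction(self, name: str) -> float:
        return self.fractions[name]

    def to_frame(self) -> pd.DataFrame:
        fe = self.free_energies
        return pd.DataFrame({
            "basin": self.names,
            "count": self.counts,
            "relative_population": [self.fractions[n] for n in self.names],
            "free_energy_kcal_mol": [fe[n] for n in self.names],
        })


def tally_populations(labels, temperature: float = DEFAULT_TEMPERATURE,
                      partition: BasinPartition | None = None) -> PopulationTable:
    """Tabulate basin labels into counts, fractions and free energies.

    ``labels`` is a sequence of basin names (or integer codes into the
    partition order).  The reference basin is the most populated one; ties
    break by partition order.
    """
    if partition is None:
        partition = default_partition()
    labels = list(labels)
    if not labels:
        raise ValueError("cannot tally an empty label list")
    names = partition.names
    if isinstance(labels[0], (int, np.integer)):
        codes = np.asarray(labels, dtype=int)
    else:
        lut = {n: i for i, n in enumerate(names)}
        try:
            codes = np.array([lut[l] for l in labels])
        except KeyError as exc:
            raise ValueError(f"label {exc.args[0]!r} not in partition") from None
    counts = np.bincount(codes, minlength=len(names))
    reference = names[int(np.argmax(counts))]  # argmax keeps first on ties
    return PopulationTable(
        names=names,
        counts=tuple(int(c) for c in counts),
        temperature=temperature,
        reference=reference,
    )


def _records_to_arrays(records):
    """Accept DihedralRecord lists, (phi, psi) arrays, or DataFrames."""
    if isinstance(records, pd.DataFrame):
        return records["phi"].to_numpy(), records["psi"].to_numpy()
    records = list(records) if not isinstance(records, np.ndarray) else records
    if len(records) and hasattr(records[0], "phi"):
        return (np.array([r.phi for r in records]),
                np.array([r.psi for r in records]))
    arr = np.asarray(records, dtype=float)
    return arr[..., 0].ravel(), arr[..., 1].ravel()


def classify_records(records, partition: BasinPartition | None = None) -> np.ndarray:
    """Basin codes for a collection of dihedral records."""
    if partition is None:
        partition = default_partition()
    phi, psi = _records_to_arrays(records)
    return partition.classify_many(phi, psi)


def psi_cutoff_scan(records, cutoff: float,
                    temperature: float = DEFAULT_TEMPERATURE,
                    partition: BasinPartition | None = None) -> PopulationTable:
    """Re-tabulate populations with the PII/β boundary moved to ``cutoff``.

    Lowering the cutoff (e.g. 135° → 115°) grows PII at the expense of β
    while conserving their union and leaving all other basins untouched.
    """
    if partition is None:
        partition = default_partition()
    moved = partition.with_psi_cutoff(cutoff)
    codes = classify_records(records, moved)
    return tally_populations(codes, temperature, partition=moved)


@dataclass(frozen=True)
class SplitHalfResult:
    first: object
    second: object
    difference: object


def split_half_convergence(series) -> SplitHalfResult:
    """Compare first- and second-half ensemble summaries of a series.

    Numeric series yield (mean₁, mean₂, |Δ|); basin-label series yield
    per-basin population fractions on each half and their absolute
    differences.  Odd lengths put the middle frame in the first half.
    """
    series = list(series)
    if len(series) < 2:
        raise ValueError("need at least 2 frames for a split-half comparison")
    mid = (len(series) + 1) // 2
    a, b = series[:mid], series[mid:]
    if isinstance(series[0], (str, np.str_)):
        names = sorted(set(series))
        fa = {n: a.count(n) / len(a) for n in names}
        fb = {n: b.count(n) / len(b) for n in names}
        diff = {n: abs(fa[n] - fb[n]) for n in names}
        return SplitHalfResult(fa, fb, diff)
    ma, mb = float(np.mean(a)), float(np.mean(b))
    return SplitHalfResult(ma, mb, abs(ma - mb))


# ---------------------------------------------------------------------------
# delimited-text interchange

def write_dihedral_table(path, frames, residues, phi, psi, labels=None):
    """Write a (frame, residue, phi, psi[, label]) table as TSV."""
    data = {"frame": frames, "residue": residues, "phi": phi, "psi": psi}
    if labels is not None:
        data["label"] = labels
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_dihedral_table(path) -> pd.DataFrame:
    """Read a dihedral table written by :func:`write_dihedral_table`."""
    df = pd.read_csv(path, sep="\t")
    missing = {"frame", "residue", "phi", "psi"} - set(df.columns)
    if missing:
        raise ValueError(f"dihedral table missing columns: {sorted(missing)}")
    return df
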