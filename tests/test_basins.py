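"""Basin classification, population thermodynamics and convergence checks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ramapop.basins import (KB_KCAL, classify_pair, classify_records,
                            default_partition, free_energy_difference,
                            psi_cutoff_scan, read_dihedral_table,
                            split_half_convergence, tally_populations,
                            write_dihedral_table)

# Printed aqueous-solution population/free-energy rows: (basin, fraction,
# reference fraction, expected kcal/mol, tolerance).  The 9-mer alphaL row
# prints 1.41 but computes to 1.40 from the rounded population.
PRINTED_ROWS = [
    ("XAO beta", 0.202, 0.534, 0.58, 0.01),
    ("XAO alphaR", 0.126, 0.534, 0.86, 0.01),
    ("XAO three10", 0.062, 0.534, 1.28, 0.01),
    ("XAO alphaL", 0.041, 0.534, 1.53, 0.01),
    ("XAO C7eq", 0.035, 0.534, 1.62, 0.01),
    ("9mer three10", 0.167, 0.440, 0.58, 0.01),
    ("9mer beta", 0.147, 0.440, 0.65, 0.01),
    ("9mer alphaR", 0.105, 0.440, 0.86, 0.01),
    ("9mer C7eq", 0.099, 0.440, 0.89, 0.01),
    ("9mer alphaL", 0.042, 0.440, 1.41, 0.02),
]


@pytest.mark.parametrize("phi, psi, basin", [
    (-75, 145, "PII"),        # canonical polyproline II torsions
    (-60, 140, "PII"),
    (-120, 130, "beta"),
    (65, 40, "alphaL"),
    (-65, -40, "alphaR"),
    (-60, -30, "alphaR"),     # ideal 3-10 point falls in the alphaR box
    (-120, 50, "beta"),       # ideal C7eq point sits on the beta floor
    (-90, 135, "PII"),        # PII lower edge is closed
    (-90, 50, "beta"),
    (-90, 0, "C7eq"),
    (-90, -25, "three10"),
    (0, 0, "alphaL"),         # phi = 0 belongs to the right half-plane
    (180, 100, "beta"),       # +180 identified with -180
    (-180, 180, "PII"),
    (-90, -180, "PII"),       # psi = -180 canonicalizes to +180
    (300, -400, "alphaR"),    # out-of-range input wraps
])
def test_classify_pair(phi, psi, basin):
    assert classify_pair(phi, psi) == basin


def test_classify_rejects_non_finite():
    with pytest.raises(ValueError):
        default_partition().classify_many([np.nan], [0.0])


def test_partition_total_and_unique_on_degree_grid():
    assert default_partition().is_total(step=1.0)


def test_shifted_partition_still_total():
    assert default_partition().with_psi_cutoff(115.0).is_total(step=1.0)


# ---------------------------------------------------------------------------
# populations and free energies

def test_tally_uniform_six_labels():
    part = default_partition()
    table = tally_populations(list(part.names), temperature=300.0)
    assert all(f == pytest.approx(1 / 6) for f in table.fractions.values())
    assert table.reference == "PII"  # tie broken by partition order


def test_tally_counts_and_reference():
    table = tally_populations(["PII"] * 3 + ["beta"], temperature=300.0)
    assert table.fraction("PII") == 0.75
    assert table.fraction("beta") == 0.25
    assert table.reference == "PII"
    assert table.free_energies["C7eq"] is None  # empty basin: undefined


def test_tally_empty_raises():
    with pytest.raises(ValueError):
        tally_populations([])


def test_fractions_sum_to_one():
    table = tally_populations(["PII", "beta", "beta", "alphaL"] * 7)
    assert sum(table.fractions.values()) == pytest.approx(1.0, abs=1e-12)


@pytest.mark.parametrize("label, nb, nref, expected, tol", PRINTED_ROWS)
def test_printed_free_energies_from_populations(label, nb, nref, expected, tol):
    """Boltzmann inversion of the printed relative populations reproduces
    the printed free-energy differences."""
    assert free_energy_difference(nb, nref, 300.0) == pytest.approx(
        expected, abs=tol)


def test_free_energy_identity_and_reference_zero():
    assert free_energy_difference(0.37, 0.37, 300.0) == 0.0
    table = tally_populations(["PII"] * 5 + ["beta"] * 2)
    assert table.free_energies["PII"] == 0.0


@given(st.floats(1e-6, 1.0), st.floats(1e-6, 1.0), st.floats(1e3, 1e9))
@settings(max_examples=50, deadline=None, derandomize=True, database=None)
def test_free_energy_scale_invariance(nb, nref, scale):
    """Counts and fractions give identical free energies (Nb/Nref ratio)."""
    a = free_energy_difference(nb, nref, 300.0)
    b = free_energy_difference(nb * scale, nref * scale, 300.0)
    assert b == pytest.approx(a, abs=1e-12)


@pytest.mark.parametrize("nb, nref", [(0, 1), (-1, 1), (1, 0)])
def test_free_energy_rejects_empty_occupancy(nb, nref):
    with pytest.raises(ValueError):
        free_energy_difference(nb, nref, 300.0)


def test_boltzmann_constant_value():
    assert KB_KCAL == pytest.approx(0.0019872)


# ---------------------------------------------------------------------------
# psi-cutoff sensitivity

def _random_records(rng, n=4000):
    return np.column_stack([rng.uniform(-180, 180, n), rng.uniform(-180, 180, n)])


def test_cutoff_at_default_is_noop(rng):
    records = _random_records(rng)
    base = tally_populations(classify_records(records))
    scanned = psi_cutoff_scan(records, 135.0)
    assert scanned.counts == base.counts


def test_cutoff_scan_conserves_union_and_other_basins(rng):
    records = _random_records(rng)
    base = tally_populations(classify_records(records))
    for cutoff in (60.0, 115.0, 150.0, 179.0):
        scanned = psi_cutoff_scan(records, cutoff)
        b = dict(zip(base.names, base.counts))
        s = dict(zip(scanned.names, scanned.counts))
        assert s["PII"] + s["beta"] == b["PII"] + b["beta"]
        for name in ("alphaR", "three10", "C7eq", "alphaL"):
            assert s[name] == b[name]


def test_cutoff_scan_analytic_fraction():
    """Phi fixed at -75, psi evenly spread over [50, 180): moving the
    boundary to 115 puts exactly half the points in PII."""
    psi = 50.0 + np.arange(130)  # 50, 51, ..., 179
    records = np.column_stack([np.full(130, -75.0), psi])
    table = psi_cutoff_scan(records, 115.0)
    assert table.fraction("PII") == pytest.approx(0.5)
    assert table.fraction("beta") == pytest.approx(0.5)


@pytest.mark.parametrize("cutoff", [50.0, 20.0, -10.0, 180.0, 200.0])
def test_cutoff_scan_rejects_degenerate_boundary(cutoff):
    records = np.array([[-75.0, 145.0]])
    with pytest.raises(ValueError):
        psi_cutoff_scan(records, cutoff)


# ---------------------------------------------------------------------------
# split-half convergence

def test_split_half_constant_series():
    res = split_half_convergence([3.3] * 10)
    assert res.difference == 0.0


def test_split_half_means():
    res = split_half_convergence(np.arange(1, 101))
    assert res.first == pytest.approx(25.5)
    assert res.second == pytest.approx(75.5)
    assert res.difference == pytest.approx(50.0)


def test_split_half_odd_length_middle_goes_first():
    res = split_half_convergence([1.0, 2.0, 3.0])
    assert res.first == pytest.approx(1.5)
    assert res.second == pytest.approx(3.0)


def test_split_half_label_series():
    res = split_half_convergence(["PII"] * 50 + ["beta"] * 50)
    assert res.first["PII"] == 1.0
    assert res.second["PII"] == 0.0
    assert res.difference["PII"] == 1.0


def test_split_half_needs_two_frames():
    with pytest.raises(ValueError):
        split_half_convergence([1.0])


# ---------------------------------------------------------------------------
# delimited-text interchange

def test_dihedral_table_round_trip(tmp_path):
    path = tmp_path / "dihedrals.tsv"
    write_dihedral_table(path, [0, 0, 1], [1, 2, 1],
                         [-75.0, -120.0, 60.0], [145.0, 130.0, 40.0],
                         ["PII", "beta", "alphaL"])
    df = read_dihedral_table(path)
    assert list(df.columns) == ["frame", "residue", "phi", "psi", "label"]
    assert df["phi"].tolist() == [-75.0, -120.0, 60.0]


def test_dihedral_table_missing_columns(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("frame\tresidue\n0\t1\n")
    with pytest.raises(ValueError, match="phi"):
        read_dihedral_table(path)
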