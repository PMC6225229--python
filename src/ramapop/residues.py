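"""Residue topology templates for internal-coordinate peptide construction.

Heavy-atom-only templates for the residues occurring in the two study
peptides: the XAO peptide X-X-A-A-A-A-A-A-A-O-O (X = 2,4-diaminobutyric
acid, O = ornithine) with acetyl/amide caps, and the bradykinin-like 9-mer
Arg-Pro-Pro-Gly-Phe-Ser-Ala-Phe-Lys with free charged termini.

Each side-chain atom is specified as an internal-coordinate step
``(name, element, (ref_a, ref_b, ref_c), bond, angle, torsion)``: the atom
is bonded to ``ref_c`` at distance ``bond`` (Å), with bond angle
``ref_b–ref_c–atom`` (degrees) and torsion ``ref_a–ref_b–ref_c–atom``
(degrees).  References name backbone or previously placed side-chain atoms
of the same residue.  Side chains are all-trans rotamers except proline,
whose ring is laid out from ideal-residue internal coordinates without
closure refinement.
"""

from __future__ import annotations

# Atomic masses (u) and electron counts for the neutral elements that occur
# in the peptides studied here.
ATOMIC_MASS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}
ELECTRON_COUNT = {"H": 1, "C": 6, "N": 7, "O": 8, "S": 16}

# Backbone internal coordinates (Engh–Huber-style canonical values).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_C_OXT = 1.249  # carboxylate C–O of a free C-terminus

ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 116.6
ANGLE_C_N_CA = 121.7
ANGLE_N_C_O = 122.9  # N(i+1)–C(i)–O(i), sp2 carbonyl
ANGLE_CA_C_OXT = 117.0

# L-amino-acid CB placement: improper torsion N–C–CA–CB measured on ideal
# (CCD) residue geometry.
CB_BOND = 1.530
CB_ANGLE_C_CA_CB = 109.5
CB_IMPROPER_N_C_CA_CB = -120.0

# (name, element, (ref_a, ref_b, ref_c), bond Å, angle deg, torsion deg)
_CB = ("CB", "C", ("N", "C", "CA"), CB_BOND, CB_ANGLE_C_CA_CB, CB_IMPROPER_N_C_CA_CB)

SIDE_CHAINS: dict[str, list[tuple]] = {
    "GLY": [],
    "ALA": [_CB],
    # X: 2,4-diaminobutyric acid, side chain CB-CG-ND (–CH2–CH2–NH3+)
    "DAB": [
        _CB,
        ("CG", "C", ("N", "CA", "CB"), 1.530, 111.0, 180.0),
        ("ND", "N", ("CA", "CB", "CG"), 1.489, 111.0, 180.0),
    ],
    # O: ornithine, side chain CB-CG-CD-NE (–[CH2]3–NH3+)
    "ORN": [
        _CB,
        ("CG", "C", ("N", "CA", "CB"), 1.530, 111.0, 180.0),
        ("CD", "C", ("CA", "CB", "CG"), 1.530, 111.0, 180.0),
        ("NE", "N", ("CB", "CG", "CD"), 1.489, 111.0, 180.0),
    ],
    "SER": [
        _CB,
        ("OG", "O", ("N", "CA", "CB"), 1.417, 110.8, 180.0),
    ],
    "LYS": [
        _CB,
        ("CG", "C", ("N", "CA", "CB"), 1.530, 111.0, 180.0),
        ("CD", "C", ("CA", "CB", "CG"), 1.530, 111.0, 180.0),
        ("CE", "C", ("CB", "CG", "CD"), 1.530, 111.0, 180.0),
        ("NZ", "N", ("CG", "CD", "CE"), 1.489, 111.0, 180.0),
    ],
    "ARG": [
        _CB,
        ("CG", "C", ("N", "CA", "CB"), 1.530, 111.0, 180.0),
        ("CD", "C", ("CA", "CB", "CG"), 1.530, 111.0, 180.0),
        ("NE", "N", ("CB", "CG", "CD"), 1.460, 112.0, 180.0),
        ("CZ", "C", ("CG", "CD", "NE"), 1.330, 124.0, 180.0),
        ("NH1", "N", ("CD", "NE", "CZ"), 1.330, 120.0, 0.0),
        ("NH2", "N", ("CD", "NE", "CZ"), 1.330, 120.0, 180.0),
    ],
    # Proline ring laid out from ideal-residue torsions; the CD–N closure is
    # approximate (no refinement).
    "PRO": [
        _CB,
        ("CG", "C", ("N", "CA", "CB"), 1.543, 105.1, 23.8),
        ("CD", "C", ("CA", "CB", "CG"), 1.544, 105.6, 0.0),
    ],
    "PHE": [
        _CB,
        ("CG", "C", ("N", "CA", "CB"), 1.510, 113.8, 180.0),
        ("CD1", "C", ("CA", "CB", "CG"), 1.390, 120.7, 90.0),
        ("CD2", "C", ("CA", "CB", "CG"), 1.390, 120.7, -90.0),
        ("CE1", "C", ("CB", "CG", "CD1"), 1.390, 120.0, 180.0),
        ("CE2", "C", ("CB", "CG", "CD2"), 1.390, 120.0, 180.0),
        ("CZ", "C", ("CG", "CD1", "CE1"), 1.390, 120.0, 0.0),
    ],
}

# One-letter codes used in sequence strings.
ONE_TO_THREE = {
    "X": "DAB",
    "O": "ORN",
    "A": "ALA",
    "G": "GLY",
    "S": "SER",
    "K": "LYS",
    "R": "ARG",
    "P": "PRO",
    "F": "PHE",
}

XAO_SEQUENCE = ("DAB", "DAB", "ALA", "ALA", "ALA", "ALA", "ALA", "ALA", "ALA", "ORN", "ORN")
NINEMER_SEQUENCE = ("ARG", "PRO", "PRO", "GLY", "PHE", "SER", "ALA", "PHE", "LYS")


def resolve_sequence(sequence) -> tuple[str, ...]:
    """Normalise a sequence given as one-letter string or 3-letter codes."""
    if isinstance(sequence, str):
        codes = []
        for ch in sequence:
            if ch not in ONE_TO_THREE:
                raise KeyError(f"unknown residue code {ch!r}")
            codes.append(ONE_TO_THREE[ch])
        return tuple(codes)
    out = []
    for code in sequence:
        code = code.upper()
        if code not in SIDE_CHAINS:
            raise KeyError(f"unknown residue code {code!r}")
        out.append(code)
    return tuple(out)
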