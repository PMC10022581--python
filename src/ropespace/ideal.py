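"""Ideal covalent geometry for rebuilding chains from torsions.

Bond lengths and bond angles come from an embedded Engh & Huber-style table
(``data/ideal_geometry.tsv``) covering the heavy atoms of the 20 standard
residues plus the peptide link.  Chains are rebuilt from torsion angles with
these values substituted for the measured lengths/angles, so any two rebuilds
share identical local geometry and differ only in their torsions.

The table is generated from per-bond-class rules plus explicit backbone
constants; run ``python -m ropespace.ideal`` to regenerate the TSV.
"""

from __future__ import annotations

from importlib import resources

from . import topology as top

PEPTIDE_BOND = 1.329  # C(i)-N(i+1), Angstrom

_BACKBONE_LENGTHS = {
    ("CA", "N"): 1.458,
    ("C", "CA"): 1.525,
    ("C", "O"): 1.231,
    ("CA", "CB"): 1.530,
}

_LENGTH_OVERRIDES: dict[tuple[str, str, str], float] = {
    ("ARG", "CD", "NE"): 1.461, ("ARG", "CZ", "NE"): 1.329,
    ("ARG", "CZ", "NH1"): 1.326, ("ARG", "CZ", "NH2"): 1.326,
    ("ASN", "CG", "OD1"): 1.231, ("ASN", "CG", "ND2"): 1.328,
    ("ASP", "CG", "OD1"): 1.249, ("ASP", "CG", "OD2"): 1.249,
    ("GLN", "CD", "OE1"): 1.231, ("GLN", "CD", "NE2"): 1.328,
    ("GLU", "CD", "OE1"): 1.249, ("GLU", "CD", "OE2"): 1.249,
    ("CYS", "CB", "SG"): 1.808,
    ("MET", "CG", "SD"): 1.803, ("MET", "CE", "SD"): 1.791,
    ("SER", "CB", "OG"): 1.417,
    ("THR", "CB", "OG1"): 1.433,
    ("TYR", "CZ", "OH"): 1.376,
    ("LYS", "CE", "NZ"): 1.489,
    ("HIS", "CB", "CG"): 1.497, ("HIS", "CG", "ND1"): 1.378,
    ("HIS", "CD2", "CG"): 1.356, ("HIS", "CE1", "ND1"): 1.345,
    ("HIS", "CD2", "NE2"): 1.382,
    ("TRP", "CB", "CG"): 1.498, ("TRP", "CD1", "CG"): 1.365,
    ("TRP", "CD2", "CG"): 1.433, ("TRP", "CD1", "NE1"): 1.374,
    ("TRP", "CD2", "CE2"): 1.409, ("TRP", "CD2", "CE3"): 1.398,
    ("TRP", "CE2", "CZ2"): 1.394, ("TRP", "CE3", "CZ3"): 1.382,
    ("TRP", "CH2", "CZ2"): 1.368,
    ("PHE", "CB", "CG"): 1.502,
    ("TYR", "CB", "CG"): 1.502,
}

_BACKBONE_ANGLES = {
    ("N", "CA", "C"): 111.2,
    ("N", "CA", "CB"): 110.4,
    ("C", "CA", "CB"): 110.5,
    ("CA", "C", "O"): 120.8,
}

# Peptide-link entries; "+"/"-" mark the next/previous residue.
_LINK_ANGLES = {
    ("CA", "C", "N+"): 116.2,
    ("O", "C", "N+"): 123.0,
    ("C-", "N", "CA"): 121.7,
}

_ANGLE_OVERRIDES: dict[tuple[str, str, str, str], float] = {
    ("PRO", "C-", "N", "CA"): 122.6,
    ("PRO", "N", "CA", "CB"): 103.2,
    ("PRO", "CA", "CB", "CG"): 104.5,
    ("PRO", "CB", "CG", "CD"): 106.1,
}

_DEFAULT_LENGTH = {
    frozenset({"C"}): 1.530,
    frozenset({"C", "N"}): 1.470,
    frozenset({"C", "O"}): 1.420,
    frozenset({"C", "S"}): 1.810,
    frozenset({"S"}): 2.033,
}


def _rule_length(res: str, a: str, b: str) -> float:
    a, b = sorted((a, b))
    if (res, a, b) in _LENGTH_OVERRIDES:
        return _LENGTH_OVERRIDES[(res, a, b)]
    if (a, b) in _BACKBONE_LENGTHS:
        return _BACKBONE_LENGTHS[(a, b)]
    if top.is_sp2(res, a) and top.is_sp2(res, b):
        return 1.390  # aromatic / conjugated C-C
    ea, eb = top.element_of(a), top.element_of(b)
    return _DEFAULT_LENGTH[frozenset({ea, eb})]


def _rule_angle(res: str, a: str, b: str, c: str) -> float:
    a, c = sorted((a, c))
    if (res, a, b, c) in _ANGLE_OVERRIDES:
        return _ANGLE_OVERRIDES[(res, a, b, c)]
    if (a, b, c) in _BACKBONE_ANGLES:
        return _BACKBONE_ANGLES[(a, b, c)]
    ring = top.FIVE_RING.get(res, set())
    if b in ring and a in ring and c in ring:
        return 108.0
    if top.is_sp2(res, b):
        return 120.0
    return 110.5


def build_tables() -> tuple[dict, dict]:
    """Enumerate every bond length and angle the atom-tree builder can request."""
    lengths: dict[tuple[str, str, str], float] = {}
    angles: dict[tuple[str, str, str, str], float] = {}
    for res in top.THREE_TO_ONE:
        bonds = [("N", "CA"), ("CA", "C"), ("C", "O")]
        bonds += top.SIDECHAIN_BONDS[res]
        adj: dict[str, list[str]] = {}
        for x, y in bonds:
            adj.setdefault(x, []).append(y)
            adj.setdefault(y, []).append(x)
            lo, hi = sorted((x, y))
            lengths[(res, lo, hi)] = _rule_length(res, lo, hi)
        for b, nbrs in adj.items():
            for i in range(len(nbrs)):
                for j in range(i + 1, len(nbrs)):
                    a, c = sorted((nbrs[i], nbrs[j]))
                    angles[(res, a, b, c)] = _rule_angle(res, a, b, c)
        # peptide-link angles, residue-resolved so proline can differ
        for (a, b, c), val in _LINK_ANGLES.items():
            key = (res, a, b, c)
            angles[key] = _ANGLE_OVERRIDES.get(key, val)
        lengths[(res, "C", "N+")] = PEPTIDE_BOND
    return lengths, angles


class IdealGeometry:
    """Lookup of ideal bond lengths (A) and bond angles (deg).

    Cross-residue atoms are marked ``N+`` (next residue) / ``C-`` (previous
    residue); intra-residue lookups are orientation-insensitive.
    """

    def __init__(self, lengths: dict, angles: dict):
        self._lengths = lengths
        self._angles = angles

    @classmethod
    def default(cls) -> "IdealGeometry":
        path = resources.files("ropespace.data").joinpath("ideal_geometry.tsv")
        lengths: dict = {}
        angles: dict = {}
        with path.open() as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if parts[0] == "length":
                    _, res, a, b, val = parts
                    lengths[(res, a, b)] = float(val)
                else:
                    _, res, a, b, c, val = parts
                    angles[(res, a, b, c)] = float(val)
        return cls(lengths, angles)

    def length(self, res: str, a: str, b: str) -> float:
        if b == "N+" or a == "N+":
            return self._lengths[(res, "C", "N+")]
        lo, hi = sorted((a, b))
        try:
            return self._lengths[(res, lo, hi)]
        except KeyError:
            return _rule_length(res, lo, hi)

    def angle(self, res: str, a: str, b: str, c: str) -> float:
        if "+" not in a + c and "-" not in a + c:
            a, c = sorted((a, c))
        try:
            return self._angles[(res, a, b, c)]
        except KeyError:
            pass
        try:
            return self._angles[(res, c, b, a)]
        except KeyError:
            return _rule_angle(res, a, b, c)


def write_table(path) -> None:
    lengths, angles = build_tables()
    with open(path, "w") as fh:
        fh.write("# ideal heavy-atom geometry, v1\n")
        fh.write("# length\tres\ta\tb\tangstrom | angle\tres\ta\tb\tc\tdegrees\n")
        for (res, a, b), val in sorted(lengths.items()):
            fh.write(f"length\t{res}\t{a}\t{b}\t{val:.3f}\n")
        for (res, a, b, c), val in sorted(angles.items()):
            fh.write(f"angle\t{res}\t{a}\t{b}\t{c}\t{val:.1f}\n")


if __name__ == "__main__":
    import pathlib

    out = pathlib.Path(__file__).parent / "data" / "ideal_geometry.tsv"
    out.parent.mkdir(exist_ok=True)
    write_table(out)
    print(f"wrote {out}")
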