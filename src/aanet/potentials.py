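"""Inter-residue contact-energy table serving as network link weights.

The network model weighs each residue–residue link with a statistical
contact energy ``w_ij`` (dimensionless, RT units) between the two residue
types.  Negative energies mean the pair is net attractive in folded
structures ("similar" weight: the effective distance between the nodes
shrinks); positive energies mean net repulsion ("dissimilar" weight: the
effective distance grows).  A self-consistent potential of this kind spans
[-1.19, 0.76] over the 210 unordered pairs of the 20 standard residues, and
that range is enforced as a validation gate on the bundled default table.

The table bundled with the package, ``data/contact_potential_synthetic.tsv``,
is a SYNTHETIC stand-in: a deterministic surrogate built from hydrophobicity
products and electrostatic sign structure and anchored exactly at the
published extremes.  It reproduces the qualitative features a real
self-consistent potential has (hydrophobic–hydrophobic strongly attractive,
like-charged pairs most repulsive, opposite charges attractive, both signs
present, a few entries below -1) but its individual entries are not
experimentally derived.  Supply a real potential file via
``load_potential_table(path)`` for production use.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "STANDARD_RESIDUES",
    "NONSTANDARD_MAP",
    "ContactPotentialTable",
    "load_potential_table",
    "lookup_weight",
]

#: The 20 standard amino-acid three-letter codes, alphabetical.
STANDARD_RESIDUES: tuple[str, ...] = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

#: Common nonstandard/variant residue codes mapped onto a standard parent.
NONSTANDARD_MAP: dict[str, str] = {
    "MSE": "MET",   # selenomethionine
    "SEC": "CYS",   # selenocysteine
    "HSD": "HIS", "HSE": "HIS", "HSP": "HIS",   # CHARMM histidine tautomers
    "HID": "HIS", "HIE": "HIS", "HIP": "HIS",   # AMBER histidine tautomers
}

#: Published range of the self-consistent contact potential; the bundled
#: default table must attain both endpoints exactly.
EXPECTED_MIN = -1.19
EXPECTED_MAX = 0.76

_SYMMETRY_TOL = 1e-9


def map_residue_code(code: str, lenient: bool = True) -> str | None:
    """Map a three-letter code onto a standard residue.

    Returns the standard code, or ``None`` when ``lenient`` and the code is
    unmappable.  Raises :class:`KeyError` in strict mode.
    """
    code = code.strip().upper()
    if code in STANDARD_RESIDUES:
        return code
    if code in NONSTANDARD_MAP:
        return NONSTANDARD_MAP[code]
    if lenient:
        return None
    raise KeyError(f"unmappable nonstandard residue code {code!r}")


@dataclass(frozen=True)
class ContactPotentialTable:
    """Symmetric 20x20 table of inter-residue contact energies w_ij.

    Attributes
    ----------
    matrix
        ``(20, 20)`` symmetric array ordered as ``residue_codes``.
    residue_codes
        The 20 standard three-letter codes indexing the matrix.
    """

    matrix: np.ndarray
    residue_codes: tuple[str, ...] = STANDARD_RESIDUES
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "_index", {c: i for i, c in enumerate(self.residue_codes)}
        )

    def energy(self, res_a: str, res_b: str) -> float:
        """Contact energy for an (unordered) pair of standard codes."""
        try:
            i, j = self._index[res_a], self._index[res_b]
        except KeyError as exc:
            raise KeyError(f"residue code {exc.args[0]!r} not in table") from None
        return float(self.matrix[i, j])

    @property
    def min(self) -> float:
        return float(self.matrix.min())

    @property
    def max(self) -> float:
        return float(self.matrix.max())

    def write(self, path: str | Path) -> None:
        """Serialize as a whitespace-delimited full matrix with code headers."""
        Path(path).write_text(self.to_text())

    def to_text(self) -> str:
        buf = io.StringIO()
        buf.write("#   " + " ".join(f"{c:>6s}" for c in self.residue_codes) + "\n")
        for i, code in enumerate(self.residue_codes):
            row = " ".join(f"{v:6.2f}" for v in self.matrix[i])
            buf.write(f"{code} {row}\n")
        return buf.getvalue()


def _validate(table: ContactPotentialTable, strict_range: bool) -> None:
    m = table.matrix
    n = len(table.residue_codes)
    if m.shape != (n, n):
        raise ValueError(f"expected a {n}x{n} matrix, got {m.shape}")
    if not np.all(np.isfinite(m)):
        bad = np.argwhere(~np.isfinite(m))[0]
        pair = (table.residue_codes[bad[0]], table.residue_codes[bad[1]])
        raise ValueError(f"missing or non-finite energy for pair {pair}")
    asym = np.abs(m - m.T)
    if asym.max() > _SYMMETRY_TOL:
        i, j = np.unravel_index(int(asym.argmax()), asym.shape)
        raise ValueError(
            f"asymmetric energies for pair ({table.residue_codes[i]}, "
            f"{table.residue_codes[j]}): {m[i, j]} vs {m[j, i]}"
        )
    if strict_range:
        lo, hi = table.min, table.max
        if abs(lo - EXPECTED_MIN) > 1e-9 or abs(hi - EXPECTED_MAX) > 1e-9:
            raise ValueError(
                f"contact-energy range [{lo}, {hi}] does not match the "
                f"expected [{EXPECTED_MIN}, {EXPECTED_MAX}]"
            )


def _parse_matrix_text(text: str) -> ContactPotentialTable:
    """Parse a whitespace- or comma-delimited matrix with code headers.

    Accepts a full square matrix or a lower-triangular one (row ``k`` holding
    ``k+1`` values); the triangle is mirrored.  A leading header row of codes
    (optionally prefixed with ``#``) fixes the column order.
    """
    rows: list[tuple[str, list[float]]] = []
    header: list[str] | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.replace(",", " ").strip()
        is_comment = line.startswith("#")
        if is_comment:
            line = line[1:].strip()
        if not line:
            continue
        tokens = line.split()
        if header is None and all(t.upper() in STANDARD_RESIDUES or
                                  t.upper() in NONSTANDARD_MAP for t in tokens):
            header = [t.upper() for t in tokens]
            continue
        if is_comment:
            continue
        code = tokens[0].upper()
        try:
            values = [float(t) for t in tokens[1:]]
        except ValueError as exc:
            raise ValueError(f"unparseable energy on line {lineno}: {exc}") from None
        rows.append((code, values))

    if len(rows) != 20:
        raise ValueError(f"expected 20 residue rows, found {len(rows)}")
    codes = [c for c, _ in rows]
    missing = set(STANDARD_RESIDUES) - set(codes)
    if missing:
        raise ValueError(f"missing residues in table: {sorted(missing)}")

    col_order = header if header is not None else codes
    n = 20
    m = np.full((n, n), np.nan)
    lower_triangular = all(len(v) == k + 1 for k, (_, v) in enumerate(rows))
    for k, (code, values) in enumerate(rows):
        i = STANDARD_RESIDUES.index(code)
        if lower_triangular and len(values) == k + 1:
            for l, v in enumerate(values):
                j = STANDARD_RESIDUES.index(rows[l][0])
                m[i, j] = m[j, i] = v
        elif len(values) == n:
            for l, v in enumerate(values):
                j = STANDARD_RESIDUES.index(col_order[l])
                m[i, j] = v
        else:
            raise ValueError(
                f"row {code} has {len(values)} values; expected {n} (full) "
                f"or {k + 1} (lower-triangular)"
            )
    return ContactPotentialTable(matrix=m)


def load_potential_table(
    source: str | Path | None = None, *, strict_range: bool | None = None
) -> ContactPotentialTable:
    """Load and validate a contact-energy table.

    Parameters
    ----------
    source
        Path to a plain-text matrix file (full or lower-triangular, with
        residue-code headers).  ``None`` loads the bundled synthetic default.
    strict_range
        Require the global min/max to equal the published extremes
        (-1.19 / 0.76).  Defaults to ``True`` for the bundled table and
        ``False`` for user-supplied files.

    Raises
    ------
    ValueError
        On a missing pair, asymmetry beyond 1e-9, or a range-gate failure.
    """
    if source is None:
        text = (
            resources.files("aanet")
            .joinpath("data/contact_potential_synthetic.tsv")
            .read_text()
        )
        strict = True if strict_range is None else strict_range
    else:
        text = Path(source).read_text()
        strict = False if strict_range is None else strict_range
    table = _parse_matrix_text(text)
    _validate(table, strict_range=strict)
    return table


def lookup_weight(
    table: ContactPotentialTable,
    res_a: str,
    res_b: str,
    *,
    lenient: bool = True,
) -> float | None:
    """Contact energy w_ij for two residue codes, mapping common variants.

    Negative = attractive (similar weight); positive = repulsive (dissimilar
    weight).  In lenient mode an unmappable code yields ``None`` (caller
    skips the node); strict mode raises :class:`KeyError`.
    """
    a = map_residue_code(res_a, lenient=lenient)
    b = map_residue_code(res_b, lenient=lenient)
    if a is None or b is None:
        return None
    return table.energy(a, b)


# ---------------------------------------------------------------------------
# Synthetic stand-in construction (the bundled default table)
# ---------------------------------------------------------------------------

#: Fauchère–Pliska side-chain hydrophobicity (kcal/mol, octanol/water).
_FP_HYDROPHOBICITY: dict[str, float] = {
    "ALA": 0.31, "ARG": -1.01, "ASN": -0.60, "ASP": -0.77, "CYS": 1.54,
    "GLN": -0.22, "GLU": -0.64, "GLY": 0.00, "HIS": 0.13, "ILE": 1.80,
    "LEU": 1.70, "LYS": -0.99, "MET": 1.23, "PHE": 1.79, "PRO": 0.72,
    "SER": -0.04, "THR": 0.26, "TRP": 2.25, "TYR": 0.96, "VAL": 1.22,
}

#: Formal side-chain charge at neutral pH (His treated as half-protonated).
_CHARGE: dict[str, float] = {
    "ASP": -1.0, "GLU": -1.0, "LYS": 1.0, "ARG": 1.0, "HIS": 0.5,
}


def build_synthetic_table() -> ContactPotentialTable:
    """Construct the bundled SYNTHETIC stand-in contact-energy table.

    Deterministic surrogate for a self-consistent statistical potential:
    the raw energy is ``-(h_i * h_j) + 0.35 * q_i * q_j`` with ``h`` the
    [0, 1]-normalized Fauchère–Pliska hydrophobicity and ``q`` the formal
    charge, affinely rescaled so the global extremes equal the published
    -1.19 (most hydrophobic pair) and +0.76 (like-charged pair) exactly,
    then rounded to two decimals as a printed table would be.
    """
    h_raw = np.array([_FP_HYDROPHOBICITY[c] for c in STANDARD_RESIDUES])
    h = (h_raw - h_raw.min()) / (h_raw.max() - h_raw.min())
    q = np.array([_CHARGE.get(c, 0.0) for c in STANDARD_RESIDUES])
    raw = -np.outer(h, h) + 0.35 * np.outer(q, q)
    span = raw.max() - raw.min()
    scaled = EXPECTED_MIN + (raw - raw.min()) * (EXPECTED_MAX - EXPECTED_MIN) / span
    return ContactPotentialTable(matrix=np.round(scaled, 2))
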