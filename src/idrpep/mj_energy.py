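"""Residue-residue contact-energy matrices and pairwise binding energies.

The design method scores a candidate peptide residue *j* facing a target
residue *i* with the knowledge-based binding energy

    E(i, j) = e_ij + e_rr - e_ir - e_jr

where ``e_ij`` is a statistical contact energy (Miyazawa-Jernigan style, in
RT units) and the subscript ``r`` denotes averaging over all amino acid
types.  The reference terms make E shift-invariant: adding a constant to
every ``e_ij`` leaves E unchanged, and any additive matrix
``e_ij = f_i + f_j`` scores identically zero.

The packaged default matrix is the Miyazawa & Jernigan (1996) effective
contact-energy table e_ij (J Mol Biol 256:623, Table 5 upper triangle);
any symmetric matrix over an arbitrary alphabet may be supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "ContactEnergyMatrix",
    "ResidueAverages",
    "MatrixFormatError",
    "load_contact_matrix",
    "load_default_matrix",
    "residue_averages",
    "pair_binding_energy",
    "DEFAULT_MATRIX_RESOURCE",
]

DEFAULT_MATRIX_RESOURCE = "mj1996.txt"
DEFAULT_PROVENANCE = "Miyazawa-Jernigan 1996 Table 5 (e_ij, RT units)"


class MatrixFormatError(ValueError):
    """Raised when a contact-matrix file violates the text format."""


@dataclass(frozen=True)
class ContactEnergyMatrix:
    """Symmetric table of residue-residue contact energies e_ij (RT units).

    Parameters
    ----------
    alphabet : tuple of str
        Ordered one-letter residue codes (20 standard residues for the
        packaged matrix; any size >= 2 is accepted for custom matrices).
    energies : ndarray of shape (n, n)
        Symmetric contact energies; ``energies[i, j]`` is e for the pair
        ``alphabet[i], alphabet[j]``.
    provenance : str
        Free-text identifier of the source table.
    """

    alphabet: tuple[str, ...]
    energies: np.ndarray
    provenance: str = "unspecified"
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        alphabet = tuple(self.alphabet)
        energies = np.asarray(self.energies, dtype=float)
        n = len(alphabet)
        if n < 2:
            raise MatrixFormatError("alphabet must contain at least 2 residues")
        if len(set(alphabet)) != n:
            dup = sorted({a for a in alphabet if alphabet.count(a) > 1})
            raise MatrixFormatError(f"duplicate residue codes: {dup}")
        if energies.shape != (n, n):
            raise MatrixFormatError(
                f"energies shape {energies.shape} does not match alphabet size {n}"
            )
        if not np.isfinite(energies).all():
            raise MatrixFormatError("contact energies must all be finite")
        if not np.array_equal(energies, energies.T):
            i, j = np.argwhere(energies != energies.T)[0]
            raise MatrixFormatError(
                f"matrix not symmetric: e({alphabet[i]},{alphabet[j]})="
                f"{energies[i, j]} but e({alphabet[j]},{alphabet[i]})={energies[j, i]}"
            )
        object.__setattr__(self, "alphabet", alphabet)
        object.__setattr__(self, "energies", energies)
        object.__setattr__(self, "_index", {a: i for i, a in enumerate(alphabet)})

    @property
    def size(self) -> int:
        return len(self.alphabet)

    def index(self, code: str) -> int:
        """Position of a residue code in the alphabet."""
        try:
            return self._index[code]
        except KeyError:
            raise KeyError(
                f"residue code {code!r} not in matrix alphabet "
                f"{''.join(self.alphabet)!r}"
            ) from None

    def energy(self, a: str, b: str) -> float:
        """Contact energy e_ab."""
        return float(self.energies[self.index(a), self.index(b)])


@dataclass(frozen=True)
class ResidueAverages:
    """Reference averages derived from a contact matrix.

    ``e_ir[i]`` is the unweighted mean of e_ij over all j (including j=i);
    ``e_rr`` is the grand mean over all ordered pairs, which equals the mean
    of the ``e_ir`` values.
    """

    e_ir: np.ndarray
    e_rr: float
    source: ContactEnergyMatrix

    def __post_init__(self) -> None:
        object.__setattr__(self, "e_ir", np.asarray(self.e_ir, dtype=float))


def _parse_lines(lines: list[str], provenance: str) -> ContactEnergyMatrix:
    rows = [ln.strip() for ln in lines]
    rows = [ln for ln in rows if ln and not ln.startswith("#")]
    if not rows:
        raise MatrixFormatError("empty matrix file")
    alphabet = tuple(rows[0].split())
    n = len(alphabet)
    if len(rows) - 1 != n:
        raise MatrixFormatError(
            f"expected {n} data rows for alphabet {''.join(alphabet)!r}, "
            f"found {len(rows) - 1}"
        )
    energies = np.empty((n, n))
    seen: set[str] = set()
    for line in rows[1:]:
        parts = line.split()
        code, cells = parts[0], parts[1:]
        if code not in alphabet:
            raise MatrixFormatError(f"row code {code!r} not in header alphabet")
        if code in seen:
            raise MatrixFormatError(f"duplicate row for residue {code!r}")
        seen.add(code)
        if len(cells) != n:
            raise MatrixFormatError(
                f"row {code!r} has {len(cells)} entries, expected {n}"
            )
        i = alphabet.index(code)
        for j, cell in enumerate(cells):
            try:
                energies[i, j] = float(cell)
            except ValueError:
                raise MatrixFormatError(
                    f"non-numeric cell {cell!r} at ({code},{alphabet[j]})"
                ) from None
    if seen != set(alphabet):
        missing = sorted(set(alphabet) - seen)
        raise MatrixFormatError(f"missing rows for residues {missing}")
    # symmetrization is never silent: reject asymmetric input outright
    return ContactEnergyMatrix(alphabet, energies, provenance)


def load_contact_matrix(path: str | Path, provenance: str | None = None) -> ContactEnergyMatrix:
    """Load and validate a contact-energy matrix from a text file.

    Format: optional ``#`` comment lines; first data line holds the
    whitespace-separated residue codes; each following line is a row code
    followed by the full row of numeric entries.  Asymmetric, incomplete or
    non-numeric input raises :class:`MatrixFormatError` naming the offending
    cell.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"contact matrix file not found: {path}")
    return _parse_lines(path.read_text().splitlines(), provenance or str(path))


def load_default_matrix() -> ContactEnergyMatrix:
    """Load the packaged Miyazawa-Jernigan 1996 e_ij table."""
    text = (resources.files("idrpep.data") / DEFAULT_MATRIX_RESOURCE).read_text()
    return _parse_lines(text.splitlines(), DEFAULT_PROVENANCE)


def residue_averages(matrix: ContactEnergyMatrix) -> ResidueAverages:
    """Compute the per-residue means e_ir and grand mean e_rr.

    Means are unweighted over residue *types* (no composition weighting);
    the diagonal term j=i is included.  e_rr equals the mean of the e_ir.
    """
    e_ir = matrix.energies.mean(axis=1)
    return ResidueAverages(e_ir=e_ir, e_rr=float(e_ir.mean()), source=matrix)


def pair_binding_energy(
    matrix: ContactEnergyMatrix,
    avgs: ResidueAverages,
    a: str,
    b: str,
) -> float:
    """Binding energy e_ab + e_rr - e_ar - e_br (RT units), symmetric in a, b."""
    ia, ib = sorted((matrix.index(a), matrix.index(b)))  # bitwise symmetry in (a, b)
    return float(
        matrix.energies[ia, ib] + avgs.e_rr - avgs.e_ir[ia] - avgs.e_ir[ib]
    )
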