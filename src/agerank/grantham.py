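"""Grantham-distance-based residue similarity and aligned-sequence comparison.

The Grantham distance is a physicochemical distance between amino-acid pairs
built from side-chain composition, polarity and molecular volume; its maximum
over the 20x20 standard-residue table is 215 (Cys-Trp).  Dividing by 215 and
subtracting from 1 yields a similarity on [0, 1] that scores conservative
substitutions (e.g. Leu-Ile) close to 1 and radical ones close to 0.

The ambiguity codes B (Asx), Z (Glx) and X (any) are handled by averaging:
B behaves as the mean of Asp and Asn, Z as the mean of Gln and Glu, and X as
the mean over all 20 standard residues.  The extended 23x23 similarity matrix
is shipped as a TSV data file and can be re-derived from the distance table.
"""

from __future__ import annotations

import hashlib
from importlib import resources
from typing import Iterable, Mapping

__all__ = [
    "STANDARD_RESIDUES",
    "AMBIGUITY_EXPANSION",
    "GRANTHAM_MAX_DISTANCE",
    "GAP_CHARS",
    "InvalidResidueError",
    "AlignmentFrameError",
    "EmptyRegionError",
    "AminoAcidSimilarityMatrix",
    "load_distance_table",
    "grantham_similarity",
    "pairwise_identity",
    "pairwise_similarity",
]

STANDARD_RESIDUES: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")

#: Each ambiguity code stands for the uniform average over these residues.
AMBIGUITY_EXPANSION: Mapping[str, tuple[str, ...]] = {
    "B": ("D", "N"),
    "Z": ("Q", "E"),
    "X": STANDARD_RESIDUES,
}

GRANTHAM_MAX_DISTANCE: int = 215

GAP_CHARS: frozenset[str] = frozenset("-.")

_DISTANCE_RESOURCE = "grantham_distance.tsv"
_SIMILARITY_RESOURCE = "grantham_similarity.tsv"
#: sha256 of the vendored distance table; guards against silent data edits.
_DISTANCE_SHA256 = "172519b638196f283cad6eda5f942466f235b6ecb63472e46cb94fe1c8701f77"


class InvalidResidueError(ValueError):
    """A residue code outside the 20 standard letters plus B/Z/X."""


class AlignmentFrameError(ValueError):
    """Two sequences supposed to share an alignment frame do not."""


class EmptyRegionError(ValueError):
    """A similarity/identity was requested over zero usable columns."""


def _read_matrix_tsv(text: str) -> dict[tuple[str, str], float]:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")[1:]
    entries: dict[tuple[str, str], float] = {}
    for line in lines[1:]:
        fields = line.split("\t")
        row = fields[0]
        for col, val in zip(header, fields[1:]):
            entries[(row, col)] = float(val)
    return entries


def load_distance_table(verify: bool = True) -> dict[tuple[str, str], int]:
    """Load the vendored 20x20 Grantham distance table.

    With ``verify`` (default) the file's sha256 is checked against the
    checksum recorded at packaging time.
    """
    data = resources.files("agerank.data").joinpath(_DISTANCE_RESOURCE).read_bytes()
    if verify:
        digest = hashlib.sha256(data).hexdigest()
        if digest != _DISTANCE_SHA256:
            raise RuntimeError(
                f"Grantham distance table checksum mismatch: {digest}"
            )
    return {k: int(v) for k, v in _read_matrix_tsv(data.decode()).items()}


class AminoAcidSimilarityMatrix:
    """Symmetric residue-similarity lookup on [0, 1] including B/Z/X.

    Entries for the 20 standard residues are ``1 - d/215`` with ``d`` the
    Grantham distance; ambiguity codes are uniform averages over their
    expansions (B: D/N, Z: Q/E, X: all 20), applied on both sides so that
    e.g. sim(B, Z) averages over the four underlying pairs.
    """

    base_distance_max = GRANTHAM_MAX_DISTANCE

    def __init__(self, entries: Mapping[tuple[str, str], float]):
        self.entries = dict(entries)
        self._codes = sorted({a for a, _ in self.entries})
        self._validate()

    def _validate(self) -> None:
        expected = set(STANDARD_RESIDUES) | set(AMBIGUITY_EXPANSION)
        if set(self._codes) != expected:
            missing = expected - set(self._codes)
            raise ValueError(f"similarity matrix missing codes: {sorted(missing)}")
        for (a, b), v in self.entries.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"similarity out of [0,1] for ({a},{b}): {v}")
            if self.entries[(b, a)] != v:
                raise ValueError(f"asymmetric entry for ({a},{b})")
        for a in STANDARD_RESIDUES:
            if self.entries[(a, a)] != 1.0:
                raise ValueError(f"sim({a},{a}) != 1")

    @classmethod
    def from_distances(
        cls, distances: Mapping[tuple[str, str], int] | None = None
    ) -> "AminoAcidSimilarityMatrix":
        """Build the extended 23x23 matrix from 20x20 Grantham distances."""
        if distances is None:
            distances = load_distance_table()
        entries: dict[tuple[str, str], float] = {}
        for a in STANDARD_RESIDUES:
            for b in STANDARD_RESIDUES:
                entries[(a, b)] = 1.0 - distances[(a, b)] / GRANTHAM_MAX_DISTANCE
        codes = list(STANDARD_RESIDUES) + list(AMBIGUITY_EXPANSION)
        # fill each unordered pair once and mirror, so float summation
        # order cannot break symmetry
        for i, a in enumerate(codes):
            for b in codes[i:]:
                if (a, b) in entries:
                    continue
                ea = AMBIGUITY_EXPANSION.get(a, (a,))
                eb = AMBIGUITY_EXPANSION.get(b, (b,))
                vals = [
                    1.0 - distances[(x, y)] / GRANTHAM_MAX_DISTANCE
                    for x in ea
                    for y in eb
                ]
                entries[(a, b)] = entries[(b, a)] = sum(vals) / len(vals)
        return cls(entries)

    @classmethod
    def load(cls, path=None) -> "AminoAcidSimilarityMatrix":
        """Load the matrix from a TSV file (default: the vendored copy)."""
        if path is None:
            text = (
                resources.files("agerank.data")
                .joinpath(_SIMILARITY_RESOURCE)
                .read_text()
            )
        else:
            with open(path) as fh:
                text = fh.read()
        return cls(_read_matrix_tsv(text))

    def dump(self, path) -> None:
        """Write the matrix as TSV; floats use shortest round-trip repr."""
        codes = self._codes
        with open(path, "w") as fh:
            fh.write("\t".join([""] + codes) + "\n")
            for a in codes:
                fh.write(
                    "\t".join([a] + [repr(self.entries[(a, b)]) for b in codes])
                    + "\n"
                )

    def similarity(self, a: str, b: str) -> float:
        a, b = a.upper(), b.upper()
        try:
            return self.entries[(a, b)]
        except KeyError:
            bad = a if (a, a) not in self.entries else b
            raise InvalidResidueError(f"unknown residue code: {bad!r}") from None


_DEFAULT_MATRIX: AminoAcidSimilarityMatrix | None = None


def default_matrix() -> AminoAcidSimilarityMatrix:
    """The shipped similarity matrix, loaded once per process."""
    global _DEFAULT_MATRIX
    if _DEFAULT_MATRIX is None:
        _DEFAULT_MATRIX = AminoAcidSimilarityMatrix.load()
    return _DEFAULT_MATRIX


def grantham_similarity(
    a: str, b: str, matrix: AminoAcidSimilarityMatrix | None = None
) -> float:
    """Similarity ``1 - GranthamDistance(a, b)/215`` on [0, 1].

    Accepts the 20 standard one-letter codes plus B, Z and X (averaged);
    case-insensitive.  Unknown codes (including U/O) raise
    :class:`InvalidResidueError` rather than scoring 0.
    """
    return (matrix or default_matrix()).similarity(a, b)


def _considered_columns(
    ref_aligned: str,
    hom_aligned: str,
    columns: Iterable[int] | None,
) -> list[int]:
    if len(ref_aligned) != len(hom_aligned):
        raise AlignmentFrameError(
            f"aligned lengths differ: {len(ref_aligned)} vs {len(hom_aligned)}"
        )
    if columns is None:
        idx = range(len(ref_aligned))
    else:
        idx = sorted(columns)
        for c in idx:
            if not 0 <= c < len(ref_aligned):
                raise AlignmentFrameError(f"column {c} outside alignment length")
    # columns where the reference itself is gapped carry no reference residue
    return [c for c in idx if ref_aligned[c] not in GAP_CHARS]


def pairwise_identity(
    ref_aligned: str,
    hom_aligned: str,
    columns: Iterable[int] | None = None,
    alignment_denominator: bool = False,
) -> float:
    """Fraction of considered columns with identical residues.

    Columns are 0-based alignment indices; when omitted, all columns are
    considered.  By default reference-gap columns are dropped from the
    denominator; with ``alignment_denominator`` every considered column
    counts (reference-gap columns then score as mismatches).  A gap in
    the homologue always counts as a mismatch.
    """
    cols = _considered_columns(ref_aligned, hom_aligned, columns)
    if alignment_denominator:
        denom = (
            len(ref_aligned)
            if columns is None
            else len(set(columns))
        )
    else:
        denom = len(cols)
    if not denom:
        raise EmptyRegionError("no usable columns for identity")
    hits = sum(
        1
        for c in cols
        if hom_aligned[c] not in GAP_CHARS
        and ref_aligned[c].upper() == hom_aligned[c].upper()
    )
    return hits / denom


def pairwise_similarity(
    ref_aligned: str,
    hom_aligned: str,
    columns: Iterable[int] | None = None,
    matrix: AminoAcidSimilarityMatrix | None = None,
) -> float:
    """Mean Grantham-based similarity over considered columns.

    Same column conventions as :func:`pairwise_identity`; a homologue gap
    contributes similarity 0 at that column.
    """
    cols = _considered_columns(ref_aligned, hom_aligned, columns)
    if not cols:
        raise EmptyRegionError("no usable columns for similarity")
    m = matrix or default_matrix()
    total = 0.0
    for c in cols:
        if hom_aligned[c] in GAP_CHARS:
            continue  # contributes 0
        total += m.similarity(ref_aligned[c], hom_aligned[c])
    return total / len(cols)
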