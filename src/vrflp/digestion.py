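"""In-silico restriction digestion and binary RFLP profiling.

Recognition sites are written with a cut mark (``AG'CT``); degenerate
positions use IUPAC codes.  A sequence position matches a recognition
position when the sequence symbol's base set is a subset of the recognition
symbol's base set — an ambiguous sequence base never certifies a definite
site.  Scanning is single-strand over linear sequences; all ten built-in
enzymes have self-reverse-complementary recognition patterns, so this
loses nothing for the default set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .seqio import IUPAC_SETS, SequenceRecord, as_frame

CUT_MARKS = ("'", "’", "`")

_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "D": "H", "H": "D", "V": "B", "N": "N",
}

# Base-set bitmasks (A=1, C=2, G=4, T=8) for vectorized subset matching.
_BITS = {
    sym: sum(1 << "ACGT".index(b) for b in bases)
    for sym, bases in IUPAC_SETS.items()
}


class EnzymeError(ValueError):
    """Raised for malformed enzyme definitions."""


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction enzyme: recognition pattern plus cut offset.

    ``cut_offset`` is the index of the cut mark within the written site,
    i.e. the enzyme cleaves between recognition positions
    ``cut_offset - 1`` and ``cut_offset``.
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not self.name:
            raise EnzymeError("enzyme name must be nonempty")
        if not self.recognition:
            raise EnzymeError(f"{self.name}: empty recognition site")
        bad = set(self.recognition) - set(IUPAC_SETS)
        if bad:
            raise EnzymeError(
                f"{self.name}: non-IUPAC symbol {sorted(bad)[0]!r} "
                "in recognition site"
            )
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise EnzymeError(
                f"{self.name}: cut offset {self.cut_offset} outside "
                f"[0, {len(self.recognition)}]"
            )

    @property
    def site_with_mark(self) -> str:
        return (self.recognition[: self.cut_offset] + "'"
                + self.recognition[self.cut_offset:])

    def is_palindromic(self) -> bool:
        """True when the recognition pattern equals its reverse complement."""
        rc = "".join(_COMPLEMENT[s] for s in reversed(self.recognition))
        return rc == self.recognition


def compile_enzyme(name: str, site_with_mark: str) -> RestrictionEnzyme:
    """Parse a written site like ``AG'CT`` into a :class:`RestrictionEnzyme`.

    Exactly one cut mark (apostrophe variants ``'``, ``’`` or a backtick)
    must be present.
    """
    site = site_with_mark.strip().upper()
    positions = [i for i, ch in enumerate(site) if ch in CUT_MARKS]
    if len(positions) != 1:
        raise EnzymeError(
            f"{name}: recognition site {site_with_mark!r} must contain "
            f"exactly one cut mark, found {len(positions)}"
        )
    offset = positions[0]
    recognition = site[:offset] + site[offset + 1:]
    return RestrictionEnzyme(name=name, recognition=recognition,
                             cut_offset=offset)


#: The ten tetrameric/pentameric enzymes routinely used for 16S ribotyping.
DEFAULT_ENZYME_SITES: tuple[tuple[str, str], ...] = (
    ("AluI", "AG'CT"),
    ("BstUI", "CG'CG"),
    ("DdeI", "C'TNAG"),
    ("HaeIII", "GG'CC"),
    ("HhaI", "GCG'C"),
    ("HinfI", "G'ANTC"),
    ("MboI", "'GATC"),
    ("MspI", "C'CGG"),
    ("RsaI", "GT'AC"),
    ("TaqI", "T'CGA"),
)


def default_enzymes() -> list[RestrictionEnzyme]:
    """The built-in ten-enzyme registry, in canonical order."""
    return [compile_enzyme(n, s) for n, s in DEFAULT_ENZYME_SITES]


def read_enzyme_table(path) -> list[RestrictionEnzyme]:
    """Read a TSV of ``name<TAB>site_with_cut_mark`` rows."""
    enzymes: list[RestrictionEnzyme] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise EnzymeError(f"{path}:{lineno}: expected name and site")
            enz = compile_enzyme(parts[0], parts[1])
            if not enz.is_palindromic():
                warnings.warn(
                    f"enzyme {enz.name} recognition {enz.recognition} is not "
                    "palindromic; only the given strand is scanned",
                    stacklevel=2,
                )
            enzymes.append(enz)
    if not enzymes:
        raise EnzymeError(f"no enzymes found in {path}")
    return enzymes


def _encode(residues: str) -> np.ndarray:
    if "-" in residues or "." in residues:
        raise ValueError("sequence contains gap characters; strip gaps first")
    try:
        return np.array([_BITS[ch] for ch in residues], dtype=np.uint8)
    except KeyError as exc:
        raise ValueError(f"illegal sequence symbol {exc.args[0]!r}") from exc


def find_sites(residues: str, enzyme: RestrictionEnzyme) -> list[int]:
    """All 0-based start indices of recognition matches, overlaps included."""
    m = len(enzyme.recognition)
    n = len(residues)
    if n < m:
        return []
    seq = _encode(residues)
    pat = [_BITS[s] for s in enzyme.recognition]
    ok = np.ones(n - m + 1, dtype=bool)
    for k, bits in enumerate(pat):
        # subset test: every base compatible with the sequence symbol must
        # also be compatible with the recognition symbol
        ok &= (seq[k: n - m + 1 + k] & ~np.uint8(bits)) == 0
    return [int(i) for i in np.flatnonzero(ok)]


@dataclass(frozen=True)
class DigestResult:
    """Digest of one ungapped sequence with one enzyme.

    ``fragments`` are ``(start, end, length)`` half-open intervals that
    partition the sequence; their lengths sum to the sequence length.
    """

    strain: str
    enzyme: str
    sequence_length: int
    match_starts: tuple[int, ...]
    cut_points: tuple[int, ...]
    fragments: tuple[tuple[int, int, int], ...]

    @property
    def fragment_lengths(self) -> tuple[int, ...]:
        return tuple(f[2] for f in self.fragments)

    def __post_init__(self) -> None:
        assert sum(self.fragment_lengths) == self.sequence_length
        assert len(self.fragments) == len(self.cut_points) + 1


def digest(residues: str, enzyme: RestrictionEnzyme,
           strain: str = "") -> DigestResult:
    """Digest an ungapped sequence: cut at ``start + cut_offset`` for every
    recognition match; fragments are the intervals between cuts."""
    starts = find_sites(residues, enzyme)
    n = len(residues)
    cuts = sorted({s + enzyme.cut_offset for s in starts} - {0, n})
    bounds = [0, *cuts, n]
    fragments = tuple(
        (a, b, b - a) for a, b in zip(bounds, bounds[1:])
    )
    return DigestResult(
        strain=strain,
        enzyme=enzyme.name,
        sequence_length=n,
        match_starts=tuple(starts),
        cut_points=tuple(cuts),
        fragments=fragments,
    )


def digest_all(
    sequences: Sequence[SequenceRecord],
    enzymes: Sequence[RestrictionEnzyme],
) -> list[DigestResult]:
    """Digest every sequence (gaps stripped) with every enzyme."""
    return [
        digest(rec.ungapped, enz, strain=rec.id)
        for rec in sequences
        for enz in enzymes
    ]


@dataclass(frozen=True)
class BinaryProfileMatrix:
    """Strains x features 0/1 matrix (site-level or band-level profiles)."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.uint8)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise ValueError("profile matrix must be two-dimensional")
        if values.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("matrix shape does not match labels")
        if len(set(self.row_labels)) != len(self.row_labels):
            raise ValueError("duplicate row labels")
        if len(set(self.col_labels)) != len(self.col_labels):
            raise ValueError("duplicate column labels")
        if not np.isin(values, (0, 1)).all():
            raise ValueError("profile matrix cells must be 0 or 1")

    def to_frame(self, symbols: bool = False) -> pd.DataFrame:
        """As a labeled DataFrame; ``symbols=True`` renders cells "+"/"-"."""
        df = as_frame(self.values.tolist(), self.row_labels, self.col_labels)
        if symbols:
            df = df.map(lambda v: "+" if v else "-")
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BinaryProfileMatrix":
        symbol_map = {"+": 1, "-": 0, "−": 0}
        values = df.map(lambda v: symbol_map.get(v, v)).to_numpy(dtype=float)
        return cls(
            row_labels=tuple(str(i) for i in df.index),
            col_labels=tuple(str(c) for c in df.columns),
            values=values.astype(np.uint8),
        )

    def row(self, label: str) -> np.ndarray:
        return self.values[self.row_labels.index(label)]

    def column(self, label: str) -> np.ndarray:
        return self.values[:, self.col_labels.index(label)]


def site_matrix(
    sequences: Sequence[SequenceRecord],
    enzymes: Sequence[RestrictionEnzyme],
) -> BinaryProfileMatrix:
    """Presence/absence of >=1 recognition site per strain per enzyme.

    Gaps are stripped per sequence before scanning; row order follows the
    input sequences, column order the input enzymes.
    """
    if not sequences or not enzymes:
        raise ValueError("need at least one sequence and one enzyme")
    values = np.zeros((len(sequences), len(enzymes)), dtype=np.uint8)
    for i, rec in enumerate(sequences):
        ungapped = rec.ungapped
        for j, enz in enumerate(enzymes):
            values[i, j] = 1 if find_sites(ungapped, enz) else 0
    return BinaryProfileMatrix(
        row_labels=tuple(r.id for r in sequences),
        col_labels=tuple(e.name for e in enzymes),
        values=values,
    )


def _bin_lengths(lengths: Sequence[int], tolerance: float) -> list[list[int]]:
    """Single-linkage binning of fragment lengths: adjacent sorted lengths
    join one bin when their relative difference (gap over the smaller
    length) is <= tolerance."""
    uniq = sorted(set(lengths))
    bins: list[list[int]] = []
    for length in uniq:
        if bins and (length - bins[-1][-1]) <= tolerance * bins[-1][-1]:
            bins[-1].append(length)
        else:
            bins.append([length])
    return bins


def band_matrix(
    digests: Iterable[DigestResult],
    tolerance: float = 0.0,
) -> BinaryProfileMatrix:
    """Band-level binary profiles: one column per (enzyme, length-bin).

    Fragment lengths of each enzyme are clustered across strains by
    single linkage; tolerance 0 keeps exact-length bins.  A cell is 1 when
    the strain has at least one fragment in the bin.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    digests = list(digests)
    strains = list(dict.fromkeys(d.strain for d in digests))
    enzymes = list(dict.fromkeys(d.enzyme for d in digests))
    per_enzyme: dict[str, list[DigestResult]] = {e: [] for e in enzymes}
    for d in digests:
        per_enzyme[d.enzyme].append(d)
    for enz, ds in per_enzyme.items():
        if {d.strain for d in ds} != set(strains):
            raise ValueError(
                f"enzyme {enz}: digests missing for some strains"
            )

    col_labels: list[str] = []
    columns: list[np.ndarray] = []
    strain_index = {s: i for i, s in enumerate(strains)}
    for enz in enzymes:
        ds = per_enzyme[enz]
        all_lengths = [ln for d in ds for ln in d.fragment_lengths]
        bins = _bin_lengths(all_lengths, tolerance)
        for bin_lengths in bins:
            members = set(bin_lengths)
            col = np.zeros(len(strains), dtype=np.uint8)
            for d in ds:
                if members & set(d.fragment_lengths):
                    col[strain_index[d.strain]] = 1
            col_labels.append(f"{enz}:{bin_lengths[0]}")
            columns.append(col)
    return BinaryProfileMatrix(
        row_labels=tuple(strains),
        col_labels=tuple(col_labels),
        values=np.column_stack(columns) if columns else
        np.zeros((len(strains), 0), dtype=np.uint8),
    )


def otu_counts(digests: Iterable[DigestResult]) -> pd.DataFrame:
    """Fragment (OTU) counts as a strains x enzymes table."""
    digests = list(digests)
    strains = list(dict.fromkeys(d.strain for d in digests))
    enzymes = list(dict.fromkeys(d.enzyme for d in digests))
    table = pd.DataFrame(0, index=strains, columns=enzymes, dtype=int)
    for d in digests:
        table.loc[d.strain, d.enzyme] = len(d.fragments)
    return table


def fragments_table(digests: Iterable[DigestResult]) -> pd.DataFrame:
    """Long-format fragment report: strain, enzyme, count, lengths."""
    rows = [
        {
            "strain": d.strain,
            "enzyme": d.enzyme,
            "n_fragments": len(d.fragments),
            "fragment_lengths": ",".join(map(str, d.fragment_lengths)),
        }
        for d in digests
    ]
    return pd.DataFrame(rows, columns=["strain", "enzyme", "n_fragments",
                                       "fragment_lengths"])
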