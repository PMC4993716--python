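"""Group-structured synthetic aligned datasets for exercising the pipeline.

The generator draws a random ancestor, derives one ancestor per group by
independent per-site substitution (probability ``d_between``, uniform over
the three alternative bases), then derives group members the same way at
rate ``d_within`` (star topology within groups).  Recognition sites can be
planted into chosen groups and knocked out again by a single point
substitution; gap columns are injected last as alignment artifacts.

Everything is a pure function of the seed: the same config reproduces the
same dataset byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .digestion import (
    BinaryProfileMatrix,
    RestrictionEnzyme,
    default_enzymes,
)
from .seqio import (
    IUPAC_SETS,
    AlignedSet,
    GroupAssignment,
    SequenceRecord,
    write_fasta,
    write_group_map,
)

_BASES = np.array(list("ACGT"))

#: Default 3-group composition mirroring a 19-strain 16S study layout.
DEFAULT_GROUPS: tuple[tuple[str, int], ...] = (
    ("pseudomonas", 4),
    ("proteobacteria", 7),
    ("actinobacteria", 8),
)


@dataclass(frozen=True)
class PlantedSite:
    """A recognition site written into the members of selected groups."""

    enzyme: str
    position: int
    groups: tuple[str, ...]


@dataclass(frozen=True)
class SynthConfig:
    seed: int = 0
    length: int = 458
    groups: tuple[tuple[str, int], ...] = DEFAULT_GROUPS
    d_within: float = 0.01
    d_between: float = 0.30
    gap_columns: int = 0
    planted_sites: tuple[PlantedSite, ...] = ()
    knockouts: tuple[tuple[str, str], ...] = ()  # (enzyme, group)

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if not self.groups:
            raise ValueError("need at least one group")
        if not 0.0 <= self.d_within <= self.d_between <= 0.75:
            raise ValueError("require 0 <= d_within <= d_between <= 0.75")
        if self.gap_columns < 0:
            raise ValueError("gap_columns must be >= 0")


@dataclass(frozen=True)
class SynthDataset:
    alignment: AlignedSet
    groups: GroupAssignment
    #: strain id -> enzyme name -> expected site presence, for every
    #: planted enzyme (background sequence may add extra sites by chance)
    truth: dict[str, dict[str, bool]]


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator
            ) -> np.ndarray:
    """Substitute each site with probability ``rate``, uniformly among the
    three alternative bases."""
    out = seq.copy()
    hit = np.flatnonzero(rng.random(seq.size) < rate)
    if hit.size:
        out[hit] = (out[hit] + rng.integers(1, 4, size=hit.size)) % 4
    return out


def _enzyme_by_name(name: str) -> RestrictionEnzyme:
    for enz in default_enzymes():
        if enz.name == name:
            return enz
    raise KeyError(f"unknown enzyme {name!r}")


def _concretize(recognition: str, rng: np.random.Generator) -> str:
    """Replace degenerate positions with one concrete base."""
    return "".join(
        sym if sym in "ACGT"
        else rng.choice(sorted(IUPAC_SETS[sym]))
        for sym in recognition
    )


def generate(config: SynthConfig) -> SynthDataset:
    """Generate an aligned dataset per the config; deterministic in seed."""
    rng = np.random.default_rng(config.seed)
    L = config.length
    group_names = [g for g, _ in config.groups]

    planted = {s.enzyme: s for s in config.planted_sites}
    if len(planted) != len(config.planted_sites):
        raise ValueError("at most one planted site per enzyme")
    site_spans: list[tuple[int, int, PlantedSite]] = []
    for spec in config.planted_sites:
        enz = _enzyme_by_name(spec.enzyme)
        span = (spec.position, spec.position + len(enz.recognition))
        if span[0] < 0 or span[1] > L:
            raise ValueError(
                f"planted {spec.enzyme} site at {spec.position} exceeds "
                f"sequence length {L}"
            )
        for a, b, other in site_spans:
            if span[0] < b and a < span[1]:
                raise ValueError(
                    f"planted sites {other.enzyme} and {spec.enzyme} overlap"
                )
        site_spans.append((*span, spec))
        unknown = set(spec.groups) - set(group_names)
        if unknown:
            raise ValueError(f"planted site names unknown groups {unknown}")
    for enz_name, group in config.knockouts:
        if enz_name not in planted:
            raise ValueError(
                f"knockout of {enz_name} has no corresponding planted site"
            )
        if group not in group_names:
            raise ValueError(f"knockout names unknown group {group!r}")

    ancestor = rng.integers(0, 4, size=L)
    rows: list[np.ndarray] = []
    ids: list[str] = []
    mapping: dict[str, str] = {}
    for gname, size in config.groups:
        ganc = _mutate(ancestor, config.d_between, rng)
        for k in range(1, size + 1):
            sid = f"{gname}_{k}"
            rows.append(_mutate(ganc, config.d_within, rng))
            ids.append(sid)
            mapping[sid] = gname

    chars = _BASES[np.stack(rows)]

    # plant recognition sites into carrying groups (one concrete instance
    # per site, shared by all carriers)
    knocked = set(config.knockouts)
    truth: dict[str, dict[str, bool]] = {sid: {} for sid in ids}
    for spec in config.planted_sites:
        enz = _enzyme_by_name(spec.enzyme)
        concrete = _concretize(enz.recognition, rng)
        mid = len(enz.recognition) // 2
        allowed = IUPAC_SETS[enz.recognition[mid]]
        ko_base = rng.choice(sorted(set("ACGT") - allowed))
        for i, sid in enumerate(ids):
            g = mapping[sid]
            carries = g in spec.groups
            if carries:
                for off, base in enumerate(concrete):
                    chars[i, spec.position + off] = base
            if (spec.enzyme, g) in knocked:
                chars[i, spec.position + mid] = ko_base
                carries = False
            truth[sid][spec.enzyme] = carries

    # gap columns: alignment artifacts, away from planted sites
    if config.gap_columns:
        blocked = {
            c for a, b, _ in site_spans for c in range(a, b)
        }
        candidates = np.array(sorted(set(range(L)) - blocked))
        if candidates.size < config.gap_columns:
            raise ValueError("length too small for requested gap columns")
        cols = rng.choice(candidates, size=config.gap_columns, replace=False)
        for col in cols:
            row = int(rng.integers(0, len(ids)))
            chars[row, col] = "-"

    records = tuple(
        SequenceRecord(id=sid, residues="".join(chars[i]), group=mapping[sid])
        for i, sid in enumerate(ids)
    )
    return SynthDataset(
        alignment=AlignedSet(records),
        groups=GroupAssignment(mapping),
        truth=truth,
    )


def write_dataset(dataset: SynthDataset, outdir: str | Path) -> dict[str, Path]:
    """Write alignment FASTA, group map TSV and truth JSON into a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "alignment": outdir / "alignment.fasta",
        "groups": outdir / "groups.tsv",
        "truth": outdir / "truth.json",
    }
    write_fasta(dataset.alignment.records, paths["alignment"])
    write_group_map(dataset.groups, paths["groups"])
    paths["truth"].write_text(json.dumps(dataset.truth, indent=2) + "\n")
    return paths


# ---------------------------------------------------------------------------
# Published 19-strain x 10-enzyme site-presence fixture (strains a-s).
# Transcribed presence (+) / absence (-) calls of each enzyme's recognition
# site across the 19 study strains.

_SITE_TABLE = """
enzyme	abcdefghijklmnopqrs
AluI	+++++++++++++++--++
BstUI	++++++++++++++++-++
DdeI	+-++-++++++++++-+++
HaeIII	+++++++++++++++++++
HhaI	+++++++++++++++++++
HinfI	+++++++++++++++----
MboI	+++++++++++++-++-++
MspI	+++++++++++-+++-+++
RsaI	+++++++++++++++++++
TaqI	+++++++++++++++--++
"""

STRAIN_LETTERS = tuple("abcdefghijklmnopqrs")

#: Accessions of the 19 study strains, keyed by their RFLP group letter.
STRAIN_ACCESSIONS: dict[str, str] = dict(
    zip(
        STRAIN_LETTERS,
        (
            "JN685209", "L40622", "AF158687", "AM040443", "JQ723680",
            "DQ234174", "HM363289", "EU600210", "KF783212", "KF733608",
            "AF094748", "KJ911224", "KJ911225", "KJ911226", "KJ911227",
            "JQ480013", "JQ480011", "JQ480009", "JQ480012",
        ),
    )
)


def table2_fixture() -> BinaryProfileMatrix:
    """The packaged 19x10 strain-by-enzyme site presence/absence matrix."""
    rows: dict[str, str] = {}
    for line in _SITE_TABLE.strip().splitlines()[1:]:
        enzyme, calls = line.split("\t")
        assert len(calls) == len(STRAIN_LETTERS)
        rows[enzyme] = calls
    enzymes = list(rows)
    values = np.array(
        [
            [1 if rows[e][i] == "+" else 0 for e in enzymes]
            for i in range(len(STRAIN_LETTERS))
        ],
        dtype=np.uint8,
    )
    return BinaryProfileMatrix(
        row_labels=STRAIN_LETTERS,
        col_labels=tuple(enzymes),
        values=values,
    )
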