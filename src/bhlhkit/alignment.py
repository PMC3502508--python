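"""Enumerated bHLH domain alignments.

An :class:`EnumeratedAlignment` holds domain sequences mapped onto the fixed
bHLH site numbering (see :mod:`bhlhkit.coordinates`): every record covers all
43 basic/helix sites (gap-padded where a residue is absent) and may carry
loop residues, which never enter numeric datasets.

Supported formats:

* aligned FASTA with exactly 43 columns, column *k* mapping to the *k*-th
  fixed site (gap character ``-``);
* TSV with columns ``sequence_id``, ``kingdom``, ``site_1`` .. ``site_28``,
  ``site_50`` .. ``site_64`` (and optionally loop columns ``site_29`` ..).

Ambiguity codes (B, Z, X, U, O) carry no factor scores and are mapped to GAP
with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .coordinates import DEFAULT_COORDINATES, CoordinateMap

logger = logging.getLogger(__name__)

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
GAP: str = "-"
AMBIGUOUS: frozenset[str] = frozenset("BZXUO")
KINGDOMS: tuple[str, ...] = ("Plant", "Animal", "Fungal")
UNCLASSIFIED: str = "Unclassified"


class AlignmentParseError(ValueError):
    """Malformed alignment input (names the offending record)."""


class AlphabetError(ValueError):
    """Residue symbol outside the 20 canonical amino acids + gap."""


def _clean_residue(symbol: str, record_id: str, site: int) -> str:
    s = str(symbol).strip().upper()
    if s in ("", ".", GAP, "NAN"):
        return GAP
    if s in AMBIGUOUS:
        logger.warning(
            "record %s site %d: ambiguity code %s mapped to GAP", record_id, site, s
        )
        return GAP
    if s not in AMINO_ACIDS:
        raise AlphabetError(
            f"record {record_id!r} site {site}: invalid residue symbol {s!r}"
        )
    return s


@dataclass
class EnumeratedAlignment:
    """bHLH domain records on the fixed site coordinate system.

    Parameters
    ----------
    residues : pandas.DataFrame
        Object-dtype frame, index = unique sequence ids (input order
        preserved), columns = integer site numbers.  All 43 fixed sites are
        present; loop sites are optional.
    kingdom : pandas.Series or None
        Kingdom label per record; ``None`` when labels are unknown.
    coordinates : CoordinateMap
    """

    residues: pd.DataFrame
    kingdom: pd.Series | None = None
    coordinates: CoordinateMap = field(default_factory=lambda: DEFAULT_COORDINATES)

    def __post_init__(self) -> None:
        fixed = self.coordinates.fixed_sites
        missing = [s for s in fixed if s not in self.residues.columns]
        if missing:
            raise AlignmentParseError(f"alignment lacks fixed sites {missing}")
        if self.residues.index.has_duplicates:
            dupes = self.residues.index[self.residues.index.duplicated()].unique()
            raise AlignmentParseError(f"duplicated sequence_id(s): {list(dupes)}")
        allowed = set(fixed) | set(self.coordinates.loop_sites)
        extra = [c for c in self.residues.columns if c not in allowed]
        if extra:
            raise AlignmentParseError(f"unknown site columns {extra}")
        if self.kingdom is not None:
            self.kingdom = self.kingdom.reindex(self.residues.index)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def ids(self) -> list[str]:
        return list(self.residues.index)

    def fixed_residues(self) -> pd.DataFrame:
        """Residues restricted to the 43 fixed sites, in site order."""
        return self.residues[self.coordinates.fixed_sites]

    def record(self, sequence_id: str) -> dict[int, str]:
        return self.residues.loc[sequence_id].to_dict()

    def subset(self, ids: Iterable[str]) -> "EnumeratedAlignment":
        ids = list(ids)
        k = self.kingdom.loc[ids] if self.kingdom is not None else None
        return EnumeratedAlignment(self.residues.loc[ids], k, self.coordinates)

    @classmethod
    def from_records(
        cls,
        records: Mapping[str, Mapping[int, str]],
        kingdom: Mapping[str, str] | None = None,
        coordinates: CoordinateMap = DEFAULT_COORDINATES,
    ) -> "EnumeratedAlignment":
        """Build from ``{id: {site: residue}}`` dictionaries."""
        rows = {}
        for rid, sitemap in records.items():
            rows[rid] = {
                int(s): _clean_residue(r, rid, int(s)) for s, r in sitemap.items()
            }
        df = pd.DataFrame.from_dict(rows, orient="index")
        for s in coordinates.fixed_sites:
            if s not in df.columns:
                df[s] = GAP
        df = df[sorted(df.columns)].fillna(GAP).astype(object)
        k = pd.Series(dict(kingdom)) if kingdom is not None else None
        return cls(df, k, coordinates)


def read_alignment_fasta(
    path: str | Path, coordinates: CoordinateMap = DEFAULT_COORDINATES
) -> EnumeratedAlignment:
    """Read a 43-column aligned FASTA; column *k* maps to the *k*-th fixed site."""
    fixed = coordinates.fixed_sites
    rows: dict[str, dict[int, str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if len(seq) != len(fixed):
            raise AlignmentParseError(
                f"record {rec.id!r}: aligned length {len(seq)} != {len(fixed)} fixed sites"
            )
        if rec.id in rows:
            raise AlignmentParseError(f"duplicated sequence_id(s): [{rec.id!r}]")
        rows[rec.id] = {
            site: _clean_residue(ch, rec.id, site) for site, ch in zip(fixed, seq)
        }
    if not rows:
        raise AlignmentParseError(f"no FASTA records in {path}")
    return EnumeratedAlignment.from_records(rows, coordinates=coordinates)


def write_alignment_fasta(
    alignment: EnumeratedAlignment, path: str | Path
) -> None:
    """Write the 43 fixed-site columns as aligned FASTA."""
    recs = [
        SeqRecord(Seq("".join(row)), id=rid, description="")
        for rid, row in alignment.fixed_residues().iterrows()
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_alignment_tsv(
    path: str | Path, coordinates: CoordinateMap = DEFAULT_COORDINATES
) -> EnumeratedAlignment:
    """Read a TSV with sequence_id, kingdom, and site_<n> columns."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sequence_id" not in df.columns:
        raise AlignmentParseError("TSV lacks a sequence_id column")
    if df["sequence_id"].duplicated().any():
        dupes = df.loc[df["sequence_id"].duplicated(), "sequence_id"].unique()
        raise AlignmentParseError(f"duplicated sequence_id(s): {list(dupes)}")
    site_cols = {c: int(c.split("_", 1)[1]) for c in df.columns if c.startswith("site_")}
    if not site_cols:
        raise AlignmentParseError("TSV lacks site_<n> columns")
    records = {}
    for _, row in df.iterrows():
        rid = row["sequence_id"]
        records[rid] = {s: row[c] for c, s in site_cols.items()}
    kingdom = None
    if "kingdom" in df.columns:
        labels = df.set_index("sequence_id")["kingdom"]
        if labels.notna().any():
            kingdom = labels
    return EnumeratedAlignment.from_records(records, kingdom, coordinates)


def write_alignment_tsv(alignment: EnumeratedAlignment, path: str | Path) -> None:
    out = alignment.residues.copy()
    out.columns = [f"site_{s}" for s in out.columns]
    out.insert(0, "kingdom", alignment.kingdom if alignment.kingdom is not None else "")
    out.index.name = "sequence_id"
    out.to_csv(path, sep="\t")


def read_alignment(
    path: str | Path, coordinates: CoordinateMap = DEFAULT_COORDINATES
) -> EnumeratedAlignment:
    """Dispatch on extension: .tsv/.txt -> TSV, otherwise aligned FASTA."""
    p = Path(path)
    if p.suffix.lower() in (".tsv", ".txt"):
        return read_alignment_tsv(p, coordinates)
    return read_alignment_fasta(p, coordinates)
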