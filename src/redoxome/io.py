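"""Readers, writers and validated domain types for every external format the
pipeline touches.

All tabular I/O is TSV (tab-separated, UTF-8, header row, '.' decimal): the
universal interchange format of post-search proteomics tooling.  Protein
sequences travel as FASTA; the accession of a record is the first
whitespace-delimited token of its header, the common UniProt convention.
Missing reporter values are written as empty cells and read back as *absent*
(not zero): a zero signal-to-noise and a channel that was never quantified
are distinct states in TMT data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    AnnotationError,
    ConsistencyError,
    CrossReferenceError,
    DesignError,
    FormatError,
)

GROUPS = ("control", "depleted")
FRACTIONS = ("oxidized", "total")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Sequence alphabet: the 20 standard residues plus 'X' (unknown / padding).
SEQUENCE_ALPHABET = frozenset(AMINO_ACIDS) | {"X"}

#: Serialised float precision for all tables (round-trip stable to 12
#: significant digits).
FLOAT_FORMAT = "%.12g"


# ---------------------------------------------------------------------------
# Plex design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlexEntry:
    """One multiplex channel: which biological sample, experimental group and
    half-sample fraction it carries."""

    channel_id: str
    sample_id: str
    group: str      # "control" | "depleted"
    fraction: str   # "oxidized" | "total"


@dataclass
class PlexDesign:
    """Channel → (sample, group, fraction) map for a single multiplex run.

    Invariants (enforced on construction):

    * channel ids are unique within the plex,
    * every (sample, fraction) pair appears exactly once,
    * every sample appears with *both* fractions — the paired half-sample
      design is what makes the oxidized/total ratio well defined.
    """

    plex_id: str
    entries: list[PlexEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen_channels: set[str] = set()
        seen_pairs: set[tuple[str, str]] = set()
        sample_fractions: dict[str, set[str]] = {}
        sample_groups: dict[str, set[str]] = {}
        for e in self.entries:
            if e.group not in GROUPS:
                raise DesignError(
                    f"plex {self.plex_id!r}: unknown group {e.group!r} "
                    f"(expected one of {GROUPS})"
                )
            if e.fraction not in FRACTIONS:
                raise DesignError(
                    f"plex {self.plex_id!r}: unknown fraction {e.fraction!r} "
                    f"(expected one of {FRACTIONS})"
                )
            if e.channel_id in seen_channels:
                raise DesignError(
                    f"plex {self.plex_id!r}: duplicate channel_id {e.channel_id!r}"
                )
            seen_channels.add(e.channel_id)
            pair = (e.sample_id, e.fraction)
            if pair in seen_pairs:
                raise DesignError(
                    f"plex {self.plex_id!r}: sample {e.sample_id!r} has more "
                    f"than one {e.fraction!r} channel"
                )
            seen_pairs.add(pair)
            sample_fractions.setdefault(e.sample_id, set()).add(e.fraction)
            sample_groups.setdefault(e.sample_id, set()).add(e.group)
        for sample, fracs in sample_fractions.items():
            if fracs != set(FRACTIONS):
                missing = set(FRACTIONS) - fracs
                raise DesignError(
                    f"plex {self.plex_id!r}: sample {sample!r} lacks "
                    f"{sorted(missing)} fraction(s); each sample needs both "
                    f"half-samples"
                )
        for sample, groups in sample_groups.items():
            if len(groups) > 1:
                raise DesignError(
                    f"plex {self.plex_id!r}: sample {sample!r} assigned to "
                    f"multiple groups {sorted(groups)}"
                )

    @property
    def channel_map(self) -> dict[str, tuple[str, str]]:
        """channel_id → (sample_id, fraction)."""
        return {e.channel_id: (e.sample_id, e.fraction) for e in self.entries}

    @property
    def samples(self) -> list[str]:
        out: list[str] = []
        for e in self.entries:
            if e.sample_id not in out:
                out.append(e.sample_id)
        return out

    @property
    def sample_groups(self) -> dict[str, str]:
        return {e.sample_id: e.group for e in self.entries}


def sample_group_map(designs: Sequence[PlexDesign]) -> dict[str, str]:
    """sample_id → group over a set of plexes (a sample lives in one plex)."""
    out: dict[str, str] = {}
    for d in designs:
        for s, g in d.sample_groups.items():
            if s in out and out[s] != g:
                raise DesignError(
                    f"sample {s!r} assigned to different groups across plexes"
                )
            out[s] = g
    return out


def read_plex_design(path: str | Path) -> list[PlexDesign]:
    """Read a plex-design TSV.

    Required columns: channel_id, sample_id, group, fraction.  An optional
    plex_id column splits rows into several multiplex runs; without it all
    rows form a single plex ``"plex1"``.  Returns one validated
    :class:`PlexDesign` per plex.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["channel_id", "sample_id", "group", "fraction"]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if "plex_id" not in df.columns:
        df["plex_id"] = "plex1"
    designs = []
    for plex_id, sub in df.groupby("plex_id", sort=True):
        entries = [
            PlexEntry(r.channel_id, r.sample_id, r.group, r.fraction)
            for r in sub.itertuples(index=False)
        ]
        designs.append(PlexDesign(str(plex_id), entries))
    return designs


def write_plex_design(designs: Sequence[PlexDesign], path: str | Path) -> None:
    rows = [
        {
            "plex_id": d.plex_id,
            "channel_id": e.channel_id,
            "sample_id": e.sample_id,
            "group": e.group,
            "fraction": e.fraction,
        }
        for d in designs
        for e in d.entries
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Protein sequences
# ---------------------------------------------------------------------------

@dataclass
class ProteinDb:
    """Accession → amino-acid sequence (uppercase, 20 residues plus 'X')."""

    records: dict[str, str]

    def __post_init__(self) -> None:
        for acc, seq in self.records.items():
            if not seq:
                raise FormatError(f"protein {acc!r}: empty sequence")
            bad = set(seq) - SEQUENCE_ALPHABET
            if bad:
                raise FormatError(
                    f"protein {acc!r}: non-standard residue(s) {sorted(bad)}"
                )

    def __contains__(self, accession: str) -> bool:
        return accession in self.records

    def __getitem__(self, accession: str) -> str:
        return self.records[accession]

    def __len__(self) -> int:
        return len(self.records)


def read_fasta(path: str | Path) -> ProteinDb:
    """Read a protein FASTA; accession = first whitespace-delimited header
    token (so ``>sp|P19096|FAS_MOUSE desc`` → ``sp|P19096|FAS_MOUSE``)."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        acc = rec.id  # Biopython takes the first whitespace-delimited token
        if acc in records:
            raise FormatError(f"{path}: duplicate accession {acc!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: record {acc!r} has an empty sequence")
        records[acc] = seq
    return ProteinDb(records)


def write_fasta(db: ProteinDb, path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(seq), id=acc, description="")
        for acc, seq in db.records.items()
    ]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# PSM-level quantification records
# ---------------------------------------------------------------------------

@dataclass
class PsmQuantRecord:
    """One peptide-spectrum match with reporter signal-to-noise per channel.

    ``channel_values`` holds only *present* channels; an absent channel is an
    absent key, never a zero.  ``site_position`` is the 1-based index of the
    quantified cysteine in the protein.
    """

    peptide_sequence: str
    protein_accession: str
    site_position: int
    plex_id: str
    channel_values: dict[str, float]

    def validate(self, db: ProteinDb) -> None:
        if "C" not in self.peptide_sequence:
            raise ConsistencyError(
                f"peptide {self.peptide_sequence!r} contains no cysteine"
            )
        if self.protein_accession not in db:
            raise CrossReferenceError(
                f"accession {self.protein_accession!r} not present in the "
                f"sequence database"
            )
        seq = db[self.protein_accession]
        if not 1 <= self.site_position <= len(seq):
            raise ConsistencyError(
                f"site {self.protein_accession}:{self.site_position} is "
                f"outside the protein (length {len(seq)})"
            )
        residue = seq[self.site_position - 1]
        if residue != "C":
            raise ConsistencyError(
                f"site {self.protein_accession}:{self.site_position} points "
                f"at residue {residue!r}, not 'C'"
            )
        for ch, v in self.channel_values.items():
            if not math.isfinite(v) or v < 0:
                raise ValueError(
                    f"site {self.protein_accession}:{self.site_position} "
                    f"channel {ch!r}: reporter S/N {v!r} must be a "
                    f"non-negative finite number"
                )

    @property
    def n_cysteines(self) -> int:
        return self.peptide_sequence.count("C")

    @property
    def site_id(self) -> str:
        return f"{self.protein_accession}:{self.site_position}"


_PSM_FIXED_COLUMNS = ["peptide_sequence", "protein_accession", "site_position", "plex_id"]


def read_psm_table(path: str | Path, db: ProteinDb) -> list[PsmQuantRecord]:
    """Read a PSM quant TSV and validate every record against ``db``.

    Columns: peptide_sequence, protein_accession, site_position, plex_id,
    then one column per reporter channel.  Empty channel cells mean the
    channel was not quantified for that PSM.
    """
    df = pd.read_csv(path, sep="\t", dtype={"site_position": "Int64"})
    for col in _PSM_FIXED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    channel_cols = [c for c in df.columns if c not in _PSM_FIXED_COLUMNS]
    if not channel_cols:
        raise FormatError(f"{path}: no reporter channel columns found")
    psms: list[PsmQuantRecord] = []
    # itertuples mangles arbitrary channel names; index channel cells
    # positionally (fixed columns are reordered first)
    df = df[_PSM_FIXED_COLUMNS + channel_cols]
    for row in df.itertuples(index=False):
        values = {}
        for ch, v in zip(channel_cols, row[len(_PSM_FIXED_COLUMNS):]):
            if pd.notna(v):
                values[ch] = float(v)
        rec = PsmQuantRecord(
            peptide_sequence=str(row.peptide_sequence),
            protein_accession=str(row.protein_accession),
            site_position=int(row.site_position),
            plex_id=str(row.plex_id),
            channel_values=values,
        )
        rec.validate(db)
        psms.append(rec)
    return psms


def write_psm_table(
    psms: Iterable[PsmQuantRecord],
    path: str | Path,
    channels: Sequence[str] | None = None,
) -> None:
    psms = list(psms)
    if channels is None:
        seen: list[str] = []
        for p in psms:
            for ch in p.channel_values:
                if ch not in seen:
                    seen.append(ch)
        channels = seen
    rows = []
    for p in psms:
        row: dict[str, object] = {
            "peptide_sequence": p.peptide_sequence,
            "protein_accession": p.protein_accession,
            "site_position": p.site_position,
            "plex_id": p.plex_id,
        }
        for ch in channels:
            row[ch] = p.channel_values.get(ch, None)
        rows.append(row)
    df = pd.DataFrame(rows, columns=_PSM_FIXED_COLUMNS + list(channels))
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# Domain annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DomainInterval:
    protein_accession: str
    domain_label: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive


@dataclass
class DomainAnnotation:
    """Non-overlapping 1-based closed intervals labelling protein domains."""

    rows: list[DomainInterval]

    def __post_init__(self) -> None:
        by_protein: dict[str, list[DomainInterval]] = {}
        for r in self.rows:
            if r.start > r.end:
                raise AnnotationError(
                    f"{r.protein_accession} {r.domain_label!r}: start "
                    f"{r.start} > end {r.end}"
                )
            if r.start < 1:
                raise AnnotationError(
                    f"{r.protein_accession} {r.domain_label!r}: start must be ≥ 1"
                )
            by_protein.setdefault(r.protein_accession, []).append(r)
        for acc, ivs in by_protein.items():
            ivs = sorted(ivs, key=lambda r: r.start)
            for a, b in zip(ivs, ivs[1:]):
                if b.start <= a.end:
                    raise AnnotationError(
                        f"{acc}: domains {a.domain_label!r} and "
                        f"{b.domain_label!r} overlap"
                    )

    def validate_against(self, db: ProteinDb) -> None:
        for r in self.rows:
            if r.protein_accession not in db:
                raise CrossReferenceError(
                    f"domain annotation references unknown accession "
                    f"{r.protein_accession!r}"
                )
            if r.end > len(db[r.protein_accession]):
                raise AnnotationError(
                    f"{r.protein_accession} {r.domain_label!r}: end {r.end} "
                    f"exceeds sequence length "
                    f"{len(db[r.protein_accession])}"
                )

    def lookup(self, accession: str, position: int) -> str | None:
        """Domain label covering ``position`` (inclusive ends), else None."""
        for r in self.rows:
            if r.protein_accession == accession and r.start <= position <= r.end:
                return r.domain_label
        return None


def read_domain_annotation(
    path: str | Path, db: ProteinDb | None = None
) -> DomainAnnotation:
    df = pd.read_csv(path, sep="\t", dtype={"start": int, "end": int})
    for col in ("protein_accession", "domain_label", "start", "end"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    annot = DomainAnnotation(
        [
            DomainInterval(str(r.protein_accession), str(r.domain_label),
                           int(r.start), int(r.end))
            for r in df.itertuples(index=False)
        ]
    )
    if db is not None:
        annot.validate_against(db)
    return annot


def write_domain_annotation(annot: DomainAnnotation, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "protein_accession": r.protein_accession,
                "domain_label": r.domain_label,
                "start": r.start,
                "end": r.end,
            }
            for r in annot.rows
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Generic result tables
# ---------------------------------------------------------------------------

def site_id(accession: str, position: int) -> str:
    """Canonical site key ``accession:position`` (1-based position)."""
    return f"{accession}:{position}"


def parse_site_id(sid: str) -> tuple[str, int]:
    acc, _, pos = sid.rpartition(":")
    if not acc:
        raise FormatError(f"malformed site_id {sid!r} (expected accession:position)")
    return acc, int(pos)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write a result table as TSV with 12-significant-digit floats, the
    round-trip-stable serialisation used by every pipeline output."""
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_results(tables: Mapping[str, pd.DataFrame], out_dir: str | Path) -> dict[str, Path]:
    """Write a named set of result tables under ``out_dir``; returns the
    file manifest (name → path)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Path] = {}
    for name, df in tables.items():
        path = out_dir / f"{name}.tsv"
        write_table(df, path)
        manifest[name] = path
    return manifest
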