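"""Reading and writing the formats the toolkit touches.

FASTA goes through Biopython; the packaged fixtures (module-family membership,
homology hit tables, taxa/ciliation table) are plain TSV with ``#`` comment
lines, loaded into validated containers.  All coordinates anywhere in the
package are 1-based inclusive.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Union

import pandas as pd
from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from ._alphabet import validate_residues
from .evidence import HitRecord

PathLike = Union[str, Path]

#: the seven module-family registry names
FAMILY_REGISTRY = ("DM10", "Mn", "PYG", "GFG", "NWE", "SNYG", "ELLEn")

_SPECIES = ("Chlamydomonas", "Human")


@dataclass(frozen=True)
class SequenceRecord:
    """A protein sequence: 20 canonical residues plus X, always uppercase."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", validate_residues(self.residues, self.id))

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class FamilyFixture:
    """Module-family membership rows (family, species, protein, alias, evidence)."""

    table: pd.DataFrame

    def count(self, family: str, species: str | None = None) -> int:
        sub = self.table[self.table["family"] == family]
        if species is not None:
            sub = sub[sub["species"] == species]
        return len(sub)

    @property
    def families(self) -> list[str]:
        return sorted(self.table["family"].unique())


@dataclass
class TaxaTable:
    """Species with a ciliation flag and a free-text clade label."""

    table: pd.DataFrame

    @property
    def species(self) -> list[str]:
        return list(self.table["species"])

    def is_ciliated(self, species: str) -> bool:
        row = self.table[self.table["species"] == species]
        if row.empty:
            raise KeyError(f"species {species!r} not in taxa table")
        return bool(row["ciliated"].iloc[0])


def read_fasta(path: PathLike, allow_empty_file: bool = False) -> list[SequenceRecord]:
    """Parse a FASTA file into :class:`SequenceRecord` objects, order preserved.

    Residues are uppercased and validated.  A record with an empty sequence,
    an illegal residue, or a file whose first non-blank line is not a header
    raise ``ValueError``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    text = path.read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip():
            if not line.startswith(">"):
                raise ValueError(
                    f"{path}: line {lineno} is not a FASTA header; expected '>'"
                )
            break
    records: list[SequenceRecord] = []
    for rec in _BioSeqIO.parse(io.StringIO(text), "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append(SequenceRecord(id=rec.id, residues=seq, description=rec.description))
    if not records and not allow_empty_file:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: PathLike, width: int = 60) -> None:
    """Write records as multi-FASTA wrapped at *width* columns."""
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    path = Path(path)
    with path.open("w") as fh:
        writer = _BioSeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def _read_tsv(path_or_buf, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path_or_buf, sep="\t", comment="#", dtype=str, **kwargs)


def load_family_fixture(path: PathLike | None = None) -> FamilyFixture:
    """Load the module-family membership table (packaged fixture by default).

    Validates family names against the seven-name registry and uniqueness of
    (family, species, protein) rows.
    """
    if path is None:
        src = resources.files("mipscan.data") / "table1_families.tsv"
        df = _read_tsv(io.StringIO(src.read_text()))
    else:
        df = _read_tsv(path)
    df = df.fillna({"alias": "", "evidence_source": ""})
    unknown = set(df["family"]) - set(FAMILY_REGISTRY)
    if unknown:
        raise ValueError(f"unknown family name(s): {sorted(unknown)}")
    bad_species = set(df["species"]) - set(_SPECIES)
    if bad_species:
        raise ValueError(f"unknown species value(s): {sorted(bad_species)}")
    dup = df.duplicated(subset=["family", "species", "protein"])
    if dup.any():
        rows = df[dup][["family", "species", "protein"]].to_records(index=False)
        raise ValueError(f"duplicate (family, species, protein) rows: {list(rows)}")
    return FamilyFixture(table=df)


def load_hit_table(path: PathLike) -> list[HitRecord]:
    """Load a homology hit table: columns query, target, evalue[, score].

    E-values may be in scientific notation; non-numeric or non-positive
    E-values are rejected.
    """
    df = _read_tsv(path)
    required = {"query", "target", "evalue"}
    if not required.issubset(df.columns):
        raise ValueError(f"hit table {path} lacks columns {required - set(df.columns)}")
    hits: list[HitRecord] = []
    for i, row in df.iterrows():
        try:
            ev = float(row["evalue"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: non-numeric E-value {row['evalue']!r} in row {i}") from exc
        score = None
        if "score" in df.columns and pd.notna(row.get("score")):
            score = float(row["score"])
        hits.append(HitRecord(query=row["query"], target=row["target"], evalue=ev, score=score))
    return hits


def load_taxa_table(path: PathLike | None = None) -> TaxaTable:
    """Load the species/ciliation table (packaged synthetic fixture by default)."""
    if path is None:
        src = resources.files("mipscan.data") / "taxa_synthetic.tsv"
        df = _read_tsv(io.StringIO(src.read_text()))
    else:
        df = _read_tsv(path)
    if df["species"].duplicated().any():
        dups = df[df["species"].duplicated()]["species"].tolist()
        raise ValueError(f"duplicate species in taxa table: {dups}")
    df["ciliated"] = df["ciliated"].map(
        {"1": True, "0": False, "true": True, "false": False, "True": True, "False": False}
    )
    if df["ciliated"].isna().any():
        raise ValueError("taxa table 'ciliated' column must be 0/1 or true/false")
    return TaxaTable(table=df.reset_index(drop=True))


def load_species_map(path: PathLike | None = None) -> dict[str, str]:
    """Protein id -> species map used when summarizing reciprocal verdicts."""
    if path is None:
        src = resources.files("mipscan.data") / "species_map.tsv"
        df = _read_tsv(io.StringIO(src.read_text()))
    else:
        df = _read_tsv(path)
    return dict(zip(df["protein"], df["species"]))


def packaged_fixture_path(name: str):
    """Return a context-manager yielding a real filesystem path to a packaged fixture."""
    return resources.as_file(resources.files("mipscan.data") / name)
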