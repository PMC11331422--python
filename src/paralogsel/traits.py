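"""Binary-trait extraction from a protein MSA at a reference-aligned column.

The trait is presence/absence of a target residue (e.g. Asp) at the alignment
column homologous to a 1-based ungapped position in a designated reference
sequence.  Records whose sequence is missing around the site are called
``unknown`` rather than ``absent``.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from typing import Mapping

from Bio import SeqIO

ABSENT = "0"
PRESENT = "1"
UNKNOWN = "unknown"
STATES = (ABSENT, PRESENT, UNKNOWN)

# residues carrying no evidence about the target amino acid
_AMBIGUOUS = set("XBZJ")
_GAP = "-"

__all__ = [
    "ProteinMSA",
    "SiteDefinition",
    "TraitTable",
    "map_reference_position",
    "assign_traits",
    "trait_census",
    "read_trait_csv",
    "write_trait_csv",
    "ABSENT",
    "PRESENT",
    "UNKNOWN",
]


class TraitTable(dict):
    """taxon -> state in {'0', '1', 'unknown'}."""

    def __setitem__(self, key: str, value: str) -> None:
        if value not in STATES:
            raise ValueError(f"invalid trait state {value!r} for {key!r}; must be one of {STATES}")
        super().__setitem__(key, value)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str]) -> "TraitTable":
        table = cls()
        for k, v in mapping.items():
            table[k] = v
        return table


@dataclass
class ProteinMSA:
    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate record ids in MSA")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"unequal alignment row lengths: {sorted(lengths)}")
        self.rows = [r.upper() for r in self.rows]

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, record_id: str) -> str:
        try:
            return self.rows[self.ids.index(record_id)]
        except ValueError:
            raise KeyError(f"record {record_id!r} not in MSA") from None

    @classmethod
    def from_fasta(cls, path) -> "ProteinMSA":
        ids, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            rows.append(str(rec.seq))
        return cls(ids, rows)


@dataclass
class SiteDefinition:
    """Reference-anchored site: residue #``position`` of ``reference_id``.

    ``gap_at_site`` chooses how a lone in-frame deletion at the column (gap at
    the site, residues within the flanking window) is called.
    """

    reference_id: str
    position: int  # 1-based, ungapped
    target_residue: str = "D"
    window: int = 5
    gap_at_site: str = "absent"  # or "unknown"

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position must be >= 1")
        self.target_residue = self.target_residue.upper()
        if len(self.target_residue) != 1 or self.target_residue not in "ACDEFGHIKLMNPQRSTVWY":
            raise ValueError(f"target residue must be a standard amino acid, got {self.target_residue!r}")
        if self.gap_at_site not in ("absent", "unknown"):
            raise ValueError("gap_at_site must be 'absent' or 'unknown'")


def map_reference_position(msa: ProteinMSA, site: SiteDefinition) -> int:
    """1-based alignment column holding the reference's ``position``-th residue."""
    row = msa.row(site.reference_id)
    seen = 0
    for col, ch in enumerate(row, start=1):
        if ch != _GAP:
            seen += 1
            if seen == site.position:
                return col
    raise ValueError(
        f"reference {site.reference_id!r} has only {seen} residues; position {site.position} out of range"
    )


def _region_missing(row: str, col0: int, window: int) -> bool:
    lo = max(0, col0 - window)
    hi = min(len(row), col0 + window + 1)
    return all(ch == _GAP or ch == "X" for ch in row[lo:hi])


def assign_traits(msa: ProteinMSA, site: SiteDefinition) -> TraitTable:
    """Call present/absent/unknown per record at the reference-mapped column."""
    col0 = map_reference_position(msa, site) - 1
    table = TraitTable()
    for rec_id, row in zip(msa.ids, msa.rows):
        ch = row[col0]
        if _region_missing(row, col0, site.window):
            state = UNKNOWN
        elif ch == _GAP:
            state = ABSENT if site.gap_at_site == "absent" else UNKNOWN
        elif ch in _AMBIGUOUS:
            state = UNKNOWN
        elif ch == site.target_residue:
            state = PRESENT
        else:
            state = ABSENT
        table[rec_id] = state
    return table


def trait_census(traits: TraitTable, partition: Mapping[str, str]) -> dict[str, dict[str, int]]:
    """Counts of present/absent/unknown per partition label."""
    out: dict[str, dict[str, int]] = {}
    for taxon, state in traits.items():
        try:
            part = partition[taxon]
        except KeyError:
            raise KeyError(f"taxon {taxon!r} has no partition label") from None
        bucket = out.setdefault(part, {"present": 0, "absent": 0, "unknown": 0})
        key = {PRESENT: "present", ABSENT: "absent", UNKNOWN: "unknown"}[state]
        bucket[key] += 1
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_trait_csv(path) -> TraitTable:
    table = TraitTable()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"taxon", "state"} <= set(reader.fieldnames):
            raise ValueError("trait CSV must have columns: taxon,state")
        for row in reader:
            table[row["taxon"]] = row["state"]
    return table


def write_trait_csv(traits: TraitTable, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["taxon", "state"])
        for taxon, state in traits.items():
            writer.writerow([taxon, state])


def write_census_json(census: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(census, fh, indent=2, sort_keys=True)
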