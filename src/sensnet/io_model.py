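"""Data model and I/O for chemical universes and sensitization study tables.

The central objects are :class:`ChemicalRecord` (one substance: structure,
binary substructure fingerprint, molecular weight, electrophilic alert flags,
sensitization label) and :class:`StudyRecord` (one sensitization study with
its assay type, outcome, Klimisch reliability score and year).

Sensitization labels are derived from study evidence: a chemical is a
*sensitizer* if any reliable key skin-sensitization study is positive or the
substance carries an H317 classification; a *non-sensitizer* if at least one
conclusive key study exists and all conclusive outcomes are negative (and no
H317); *unknown* otherwise.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

SENSITIZER = "sensitizer"
NON_SENSITIZER = "non-sensitizer"
UNKNOWN = "unknown"
LABELS = (SENSITIZER, NON_SENSITIZER, UNKNOWN)

ALERT_NAMES = ("sn2", "ma", "sb", "aa", "snar")

_LABEL_ALIASES = {
    "sensitizer": SENSITIZER,
    "sensitiser": SENSITIZER,
    "sensitizing": SENSITIZER,
    "sensitising": SENSITIZER,
    "positive": SENSITIZER,
    "pos": SENSITIZER,
    "1": SENSITIZER,
    "true": SENSITIZER,
    "non-sensitizer": NON_SENSITIZER,
    "non-sensitiser": NON_SENSITIZER,
    "nonsensitizer": NON_SENSITIZER,
    "non-sensitizing": NON_SENSITIZER,
    "not-sensitising": NON_SENSITIZER,
    "not sensitising": NON_SENSITIZER,
    "negative": NON_SENSITIZER,
    "neg": NON_SENSITIZER,
    "0": NON_SENSITIZER,
    "false": NON_SENSITIZER,
    "unknown": UNKNOWN,
    "na": UNKNOWN,
    "n/a": UNKNOWN,
    "": UNKNOWN,
}

STUDY_TYPES = ("Buehler", "GPMT", "LLNA", "PatchTest", "other")

OUTCOME_SENS = "sensitising"
OUTCOME_NON = "not-sensitising"
OUTCOME_INCONCLUSIVE = "inconclusive"
OUTCOMES = (OUTCOME_SENS, OUTCOME_NON, OUTCOME_INCONCLUSIVE)


class DataError(ValueError):
    """Raised for malformed input rows or violated record invariants."""


@dataclass(frozen=True)
class AlertFlags:
    """Electrophilic structural-alert flags for one chemical.

    sn2: second-order nucleophilic aliphatic substitution
    ma: Michael-type addition
    sb: Schiff base formation
    aa: acylation
    snar: nucleophilic aromatic substitution
    rd: reactivity domain — true whenever any mechanism flag is true
    """

    sn2: bool = False
    ma: bool = False
    sb: bool = False
    aa: bool = False
    snar: bool = False
    rd: bool = False

    def normalized(self) -> "AlertFlags":
        """Return a copy with rd recomputed as the OR of the five mechanisms."""
        return replace(self, rd=self.sn2 or self.ma or self.sb or self.aa or self.snar)

    @property
    def alert_count(self) -> int:
        """Number of firing mechanism alerts (rd excluded: it is their OR)."""
        return sum((self.sn2, self.ma, self.sb, self.aa, self.snar))

    def get(self, name: str) -> bool:
        return getattr(self, name)


@dataclass
class ChemicalRecord:
    """One substance in the chemical universe."""

    id: str
    structure: str | None = None
    fingerprint: frozenset[int] | None = None
    mw: float | None = None
    alert_flags: AlertFlags | None = None
    label: str = UNKNOWN

    def __post_init__(self) -> None:
        if self.mw is not None and not self.mw > 0:
            raise DataError(
                f"chemical {self.id!r}: molecular weight must be > 0, got {self.mw}"
            )
        if self.label not in LABELS:
            raise DataError(f"chemical {self.id!r}: unknown label {self.label!r}")
        if self.fingerprint is not None:
            self.fingerprint = frozenset(int(b) for b in self.fingerprint)


@dataclass(frozen=True)
class StudyRecord:
    """One sensitization study attached to a chemical."""

    chemical_id: str
    study_type: str = "other"
    study_kind: str = ""
    outcome: str = OUTCOME_INCONCLUSIVE
    klimisch: int = 4
    year: int = 0
    has_results: bool = True
    has_methods: bool = True

    def __post_init__(self) -> None:
        if self.klimisch not in (1, 2, 3, 4):
            raise DataError(
                f"study for {self.chemical_id!r}: Klimisch score must be 1-4, "
                f"got {self.klimisch}"
            )
        if self.outcome not in OUTCOMES:
            raise DataError(
                f"study for {self.chemical_id!r}: unknown outcome {self.outcome!r}"
            )


def normalize_label(raw: str) -> str:
    key = raw.strip().lower()
    if key in _LABEL_ALIASES:
        return _LABEL_ALIASES[key]
    raise DataError(f"unrecognized sensitization label {raw!r}")


# ---------------------------------------------------------------------------
# fingerprint serialization: sets of bit indices <-> hex strings

def fingerprint_to_hex(bits: frozenset[int] | set[int], n_bits: int | None = None) -> str:
    """Serialize a bit-index set as a big-endian hex string.

    ``n_bits`` pads the vector so round-trips preserve fingerprint length
    modulo 4; trailing zero bits beyond the highest set bit are otherwise
    not recoverable from hex.
    """
    if not bits:
        return "0"
    width = max(bits) + 1 if n_bits is None else n_bits
    width = (width + 3) // 4 * 4  # hex round-trips require nibble alignment
    value = 0
    for b in bits:
        if b < 0 or b >= width:
            raise DataError(f"bit index {b} outside fingerprint width {width}")
        value |= 1 << (width - 1 - b)
    return format(value, f"0{(width + 3) // 4}x")


def hex_to_fingerprint(hexstr: str) -> frozenset[int]:
    """Parse a hex string into the set of indices of set bits (big-endian)."""
    hexstr = hexstr.strip()
    if not hexstr:
        return frozenset()
    value = int(hexstr, 16)
    width = 4 * len(hexstr)
    return frozenset(width - 1 - i for i in range(value.bit_length()) if value >> i & 1)


# ---------------------------------------------------------------------------
# readers / writers

CHEMICAL_COLUMNS = ("id", "smiles", "mw", "fingerprint_hex", "label",
                    "sn2", "ma", "sb", "aa", "snar")
STUDY_COLUMNS = ("chemical_id", "study_type", "study_kind", "outcome",
                 "klimisch", "year", "has_results", "has_methods")

_TRUTHY = {"1", "true", "t", "yes", "y"}
_FALSY = {"0", "false", "f", "no", "n", ""}


def _parse_bool(raw: str, where: str) -> bool:
    key = raw.strip().lower()
    if key in _TRUTHY:
        return True
    if key in _FALSY:
        return False
    raise DataError(f"{where}: cannot parse boolean {raw!r}")


def _chemical_from_csv_row(row: dict[str, str], rownum: int) -> ChemicalRecord:
    cid = (row.get("id") or "").strip()
    if not cid:
        raise DataError(f"row {rownum}: missing chemical id")
    smiles = (row.get("smiles") or "").strip() or None
    mw_raw = (row.get("mw") or "").strip()
    mw = float(mw_raw) if mw_raw else None
    fp_raw = (row.get("fingerprint_hex") or "").strip()
    fingerprint = hex_to_fingerprint(fp_raw) if fp_raw else None
    label = normalize_label(row.get("label") or "")
    flags = None
    if any((row.get(a) or "").strip() for a in ALERT_NAMES):
        flags = AlertFlags(
            **{a: _parse_bool(row.get(a) or "", f"row {rownum} column {a}")
               for a in ALERT_NAMES}
        ).normalized()
    return ChemicalRecord(id=cid, structure=smiles, fingerprint=fingerprint,
                          mw=mw, alert_flags=flags, label=label)


def read_chemicals(path: str | Path, format: str = "csv") -> list[ChemicalRecord]:
    """Read a chemical table.

    Formats: ``csv`` (columns id, smiles, mw, fingerprint_hex, label, and
    optional alert columns sn2/ma/sb/aa/snar), ``sdf`` (RDKit-parsed; id from
    the _Name field or a sequential index, MW computed from the structure),
    and ``smiles`` (one SMILES per line, optionally ``SMILES<tab>id``).

    Malformed rows are reported with their row number and skipped (logged at
    warning level); a duplicate id is an error.
    """
    path = Path(path)
    if format == "csv":
        records = []
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                return []
            for rownum, row in enumerate(reader, start=2):
                try:
                    records.append(_chemical_from_csv_row(row, rownum))
                except (DataError, ValueError) as exc:
                    logger.warning("skipping malformed row %d in %s: %s",
                                   rownum, path, exc)
    elif format == "sdf":
        records = _read_sdf(path)
    elif format == "smiles":
        records = _read_smiles(path)
    else:
        raise ValueError(f"unknown chemical file format {format!r}")

    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise DataError(f"duplicate chemical id {rec.id!r} in {path}")
        seen.add(rec.id)
    return records


def _read_sdf(path: Path) -> list[ChemicalRecord]:
    from rdkit import Chem
    from rdkit.Chem import Descriptors

    records = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            logger.warning("skipping unparsable molecule %d in %s", i, path)
            continue
        cid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol{i}"
        records.append(ChemicalRecord(
            id=cid, structure=Chem.MolToSmiles(mol),
            mw=float(Descriptors.MolWt(mol))))
    return records


def _read_smiles(path: Path) -> list[ChemicalRecord]:
    from rdkit import Chem
    from rdkit.Chem import Descriptors

    records = []
    with path.open(encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            mol = Chem.MolFromSmiles(parts[0])
            if mol is None:
                logger.warning("skipping unparsable SMILES on line %d of %s", i, path)
                continue
            cid = parts[1] if len(parts) > 1 else f"mol{i}"
            records.append(ChemicalRecord(
                id=cid, structure=parts[0], mw=float(Descriptors.MolWt(mol))))
    return records


def write_chemicals(records: Iterable[ChemicalRecord], path: str | Path,
                    fingerprint_bits: int | None = None) -> None:
    """Write a chemical table CSV that :func:`read_chemicals` round-trips."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CHEMICAL_COLUMNS)
        for rec in records:
            flags = rec.alert_flags
            writer.writerow([
                rec.id,
                rec.structure or "",
                repr(rec.mw) if rec.mw is not None else "",
                fingerprint_to_hex(rec.fingerprint, fingerprint_bits)
                if rec.fingerprint is not None else "",
                rec.label,
                *(["", "", "", "", ""] if flags is None
                  else [str(flags.get(a)).lower() for a in ALERT_NAMES]),
            ])


def read_studies(path: str | Path) -> list[StudyRecord]:
    """Read a study table CSV (columns chemical_id, study_type, study_kind,
    outcome, klimisch, year, has_results, has_methods)."""
    path = Path(path)
    records = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for rownum, row in enumerate(reader, start=2):
            try:
                records.append(StudyRecord(
                    chemical_id=(row.get("chemical_id") or "").strip(),
                    study_type=(row.get("study_type") or "other").strip(),
                    study_kind=(row.get("study_kind") or "").strip(),
                    outcome=(row.get("outcome") or OUTCOME_INCONCLUSIVE).strip(),
                    klimisch=int(row.get("klimisch") or 4),
                    year=int(row.get("year") or 0),
                    has_results=_parse_bool(row.get("has_results") or "true",
                                            f"row {rownum} has_results"),
                    has_methods=_parse_bool(row.get("has_methods") or "true",
                                            f"row {rownum} has_methods"),
                ))
            except (DataError, ValueError) as exc:
                logger.warning("skipping malformed study row %d in %s: %s",
                               rownum, path, exc)
    return records


def write_studies(records: Iterable[StudyRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(STUDY_COLUMNS)
        for s in records:
            writer.writerow([s.chemical_id, s.study_type, s.study_kind,
                             s.outcome, s.klimisch, s.year,
                             str(s.has_results).lower(),
                             str(s.has_methods).lower()])


# ---------------------------------------------------------------------------
# key-study selection and label derivation

def select_key_studies(studies: Sequence[StudyRecord]) -> list[StudyRecord]:
    """Retain reliable experimental key skin-sensitization studies.

    A study qualifies when its kind mentions "skin", it has both a results
    and a methods section, and its Klimisch reliability score is <= 2.
    """
    return [s for s in studies
            if "skin" in s.study_kind.lower()
            and s.has_results and s.has_methods
            and s.klimisch <= 2]


def derive_label(chemical_id: str, key_studies: Sequence[StudyRecord],
                 h317_flag: bool | None = None) -> str:
    """Derive a sensitization label from key-study evidence.

    Positive if any key study is positive or the substance is classified
    H317. Negative only with at least one conclusive key study, all of them
    negative, and no H317. Inconclusive outcomes carry no evidence.
    """
    mine = [s for s in key_studies if s.chemical_id == chemical_id]
    if h317_flag or any(s.outcome == OUTCOME_SENS for s in mine):
        return SENSITIZER
    conclusive = [s for s in mine if s.outcome != OUTCOME_INCONCLUSIVE]
    if conclusive and all(s.outcome == OUTCOME_NON for s in conclusive) \
            and h317_flag is not True:
        return NON_SENSITIZER
    return UNKNOWN
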