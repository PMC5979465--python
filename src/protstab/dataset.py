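"""Curation of experimental protein-stability (ddG) variant records.

Thermodynamic databases mix units (kcal/mol vs kJ/mol), temperature scales
(Celsius vs Kelvin), measurement backgrounds (wild type vs pseudo-wild-type
carrying extra substitutions), duplicated entries and measurements taken far
from physiological conditions.  This module parses tab-separated variant
records, harmonizes units, validates the reported substitution against the
reference sequence, applies auditable filtering rules, and assigns each
record one of three stability labels:

* ``increase``  — ddG > +0.5 kcal/mol (positive ddG = stabilizing),
* ``decrease``  — ddG < −0.5 kcal/mol,
* ``no_effect`` — |ddG| ≤ 0.5 kcal/mol (closed neutral band).

Every exclusion is recorded with a machine-readable reason code so the
curation is reproducible and auditable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: kJ per kcal (thermochemical calorie).
KJ_PER_KCAL = 4.184

#: Temperatures above this are read as Kelvin and shifted by −273.15.
KELVIN_CUTOFF_C = 150.0

INCREASE = "increase"
DECREASE = "decrease"
NO_EFFECT = "no_effect"
LABELS = (INCREASE, NO_EFFECT, DECREASE)

#: Measurement-method preference, best first.
METHODS = ("DSC", "thermal_other", "chemical_denaturation", "other")

STATE_FLAGS = ("folded", "unfolded", "stage_partial", "stage_total")

REQUIRED_COLUMNS = (
    "record_id", "protein_id", "sequence_ref", "wt_aa", "position",
    "mut_aa", "ddg", "ddg_unit", "temperature", "ph",
)
OPTIONAL_COLUMNS = (
    "salt_molar", "method", "pdb_ref", "background_variants", "state_flag",
)

# Reason codes emitted by apply_curation (the auditable issue classes).
REASON_UNFOLDED = "unfolded_protein"
REASON_STAGE = "stage_value"
REASON_SHORT = "short_peptide"
REASON_SEQ_MISMATCH = "sequence_mismatch"
REASON_DUPLICATE = "duplicate"
REASON_PH = "ph_out_of_range_superseded"
REASON_SALT = "salt_out_of_range_superseded"
REASON_SUPERSEDED = "non_preferred_superseded"


@dataclass(frozen=True)
class VariantRecord:
    """One stability measurement with experimental conditions.

    ``ddg`` is positive for stabilizing substitutions; after
    :func:`harmonize_units` it is always in kcal/mol and ``temperature_c``
    in Celsius.  ``background_variants`` lists substitutions already present
    in the experimental reference relative to the wild type (e.g. the
    cysteine-free T4 lysozyme background C54T/C97A).
    """

    record_id: str
    protein_id: str
    sequence_ref: str
    wt_aa: str
    position: int
    mut_aa: str
    ddg: float
    ddg_unit_raw: str = "kcal/mol"
    temperature_c: float = 25.0
    ph: float = 7.0
    salt_molar: float | None = None
    method: str = "other"
    pdb_ref: str | None = None
    background_variants: tuple[tuple[str, int, str], ...] = ()
    state_flag: str = "folded"
    is_reverse: bool = False

    def __post_init__(self) -> None:
        if self.wt_aa == self.mut_aa:
            raise ValueError(
                f"{self.record_id}: wild-type and variant residue are "
                f"identical ({self.wt_aa})"
            )
        if self.position < 1:
            raise ValueError(f"{self.record_id}: position must be >= 1")
        for aa in (self.wt_aa, self.mut_aa):
            if aa not in AMINO_ACIDS:
                raise ValueError(f"{self.record_id}: bad amino acid {aa!r}")
        if self.state_flag not in STATE_FLAGS:
            raise ValueError(
                f"{self.record_id}: unknown state_flag {self.state_flag!r}"
            )

    @property
    def variant_key(self) -> tuple[str, str, int, str]:
        return (self.protein_id, self.wt_aa, self.position, self.mut_aa)


@dataclass(frozen=True)
class CurationConfig:
    """Thresholds of the record-selection rules."""

    ph_min: float = 5.0
    ph_max: float = 9.0
    salt_max_molar: float = 0.2
    neutral_halfwidth: float = 0.5
    min_protein_length: int = 30
    method_preference: tuple[str, ...] = METHODS

    def __post_init__(self) -> None:
        if not self.ph_min < self.ph_max:
            raise ValueError("ph_min must be < ph_max")
        if not self.neutral_halfwidth > 0:
            raise ValueError("neutral_halfwidth must be > 0")


@dataclass
class RowError:
    line: int
    record_id: str
    message: str


@dataclass
class ParseResult:
    records: list[VariantRecord]
    errors: list[RowError] = field(default_factory=list)


@dataclass
class CurationReport:
    """Disposition of every input record: kept or (reason-coded) rejected."""

    kept: list[str] = field(default_factory=list)
    rejected: list[tuple[str, str, str]] = field(default_factory=list)

    def rejected_ids(self) -> set[str]:
        return {rid for rid, _, _ in self.rejected}

    def to_frame(self) -> pd.DataFrame:
        rows = [{"record_id": r, "disposition": "kept", "reason": "", "detail": ""}
                for r in self.kept]
        rows += [{"record_id": r, "disposition": "rejected", "reason": c,
                  "detail": d} for r, c, d in self.rejected]
        return pd.DataFrame(rows, columns=["record_id", "disposition",
                                           "reason", "detail"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


_BG_RE = re.compile(r"^([A-Y])(\d+)([A-Y])$")


def parse_background(text: str) -> tuple[tuple[str, int, str], ...]:
    """Parse ``'C54T;C97A'`` into ``((C,54,T), (C,97,A))``."""
    text = (text or "").strip()
    if not text:
        return ()
    out = []
    for tok in re.split(r"[;,]", text):
        tok = tok.strip()
        if not tok:
            continue
        m = _BG_RE.match(tok)
        if not m:
            raise ValueError(f"bad background variant token {tok!r}")
        out.append((m.group(1), int(m.group(2)), m.group(3)))
    return tuple(out)


def parse_records(path) -> ParseResult:
    """Read a tab-separated variant file into :class:`VariantRecord` objects.

    Rows that violate record invariants (bad residue code, position < 1, ...)
    are reported in ``errors`` rather than silently dropped.  A missing
    mandatory column is a hard error naming the column.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing mandatory column: {col}")

    result = ParseResult(records=[])
    for i, row in enumerate(df.to_dict("records")):
        line = i + 2  # header is line 1
        rid = row.get("record_id", f"row{line}")
        try:
            unit = row["ddg_unit"].strip() or "kcal/mol"
            salt = row.get("salt_molar", "").strip()
            rec = VariantRecord(
                record_id=rid,
                protein_id=row["protein_id"].strip(),
                sequence_ref=row["sequence_ref"].strip(),
                wt_aa=row["wt_aa"].strip(),
                position=int(row["position"]),
                mut_aa=row["mut_aa"].strip(),
                ddg=float(row["ddg"]),
                ddg_unit_raw=unit,
                temperature_c=float(row["temperature"]),
                ph=float(row["ph"]),
                salt_molar=float(salt) if salt else None,
                method=(row.get("method", "").strip() or "other"),
                pdb_ref=(row.get("pdb_ref", "").strip() or None),
                background_variants=parse_background(
                    row.get("background_variants", "")),
                state_flag=(row.get("state_flag", "").strip() or "folded"),
            )
        except (ValueError, KeyError) as exc:
            result.errors.append(RowError(line=line, record_id=rid,
                                          message=str(exc)))
            continue
        if rec.method not in METHODS:
            result.errors.append(RowError(line=line, record_id=rid,
                                          message=f"unknown method {rec.method!r}"))
            continue
        result.records.append(rec)
    return result


def harmonize_units(record: VariantRecord) -> VariantRecord:
    """Convert ddG to kcal/mol and temperature to Celsius.

    kJ/mol values are divided by 4.184; temperatures above 150 are read as
    Kelvin and shifted down by 273.15 (no folded-protein measurement exists
    above 150 °C).  Idempotent: a harmonized record passes through unchanged.
    """
    unit = record.ddg_unit_raw.strip().lower().replace(" ", "")
    if unit in ("kcal/mol", "kcal"):
        ddg = record.ddg
    elif unit in ("kj/mol", "kj"):
        ddg = record.ddg / KJ_PER_KCAL
    else:
        raise ValueError(f"unknown ddG unit {record.ddg_unit_raw!r}")
    temp = record.temperature_c
    if temp > KELVIN_CUTOFF_C:
        temp -= 273.15
    if not (-10.0 <= temp <= 150.0):
        raise ValueError(
            f"{record.record_id}: temperature {temp} out of plausible range")
    return replace(record, ddg=ddg, ddg_unit_raw="kcal/mol",
                   temperature_c=temp)


def label_stability(ddg: float, neutral_halfwidth: float = 0.5) -> str:
    """Three-way stability label from a harmonized ddG (kcal/mol)."""
    if ddg > neutral_halfwidth:
        return INCREASE
    if ddg < -neutral_halfwidth:
        return DECREASE
    return NO_EFFECT


def apply_background(sequence: str,
                     background: Iterable[tuple[str, int, str]]) -> str:
    """Apply background substitutions to a reference sequence (1-based)."""
    seq = list(sequence)
    for wt, pos, mut in background:
        if pos < 1 or pos > len(seq):
            raise ValueError(f"background position {pos} outside sequence")
        if seq[pos - 1] != wt:
            raise ValueError(
                f"background variant {wt}{pos}{mut}: reference has "
                f"{seq[pos - 1]} at {pos}")
        seq[pos - 1] = mut
    return "".join(seq)


def validate_sequence(record: VariantRecord,
                      sequence: str) -> tuple[bool, str]:
    """Check that the reported wild-type residue matches the sequence.

    Background variants are applied first.  On mismatch, nearby offsets
    (±5) are probed to distinguish a numbering shift from an outright
    mismatch; the diagnosis string reports the candidate offset.
    """
    if not sequence:
        raise ValueError("empty sequence")
    try:
        seq = apply_background(sequence, record.background_variants)
    except ValueError as exc:
        return False, f"bad_background: {exc}"
    pos = record.position
    if pos > len(seq):
        return False, "out_of_range"
    if seq[pos - 1] == record.wt_aa:
        return True, "match"
    for off in sorted(range(-5, 6), key=abs):
        if off == 0:
            continue
        j = pos - 1 + off
        if 0 <= j < len(seq) and seq[j] == record.wt_aa:
            return False, f"shift_candidate offset {off:+d}"
    return False, "mismatch"


def select_representative(records: Sequence[VariantRecord],
                          config: CurationConfig | None = None
                          ) -> VariantRecord:
    """Pick one record among replicate measurements of the same variant.

    Ordered preference: thermal denaturation with a calorimeter first
    (DSC > thermal_other > chemical_denaturation > other), then pH closest
    to 7, then lowest salt; record_id order breaks remaining ties.
    """
    if not records:
        raise ValueError("no records to select from")
    config = config or CurationConfig()
    rank = {m: i for i, m in enumerate(config.method_preference)}

    def key(r: VariantRecord):
        salt = r.salt_molar if r.salt_molar is not None else 0.0
        return (rank.get(r.method, len(rank)), abs(r.ph - 7.0), salt,
                r.record_id)

    return min(records, key=key)


def _conditions_in_range(r: VariantRecord, config: CurationConfig) -> bool:
    if not (config.ph_min <= r.ph <= config.ph_max):
        return False
    if r.salt_molar is not None and r.salt_molar >= config.salt_max_molar:
        return False
    return True


def apply_curation(records: Sequence[VariantRecord],
                   config: CurationConfig | None = None,
                   sequences: Mapping[str, str] | None = None
                   ) -> tuple[list[VariantRecord], CurationReport]:
    """Filter harmonized records into a clean dataset plus an audit report.

    Rules, in order:

    1. unfolded-protein and per-stage denaturation records are rejected
       outright (whole-pathway totals are genuine ddG values and are kept);
    2. with sequences available: very short peptides are rejected, and the
       reported wild-type residue must match the (background-corrected)
       reference sequence;
    3. exact duplicates (same variant, ddG, T, pH) are collapsed;
    4. out-of-range pH or salt measurements are rejected *only when* an
       in-range measurement of the same variant exists;
    5. remaining replicate measurements are resolved by
       :func:`select_representative`.

    Every rejection carries a reason code; kept ∪ rejected = input.
    """
    config = config or CurationConfig()
    report = CurationReport()
    survivors: list[VariantRecord] = []

    for rec in records:
        if rec.state_flag == "unfolded":
            report.rejected.append((rec.record_id, REASON_UNFOLDED, ""))
            continue
        if rec.state_flag == "stage_partial":
            report.rejected.append((rec.record_id, REASON_STAGE,
                                    "per-stage denaturation value"))
            continue
        if sequences is not None and rec.sequence_ref in sequences:
            seq = sequences[rec.sequence_ref]
            if len(seq) < config.min_protein_length:
                report.rejected.append(
                    (rec.record_id, REASON_SHORT,
                     f"length {len(seq)} < {config.min_protein_length}"))
                continue
            ok, diag = validate_sequence(rec, seq)
            if not ok:
                report.rejected.append((rec.record_id, REASON_SEQ_MISMATCH,
                                        diag))
                continue
        survivors.append(rec)

    curated: list[VariantRecord] = []
    by_variant: dict[tuple, list[VariantRecord]] = {}
    for rec in survivors:
        by_variant.setdefault(rec.variant_key, []).append(rec)

    for key in sorted(by_variant):
        group = sorted(by_variant[key], key=lambda r: r.record_id)
        # collapse exact duplicates
        seen: dict[tuple, VariantRecord] = {}
        deduped = []
        for rec in group:
            sig = (round(rec.ddg, 6), round(rec.temperature_c, 2),
                   round(rec.ph, 2))
            if sig in seen:
                report.rejected.append(
                    (rec.record_id, REASON_DUPLICATE,
                     f"duplicate of {seen[sig].record_id}"))
            else:
                seen[sig] = rec
                deduped.append(rec)
        # conditional condition filter
        in_range = [r for r in deduped if _conditions_in_range(r, config)]
        if in_range:
            for rec in deduped:
                if rec in in_range:
                    continue
                if not (config.ph_min <= rec.ph <= config.ph_max):
                    report.rejected.append(
                        (rec.record_id, REASON_PH, f"pH {rec.ph}"))
                else:
                    report.rejected.append(
                        (rec.record_id, REASON_SALT,
                         f"salt {rec.salt_molar} M"))
            candidates = in_range
        else:
            candidates = deduped
        rep = select_representative(candidates, config)
        for rec in candidates:
            if rec is not rep:
                report.rejected.append(
                    (rec.record_id, REASON_SUPERSEDED,
                     f"superseded by {rep.record_id}"))
        curated.append(rep)
        report.kept.append(rep.record_id)

    return curated, report


def make_reverse_variants(records: Sequence[VariantRecord],
                          sequences: Mapping[str, str] | None = None
                          ) -> tuple[list[VariantRecord], dict[str, str]]:
    """Augment a dataset with mirrored (reverse) variants.

    For each record a mirror is emitted with wild-type and variant residue
    swapped and ddG negated; the mirror's reference sequence is the original
    sequence carrying the substitution.  Originals are retained and mirrors
    flagged ``is_reverse``.  Returns the augmented list and a dict of the
    newly created mutated reference sequences (empty when ``sequences`` is
    not supplied).
    """
    out = list(records)
    new_seqs: dict[str, str] = {}
    for rec in records:
        new_ref = f"{rec.sequence_ref}|{rec.wt_aa}{rec.position}{rec.mut_aa}"
        if sequences is not None and rec.sequence_ref in sequences:
            seq = list(sequences[rec.sequence_ref])
            if rec.position <= len(seq):
                seq[rec.position - 1] = rec.mut_aa
                new_seqs[new_ref] = "".join(seq)
        out.append(replace(
            rec,
            record_id=rec.record_id + "_rev",
            sequence_ref=new_ref,
            wt_aa=rec.mut_aa,
            mut_aa=rec.wt_aa,
            ddg=-rec.ddg,
            is_reverse=True,
        ))
    return out, new_seqs


def records_to_frame(records: Sequence[VariantRecord],
                     neutral_halfwidth: float = 0.5) -> pd.DataFrame:
    """Tabulate records (plus the derived stability label) as a DataFrame."""
    rows = []
    for r in records:
        rows.append({
            "record_id": r.record_id, "protein_id": r.protein_id,
            "sequence_ref": r.sequence_ref, "wt_aa": r.wt_aa,
            "position": r.position, "mut_aa": r.mut_aa, "ddg": r.ddg,
            "ddg_unit": r.ddg_unit_raw, "temperature": r.temperature_c,
            "ph": r.ph,
            "salt_molar": "" if r.salt_molar is None else r.salt_molar,
            "method": r.method, "pdb_ref": r.pdb_ref or "",
            "background_variants": ";".join(
                f"{w}{p}{m}" for w, p, m in r.background_variants),
            "state_flag": r.state_flag,
            "label": label_stability(r.ddg, neutral_halfwidth),
        })
    return pd.DataFrame(rows)


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an id → sequence dict (first token of header)."""
    from Bio import SeqIO
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
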