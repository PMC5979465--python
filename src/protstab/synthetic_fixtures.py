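"""Seeded generators for every input the pipeline consumes.

These emulate the *mechanics* of real stability data — not protein
energetics: variant corpora with the benchmark's class imbalance
(increase : no_effect : decrease ≈ 1 : 2 : 4), ddG values inside the
observed −17.4 … 23.0 kcal/mol span, measurement conditions in the
pH 2.7–9.6 / 0–89 °C ranges, toy alignments with planted conservation and
co-evolution, feature tables with a known number of informative columns,
and deliberately corrupted record files with a ground-truth curation
report.  Every generator is a pure function of its parameters and seed,
and every fixture carries a ground-truth sidecar so tests never re-derive
truth from the fixture itself.

Class-conditional ddG values are truncated normals: decrease centred at
−2 kcal/mol, increase at +1.5 kcal/mol, both sd 1, clipped to their class
interval.
"""

from __future__ import annotations

import functools
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import (AMINO_ACIDS, DECREASE, INCREASE, METHODS, NO_EFFECT,
                      VariantRecord, label_stability, records_to_frame,
                      write_fasta)

DDG_MIN, DDG_MAX = -17.4, 23.0
PH_RANGE = (2.7, 9.6)
TEMPERATURE_RANGE = (0.0, 89.0)
CLASS_PROPORTIONS = {INCREASE: 1, NO_EFFECT: 2, DECREASE: 4}


@dataclass
class FixtureSpec:
    """Parameters of a synthetic variant corpus."""

    n_proteins: int = 12
    variants_per_protein: int = 10
    class_proportions: dict = field(
        default_factory=lambda: dict(CLASS_PROPORTIONS))
    ph_range: tuple[float, float] = PH_RANGE
    temperature_range: tuple[float, float] = TEMPERATURE_RANGE
    min_length: int = 80
    max_length: int = 160
    n_homolog_pairs: int = 0
    seed: int = 0


@dataclass
class Corpus:
    records: list[VariantRecord]
    sequences: dict[str, str]
    truth: pd.DataFrame
    spec: FixtureSpec

    def write(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        df = records_to_frame(self.records).drop(columns="label")
        df.to_csv(directory / "records.tsv", sep="\t", index=False)
        write_fasta(self.sequences, directory / "sequences.fasta")
        self.truth.to_csv(directory / "truth.tsv", sep="\t", index=False)
        with open(directory / "manifest.json", "w") as fh:
            json.dump(asdict(self.spec), fh, indent=2, default=str)


def _random_sequence(rng, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def sample_ddg(rng, label: str) -> float:
    """Class-consistent ddG (truncated normal, kcal/mol)."""
    if label == NO_EFFECT:
        return float(rng.uniform(-0.5, 0.5))
    if label == DECREASE:
        return float(np.clip(rng.normal(-2.0, 1.0), DDG_MIN, -0.51))
    if label == INCREASE:
        return float(np.clip(rng.normal(1.5, 1.0), 0.51, DDG_MAX))
    raise ValueError(label)


def generate_variant_corpus(spec: FixtureSpec | None = None,
                            **kwargs) -> Corpus:
    """Random proteins, class-consistent variant records and a truth table.

    Proteins are unrelated by construction (i.i.d. sequences); with
    ``n_homolog_pairs > 0`` the first proteins get a planted ~90%-identity
    homolog each, for exercising identity clustering.
    """
    spec = spec or FixtureSpec(**kwargs)
    if spec.n_proteins < 1 or spec.variants_per_protein < 1:
        raise ValueError("need at least one protein and one variant")
    labels_pool = list(spec.class_proportions)
    weights = np.array([spec.class_proportions[c] for c in labels_pool],
                       dtype=float)
    if (weights <= 0).any():
        raise ValueError("class proportions must be positive")
    weights /= weights.sum()
    rng = np.random.default_rng(spec.seed)

    sequences: dict[str, str] = {}
    for i in range(spec.n_proteins):
        pid = f"P{i + 1:03d}"
        sequences[pid] = _random_sequence(
            rng, int(rng.integers(spec.min_length, spec.max_length + 1)))
    if spec.n_homolog_pairs > spec.n_proteins:
        raise ValueError("more homolog pairs than proteins")
    for i in range(spec.n_homolog_pairs):
        pid = f"P{i + 1:03d}"
        seq = list(sequences[pid])
        n_mut = max(1, len(seq) // 10)
        for pos in rng.choice(len(seq), size=n_mut, replace=False):
            seq[pos] = rng.choice([a for a in AMINO_ACIDS
                                   if a != seq[pos]])
        sequences[pid + "h"] = "".join(seq)

    records, truth_rows = [], []
    for pid in [p for p in sequences if not p.endswith("h")]:
        seq = sequences[pid]
        for j in range(spec.variants_per_protein):
            pos = int(rng.integers(1, len(seq) + 1))
            wt = seq[pos - 1]
            mut = str(rng.choice([a for a in AMINO_ACIDS if a != wt]))
            label = str(rng.choice(labels_pool, p=weights))
            rec = VariantRecord(
                record_id=f"{pid}_v{j:03d}", protein_id=pid,
                sequence_ref=pid, wt_aa=wt, position=pos, mut_aa=mut,
                ddg=sample_ddg(rng, label),
                temperature_c=float(rng.uniform(*spec.temperature_range)),
                ph=float(rng.uniform(*spec.ph_range)),
                method=str(rng.choice(METHODS)),
            )
            records.append(rec)
            truth_rows.append({"record_id": rec.record_id,
                               "protein_id": pid, "label": label,
                               "ddg": rec.ddg})
    truth = pd.DataFrame(truth_rows)
    assert (truth["label"]
            == [label_stability(d) for d in truth["ddg"]]).all()
    return Corpus(records=records, sequences=sequences, truth=truth,
                  spec=spec)


def generate_feature_table(n_rows: int, n_features: int,
                           n_informative: int, effect_size: float,
                           seed: int, classes=(INCREASE, NO_EFFECT,
                                               DECREASE),
                           proportions=None
                           ) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Numeric table with planted class signal in known columns.

    Noise columns are standard normal; each informative column shifts its
    mean by ``effect_size`` per class (class order randomly permuted per
    column so informative columns are not redundant copies).
    """
    if n_informative > n_features:
        raise ValueError("n_informative > n_features")
    rng = np.random.default_rng(seed)
    if proportions is None:
        proportions = [CLASS_PROPORTIONS.get(c, 1) for c in classes]
    p = np.asarray(proportions, dtype=float)
    p /= p.sum()
    y = rng.choice(list(classes), size=n_rows, p=p)
    X = rng.standard_normal((n_rows, n_features))
    informative = [f"f{i:03d}" for i in range(n_informative)]
    class_index = {c: k for k, c in enumerate(classes)}
    for col in range(n_informative):
        order = rng.permutation(len(classes))
        shifts = order * effect_size
        X[:, col] += shifts[[class_index[c] for c in y]]
    names = informative + [f"noise{i:03d}"
                           for i in range(n_features - n_informative)]
    return (pd.DataFrame(X, columns=names), pd.Series(y, name="label"),
            informative)


# ---------------------------------------------------------------------------
# corrupted record files with ground-truth curation outcome

SUPPORTED_CORRUPTIONS = ("kj", "kelvin", "duplicate", "short_peptide",
                         "unfolded", "stage", "ph", "salt",
                         "non_preferred")


def generate_corrupted_protherm_file(n_clean: int, corruption_plan: dict,
                                     seed: int, directory=None
                                     ) -> tuple[pd.DataFrame, dict[str, str],
                                                pd.DataFrame]:
    """Record table with planted curation issues and their expected outcome.

    Returns ``(records_frame, sequences, truth)`` where truth lists, per
    record_id, the expected disposition (``kept`` / ``rejected``) and
    reason code.  Unit and temperature-scale corruptions (kJ/mol, Kelvin)
    are *corrections*, not rejections: those records stay kept.  With
    ``directory`` given, records.tsv / sequences.fasta / truth.tsv are
    written there.
    """
    unknown = set(corruption_plan) - set(SUPPORTED_CORRUPTIONS)
    if unknown:
        raise ValueError(f"unsupported corruption(s): {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    corpus = generate_variant_corpus(FixtureSpec(
        n_proteins=max(3, (n_clean + 3) // 4), variants_per_protein=4,
        ph_range=(5.5, 8.5), seed=seed))
    clean = corpus.records[:n_clean]
    if len(clean) < n_clean:
        raise ValueError("not enough clean records generated")
    # clean records get the preferred method so planted alternatives lose
    clean = [rec.__class__(**{**rec.__dict__, "method": "DSC"})
             for rec in clean]
    sequences = dict(corpus.sequences)
    records = list(clean)
    truth_rows = [{"record_id": r.record_id, "disposition": "kept",
                   "reason": ""} for r in clean]
    counter = 0
    used_keys = {r.variant_key for r in clean}

    def next_id(kind):
        nonlocal counter
        counter += 1
        return f"bad_{kind}_{counter:02d}"

    def clone(rec, **changes) -> VariantRecord:
        return rec.__class__(**{**rec.__dict__, **changes})

    def fresh_variant(base, **changes) -> VariantRecord:
        """Clone onto an unused (protein, position) so no replicate logic
        interferes with the planted issue."""
        seq = sequences[base.protein_id]
        for pos in rng.permutation(len(seq)) + 1:
            wt = seq[pos - 1]
            muts = [a for a in AMINO_ACIDS if a != wt]
            mut = str(rng.choice(muts))
            key = (base.protein_id, wt, int(pos), mut)
            if key not in used_keys:
                used_keys.add(key)
                return clone(base, position=int(pos), wt_aa=wt,
                             mut_aa=mut, **changes)
        raise RuntimeError("protein exhausted")

    for kind, count in corruption_plan.items():
        for _ in range(count):
            base = clean[int(rng.integers(len(clean)))]
            rid = next_id(kind)
            if kind == "kj":
                # wrong unit: a correction, the record survives curation
                records.append(fresh_variant(
                    base, record_id=rid,
                    ddg=round(base.ddg * 4.184, 4),
                    ddg_unit_raw="kJ/mol"))
                truth_rows.append({"record_id": rid,
                                   "disposition": "kept", "reason": ""})
            elif kind == "kelvin":
                # Kelvin temperature: corrected, record kept
                records.append(fresh_variant(
                    base, record_id=rid,
                    temperature_c=round(base.temperature_c + 273.15, 2)))
                truth_rows.append({"record_id": rid,
                                   "disposition": "kept", "reason": ""})
            elif kind == "duplicate":
                records.append(clone(base, record_id=rid))
                truth_rows.append({"record_id": rid,
                                   "disposition": "rejected",
                                   "reason": "duplicate"})
            elif kind == "short_peptide":
                pid = f"SHORT{counter:02d}"
                seq = _random_sequence(rng, 15)
                sequences[pid] = seq
                pos = int(rng.integers(1, len(seq) + 1))
                wt = seq[pos - 1]
                mut = str(rng.choice([a for a in AMINO_ACIDS if a != wt]))
                records.append(VariantRecord(
                    record_id=rid, protein_id=pid, sequence_ref=pid,
                    wt_aa=wt, position=pos, mut_aa=mut, ddg=-1.0,
                    ph=7.0))
                truth_rows.append({"record_id": rid,
                                   "disposition": "rejected",
                                   "reason": "short_peptide"})
            elif kind == "unfolded":
                records.append(clone(base, record_id=rid, ddg=base.ddg + 0.2,
                                     state_flag="unfolded"))
                truth_rows.append({"record_id": rid,
                                   "disposition": "rejected",
                                   "reason": "unfolded_protein"})
            elif kind == "stage":
                records.append(clone(base, record_id=rid, ddg=base.ddg / 2,
                                     state_flag="stage_partial"))
                truth_rows.append({"record_id": rid,
                                   "disposition": "rejected",
                                   "reason": "stage_value"})
            elif kind == "ph":
                records.append(clone(base, record_id=rid, ph=3.0,
                                     ddg=base.ddg + 0.3))
                truth_rows.append({"record_id": rid,
                                   "disposition": "rejected",
                                   "reason": "ph_out_of_range_superseded"})
            elif kind == "salt":
                records.append(clone(base, record_id=rid, salt_molar=0.5,
                                     ddg=base.ddg + 0.3))
                truth_rows.append({"record_id": rid,
                                   "disposition": "rejected",
                                   "reason":
                                   "salt_out_of_range_superseded"})
            elif kind == "non_preferred":
                records.append(clone(base, record_id=rid,
                                     method="chemical_denaturation",
                                     ddg=base.ddg + 0.15))
                truth_rows.append({"record_id": rid,
                                   "disposition": "rejected",
                                   "reason": "non_preferred_superseded"})
    frame = records_to_frame(records).drop(columns="label")
    truth = pd.DataFrame(truth_rows)
    if directory is not None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        frame.to_csv(directory / "records.tsv", sep="\t", index=False)
        write_fasta(sequences, directory / "sequences.fasta")
        truth.to_csv(directory / "truth.tsv", sep="\t", index=False)
        with open(directory / "manifest.json", "w") as fh:
            json.dump({"n_clean": n_clean, "plan": corruption_plan,
                       "seed": seed}, fh, indent=2)
    return frame, sequences, truth


def generate_toy_msa(depth: int, length: int,
                     conserved_positions=(), coevolving_pairs=(),
                     seed: int = 0):
    """Alignment with planted invariant columns and perfectly coupled pairs.

    Background columns are i.i.d. uniform over the 20 residues; conserved
    positions carry one residue in every row; each co-evolving pair shares
    a hidden 4-state pattern across rows (association 1).  Row 0 is the
    reference; no gaps are introduced.
    """
    from .conservation import MSA
    rng = np.random.default_rng(seed)
    for pos in list(conserved_positions) + [p for pair in coevolving_pairs
                                            for p in pair]:
        if not 1 <= pos <= length:
            raise ValueError(f"position {pos} outside length {length}")
    cols = rng.choice(list(AMINO_ACIDS), size=(depth, length))
    for pos in conserved_positions:
        cols[:, pos - 1] = rng.choice(list(AMINO_ACIDS))
    for a, b in coevolving_pairs:
        states = rng.integers(0, 4, size=depth)
        map_a = rng.choice(list(AMINO_ACIDS), size=4, replace=False)
        map_b = rng.choice(list(AMINO_ACIDS), size=4, replace=False)
        cols[:, a - 1] = map_a[states]
        cols[:, b - 1] = map_b[states]
    rows = ["".join(r) for r in cols]
    return MSA(rows, reference_index=0)


# ---------------------------------------------------------------------------
# synthetic amino-acid index collection with the reference census

N_PER_RESIDUE = 544
N_SUBSTITUTION = 94
N_CONTACT = 47
N_INCOMPLETE = 68   # planted NA records; 685 − 68 = 617 usable
AAINDEX_SEED = 1009


def synthetic_aaindex_text(seed: int = AAINDEX_SEED) -> str:
    """AAindex-dialect text with the full reference census.

    Synthetic stand-in for a complete amino-acid index collection (the
    real one is hundreds of kilobytes): 544 per-residue indices, 94
    substitution matrices and 47 contact potentials, with 68 records made
    incomplete (NA entries) so that exactly 617 usable features remain
    after filtering.  Values are random but deterministic in the seed.
    """
    from .features import AAIndexTable
    rng = np.random.default_rng(seed)
    incomplete = set(rng.choice(N_PER_RESIDUE, size=N_INCOMPLETE,
                                replace=False))
    order = AAIndexTable._I_ORDER
    out = []
    for i in range(N_PER_RESIDUE):
        vals = np.round(rng.normal(0, 2, size=20), 3).astype(object)
        if i in incomplete:
            vals[rng.integers(20)] = "NA"
        out.append(f"H SYNI{i + 1:04d}\nD synthetic per-residue index\n"
                   f"I    A/L     R/K     N/M     D/F     C/P     Q/S"
                   f"     E/T     G/W     H/Y     I/V\n")
        row1 = "  " + " ".join(f"{v:>7}" for v in vals[:10])
        row2 = "  " + " ".join(f"{v:>7}" for v in vals[10:])
        out.append(row1 + "\n" + row2 + "\n//\n")
    for prefix, count in (("SYNM", N_SUBSTITUTION), ("SYNC", N_CONTACT)):
        kind = ("substitution matrix" if prefix == "SYNM"
                else "contact potential")
        for i in range(count):
            out.append(f"H {prefix}{i + 1:04d}\nD synthetic {kind}\n"
                       f"M rows = {order}, cols = {order}\n")
            for r in range(20):
                vals = np.round(rng.normal(0, 1, size=r + 1), 2)
                out.append("  " + " ".join(f"{v:>6}" for v in vals) + "\n")
            out.append("//\n")
    return "".join(out)


@functools.lru_cache(maxsize=1)
def synthetic_aaindex_table(seed: int = AAINDEX_SEED):
    """Parsed synthetic index table (617 usable features), cached."""
    from .features import AAIndexTable
    return AAIndexTable.from_text(synthetic_aaindex_text(seed))
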