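"""Assembly of the 1106-slot variant descriptor.

Each variant is described by seven feature families:

==================== ===== =======================================================
family               slots content
==================== ===== =======================================================
condition                2 measurement temperature (°C) and pH
conservation             3 information content, PSSM(wt), PSSM(mut) at the site
coevolution              4 is_coevolving, max_cor, is_coevolving_grp, grp_count
aaindex                617 amino-acid indices, substitution matrices, contact
                           potentials (incomplete sets filtered at load)
vartype20x20           400 one-hot (wt, mut) substitution cell
vartype6x6              36 one-hot physicochemical-group substitution cell
neighborhood_counts     20 residue-type counts in a 23-wide window (site excluded)
neighborhood_classes     5 NonPolarAA, PolarAA, ChargedAA, PosAA, NegAA counts
external_protein        19 precomputed whole-protein descriptors (sidecar table)
==================== ===== =======================================================

The registry fixes names and order; the census must total exactly 1106.
Per-residue amino-acid indices are encoded as value(mut) − value(wt);
matrix-type indices contribute their (wt, mut) entry.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .conservation import ConservationProfile
from .dataset import AMINO_ACIDS, VariantRecord

TOTAL_FEATURES = 1106
N_AAINDEX = 617
N_EXTERNAL = 19

FAMILY_SIZES = {
    "condition": 2,
    "conservation": 3,
    "coevolution": 4,
    "aaindex": N_AAINDEX,
    "vartype20x20": 400,
    "vartype6x6": 36,
    "neighborhood_counts": 20,
    "neighborhood_classes": 5,
    "external_protein": N_EXTERNAL,
}

# Physicochemical groups of the 6x6 substitution-type block.
GROUPS6 = (
    ("hydrophobic", "VILFMWYC"),
    ("negative", "DE"),
    ("positive", "RKH"),
    ("conformational", "GP"),
    ("polar", "NQS"),
    ("other", "AT"),
)
_GROUP_OF = {aa: name for name, members in GROUPS6 for aa in members}

# Neighborhood class-count scheme (histidine counted polar-uncharged here;
# this deliberately differs from the 6x6 grouping above, which puts H with
# the positively charged residues).
NB_NONPOLAR = set("AVLIPFMWGC")
NB_POLAR = set("STYNQH")
NB_POSITIVE = set("KR")
NB_NEGATIVE = set("DE")
NB_CHARGED = NB_POSITIVE | NB_NEGATIVE
NB_CLASS_NAMES = ("NonPolarAA", "PolarAA", "ChargedAA", "PosAA", "NegAA")

#: Half-width of the sequence window: 11 before + 11 after = 23 positions.
WINDOW_FLANK = 11

_AA_POS = {a: i for i, a in enumerate(AMINO_ACIDS)}


@dataclass
class AAIndexTable:
    """Amino-acid index collection in the AAindex flat-file dialect.

    Holds per-residue indices (20 values each), and 20×20 substitution
    matrices / contact potentials.  Records containing ``NA`` entries are
    flagged incomplete and excluded from the usable feature set.
    """

    per_residue: dict[str, dict[str, float]] = field(default_factory=dict)
    matrices: dict[str, np.ndarray] = field(default_factory=dict)
    incomplete: set[str] = field(default_factory=set)

    # AAindex "I" line residue order: row 1 then row 2.
    _I_ORDER = "ARNDCQEGHI" "LKMFPSTWYV"

    @property
    def usable_per_residue(self) -> list[str]:
        return [a for a in self.per_residue if a not in self.incomplete]

    @property
    def usable_matrices(self) -> list[str]:
        return [a for a in self.matrices if a not in self.incomplete]

    @property
    def n_usable(self) -> int:
        return len(self.usable_per_residue) + len(self.usable_matrices)

    def feature_names(self) -> list[str]:
        return ([f"aa_{a}" for a in self.usable_per_residue]
                + [f"aa_{a}" for a in self.usable_matrices])

    def values(self, wt_aa: str, mut_aa: str) -> np.ndarray:
        """Encode a substitution against every usable index.

        Per-residue indices: value(mut) − value(wt).  Matrices: the
        (wt, mut) entry, rows indexed by the original residue.
        """
        for aa in (wt_aa, mut_aa):
            if aa not in _AA_POS:
                raise ValueError(f"non-canonical residue {aa!r}")
        out = np.empty(self.n_usable)
        k = 0
        for acc in self.usable_per_residue:
            idx = self.per_residue[acc]
            out[k] = idx[mut_aa] - idx[wt_aa]
            k += 1
        i, j = _AA_POS[wt_aa], _AA_POS[mut_aa]
        for acc in self.usable_matrices:
            out[k] = self.matrices[acc][i, j]
            k += 1
        return out

    @classmethod
    def from_text(cls, text: str) -> "AAIndexTable":
        table = cls()
        for chunk in text.split("//"):
            lines = [ln for ln in chunk.splitlines() if ln.strip()]
            if not lines:
                continue
            acc = None
            i = 0
            while i < len(lines):
                line = lines[i]
                tag = line[:1]
                if tag == "H":
                    acc = line[1:].strip()
                elif tag == "I":
                    vals = []
                    i += 1
                    while i < len(lines) and lines[i][:1] == " ":
                        vals.extend(lines[i].split())
                        i += 1
                    i -= 1
                    if acc is None:
                        raise ValueError("I record before H accession")
                    if len(vals) != 20:
                        raise ValueError(
                            f"{acc}: expected 20 index values, got {len(vals)}")
                    idx = {}
                    bad = False
                    for aa, v in zip(cls._I_ORDER, vals):
                        if v.upper() == "NA":
                            bad = True
                        else:
                            idx[aa] = float(v)
                    table.per_residue[acc] = {a: idx.get(a, np.nan)
                                              for a in AMINO_ACIDS}
                    if bad:
                        table.incomplete.add(acc)
                elif tag == "M":
                    if acc is None:
                        raise ValueError("M record before H accession")
                    spec = line[1:]
                    rows_order = spec.split("rows =")[1].split(",")[0].strip()
                    cols_order = spec.split("cols =")[1].strip().rstrip(",")
                    mat_rows = []
                    i += 1
                    while i < len(lines) and lines[i][:1] == " ":
                        mat_rows.append(lines[i].split())
                        i += 1
                    i -= 1
                    m = np.full((20, 20), np.nan)
                    bad = False
                    lower = any(len(r) < len(cols_order) for r in mat_rows)
                    for r, row in enumerate(mat_rows):
                        for c, v in enumerate(row):
                            if v.upper() in ("NA", "-"):
                                bad = True
                                val = np.nan
                            else:
                                val = float(v)
                            ri = _AA_POS[rows_order[r]]
                            ci = _AA_POS[cols_order[c]]
                            m[ri, ci] = val
                            if lower:
                                m[ci, ri] = val
                    if np.isnan(m).any():
                        bad = True
                    table.matrices[acc] = m
                    if bad:
                        table.incomplete.add(acc)
                i += 1
        return table

    @classmethod
    def from_file(cls, path) -> "AAIndexTable":
        with open(path) as fh:
            return cls.from_text(fh.read())


def load_sample_table() -> AAIndexTable:
    """Small packaged table of real published indices (for quick checks)."""
    text = (importlib.resources.files("protstab.data")
            .joinpath("aaindex_sample.txt").read_text())
    return AAIndexTable.from_text(text)


@dataclass
class FeatureRegistry:
    """Stable, ordered names of every descriptor slot."""

    names: list[str]
    families: list[str]

    def __post_init__(self) -> None:
        if len(self.names) != len(set(self.names)):
            raise ValueError("duplicate feature names in registry")
        if len(self.names) != len(self.families):
            raise ValueError("names/families length mismatch")

    def __len__(self) -> int:
        return len(self.names)

    def family_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for fam in self.families:
            out[fam] = out.get(fam, 0) + 1
        return out

    def names_in_family(self, family: str) -> list[str]:
        return [n for n, f in zip(self.names, self.families) if f == family]


def build_registry(table: AAIndexTable) -> FeatureRegistry:
    """Construct the 1106-slot registry for a given amino-acid index table."""
    if table.n_usable != N_AAINDEX:
        raise ValueError(
            f"index table provides {table.n_usable} usable features, "
            f"registry requires {N_AAINDEX}")
    names: list[str] = []
    families: list[str] = []

    def add(family, new_names):
        names.extend(new_names)
        families.extend([family] * len(new_names))

    add("condition", ["cond_temperature", "cond_ph"])
    add("conservation", ["cons_info_content", "cons_pssm_wt",
                         "cons_pssm_mut"])
    add("coevolution", ["coev_is_coevolving", "coev_max_cor",
                        "coev_is_coevolving_grp", "coev_grp_count"])
    add("aaindex", table.feature_names())
    add("vartype20x20", [f"vt20_{w}{m}" for w in AMINO_ACIDS
                         for m in AMINO_ACIDS])
    add("vartype6x6", [f"vt6_{gw}_{gm}" for gw, _ in GROUPS6
                       for gm, _ in GROUPS6])
    add("neighborhood_counts", [f"nb_count_{a}" for a in AMINO_ACIDS])
    add("neighborhood_classes", [f"nb_{c}" for c in NB_CLASS_NAMES])
    add("external_protein", [f"external_{i:02d}" for i in range(1, 20)])
    reg = FeatureRegistry(names, families)
    assert len(reg) == TOTAL_FEATURES, len(reg)
    return reg


def condition_features(record: VariantRecord) -> np.ndarray:
    """(temperature °C, pH), copied verbatim from the harmonized record."""
    if record.ph is None or np.isnan(record.ph):
        raise ValueError(f"{record.record_id}: pH is mandatory")
    return np.array([record.temperature_c, record.ph], dtype=float)


def conservation_features(profile: ConservationProfile, position: int,
                          wt_aa: str, mut_aa: str) -> np.ndarray:
    return np.array(profile.features_at(position, wt_aa, mut_aa))


def coevolution_features(profile: ConservationProfile,
                         position: int) -> np.ndarray:
    co = profile.coevolution[position]
    return np.array([co.is_coevolving, co.max_cor, co.is_coevolving_grp,
                     co.grp_count], dtype=float)


def aaindex_features(table: AAIndexTable, wt_aa: str,
                     mut_aa: str) -> np.ndarray:
    return table.values(wt_aa, mut_aa)


def variation_type_features(wt_aa: str, mut_aa: str
                            ) -> tuple[np.ndarray, np.ndarray]:
    """One-hot 20×20 substitution cell and one-hot 6×6 group cell."""
    for aa in (wt_aa, mut_aa):
        if aa not in _AA_POS:
            raise ValueError(f"non-canonical residue {aa!r}")
    v20 = np.zeros(400)
    v20[_AA_POS[wt_aa] * 20 + _AA_POS[mut_aa]] = 1.0
    group_index = {name: k for k, (name, _) in enumerate(GROUPS6)}
    v6 = np.zeros(36)
    v6[group_index[_GROUP_OF[wt_aa]] * 6 + group_index[_GROUP_OF[mut_aa]]] = 1.0
    return v20, v6


def neighborhood_features(sequence: str, position: int
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Residue and class counts in the 23-position window around a site.

    The window spans 11 positions either side of the variant site; the site
    itself is excluded and the window is truncated at the termini, so the
    counts sum to at most 22.
    """
    if not 1 <= position <= len(sequence):
        raise ValueError(f"position {position} outside sequence")
    lo = max(0, position - 1 - WINDOW_FLANK)
    hi = min(len(sequence), position + WINDOW_FLANK)
    counts = np.zeros(20)
    classes = np.zeros(5)
    for i in range(lo, hi):
        if i == position - 1:
            continue
        aa = sequence[i]
        if aa not in _AA_POS:
            continue
        counts[_AA_POS[aa]] += 1
        if aa in NB_NONPOLAR:
            classes[0] += 1
        if aa in NB_POLAR:
            classes[1] += 1
        if aa in NB_CHARGED:
            classes[2] += 1
        if aa in NB_POSITIVE:
            classes[3] += 1
        if aa in NB_NEGATIVE:
            classes[4] += 1
    return counts, classes


@dataclass
class FeatureVector:
    """A 1106-value descriptor aligned to a registry.

    ``external_mask`` marks external_protein slots that were absent from
    the sidecar table (their values are NaN until imputed by the model).
    """

    values: np.ndarray
    registry: FeatureRegistry
    external_mask: np.ndarray

    def __post_init__(self) -> None:
        if len(self.values) != len(self.registry):
            raise ValueError(
                f"vector length {len(self.values)} != registry "
                f"{len(self.registry)}")


def assemble(record: VariantRecord, profile: ConservationProfile,
             table: AAIndexTable, sequence: str,
             registry: FeatureRegistry | None = None,
             external: np.ndarray | None = None) -> FeatureVector:
    """Build the full descriptor of one variant.

    ``external`` supplies the 19 precomputed whole-protein descriptors;
    when absent those slots are NaN and masked for later imputation.
    Pure function of its inputs: identical calls give identical vectors.
    """
    registry = registry or build_registry(table)
    v20, v6 = variation_type_features(record.wt_aa, record.mut_aa)
    counts, classes = neighborhood_features(sequence, record.position)
    if external is None:
        ext = np.full(N_EXTERNAL, np.nan)
        mask = np.ones(N_EXTERNAL, dtype=bool)
    else:
        ext = np.asarray(external, dtype=float)
        if len(ext) != N_EXTERNAL:
            raise ValueError(f"expected {N_EXTERNAL} external descriptors")
        mask = np.isnan(ext)
    values = np.concatenate([
        condition_features(record),
        conservation_features(profile, record.position, record.wt_aa,
                              record.mut_aa),
        coevolution_features(profile, record.position),
        aaindex_features(table, record.wt_aa, record.mut_aa),
        v20, v6, counts, classes, ext,
    ])
    full_mask = np.zeros(len(registry), dtype=bool)
    full_mask[-N_EXTERNAL:] = mask
    return FeatureVector(values=values, registry=registry,
                         external_mask=full_mask)


def build_feature_table(records, sequences, profiles, table,
                        registry: FeatureRegistry | None = None,
                        external_df: pd.DataFrame | None = None
                        ) -> pd.DataFrame:
    """Descriptor matrix for many records (rows indexed by record_id).

    ``profiles`` maps protein_id → ConservationProfile and ``sequences``
    sequence_ref → residue string.  ``external_df`` is the optional sidecar
    of 19 whole-protein descriptors indexed by protein_id.
    """
    registry = registry or build_registry(table)
    rows, index = [], []
    for rec in records:
        ext = None
        if external_df is not None and rec.protein_id in external_df.index:
            ext = external_df.loc[rec.protein_id].to_numpy(dtype=float)
        fv = assemble(rec, profiles[rec.protein_id], table,
                      sequences[rec.sequence_ref], registry=registry,
                      external=ext)
        rows.append(fv.values)
        index.append(rec.record_id)
    return pd.DataFrame(rows, index=pd.Index(index, name="record_id"),
                        columns=registry.names)
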