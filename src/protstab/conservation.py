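"""Per-position conservation descriptors from a multiple sequence alignment.

Three kinds of descriptor are derived for every position of the reference
(query) sequence:

* **information content** (bits): ``IC = log2(20) + sum_a p_a log2 p_a``
  over the 20 amino acids, 0 bits for a uniform column, log2(20) ≈ 4.322
  bits for an invariant one.  Gaps are excluded from the counts.
* **PSSM** log-odds: ``score(pos, a) = log2(((n_a + c·b_a) / (N + c)) / b_a)``
  with pseudocount ``c`` distributed by the background frequencies ``b``.
* a **co-evolution proxy**: pairwise column association measured by
  Cramér's V on residue identities; a position is called co-evolving when
  its maximum association with any other column reaches a threshold, and
  co-evolving groups are the connected components of the thresholded
  association graph.

The MSA itself is an input: homolog collection (e.g. a BLAST search at
E-value < 0.001) and alignment are expected to happen upstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import AMINO_ACIDS

GAP = "-"
MAX_IC_BITS = math.log2(20)

#: Default association threshold for calling a position co-evolving.
COEVOLUTION_THRESHOLD = 0.8

#: Minimum number of non-reference rows for the co-evolution proxy.
MIN_COEVOLUTION_DEPTH = 10

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


class MSA:
    """A gapped alignment with a designated reference (query) row.

    Maintains the column ↔ reference-position map: reference positions are
    1-based and skip columns where the reference row is gapped, so every
    reference position is assigned exactly one column.
    """

    def __init__(self, sequences: list[str], reference_index: int = 0,
                 ids: list[str] | None = None):
        if not sequences:
            raise ValueError("empty alignment")
        length = len(sequences[0])
        if any(len(s) != length for s in sequences):
            raise ValueError("alignment rows differ in length")
        self.sequences = [s.upper() for s in sequences]
        self.reference_index = reference_index
        self.ids = ids or [f"seq{i}" for i in range(len(sequences))]
        self.length = length
        ref = self.sequences[reference_index]
        self.column_of_position: dict[int, int] = {}
        self.position_of_column: dict[int, int] = {}
        pos = 0
        for col, aa in enumerate(ref):
            if aa != GAP:
                pos += 1
                self.column_of_position[pos] = col
                self.position_of_column[col] = pos

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def reference_length(self) -> int:
        return len(self.column_of_position)

    @property
    def reference_sequence(self) -> str:
        return self.sequences[self.reference_index].replace(GAP, "")

    def column(self, col: int) -> list[str]:
        return [s[col] for s in self.sequences]

    @classmethod
    def from_file(cls, path, reference_index: int = 0) -> "MSA":
        """Load an aligned FASTA or Clustal file, auto-detected by content."""
        from Bio import AlignIO
        with open(path) as fh:
            head = fh.read(64)
        fmt = "clustal" if head.upper().startswith("CLUSTAL") else "fasta"
        aln = AlignIO.read(str(path), fmt)
        return cls([str(r.seq) for r in aln], reference_index,
                   ids=[r.id for r in aln])


def _column_counts(msa: MSA, col: int) -> np.ndarray:
    counts = np.zeros(20)
    for aa in msa.column(col):
        idx = _AA_INDEX.get(aa)
        if idx is not None:
            counts[idx] += 1
    return counts


def column_information_content(msa: MSA, column: int,
                               pseudocount: float = 0.0,
                               background: np.ndarray | None = None) -> float:
    """Information content of one alignment column, in bits.

    Gaps and non-canonical residues are excluded from the counts.  The
    default is the plain plug-in estimate (no pseudocount).
    """
    counts = _column_counts(msa, column)
    n = counts.sum()
    if n == 0:
        raise ValueError(f"column {column} contains only gaps")
    bg = np.full(20, 0.05) if background is None else np.asarray(background)
    p = (counts + pseudocount * bg) / (n + pseudocount)
    nz = p > 0
    return float(MAX_IC_BITS + np.sum(p[nz] * np.log2(p[nz])))


def build_pssm(msa: MSA, pseudocount: float = 1.0,
               background: np.ndarray | None = None) -> pd.DataFrame:
    """Position-specific log-odds scores, one row per reference position.

    ``score = log2(((n_a + c·b_a) / (N + c)) / b_a)`` with pseudocount
    ``c > 0`` (required: with c = 0 unobserved residues would score −inf).
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0 for finite log-odds")
    bg = np.full(20, 0.05) if background is None else np.asarray(background)
    rows = {}
    for pos, col in msa.column_of_position.items():
        counts = _column_counts(msa, col)
        n = counts.sum()
        p = (counts + pseudocount * bg) / (n + pseudocount)
        rows[pos] = np.log2(p / bg)
    pssm = pd.DataFrame.from_dict(rows, orient="index",
                                  columns=list(AMINO_ACIDS))
    pssm.index.name = "position"
    return pssm


def cramers_v(col_a: list[str], col_b: list[str]) -> float:
    """Cramér's V association between two residue columns.

    Rows gapped in either column are dropped; a column with a single
    residue state carries no association (V = 0).
    """
    pairs = [(a, b) for a, b in zip(col_a, col_b)
             if a in _AA_INDEX and b in _AA_INDEX]
    if len(pairs) < 2:
        return 0.0
    a_states = sorted({a for a, _ in pairs})
    b_states = sorted({b for _, b in pairs})
    if len(a_states) < 2 or len(b_states) < 2:
        return 0.0
    table = np.zeros((len(a_states), len(b_states)))
    ai = {s: i for i, s in enumerate(a_states)}
    bi = {s: i for i, s in enumerate(b_states)}
    for a, b in pairs:
        table[ai[a], bi[b]] += 1
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    chi2 = float(np.sum((table - expected) ** 2 / expected))
    k = min(len(a_states), len(b_states)) - 1
    return math.sqrt(chi2 / (n * k))


@dataclass
class CoevolutionTuple:
    is_coevolving: int
    max_cor: float
    is_coevolving_grp: int
    grp_count: int


@dataclass
class ConservationProfile:
    """Conservation descriptors indexed by 1-based reference position."""

    positions: list[int]
    reference_residues: dict[int, str]
    info_content: dict[int, float]
    pssm: pd.DataFrame
    coevolution: dict[int, CoevolutionTuple]
    degenerate_positions: set[int] = field(default_factory=set)
    low_depth: bool = False

    def features_at(self, position: int, wt_aa: str, mut_aa: str
                    ) -> tuple[float, float, float]:
        """(IC, pssm(wt), pssm(mut)) at a reference position."""
        if position not in self.info_content:
            raise KeyError(f"position {position} not mapped in the profile")
        row = self.pssm.loc[position]
        return (self.info_content[position], float(row[wt_aa]),
                float(row[mut_aa]))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pos in self.positions:
            co = self.coevolution[pos]
            row = {"position": pos, "wt": self.reference_residues[pos],
                   "info_content": self.info_content[pos]}
            row.update({f"pssm_{a}": self.pssm.loc[pos, a]
                        for a in AMINO_ACIDS})
            row.update({"is_coevolving": co.is_coevolving,
                        "max_cor": co.max_cor,
                        "is_coevolving_grp": co.is_coevolving_grp,
                        "grp_count": co.grp_count})
            rows.append(row)
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def coevolution_proxy(msa: MSA,
                      correlation_threshold: float = COEVOLUTION_THRESHOLD
                      ) -> tuple[dict[int, CoevolutionTuple], bool]:
    """Per-position co-evolution calls from pairwise column association.

    Returns ``(tuples, low_depth)``.  Below ``MIN_COEVOLUTION_DEPTH``
    non-reference rows all tuples are zeros and the profile is flagged
    low-depth rather than reporting spurious associations.
    """
    positions = sorted(msa.column_of_position)
    n_hom = len(msa) - 1
    if n_hom < MIN_COEVOLUTION_DEPTH:
        return ({p: CoevolutionTuple(0, 0.0, 0, 0) for p in positions},
                True)
    cols = {p: msa.column(msa.column_of_position[p]) for p in positions}
    npos = len(positions)
    assoc = np.zeros((npos, npos))
    for i in range(npos):
        for j in range(i + 1, npos):
            v = cramers_v(cols[positions[i]], cols[positions[j]])
            assoc[i, j] = assoc[j, i] = v
    # connected components of the thresholded graph (union-find)
    parent = list(range(npos))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges = assoc >= correlation_threshold
    for i in range(npos):
        for j in range(i + 1, npos):
            if edges[i, j]:
                parent[find(i)] = find(j)
    comp_size: dict[int, int] = {}
    for i in range(npos):
        comp_size[find(i)] = comp_size.get(find(i), 0) + 1
    out = {}
    for i, pos in enumerate(positions):
        max_cor = float(assoc[i].max()) if npos > 1 else 0.0
        is_co = int(max_cor >= correlation_threshold)
        in_group = int(comp_size[find(i)] > 1)
        out[pos] = CoevolutionTuple(is_co, max_cor, in_group, in_group)
    return out, False


def build_profile(msa: MSA, pseudocount: float = 1.0,
                  background: np.ndarray | None = None,
                  correlation_threshold: float = COEVOLUTION_THRESHOLD,
                  compute_coevolution: bool = True) -> ConservationProfile:
    """Full conservation profile of the reference sequence of an MSA."""
    positions = sorted(msa.column_of_position)
    ref = msa.sequences[msa.reference_index]
    info, degenerate = {}, set()
    for pos in positions:
        col = msa.column_of_position[pos]
        info[pos] = column_information_content(msa, col)
        others = [s[col] for i, s in enumerate(msa.sequences)
                  if i != msa.reference_index]
        if all(a not in _AA_INDEX for a in others):
            degenerate.add(pos)
    pssm = build_pssm(msa, pseudocount=pseudocount, background=background)
    if compute_coevolution:
        coev, low_depth = coevolution_proxy(msa, correlation_threshold)
    else:
        coev = {p: CoevolutionTuple(0, 0.0, 0, 0) for p in positions}
        low_depth = True
    return ConservationProfile(
        positions=positions,
        reference_residues={p: ref[msa.column_of_position[p]]
                            for p in positions},
        info_content=info,
        pssm=pssm,
        coevolution=coev,
        degenerate_positions=degenerate,
        low_depth=low_depth,
    )
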