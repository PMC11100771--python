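"""Structure-anchored multiple-sequence-alignment analytics.

Everything here is organised around a *reference* sequence (the structurally
characterised family member) whose ungapped alignment row maps columns to
author residue numbers.  On top of that map the module projects helix
boundary tables onto the alignment, measures inter-helix loop lengths per
sequence, computes per-position amino-acid frequencies, collapses them into
the six chemical classes used for pocket heatmaps, grades per-column
conservation on a 1-9 scale, matches class-pattern motifs, and exports
sequence-logo letter heights.

Two residue-class schemes coexist deliberately and must not be conflated:

* heatmap (6 classes): aliphatic {A,C,L,M,V}, polar {N,Q,S,T}, negative
  {D,E}, positive {R,K}, aromatic {H,F,W,Y}, shape {G,P};
* logo colours (4 classes): polar {G,S,T,Y,C,Q,N}, basic {K,R,H}, acidic
  {D,E}, hydrophobic {A,V,L,I,P,W,F,M}.

Histidine is aromatic in heatmaps but basic in logo colours.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("structprof")

__all__ = [
    "AA_ORDER", "GAP", "HEATMAP_CLASSES", "HEATMAP_CLASS_ORDER", "LOGO_CLASSES",
    "BMGR9_HELICES", "MHOR5_HELICES",
    "AlignmentError", "AnnotatedAlignment", "HelixAnnotation", "ColumnProfile",
    "ClassHeatmap", "ConservationGrades",
    "read_alignment", "write_alignment", "filter_sequences", "loop_lengths",
    "loop_length_summary", "column_frequencies", "class_heatmap",
    "conservation_grades", "sequence_weights", "motif_match", "logo_data",
]

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}

# 6-class scheme used for the pocket-composition heatmaps
HEATMAP_CLASSES = {
    "aliphatic": set("ACLMV"),
    "polar": set("NQST"),
    "negative": set("DE"),
    "positive": set("RK"),
    "aromatic": set("HFWY"),
    "shape": set("GP"),
}
# dominant-class tie-break order
HEATMAP_CLASS_ORDER = ["aromatic", "polar", "aliphatic", "negative", "positive", "shape"]

# 4-class logo colour scheme
LOGO_CLASSES = {
    "polar": set("GSTYCQN"),
    "basic": set("KRH"),
    "acidic": set("DE"),
    "hydrophobic": set("AVLIPWFM"),
}
LOGO_COLORS = {"polar": "green", "basic": "blue", "acidic": "red",
               "hydrophobic": "black"}

_HYDROPHOBIC = set("AVLIPWFM")   # 'h' in class patterns such as TYhhhhhQF


class AlignmentError(ValueError):
    """Malformed alignment, unknown reference, or unmappable position."""


# ---------------------------------------------------------------------------
# Helix boundary tables (author numbering on the reference structures)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HelixAnnotation:
    """Named inclusive residue ranges on the reference, ascending."""

    ranges: tuple          # ((name, (start, end)), ...)

    def __post_init__(self) -> None:
        rngs = tuple((str(n), (int(a), int(b))) for n, (a, b) in self.ranges)
        prev_end = -10 ** 9
        for name, (a, b) in rngs:
            if a > b:
                raise AlignmentError(f"helix {name}: start {a} > end {b}")
            if a <= prev_end:
                raise AlignmentError(f"helix {name} overlaps or is out of order")
            prev_end = b
        object.__setattr__(self, "ranges", rngs)

    def __iter__(self):
        return iter(self.ranges)

    def __getitem__(self, name: str) -> tuple[int, int]:
        for n, rng in self.ranges:
            if n == name:
                return rng
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.ranges]


BMGR9_HELICES = HelixAnnotation(ranges=(
    ("S1", (52, 79)), ("S2", (90, 135)), ("S3", (141, 176)), ("S4", (178, 229)),
    ("S5", (287, 339)), ("S6", (345, 389)), ("S7a", (395, 409)), ("S7b", (424, 444)),
))
MHOR5_HELICES = HelixAnnotation(ranges=(
    ("S1", (49, 76)), ("S2", (78, 123)), ("S3", (130, 159)), ("S4", (198, 251)),
    ("S5", (317, 368)), ("S6", (371, 415)), ("S7a", (420, 434)), ("S7b", (448, 472)),
))


# ---------------------------------------------------------------------------
# Alignment container
# ---------------------------------------------------------------------------

@dataclass
class AnnotatedAlignment:
    """Aligned sequences plus a column ↔ reference-residue map."""

    ids: list
    rows: list                  # aligned sequences, uppercase, '-' gaps
    reference_id: str
    ref_start: int = 1          # author number of the reference's first residue
    colmap: list = field(default=None, repr=False)   # per column: resnum or None

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows) or not self.ids:
            raise AlignmentError("ids and rows must be equal-length and nonempty")
        L = len(self.rows[0])
        for rid, row in zip(self.ids, self.rows):
            if len(row) != L:
                raise AlignmentError(f"ragged row for {rid!r}: {len(row)} != {L}")
        self.rows = [r.upper().replace(".", GAP) for r in self.rows]
        if self.reference_id not in self.ids:
            raise AlignmentError(f"reference {self.reference_id!r} not in alignment")
        if self.colmap is None:
            ref = self.rows[self.ids.index(self.reference_id)]
            num = self.ref_start
            cm = []
            for ch in ref:
                if ch == GAP:
                    cm.append(None)
                else:
                    cm.append(num)
                    num += 1
            self.colmap = cm

    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @property
    def reference_row(self) -> str:
        return self.rows[self.ids.index(self.reference_id)]

    @property
    def reference_sequence(self) -> str:
        return self.reference_row.replace(GAP, "")

    def column_of(self, resnum: int) -> int:
        try:
            return self.colmap.index(resnum)
        except ValueError:
            raise AlignmentError(f"reference residue {resnum} is not mapped") from None

    def columns_between(self, res_a: int, res_b: int) -> list[int]:
        """Columns strictly between the columns of two reference residues."""
        ca, cb = self.column_of(res_a), self.column_of(res_b)
        if ca > cb:
            ca, cb = cb, ca
        return list(range(ca + 1, cb))

    def matrix(self) -> np.ndarray:
        """(n, L) uint8 state matrix; 0..19 amino acids, 20 gap/other."""
        lut = np.full(256, 20, dtype=np.uint8)
        for a, i in AA_INDEX.items():
            lut[ord(a)] = i
        arr = np.frombuffer("".join(self.rows).encode(), dtype=np.uint8)
        return lut[arr].reshape(self.n_sequences, self.n_columns)


def read_alignment(path, format: str = "fasta", reference_id: str | None = None,
                   ref_start: int = 1) -> AnnotatedAlignment:
    """Read a FASTA or Stockholm alignment and bind the reference row."""
    if format not in ("fasta", "stockholm"):
        raise AlignmentError(f"unsupported alignment format {format!r}")
    try:
        msa = AlignIO.read(path, format)
    except ValueError as exc:
        raise AlignmentError(f"failed to parse {path}: {exc}") from exc
    ids = [rec.id for rec in msa]
    rows = [str(rec.seq) for rec in msa]
    if reference_id is None:
        reference_id = ids[0]
    return AnnotatedAlignment(ids=ids, rows=rows, reference_id=reference_id,
                              ref_start=ref_start)


def write_alignment(aln: AnnotatedAlignment, path, format: str = "fasta") -> None:
    msa = MultipleSeqAlignment(
        [SeqRecord(Seq(r), id=i, description="") for i, r in zip(aln.ids, aln.rows)])
    AlignIO.write(msa, path, format)


def filter_sequences(aln: AnnotatedAlignment, min_len: int = 300,
                     max_len: int = 600) -> AnnotatedAlignment:
    """Keep sequences whose ungapped length is within [min_len, max_len].

    The reference is always retained.  Idempotent.
    """
    keep = []
    for i, (rid, row) in enumerate(zip(aln.ids, aln.rows)):
        n = len(row) - row.count(GAP)
        if rid == aln.reference_id:
            if not min_len <= n <= max_len:
                log.warning("reference %s length %d outside [%d, %d]; retained",
                            rid, n, min_len, max_len)
            keep.append(i)
        elif min_len <= n <= max_len:
            keep.append(i)
    if len(keep) == 1:
        log.warning("filter_sequences: only the reference survived the length filter")
    return AnnotatedAlignment(ids=[aln.ids[i] for i in keep],
                              rows=[aln.rows[i] for i in keep],
                              reference_id=aln.reference_id,
                              ref_start=aln.ref_start)


# ---------------------------------------------------------------------------
# Loop lengths
# ---------------------------------------------------------------------------

def loop_lengths(aln: AnnotatedAlignment, helices: HelixAnnotation,
                 shrink: int = 1) -> pd.DataFrame:
    """Per-sequence inter-helix loop lengths.

    Each helix range is shrunk by ``shrink`` residues on each end (tolerating
    alignment noise at helix termini); a sequence's loop length between two
    adjacent helices is its number of non-gap characters in the alignment
    columns strictly between the shrunk helix projections.
    """
    for name, (a0, a1) in helices.ranges:
        if a0 + shrink > a1 - shrink:
            raise AlignmentError(f"helix {name} vanishes under shrink={shrink}")
    pairs = list(zip(helices.ranges, helices.ranges[1:]))
    loop_cols = {}
    for (name_a, (a0, a1)), (name_b, (b0, b1)) in pairs:
        end_a, start_b = a1 - shrink, b0 + shrink
        if end_a >= start_b:
            raise AlignmentError(
                f"helices {name_a} and {name_b} overlap after shrink={shrink}")
        loop_cols[f"{name_a}-{name_b}"] = aln.columns_between(end_a, start_b)
    mat = aln.matrix()
    out = {}
    for loop, cols in loop_cols.items():
        if cols:
            out[loop] = (mat[:, cols] != 20).sum(axis=1)
        else:
            out[loop] = np.zeros(aln.n_sequences, dtype=int)
    return pd.DataFrame(out, index=aln.ids)


def loop_length_summary(lengths: pd.DataFrame) -> pd.DataFrame:
    """Mean/median/count per loop over sequences with non-zero loop length
    (zero-length rows usually indicate incomplete sequences)."""
    rows = []
    for loop in lengths.columns:
        vals = lengths[loop][lengths[loop] > 0]
        rows.append({"loop": loop, "n": int(len(vals)),
                     "mean": float(vals.mean()) if len(vals) else np.nan,
                     "median": float(vals.median()) if len(vals) else np.nan})
    return pd.DataFrame(rows).set_index("loop")


# ---------------------------------------------------------------------------
# Column profiles and class heatmaps
# ---------------------------------------------------------------------------

@dataclass
class ColumnProfile:
    """Amino-acid + gap counts at selected reference positions."""

    positions: list                # reference residue numbers
    counts: np.ndarray             # (n_positions, 21): 20 aa + gap
    n_sequences: int

    def frequencies(self, denominator: str = "all") -> pd.DataFrame:
        """Per-position frequencies.

        ``denominator='all'`` divides by the number of sequences (gap fraction
        reported separately); ``'nongap'`` divides by non-gap counts only.
        """
        counts = self.counts.astype(float)
        if denominator == "all":
            denom = np.full(len(self.positions), float(self.n_sequences))
        elif denominator == "nongap":
            denom = counts[:, :20].sum(axis=1)
            denom[denom == 0] = np.nan
        else:
            raise AlignmentError(f"unknown denominator mode {denominator!r}")
        freq = counts / denom[:, None]
        return pd.DataFrame(freq, index=self.positions, columns=list(AA_ORDER) + ["gap"])


def column_frequencies(aln: AnnotatedAlignment, positions) -> ColumnProfile:
    """Counts of the 20 amino acids + gap at the given reference positions."""
    mat = aln.matrix()
    counts = np.zeros((len(positions), 21), dtype=int)
    for i, pos in enumerate(positions):
        col = mat[:, aln.column_of(int(pos))]
        counts[i] = np.bincount(col, minlength=21)
    return ColumnProfile(positions=[int(p) for p in positions], counts=counts,
                         n_sequences=aln.n_sequences)


@dataclass
class ClassHeatmap:
    """Six-class frequency summary per position."""

    positions: list
    class_freq: pd.DataFrame       # columns = 6 classes, + "gap"
    dominant_class: list
    ties: list                     # positions where the dominant class was tied


def class_heatmap(profile: ColumnProfile, denominator: str = "all") -> ClassHeatmap:
    """Collapse amino-acid frequencies into the six heatmap classes."""
    freq = profile.frequencies(denominator=denominator)
    data = {}
    for cls in HEATMAP_CLASS_ORDER:
        members = [a for a in AA_ORDER if a in HEATMAP_CLASSES[cls]]
        data[cls] = freq[members].sum(axis=1)
    data["gap"] = freq["gap"] if denominator == "all" else 0.0 * freq["A"]
    cf = pd.DataFrame(data, index=profile.positions)
    dominant, ties = [], []
    class_block = cf[HEATMAP_CLASS_ORDER]
    for pos, row in class_block.iterrows():
        best = row.max()
        winners = [c for c in HEATMAP_CLASS_ORDER if np.isclose(row[c], best)]
        dominant.append(winners[0])
        if len(winners) > 1:
            ties.append(pos)
    return ClassHeatmap(positions=profile.positions, class_freq=cf,
                        dominant_class=dominant, ties=ties)


# ---------------------------------------------------------------------------
# Conservation grading
# ---------------------------------------------------------------------------

def sequence_weights(aln: AnnotatedAlignment, identity: float = 0.8,
                     chunk: int = 256) -> np.ndarray:
    """Redundancy weights: 1 / (number of sequences within the identity
    threshold, counting matches over alignment columns)."""
    mat = aln.matrix()
    n, L = mat.shape
    counts = np.zeros(n, dtype=int)
    for start in range(0, n, chunk):
        block = mat[start:start + chunk]
        sim = (block[:, None, :] == mat[None, :, :]).mean(axis=2)
        counts[start:start + chunk] = (sim >= identity).sum(axis=1)
    return 1.0 / counts


@dataclass
class ConservationGrades:
    positions: list                # reference residue numbers (mapped cols only)
    scores: np.ndarray             # per mapped column, higher = more conserved
    grades: np.ndarray             # 1..9, 9 = most conserved; 0 = undefined
    flagged: list                  # positions with undefined (all-gap) columns


def conservation_grades(aln: AnnotatedAlignment,
                        background: np.ndarray | None = None,
                        reweight_identity: float = 0.8,
                        min_effective: float = 10.0) -> ConservationGrades:
    """Per-column conservation scores and 1-9 grades (9 = most conserved).

    The score is the Jensen-Shannon divergence between the gap-excluded,
    redundancy-weighted column composition and a background distribution
    (default: the weighted overall composition of the alignment).  Grades are
    a 9-quantile binning of the scores over mapped columns; invariant columns
    land in grade 9, background-like columns in grade 1.
    """
    mat = aln.matrix()
    w = sequence_weights(aln, identity=reweight_identity)
    n_eff = float(w.sum())
    if n_eff < min_effective:
        raise AlignmentError(f"only {n_eff:.1f} effective sequences (< {min_effective})")
    cols = [c for c, r in enumerate(aln.colmap) if r is not None]
    positions = [aln.colmap[c] for c in cols]

    global_counts = np.zeros(20)
    for a in range(20):
        global_counts[a] = (w[:, None] * (mat == a)).sum()
    if background is None:
        background = global_counts / global_counts.sum()
    background = np.asarray(background, float)
    background = background / background.sum()

    eps = 1e-12
    scores = np.full(len(cols), np.nan)
    flagged = []
    for i, c in enumerate(cols):
        col = mat[:, c]
        nongap = col < 20
        if not nongap.any():
            flagged.append(positions[i])
            continue
        wc = w[nongap]
        p = np.bincount(col[nongap], weights=wc, minlength=20)[:20]
        p = p / p.sum()
        m = 0.5 * (p + background)
        jsd = 0.5 * np.sum(p * np.log2((p + eps) / (m + eps))) \
            + 0.5 * np.sum(background * np.log2((background + eps) / (m + eps)))
        scores[i] = jsd

    valid = ~np.isnan(scores)
    grades = np.zeros(len(cols), dtype=int)
    if valid.any():
        edges = np.quantile(scores[valid], np.arange(1, 9) / 9.0)
        grades[valid] = 1 + np.searchsorted(edges, scores[valid], side="right")
        grades[valid] = np.clip(grades[valid], 1, 9)
    return ConservationGrades(positions=positions, scores=scores, grades=grades,
                              flagged=flagged)


# ---------------------------------------------------------------------------
# Motif matching and logos
# ---------------------------------------------------------------------------

def motif_match(sequence: str, pattern: str) -> list[tuple[int, int]]:
    """All matches of a residue-class pattern, 1-based inclusive.

    Uppercase letters match literally; ``h`` matches any hydrophobic residue
    {A,V,L,I,P,W,F,M} (as in the channel-family signature TYhhhhhQF);
    ``x`` matches any residue.
    """
    if not pattern:
        raise AlignmentError("empty pattern")
    parts = []
    for ch in pattern:
        if ch == "h":
            parts.append("[" + "".join(sorted(_HYDROPHOBIC)) + "]")
        elif ch == "x":
            parts.append("[A-Z]")
        elif ch.isupper() and ch in AA_INDEX:
            parts.append(ch)
        else:
            raise AlignmentError(f"unknown pattern symbol {ch!r}")
    rx = re.compile("(?=(" + "".join(parts) + "))")
    seq = sequence.upper().replace(GAP, "")
    m = len(pattern)
    return [(mo.start() + 1, mo.start() + m) for mo in rx.finditer(seq)]


def logo_data(profile: ColumnProfile) -> pd.DataFrame:
    """Per-position letter heights (information content x frequency) in bits.

    Information content is log2(20) − H(column) over the non-gap
    distribution, without a small-sample correction; total column height is
    therefore bounded by log2(20).  The colour for each letter follows the
    4-class logo scheme in :data:`LOGO_CLASSES`.
    """
    freq = profile.frequencies(denominator="nongap")[list(AA_ORDER)].to_numpy()
    eps = 1e-12
    H = -np.nansum(freq * np.log2(freq + eps), axis=1)
    ic = np.maximum(np.log2(20.0) - H, 0.0)
    heights = freq * ic[:, None]
    df = pd.DataFrame(heights, index=profile.positions, columns=list(AA_ORDER))
    df.attrs["colors"] = {a: LOGO_COLORS[cls] for cls, members in LOGO_CLASSES.items()
                          for a in members}
    return df
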