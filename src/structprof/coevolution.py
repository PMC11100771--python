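"""Column-pair covariation scoring and contact-map evaluation.

The coupling statistic is mutual information over 21 states (20 amino acids
plus gap) with sequence redundancy reweighting (80 % identity clusters), a
small pseudocount, and the average-product correction (APC)

    score(i, j) = MI(i, j) − MI(i, ·) MI(·, j) / MI(·, ·)

which removes the phylogenetic/entropic background that inflates raw MI.
Columns with more than half gaps are excluded.  The intended claims are
enrichment properties — strongly covarying column pairs are enriched for
spatial contacts on the reference structure — evaluated against a Cα
contact map (8 Å by convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import ContactMap
from .seqprofile import AlignmentError, AnnotatedAlignment, sequence_weights

log = logging.getLogger("structprof")

__all__ = ["CouplingScores", "coupling_scores", "top_pairs", "contact_precision"]


@dataclass
class CouplingScores:
    """Symmetric column-pair scores; diagonal and excluded columns are NaN."""

    scores: np.ndarray             # (L, L) over all alignment columns
    columns: np.ndarray            # indices of the columns actually scored
    ref_positions: list            # per alignment column: resnum or None
    weights: np.ndarray            # per-sequence redundancy weights
    method: str = "MI-APC"

    @property
    def n_effective(self) -> float:
        return float(self.weights.sum())


def coupling_scores(aln: AnnotatedAlignment, reweight_identity: float = 0.8,
                    pseudocount: float | None = None,
                    max_gap_fraction: float = 0.5,
                    min_effective: float = 50.0) -> CouplingScores:
    """MI-APC coupling scores between alignment columns.

    ``pseudocount`` defaults to 0.5/n_eff per joint-count cell.  Duplicated
    sequences do not change the scores (they share a redundancy cluster).
    """
    mat = aln.matrix()              # (n, L), states 0..20
    n, L = mat.shape
    w = sequence_weights(aln, identity=reweight_identity)
    n_eff = float(w.sum())
    if n_eff < min_effective:
        raise AlignmentError(f"only {n_eff:.1f} effective sequences (< {min_effective})")
    lam = 0.5 / n_eff if pseudocount is None else pseudocount

    gap_frac = (mat == 20).mean(axis=0)
    keep = np.flatnonzero(gap_frac <= max_gap_fraction)
    K = len(keep)

    # weighted one-hot: (n, K*21)
    onehot = np.zeros((n, K * 21), dtype=np.float32)
    sub = mat[:, keep]
    rows = np.repeat(np.arange(n), K)
    cols = (np.tile(np.arange(K), n) * 21 + sub.ravel())
    onehot[rows, cols] = 1.0
    weighted = onehot * w[:, None].astype(np.float32)

    norm = n_eff + lam * 21 * 21
    mi = np.zeros((K, K))
    logs = np.log
    # marginals with matching smoothing
    marg = weighted.reshape(n, K, 21).sum(axis=0).astype(float)   # (K, 21)
    p_marg = (marg + lam * 21) / norm
    chunk = 64
    for a0 in range(0, K, chunk):
        a1 = min(a0 + chunk, K)
        block = weighted[:, a0 * 21:a1 * 21].T @ onehot            # (ca*21, K*21)
        cb = block.reshape(a1 - a0, 21, K, 21).astype(float)
        pj = (cb + lam) / norm                                     # joint probs
        outer = np.einsum("ax,ky->axky", p_marg[a0:a1], p_marg)
        mi_block = (pj * (logs(pj) - logs(outer))).sum(axis=(1, 3))
        mi[a0:a1] = mi_block
    np.fill_diagonal(mi, 0.0)
    mi = 0.5 * (mi + mi.T)
    mi = np.maximum(mi, 0.0)

    # average-product correction over off-diagonal entries
    row_mean = (mi.sum(axis=1) - np.diag(mi)) / max(K - 1, 1)
    total_mean = mi[~np.eye(K, dtype=bool)].mean() if K > 1 else 1.0
    apc = np.outer(row_mean, row_mean) / total_mean if total_mean > 0 else 0.0
    corrected = mi - apc
    np.fill_diagonal(corrected, np.nan)

    full = np.full((L, L), np.nan)
    full[np.ix_(keep, keep)] = corrected
    return CouplingScores(scores=full, columns=keep,
                          ref_positions=list(aln.colmap), weights=w)


def top_pairs(scores: CouplingScores, k: int | None = None,
              percentile: float | None = None,
              min_separation: int = 5) -> pd.DataFrame:
    """Ranked column pairs mapped to reference residue numbers.

    Pairs of columns closer than ``min_separation`` are excluded (trivial
    neighbour correlations).  Pairs where either column does not map to a
    reference residue keep ``NaN`` in the ref columns.
    """
    S = scores.scores
    L = S.shape[0]
    iu = np.triu_indices(L, 1)
    vals = S[iu]
    ok = np.isfinite(vals) & (np.abs(iu[0] - iu[1]) >= min_separation)
    order = np.argsort(vals[ok])[::-1]
    ii, jj, vv = iu[0][ok][order], iu[1][ok][order], vals[ok][order]
    if percentile is not None:
        thr = np.percentile(vv, percentile)
        sel = vv >= thr
        ii, jj, vv = ii[sel], jj[sel], vv[sel]
    if k is not None:
        ii, jj, vv = ii[:k], jj[:k], vv[:k]
    refs = scores.ref_positions
    return pd.DataFrame({
        "col_i": ii, "col_j": jj,
        "ref_i": [refs[i] if refs[i] is not None else np.nan for i in ii],
        "ref_j": [refs[j] if refs[j] is not None else np.nan for j in jj],
        "score": vv,
    })


def contact_precision(pairs: pd.DataFrame, cmap: ContactMap,
                      n_top: int | None = None) -> float:
    """Fraction of the top pairs that are contacts on the map.

    Pairs are matched to the map by residue number (single-chain maps);
    unmappable pairs are skipped and counted in the log.
    """
    index = {}
    for idx, (chain, resnum) in enumerate(cmap.residue_labels):
        index.setdefault(resnum, idx)
    sel = pairs if n_top is None else pairs.head(n_top)
    hits = total = skipped = 0
    for _, row in sel.iterrows():
        ri, rj = row["ref_i"], row["ref_j"]
        if not (np.isfinite(ri) and np.isfinite(rj)):
            skipped += 1
            continue
        ia, ib = index.get(int(ri)), index.get(int(rj))
        if ia is None or ib is None:
            skipped += 1
            continue
        total += 1
        if cmap.contacts[ia, ib]:
            hits += 1
    if skipped:
        log.warning("contact_precision: %d pairs could not be mapped", skipped)
    return hits / total if total else float("nan")
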