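"""Similarity-profile screening and the structural baseline.

A library compound's screening score is the maximum cosine similarity
between its bioactivity-profile fingerprint and any one reference
fingerprint (1-nearest-neighbour search). The library is ranked by that
score and the top-k compounds are reported. A hashed Morgan bit
fingerprint with Tanimoto similarity serves as the purely structural
baseline for judging scaffold hopping: a hit whose profile similarity
is high while its structural similarity to every reference is low has
been retrieved across a scaffold boundary.

Ties are broken deterministically: among references, by lexicographically
smallest reference id; in the ranking, by ascending compound id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import DataStructs
from rdkit.Chem import rdFingerprintGenerator

from .chem_io import Compound, FingerprintMatrix
from .cgbfp import CGBFP

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreenHit:
    compound_id: str
    cgbsp_score: float
    nearest_reference_id: str
    rank: int


@dataclass(frozen=True)
class ProfileComparison:
    """Profile vs structural similarity for one hit/reference pair."""

    hit_id: str
    reference_id: str
    cgbsp_score: float
    morgan_tanimoto: float


def cosine(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine similarity dot(a,b)/(|a||b|); in [0,1] for nonnegative inputs.

    A zero-norm vector (a degenerate all-zero profile) scores 0 with a
    logged warning rather than raising mid-screen.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        logger.warning("cosine: zero-norm vector, returning 0")
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def _check_same_panel(query: CGBFP, refs: Sequence[CGBFP]) -> None:
    for r in refs:
        if r.panel.target_ids != query.panel.target_ids:
            raise ValueError(
                f"panel mismatch between query {query.compound_id} and reference {r.compound_id}"
            )


def nn_score(query: CGBFP, refs: Sequence[CGBFP]) -> tuple[float, str]:
    """Maximum cosine over the references (1-NN) and the winning reference.

    Ties go to the lexicographically smallest reference id.
    """
    if not refs:
        raise ValueError("at least one reference is required")
    _check_same_panel(query, refs)
    best_score, best_id = -np.inf, ""
    for r in sorted(refs, key=lambda r: r.compound_id):
        s = cosine(query.values, r.values)
        if s > best_score:
            best_score, best_id = s, r.compound_id
    return best_score, best_id


def rank_library(
    library: FingerprintMatrix,
    refs: Sequence[CGBFP],
    top_k: int = 40,
) -> list[ScreenHit]:
    """Score the whole library by 1-NN cosine and return the top_k hits.

    Scoring is vectorized over the precomputed fingerprint matrix. Sort
    order is score descending, then compound id ascending; ranks are
    contiguous from 1. ``top_k`` larger than the library returns the
    whole ranking with a warning.
    """
    if not refs:
        raise ValueError("at least one reference is required")
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    ref_sorted = sorted(refs, key=lambda r: r.compound_id)
    for r in ref_sorted:
        if tuple(library.col_ids) != r.panel.target_ids:
            raise ValueError(
                f"panel mismatch between library matrix and reference {r.compound_id}"
            )

    L = library.values
    R = np.vstack([r.values for r in ref_sorted])
    l_norm = np.linalg.norm(L, axis=1)
    r_norm = np.linalg.norm(R, axis=1)
    n_zero = int(np.sum(l_norm == 0)) + int(np.sum(r_norm == 0))
    if n_zero:
        logger.warning("rank_library: %d zero-norm fingerprint(s) score 0", n_zero)
    sims = (L @ R.T) / np.outer(np.where(l_norm == 0, 1.0, l_norm),
                                np.where(r_norm == 0, 1.0, r_norm))
    sims[l_norm == 0, :] = 0.0
    sims[:, r_norm == 0] = 0.0

    best = sims.max(axis=1)
    # first max along sorted references = lexicographically smallest winner
    best_ref = np.argmax(sims, axis=1)

    if top_k > len(library.row_ids):
        logger.warning(
            "top_k=%d exceeds library size %d; returning all", top_k, len(library.row_ids)
        )
        top_k = len(library.row_ids)

    order = sorted(range(len(best)), key=lambda i: (-best[i], library.row_ids[i]))
    hits = [
        ScreenHit(
            compound_id=library.row_ids[i],
            cgbsp_score=float(best[i]),
            nearest_reference_id=ref_sorted[best_ref[i]].compound_id,
            rank=rank,
        )
        for rank, i in enumerate(order[:top_k], start=1)
    ]
    return hits


def write_hits(hits: Sequence[ScreenHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("rank\tcompound_id\tcgbsp_score\tnearest_reference\n")
        for h in hits:
            fh.write(f"{h.rank}\t{h.compound_id}\t{h.cgbsp_score:.6f}\t{h.nearest_reference_id}\n")


# ---------------------------------------------------------------------------
# structural baseline

_BIT_GENERATORS: dict[tuple[int, int], object] = {}


def morgan_fingerprint(c: Compound, radius: int = 2, n_bits: int = 2048):
    """Hashed circular-substructure bit fingerprint (ECFP analogue)."""
    key = (radius, n_bits)
    if key not in _BIT_GENERATORS:
        _BIT_GENERATORS[key] = rdFingerprintGenerator.GetMorganGenerator(
            radius=radius, fpSize=n_bits
        )
    return _BIT_GENERATORS[key].GetFingerprint(c.mol())


def tanimoto(a, b) -> float:
    """Tanimoto coefficient |a&b|/|a|b|; two empty bitsets score 0."""
    if a.GetNumOnBits() == 0 and b.GetNumOnBits() == 0:
        return 0.0
    return float(DataStructs.TanimotoSimilarity(a, b))


def compare_profiles(
    hit: Compound,
    hit_fp: CGBFP,
    ref: Compound,
    ref_fp: CGBFP,
    radius: int = 2,
    n_bits: int = 2048,
) -> ProfileComparison:
    """Bundle profile cosine and Morgan/Tanimoto for a hit/reference pair."""
    _check_same_panel(hit_fp, [ref_fp])
    return ProfileComparison(
        hit_id=hit.id,
        reference_id=ref.id,
        cgbsp_score=cosine(hit_fp.values, ref_fp.values),
        morgan_tanimoto=tanimoto(
            morgan_fingerprint(hit, radius, n_bits), morgan_fingerprint(ref, radius, n_bits)
        ),
    )


def plot_profile_comparison(
    comparison: ProfileComparison, hit_fp: CGBFP, ref_fp: CGBFP, path: str | Path
) -> None:
    """Overlay the two binding-probability profiles (one panel target per x)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.arange(len(hit_fp.values))
    fig, ax = plt.subplots(figsize=(10, 3))
    ax.plot(x, ref_fp.values, lw=0.8, label=f"reference {comparison.reference_id}")
    ax.plot(x, hit_fp.values, lw=0.8, label=f"hit {comparison.hit_id}")
    ax.set_xlabel("panel target index")
    ax.set_ylabel("binding probability score")
    ax.set_ylim(0, 1)
    ax.set_title(
        f"profile cosine {comparison.cgbsp_score:.2f}, "
        f"Morgan/Tanimoto {comparison.morgan_tanimoto:.2f}"
    )
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def mean_structural_similarity(
    ref: Compound, library: Sequence[Compound], radius: int = 2, n_bits: int = 2048
) -> float:
    """Mean Tanimoto of the reference against every library compound."""
    if not library:
        raise ValueError("library is empty")
    rfp = morgan_fingerprint(ref, radius, n_bits)
    fps = [morgan_fingerprint(c, radius, n_bits) for c in library]
    sims = DataStructs.BulkTanimotoSimilarity(rfp, fps)
    return float(np.mean(sims))
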