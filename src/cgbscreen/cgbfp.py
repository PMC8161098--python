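"""Bioactivity-profile fingerprints from predicted compound-protein scores.

A compound's fingerprint is the vector of SVM binding probability
scores against an eligible *target panel*: one component per retained
target, each in [0, 1]. Panel eligibility mirrors training-data volume
— only targets with at least ``min_count`` positive training pairs are
retained, because scores for sparsely trained targets are unreliable.
Panel order is lexicographic by target id and is serialized with every
matrix, so cosine comparisons between fingerprints are always aligned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .chem_io import Compound, CPIRecord, FingerprintMatrix, ProteinTarget
from .cpi_model import CPIModel, predict_score
from .descriptors import DescriptorVector

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TargetPanel:
    """Ordered target ids defining fingerprint components."""

    target_ids: tuple[str, ...]
    positive_counts: dict[str, int]
    min_count: int

    def __len__(self) -> int:
        return len(self.target_ids)


@dataclass(frozen=True)
class CGBFP:
    """One compound's binding-probability profile over a target panel."""

    compound_id: str
    panel: TargetPanel
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (len(self.panel),):
            raise ValueError(
                f"{self.compound_id}: profile length {v.shape} != panel size {len(self.panel)}"
            )
        if v.size and (v.min() < 0 or v.max() > 1):
            raise ValueError(f"{self.compound_id}: scores outside [0, 1]")


def build_panel(records: Sequence[CPIRecord], min_count: int = 100) -> TargetPanel:
    """Retain targets with >= ``min_count`` positive (binding) records.

    Only positives are counted: negatives are typically synthesized at a
    configurable ratio, so counting them would make panel eligibility
    depend on the sampling ratio rather than on curated data volume.
    Panel order is lexicographic by target id.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    counts: dict[str, int] = {}
    for r in records:
        if r.label == 1:
            counts[r.target_id] = counts.get(r.target_id, 0) + 1
    kept = sorted(t for t, n in counts.items() if n >= min_count)
    if not kept:
        raise ValueError(
            f"no target has >= {min_count} positive records; lower min_count "
            f"(max observed: {max(counts.values(), default=0)})"
        )
    return TargetPanel(
        target_ids=tuple(kept),
        positive_counts={t: counts[t] for t in kept},
        min_count=min_count,
    )


def save_panel(panel: TargetPanel, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# min_count={panel.min_count}\n")
        fh.write("target_id\tn_pos\n")
        for t in panel.target_ids:
            fh.write(f"{t}\t{panel.positive_counts[t]}\n")


def load_panel(path: str | Path) -> TargetPanel:
    lines = Path(path).read_text().splitlines()
    min_count = int(lines[0].split("=", 1)[1])
    ids, counts = [], {}
    for ln in lines[2:]:
        t, n = ln.split("\t")
        ids.append(t)
        counts[t] = int(n)
    return TargetPanel(tuple(ids), counts, min_count)


def _panel_targets(
    panel: TargetPanel, targets: Sequence[ProteinTarget]
) -> list[ProteinTarget]:
    by_id = {t.id: t for t in targets}
    missing = [t for t in panel.target_ids if t not in by_id]
    if missing:
        raise ValueError(f"panel target(s) missing from collection: {missing[:5]}")
    return [by_id[t] for t in panel.target_ids]


def fingerprint(
    m: CPIModel, c: Compound, panel: TargetPanel, targets: Sequence[ProteinTarget]
) -> CGBFP:
    """Profile one compound: component i = predicted score against panel[i]."""
    ordered = _panel_targets(panel, targets)
    values = np.array([predict_score(m, c, t).value for t in ordered])
    return CGBFP(compound_id=c.id, panel=panel, values=values)


def _rbf_batch_scores(
    m: CPIModel,
    cvals: np.ndarray,  # (n_compounds, d_c) raw compound descriptors
    pvals: np.ndarray,  # (n_targets, d_p) raw protein descriptors
) -> np.ndarray:
    """Score every compound x target pair through the calibrated RBF SVM.

    The RBF kernel over a concatenated pair vector factorizes over the
    blocks: ||z - sv||^2 = ||c - sv_c||^2 + ||p - sv_p||^2, so
    K(z, sv) = exp(-g||c - sv_c||^2) * exp(-g||p - sv_p||^2) and the
    whole decision-value grid is one matrix product. This is exactly the
    per-pair computation, just evaluated with BLAS.
    """
    calibrated = m.classifier.calibrated_classifiers_[0]
    svc = calibrated.estimator
    calibrator = calibrated.calibrators[0]
    gamma = svc._gamma
    d_c = cvals.shape[1]

    # the per-dimension affine scaler splits over the two blocks
    mean = getattr(m.scaler, "mean_", None)
    if mean is None:
        mean = np.zeros(m.scaler.scale_.shape)
    scale = m.scaler.scale_
    Cs = (cvals - mean[:d_c]) / scale[:d_c]
    Ps = (pvals - mean[d_c:]) / scale[d_c:]
    SVc = svc.support_vectors_[:, :d_c]
    SVp = svc.support_vectors_[:, d_c:]

    def sqdist(A: np.ndarray, B: np.ndarray) -> np.ndarray:
        aa = np.einsum("ij,ij->i", A, A)[:, None]
        bb = np.einsum("ij,ij->i", B, B)[None, :]
        return np.maximum(aa + bb - 2.0 * (A @ B.T), 0.0)

    Ec = np.exp(-gamma * sqdist(Cs, SVc))  # (n_c, n_sv)
    Ep = np.exp(-gamma * sqdist(Ps, SVp))  # (n_p, n_sv)
    dual = svc.dual_coef_[0]
    decision = (Ec * dual) @ Ep.T + svc.intercept_[0]  # (n_c, n_p)
    # Platt sigmoid calibration of the decision value for the positive class
    prob_pos = calibrator.predict(decision.ravel()).reshape(decision.shape)
    if m.classifier.classes_[1] != 1:  # calibrator models classes_[1]
        prob_pos = 1.0 - prob_pos
    return np.clip(prob_pos, 0.0, 1.0)


def fingerprint_batch(
    m: CPIModel,
    compounds: Sequence[Compound],
    panel: TargetPanel,
    targets: Sequence[ProteinTarget],
    n_workers: int = 1,
    descriptor_cache: Mapping[str, DescriptorVector] | None = None,
) -> FingerprintMatrix:
    """Profile a compound library against the panel.

    Row order follows input order; results are identical to per-compound
    :func:`fingerprint` calls and independent of ``n_workers`` (the
    worker count controls BLAS chunking only). Compounds whose
    descriptors fail are dropped with a logged warning.
    """
    ordered_targets = _panel_targets(panel, targets)

    kept: list[Compound] = []
    crows: list[np.ndarray] = []
    for c in compounds:
        try:
            if descriptor_cache is not None and c.id in descriptor_cache:
                cd = descriptor_cache[c.id]
            else:
                from .descriptors import compound_descriptor

                cd = compound_descriptor(c, m.compound_schema)
            if cd.schema_id != m.compound_schema.schema_id:
                raise ValueError(f"schema mismatch for {c.id}")
            kept.append(c)
            crows.append(cd.values)
        except ValueError as exc:
            logger.warning("dropping compound %s: %s", c.id, exc)
    if len(kept) < len(compounds):
        logger.warning(
            "fingerprint_batch: %d/%d compounds dropped",
            len(compounds) - len(kept),
            len(compounds),
        )
    if not kept:
        raise ValueError("no compounds could be profiled")

    cvals = np.vstack(crows)
    from .descriptors import protein_descriptor

    pvals = np.vstack(
        [protein_descriptor(t, m.protein_schema).values for t in ordered_targets]
    )

    if m.manifest.hyperparams.get("kernel", "rbf") == "rbf":
        chunk = max(1, len(kept) // max(1, n_workers) if len(kept) > 4096 else len(kept))
        blocks = [
            _rbf_batch_scores(m, cvals[i : i + chunk], pvals)
            for i in range(0, len(kept), chunk)
        ]
        scores = np.vstack(blocks)
    else:  # generic kernels: evaluate pair by pair through the model
        n_c, n_p = len(kept), len(ordered_targets)
        X = np.empty((n_c * n_p, cvals.shape[1] + pvals.shape[1]))
        for i in range(n_c):
            for j in range(n_p):
                X[i * n_p + j] = np.concatenate([cvals[i], pvals[j]])
        scores = m.score_matrix_rows(X).reshape(n_c, n_p)

    logger.info("profiled %d compounds x %d targets", scores.shape[0], scores.shape[1])
    return FingerprintMatrix(
        row_ids=[c.id for c in kept],
        col_ids=list(panel.target_ids),
        values=scores,
    )
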