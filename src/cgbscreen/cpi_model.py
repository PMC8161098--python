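"""Compound-protein interaction (CPI) classifier.

A compound-protein pair is represented by the concatenation of its
compound descriptor and protein descriptor (compound block first). A
kernel SVM trained on binding / non-binding pairs then yields a
*binding probability score* in [0, 1] for any pair; scores >= 0.5 are
read as predicted binding. The probability semantics come from Platt
sigmoid calibration of the SVM margin, fitted on internal
cross-validation folds fixed by the training seed.

Negative (non-binding) training pairs are usually not curated, so
:func:`sample_negative_pairs` draws them uniformly from the complement
of the positive pair set. The sampling ratio is the main lever
affecting score calibration and is recorded in the model manifest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import MaxAbsScaler
from sklearn.svm import SVC

from .chem_io import Compound, CPIRecord, ProteinTarget
from .descriptors import (
    CompoundSchema,
    DescriptorVector,
    ProteinSchema,
    compound_descriptor,
    protein_descriptor,
)

logger = logging.getLogger(__name__)

_MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class InteractionVector:
    compound_id: str
    target_id: str
    values: np.ndarray


@dataclass(frozen=True)
class BindingScore:
    """A binding probability score; >= 0.5 means predicted binding."""

    value: float
    positive: bool

    @classmethod
    def from_value(cls, value: float) -> "BindingScore":
        return cls(value=float(value), positive=bool(value >= 0.5))


@dataclass
class Hyperparams:
    """SVM and negative-sampling configuration.

    Descriptor blocks are max-abs scaled per dimension before the
    kernel (bounded inputs without destroying count-fingerprint
    sparsity); ``gamma`` is expressed on that scaled space.
    """

    kernel: str = "rbf"
    C: float = 10.0
    gamma: str | float = 0.01
    negative_ratio: float = 1.0
    calibration_folds: int = 3
    class_weight: str | None = "balanced"
    cache_size: float = 500.0
    tol: float = 1e-3


def make_interaction_vector(
    cd: DescriptorVector, pd_: DescriptorVector
) -> InteractionVector:
    """Concatenate compound and protein descriptors, compound block first."""
    if cd.kind != "compound" or pd_.kind != "protein":
        raise ValueError(
            f"expected (compound, protein) descriptors, got ({cd.kind}, {pd_.kind})"
        )
    return InteractionVector(
        compound_id=cd.owner_id,
        target_id=pd_.owner_id,
        values=np.concatenate([cd.values, pd_.values]),
    )


def sample_negative_pairs(
    positives: Sequence[CPIRecord],
    compounds: Sequence[Compound],
    targets: Sequence[ProteinTarget],
    ratio: float = 1.0,
    seed: int = 0,
) -> list[CPIRecord]:
    """Draw non-binding pairs uniformly from the non-positive pair universe.

    Samples ``round(ratio * n_pos)`` (compound, target) pairs without
    replacement, excluding every pair present in ``positives`` (any
    label). Reproducible for a given seed.
    """
    if ratio <= 0:
        raise ValueError("ratio must be > 0")
    pos_keys = {(r.compound_id, r.target_id) for r in positives}
    n_pos = sum(r.label == 1 for r in positives)
    n_wanted = round(ratio * n_pos)
    n_universe = len(compounds) * len(targets)
    n_available = n_universe - len(pos_keys)
    if n_wanted > n_available:
        raise ValueError(
            f"requested {n_wanted} negatives but only {n_available} non-positive pairs exist"
        )
    rng = np.random.default_rng(seed)
    n_t = len(targets)
    chosen: list[CPIRecord] = []
    seen: set[int] = set()
    # rejection sampling over the flat pair index; the positive set is a
    # vanishing fraction of the universe in realistic inputs, and the dense
    # fallback below covers the adversarial case.
    if n_available > 4 * n_wanted:
        while len(chosen) < n_wanted:
            idx = int(rng.integers(0, n_universe))
            if idx in seen:
                continue
            ci, ti = divmod(idx, n_t)
            key = (compounds[ci].id, targets[ti].id)
            if key in pos_keys:
                continue
            seen.add(idx)
            chosen.append(CPIRecord(key[0], key[1], 0))
    else:
        all_free = [
            (c.id, t.id) for c in compounds for t in targets if (c.id, t.id) not in pos_keys
        ]
        picks = rng.choice(len(all_free), size=n_wanted, replace=False)
        chosen = [CPIRecord(*all_free[i], 0) for i in sorted(picks)]
    return chosen


@dataclass
class TrainingManifest:
    n_pos: int
    n_neg: int
    per_target_pos: dict[str, int]
    hyperparams: dict
    seed: int
    compound_schema_id: str
    protein_schema_id: str


@dataclass
class CPIModel:
    """A trained, calibrated CPI classifier with its descriptor schemas."""

    scaler: MaxAbsScaler
    classifier: CalibratedClassifierCV
    compound_schema: CompoundSchema
    protein_schema: ProteinSchema
    manifest: TrainingManifest
    _pos_index: int = field(default=-1)

    def __post_init__(self) -> None:
        classes = list(self.classifier.classes_)
        self._pos_index = classes.index(1)

    # -- internals shared with the batch fingerprint path -------------------

    def _check_schemas(self, cd: DescriptorVector, pd_: DescriptorVector) -> None:
        if cd.schema_id != self.compound_schema.schema_id:
            raise ValueError(
                f"compound schema mismatch: {cd.schema_id} != {self.compound_schema.schema_id}"
            )
        if pd_.schema_id != self.protein_schema.schema_id:
            raise ValueError(
                f"protein schema mismatch: {pd_.schema_id} != {self.protein_schema.schema_id}"
            )

    def score_matrix_rows(self, X: np.ndarray) -> np.ndarray:
        """Binding probabilities for rows of raw interaction vectors."""
        Xs = self.scaler.transform(X)
        return self.classifier.predict_proba(Xs)[:, self._pos_index]

    def predict_score_vec(self, iv: InteractionVector) -> BindingScore:
        value = self.score_matrix_rows(iv.values[None, :])[0]
        return BindingScore.from_value(value)


def _build_design_matrix(
    records: Sequence[CPIRecord],
    cdescs: Mapping[str, DescriptorVector],
    pdescs: Mapping[str, DescriptorVector],
) -> tuple[np.ndarray, np.ndarray]:
    d = len(next(iter(cdescs.values())).values) + len(next(iter(pdescs.values())).values)
    X = np.empty((len(records), d))
    y = np.empty(len(records), dtype=int)
    for i, r in enumerate(records):
        iv = make_interaction_vector(cdescs[r.compound_id], pdescs[r.target_id])
        X[i] = iv.values
        y[i] = r.label
    return X, y


def compute_descriptors(
    compounds: Sequence[Compound],
    targets: Sequence[ProteinTarget],
    compound_schema: CompoundSchema,
    protein_schema: ProteinSchema,
) -> tuple[dict[str, DescriptorVector], dict[str, DescriptorVector]]:
    cdescs = {c.id: compound_descriptor(c, compound_schema) for c in compounds}
    pdescs = {t.id: protein_descriptor(t, protein_schema) for t in targets}
    return cdescs, pdescs


def train(
    records: Sequence[CPIRecord],
    compounds: Sequence[Compound],
    targets: Sequence[ProteinTarget],
    hyperparams: Hyperparams | None = None,
    seed: int = 0,
    compound_schema: CompoundSchema | None = None,
    protein_schema: ProteinSchema | None = None,
    descriptors: tuple[Mapping[str, DescriptorVector], Mapping[str, DescriptorVector]]
    | None = None,
) -> CPIModel:
    """Fit the calibrated kernel SVM on labelled CPI records.

    ``records`` must contain both classes and every id must resolve
    against ``compounds`` / ``targets``. Features are standardized
    per-dimension on the training data; the scaler is stored in the
    model. Pass ``descriptors`` to reuse precomputed descriptor caches.
    """
    hp = hyperparams or Hyperparams()
    compound_schema = compound_schema or CompoundSchema()
    protein_schema = protein_schema or ProteinSchema()

    labels = {r.label for r in records}
    if labels != {0, 1}:
        raise ValueError(f"training needs both classes, got labels {sorted(labels)}")

    known_c = {c.id for c in compounds}
    known_t = {t.id for t in targets}
    for r in records:
        if r.compound_id not in known_c:
            raise ValueError(f"unknown compound id {r.compound_id!r}")
        if r.target_id not in known_t:
            raise ValueError(f"unknown target id {r.target_id!r}")

    if descriptors is None:
        used_c = {r.compound_id for r in records}
        used_t = {r.target_id for r in records}
        cdescs, pdescs = compute_descriptors(
            [c for c in compounds if c.id in used_c],
            [t for t in targets if t.id in used_t],
            compound_schema,
            protein_schema,
        )
    else:
        cdescs, pdescs = descriptors

    X, y = _build_design_matrix(records, cdescs, pdescs)
    scaler = MaxAbsScaler().fit(X)
    Xs = scaler.transform(X)

    svc = SVC(
        kernel=hp.kernel,
        C=hp.C,
        gamma=hp.gamma,
        class_weight=hp.class_weight,
        cache_size=hp.cache_size,
        tol=hp.tol,
        random_state=seed,
    )
    cv = StratifiedKFold(n_splits=hp.calibration_folds, shuffle=True, random_state=seed)
    clf = CalibratedClassifierCV(svc, method="sigmoid", cv=cv, ensemble=False)
    clf.fit(Xs, y)

    per_target = {}
    for r in records:
        if r.label == 1:
            per_target[r.target_id] = per_target.get(r.target_id, 0) + 1
    manifest = TrainingManifest(
        n_pos=int(np.sum(y == 1)),
        n_neg=int(np.sum(y == 0)),
        per_target_pos=dict(sorted(per_target.items())),
        hyperparams=vars(hp).copy(),
        seed=seed,
        compound_schema_id=compound_schema.schema_id,
        protein_schema_id=protein_schema.schema_id,
    )
    logger.info(
        "trained CPI model: %d pos / %d neg, %d targets",
        manifest.n_pos,
        manifest.n_neg,
        len(per_target),
    )
    return CPIModel(
        scaler=scaler,
        classifier=clf,
        compound_schema=compound_schema,
        protein_schema=protein_schema,
        manifest=manifest,
    )


def predict_score(m: CPIModel, c: Compound, t: ProteinTarget) -> BindingScore:
    """Binding probability score for one compound-target pair."""
    cd = compound_descriptor(c, m.compound_schema)
    pd_ = protein_descriptor(t, m.protein_schema)
    m._check_schemas(cd, pd_)
    return m.predict_score_vec(make_interaction_vector(cd, pd_))


def save_model(m: CPIModel, path: str | Path) -> None:
    """Persist the model as a single versioned joblib archive."""
    joblib.dump({"format_version": _MODEL_FORMAT_VERSION, "model": m}, path)


def load_model(path: str | Path) -> CPIModel:
    payload = joblib.load(path)
    version = payload.get("format_version")
    if version != _MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {version!r}")
    return payload["model"]
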